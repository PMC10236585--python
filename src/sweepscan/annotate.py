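"""Genomic region classification and coding-consequence calling.

Variants are assigned exactly one region class with precedence
exonic > splicing > intronic > upstream/downstream > upstream >
downstream > intergenic. "Upstream"/"downstream" mean the 1 kb flanks of
the gene start/end in genomic orientation; "splicing" means within 2 bp of
a splice junction on the intron side (exon-side bases stay exonic);
"upstream/downstream" marks a position that is upstream of one gene and
downstream of another. Exonic variants inside a CDS additionally receive a
codon-level consequence call (synonymous / missense / stop_gain /
stop_loss) when the gene model carries its CDS sequence; UTR-exonic
variants stay "exonic" with no consequence call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from Bio.Seq import Seq

from .genes import GeneModel, GeneModelSet
from .variants import GenotypeTable, VariantRecord

__all__ = ["RegionClass", "ConsequenceCall", "Annotation", "NotCodingError",
           "ReferenceMismatchError", "classify_region", "map_cds_position",
           "genomic_position_for_cds", "call_coding_consequence",
           "annotate_table", "annotation_frame"]

FLANK_BP = 1_000          # upstream/downstream window
SPLICE_BP = 2             # intron-side distance defining "splicing"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class RegionClass(str, Enum):
    UPSTREAM = "upstream"
    EXONIC = "exonic"
    INTRONIC = "intronic"
    SPLICING = "splicing"
    DOWNSTREAM = "downstream"
    UPSTREAM_DOWNSTREAM = "upstream/downstream"
    INTERGENIC = "intergenic"


class NotCodingError(ValueError):
    """Position does not fall in any CDS segment of the gene."""


class ReferenceMismatchError(ValueError):
    """Supplied reference base disagrees with the gene's CDS sequence."""


@dataclass(frozen=True)
class ConsequenceCall:
    gene_id: str
    cds_position: int       # 1-based within the spliced CDS
    codon_index: int        # 1-based codon number
    codon_offset: int       # 1 | 2 | 3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    category: str           # synonymous | missense | stop_gain | stop_loss


@dataclass(frozen=True)
class Annotation:
    chromosome: str
    position: int
    region: RegionClass
    gene_id: str | None = None
    consequence: ConsequenceCall | None = None


def classify_region(variant: VariantRecord, genes: GeneModelSet) -> RegionClass:
    """Assign the single region class of one variant."""
    region, _ = _classify(variant.chromosome, variant.position, genes)
    return region


def _classify(chrom: str, pos: int, genes: GeneModelSet
              ) -> tuple[RegionClass, str | None]:
    gene_list = genes.on_chromosome(chrom)
    if not genes.genes or all(g.chromosome != chrom for g in genes.genes):
        if genes.genes:
            warnings.warn(f"no gene models on chromosome {chrom}; "
                          f"classifying as intergenic", stacklevel=2)
    exonic_gene = splicing_gene = intronic_gene = None
    upstream_gene = downstream_gene = None
    for g in gene_list:
        if g.contains(pos):
            if g.in_exon(pos):
                exonic_gene = exonic_gene or g
            elif _near_junction(pos, g):
                splicing_gene = splicing_gene or g
            else:
                intronic_gene = intronic_gene or g
        elif g.gene_start - FLANK_BP <= pos < g.gene_start:
            upstream_gene = upstream_gene or g
        elif g.gene_end < pos <= g.gene_end + FLANK_BP:
            downstream_gene = downstream_gene or g
    if exonic_gene:
        return RegionClass.EXONIC, exonic_gene.gene_id
    if splicing_gene:
        return RegionClass.SPLICING, splicing_gene.gene_id
    if intronic_gene:
        return RegionClass.INTRONIC, intronic_gene.gene_id
    if upstream_gene and downstream_gene:
        return RegionClass.UPSTREAM_DOWNSTREAM, upstream_gene.gene_id
    if upstream_gene:
        return RegionClass.UPSTREAM, upstream_gene.gene_id
    if downstream_gene:
        return RegionClass.DOWNSTREAM, downstream_gene.gene_id
    return RegionClass.INTERGENIC, None


def _near_junction(pos: int, gene: GeneModel) -> bool:
    """True when ``pos`` lies in an intron within SPLICE_BP of an exon edge."""
    if gene.in_exon(pos):
        return False
    for s, e in gene.exons:
        if 0 < s - pos <= SPLICE_BP or 0 < pos - e <= SPLICE_BP:
            return True
    return False


def map_cds_position(genomic_position: int, gene: GeneModel
                     ) -> tuple[int, int, int]:
    """Map a genomic position into (cds_position, codon_index, codon_offset).

    CDS nucleotides are numbered 1..L in translation order: ascending
    through the segments on the plus strand, descending (rightmost base
    first) on the minus strand. codon_index = ceil(cds_position / 3) and
    codon_offset = ((cds_position - 1) mod 3) + 1.
    """
    if not gene.in_cds(genomic_position):
        raise NotCodingError(
            f"{gene.gene_id}: position {genomic_position} not in CDS")
    cds_pos = 0
    if gene.strand == "+":
        for s, e in gene.cds_segments:
            if genomic_position > e:
                cds_pos += e - s + 1
            else:
                cds_pos += genomic_position - s + 1
                break
    else:
        for s, e in reversed(gene.cds_segments):
            if genomic_position < s:
                cds_pos += e - s + 1
            else:
                cds_pos += e - genomic_position + 1
                break
    codon_index = (cds_pos + 2) // 3
    codon_offset = (cds_pos - 1) % 3 + 1
    return cds_pos, codon_index, codon_offset


def genomic_position_for_cds(gene: GeneModel, cds_position: int) -> int:
    """Inverse of :func:`map_cds_position` (1-based both ways)."""
    if not 1 <= cds_position <= gene.cds_length:
        raise ValueError(f"cds_position {cds_position} outside 1..{gene.cds_length}")
    remaining = cds_position
    if gene.strand == "+":
        for s, e in gene.cds_segments:
            seg_len = e - s + 1
            if remaining <= seg_len:
                return s + remaining - 1
            remaining -= seg_len
    else:
        for s, e in reversed(gene.cds_segments):
            seg_len = e - s + 1
            if remaining <= seg_len:
                return e - remaining + 1
            remaining -= seg_len
    raise AssertionError("unreachable")


def call_coding_consequence(gene: GeneModel, cds_sequence: str,
                            cds_position: int, ref_base: str, alt_base: str
                            ) -> ConsequenceCall:
    """Codon-table consequence of a single-base CDS substitution.

    ``ref_base``/``alt_base`` are on the coding strand. Categories:
    synonymous (amino acid unchanged), stop_gain (non-stop → stop),
    stop_loss (stop → non-stop), otherwise missense.
    """
    if len(cds_sequence) != gene.cds_length:
        raise ValueError(
            f"cds_sequence length {len(cds_sequence)} != CDS length "
            f"{gene.cds_length} of {gene.gene_id}")
    cds_sequence = cds_sequence.upper()
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    if cds_sequence[cds_position - 1] != ref_base:
        raise ReferenceMismatchError(
            f"{gene.gene_id} CDS position {cds_position}: expected "
            f"{cds_sequence[cds_position - 1]}, got ref {ref_base}")
    codon_index = (cds_position + 2) // 3
    codon_offset = (cds_position - 1) % 3 + 1
    ref_codon = cds_sequence[3 * (codon_index - 1):3 * codon_index]
    alt_codon = (ref_codon[:codon_offset - 1] + alt_base
                 + ref_codon[codon_offset:])
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        category = "synonymous"
    elif ref_aa == "*":
        category = "stop_loss"
    elif alt_aa == "*":
        category = "stop_gain"
    else:
        category = "missense"
    return ConsequenceCall(gene.gene_id, cds_position, codon_index,
                           codon_offset, ref_codon, alt_codon, ref_aa,
                           alt_aa, category)


def annotate_table(table: GenotypeTable, genes: GeneModelSet,
                   on_ref_mismatch: str = "warn") -> list[Annotation]:
    """Annotate every variant with its region class and, for CDS SNPs of
    genes that carry a CDS sequence, a consequence call.

    When the VCF reference base disagrees with the gene's CDS sequence the
    consequence is skipped with a warning (``on_ref_mismatch="warn"``) or
    raised (``"error"``).
    """
    out: list[Annotation] = []
    for i in range(table.n_variants):
        chrom = table.chromosomes[i]
        pos = int(table.positions[i])
        region, gene_id = _classify(chrom, pos, genes)
        consequence = None
        if (region is RegionClass.EXONIC and gene_id is not None
                and not table.is_indel[i]):
            gene = genes.by_id(gene_id)
            if gene.in_cds(pos) and gene.cds_sequence is not None:
                ref, alt = table.refs[i], table.alts[i]
                if gene.strand == "-":
                    ref = ref.translate(_COMPLEMENT)
                    alt = alt.translate(_COMPLEMENT)
                cds_pos, _, _ = map_cds_position(pos, gene)
                try:
                    consequence = call_coding_consequence(
                        gene, gene.cds_sequence, cds_pos, ref, alt)
                except ReferenceMismatchError:
                    if on_ref_mismatch == "error":
                        raise
                    warnings.warn(
                        f"{chrom}:{pos}: VCF ref disagrees with CDS of "
                        f"{gene_id}; consequence skipped", stacklevel=2)
        out.append(Annotation(chrom, pos, region, gene_id, consequence))
    return out


def annotation_frame(annotations: list[Annotation]) -> pd.DataFrame:
    """Flatten annotations for TSV export."""
    rows = []
    for a in annotations:
        row = {"chromosome": a.chromosome, "position": a.position,
               "region": a.region.value, "gene_id": a.gene_id or "",
               "category": "", "cds_position": "", "codon_index": "",
               "ref_aa": "", "alt_aa": ""}
        if a.consequence:
            c = a.consequence
            row.update(category=c.category, cds_position=c.cds_position,
                       codon_index=c.codon_index, ref_aa=c.ref_aa,
                       alt_aa=c.alt_aa)
        rows.append(row)
    return pd.DataFrame(rows)
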