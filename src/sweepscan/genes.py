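"""Strand-aware multi-exon gene models and GFF3 I/O.

Coordinates are 1-based inclusive, as in GFF3. A :class:`GeneModel` may
carry its spliced CDS nucleotide sequence (in translation order); gene
models produced by the simulator do, models loaded from a plain GFF3 (no
FASTA) do not, in which case coding-consequence calls are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GeneModel", "GeneModelSet", "read_gff3", "write_gff3"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int], ...]
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        cds = tuple(sorted(tuple(c) for c in self.cds_segments))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds_segments", cds)
        prev_end = 0
        for s, e in exons:
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            if e < s:
                raise ValueError(f"{self.gene_id}: exon end < start")
            prev_end = e
        for cs, ce in cds:
            if not any(s <= cs and ce <= e for s, e in exons):
                raise ValueError(f"{self.gene_id}: CDS segment outside exons")
        if cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")
        if self.cds_sequence is not None and len(self.cds_sequence) != self.cds_length:
            raise ValueError(f"{self.gene_id}: cds_sequence length mismatch")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def contains(self, position: int) -> bool:
        return self.gene_start <= position <= self.gene_end

    def in_exon(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.exons)

    def in_cds(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.cds_segments)


@dataclass
class GeneModelSet:
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes,
                            key=lambda g: (g.chromosome, g.gene_start))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in gene set")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def on_chromosome(self, chromosome: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chromosome == chromosome]


def write_gff3(genes: GeneModelSet, path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chromosome}\tsweepscan"
            fh.write(f"{base}\tgene\t{g.gene_start}\t{g.gene_end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(f"{base}\tmRNA\t{g.gene_start}\t{g.gene_end}\t.\t"
                     f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{base}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna_id}.exon{i};Parent={mrna_id}\n")
            # phase: bases to skip before the first complete codon,
            # accumulated in translation order
            segs = list(g.cds_segments)
            if g.strand == "-":
                segs = segs[::-1]
            consumed = 0
            phases = []
            for s, e in segs:
                phases.append((3 - consumed % 3) % 3)
                consumed += e - s + 1
            if g.strand == "-":
                phases = phases[::-1]
                segs = segs[::-1]
            for (s, e), ph in zip(segs, phases):
                fh.write(f"{base}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\t"
                         f"ID={mrna_id}.cds;Parent={mrna_id}\n")


def read_gff3(path) -> GeneModelSet:
    """Load gene models from GFF3 via gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for child in db.children(gene, featuretype="exon"):
            exons.append((child.start, child.end))
        for child in db.children(gene, featuretype="CDS"):
            cds.append((child.start, child.end))
        models.append(GeneModel(
            gene_id=gene.id, chromosome=gene.seqid, strand=gene.strand,
            gene_start=gene.start, gene_end=gene.end,
            exons=tuple(exons), cds_segments=tuple(cds)))
    return GeneModelSet(models)
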