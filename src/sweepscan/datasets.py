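"""Published summary tables of the three-breed rabbit resequencing cohort.

These are the printed per-sample sequencing/mapping statistics and the
population-scale SNP annotation counts of the 18-rabbit study (6 Angora,
6 New Zealand, 6 Rex; Illumina resequencing against OryCun2.0). They are
inputs for the reporting arithmetic — column totals and means, derived
coding totals, the shared-SNP percentage — not outputs of this package.
"""

from __future__ import annotations

from .enrich import SampleStats

__all__ = ["COHORT_SEQUENCING_SUMMARY_TSV", "load_cohort_sequencing_summary",
           "SNP_ANNOTATION_COUNTS", "POOLED_SNP_COUNTS_MILLIONS",
           "POOLED_SNP_COUNTS"]

COHORT_SEQUENCING_SUMMARY_TSV = """\
sample_id\traw_bases\teffective_rate\tmapped_reads\ttotal_reads\tmapping_rate\taverage_depth\tcoverage_1x
Angora_1\t17119857250\t97.61\t131343732\t133723114\t98.22\t6.29\t97.69
Angora_2\t17425961500\t98.29\t134957371\t137010030\t98.50\t6.46\t97.69
Angora_3\t17574152750\t98.20\t135443645\t137771608\t98.31\t6.48\t97.65
Angora_4\t17258029750\t97.94\t132950495\t135216400\t98.32\t6.36\t97.68
Angora_5\t17370164250\t98.62\t134813390\t136932174\t98.45\t6.43\t98.25
Angora_6\t19624237750\t98.79\t152844924\t155093428\t98.55\t7.28\t98.23
NewZealand_1\t17276228250\t98.04\t133413523\t135650682\t98.35\t6.39\t97.64
NewZealand_2\t18211094500\t98.37\t140666365\t143137310\t98.27\t6.72\t97.94
NewZealand_3\t17840751000\t98.66\t138626184\t140714772\t98.52\t6.61\t98.02
NewZealand_4\t17206992000\t98.58\t133417312\t135597100\t98.39\t6.37\t97.94
NewZealand_5\t16737332250\t98.56\t129490187\t131975650\t98.12\t6.22\t97.51
NewZealand_6\t19740318000\t98.81\t153701118\t156047852\t98.50\t7.32\t98.17
Rex_1\t17600293000\t98.17\t135831383\t138045552\t98.40\t6.51\t97.54
Rex_2\t17661203000\t97.80\t135686374\t138018346\t98.31\t6.50\t97.75
Rex_3\t16627732000\t97.85\t128302425\t130183248\t98.56\t6.15\t97.44
Rex_4\t17415676000\t97.79\t133653166\t136104786\t98.20\t6.39\t97.85
Rex_5\t18661197250\t98.52\t144774198\t147082754\t98.43\t6.88\t98.47
Rex_6\t18735044000\t98.65\t145584115\t147848336\t98.47\t6.91\t98.57
"""


def load_cohort_sequencing_summary() -> list[SampleStats]:
    """The 18 per-sample sequencing summary records."""
    rows = []
    lines = COHORT_SEQUENCING_SUMMARY_TSV.strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        vals = dict(zip(header, line.split("\t")))
        rows.append(SampleStats(
            sample_id=vals["sample_id"],
            raw_bases=int(vals["raw_bases"]),
            effective_rate=float(vals["effective_rate"]),
            mapped_reads=int(vals["mapped_reads"]),
            total_reads=int(vals["total_reads"]),
            mapping_rate=float(vals["mapping_rate"]),
            average_depth=float(vals["average_depth"]),
            coverage_1x=float(vals["coverage_1x"])))
    return rows


# Population-scale SNP annotation counts of the 24.83 M-SNP callset.
SNP_ANNOTATION_COUNTS: dict[str, int] = {
    "total": 24_831_754,
    "upstream": 156_603,
    "exonic": 161_407,
    "intronic": 6_751_084,
    "splicing": 670,
    "downstream": 148_646,
    "upstream/downstream": 1_729,
    "intergenic": 17_610_944,
    # exonic (coding) subcategories
    "synonymous": 103_686,
    "missense": 57_050,
    "stop_gain": 607,
    "stop_loss": 64,
}

# Per-breed pooled SNP totals and the three-way shared count.
POOLED_SNP_COUNTS: dict[str, int] = {
    "Angora": 15_622_108,
    "NewZealand": 16_948_460,
    "Rex": 16_539_048,
    "union": 24_831_754,
    "shared": 12_234_559,
}

# The same quantities as printed, rounded to 0.01 million; the published
# shared percentage (49.25%) is the ratio of these rounded counts.
POOLED_SNP_COUNTS_MILLIONS: dict[str, float] = {
    "Angora": 15.62,
    "NewZealand": 16.95,
    "Rex": 16.54,
    "union": 24.83,
    "shared": 12.23,
}
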