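# Methods

## Scan model

The scan targets the classical signature of a recent artificial-selection
sweep in a focal population: a local loss of diversity together with a
local excess of differentiation against reference populations. Two window
statistics are computed over sliding windows (default 100 kb, stepping
10 kb; the final, possibly truncated window guarantees every base is
covered):

**Pooled heterozygosity.** At each SNP the focal population's called
allele slots are tallied into the most and least frequent allele counts
(nMAJ, nMIN; frequency ties assign the reference allele to nMAJ, which
cannot change any downstream value since the counts are equal). Per
window,

    Hp = (Σ nMAJ · Σ nMIN) / (Σ nMAJ + Σ nMIN)²

which is algebraically confined to [0, 0.25]; a window whose summed counts
are zero is undefined and excluded.

**Differentiation.** Per SNP, the Weir & Cockerham (1984) variance
components a (among demes), b (among individuals within demes) and c
(within individuals) are computed for two demes: the focal population
versus the two non-focal populations pooled into a single deme (the
focal-vs-combined-rest contrast the scan design calls for, not an average
of pairwise comparisons). Sample sizes, allele frequencies and observed
heterozygosities are taken over called genotypes only; monomorphic or
unusable sites carry zero components. The window value is the
ratio-of-sums ("weighted") estimator Σa / Σ(a+b+c), the documented
combination of the standard command-line Fst tools; negative values, the
estimator's normal behaviour near zero differentiation, are retained as
computed.

**Thresholding.** Windows with fewer than `min_snps_per_window` SNPs
(default 10) or an undefined statistic are excluded; the rest are
"evaluated". Both statistics are Z-transformed using the mean and sample
(n−1) standard deviation over evaluated windows genome-wide. Cutoffs are
nearest-rank empirical quantiles (k = ⌈tail·n⌉ from the relevant end,
default tail 5%, requiring ≥ 20 evaluated windows): the *lower* tail of
ZHp and the *upper* tail of ZFst. A window is an outlier only when it
passes both cutoffs simultaneously (boundary inclusive), so the flagged
fraction can never exceed the tail fraction. Overlapping or bookended
outlier windows are merged into maximal sweep regions (0-based half-open;
the reported total span counts merged length, not summed window lengths),
and genes are assigned on ≥ 1 bp overlap. At a region's half-open end the
gene-start coordinate is treated as exclusive (a gene starting exactly at
`region.end` is not assigned), matching the interval convention of the
exported BED.

## Site filters

SNP records are kept when depth ∈ [4, 1000], RMS MQ ≥ 20, no InDel from
the *input* (whether or not that InDel survives anything) lies within
±3 bp, the nearest neighbouring input SNP is ≥ 5 bp away, and the
missing-genotype fraction is ≤ 50% within every population. Two choices
the filter wording leaves open are resolved as follows: the adjacency rule
removes *both* members of a too-close pair (symmetric and
order-independent), and both neighbourhood rules are evaluated against all
input sites rather than survivors — this keeps every filter monotone (a
stricter threshold can only shrink the retained set). For reporting, a
failing site is attributed to the first rule it fails in the order depth →
MQ → InDel proximity → adjacency → group missingness, so the per-rule
counts plus the retained count always partition the input SNPs.

## Annotation

Region classes follow the precedence exonic > splicing > intronic >
upstream/downstream (both, for different genes) > upstream > downstream >
intergenic, with 1 kb flanks measured from the gene start/end in genomic
orientation (not strand-flipped) and "splicing" meaning within 2 bp of a
junction on the intron side; exon-side bases stay exonic. CDS positions
are numbered 1..L in translation order (descending coordinates on the
minus strand), codon_index = ⌈cds/3⌉. Consequences use the standard codon
table: synonymous, stop gain (non-stop → stop), stop loss (stop →
non-stop), else missense. UTR-exonic variants are "exonic" with no
consequence call. Consequence calling requires the gene model to carry its
spliced CDS sequence; models loaded from a plain GFF3 (no FASTA) have
none, and a VCF reference base disagreeing with the CDS sequence skips the
call with a warning (or raises, configurably).

## LD and PCA

The default r² estimator recovers haplotype-based semantics from unphased
diploids: the four two-locus haplotype frequencies are estimated by EM
(initialised at linkage equilibrium, relative tolerance 1e-10, ≤ 1000
iterations; only double heterozygotes are phase-ambiguous) and
r² = D²/(pA·pa·pB·pb). The degenerate all-double-heterozygote input has
the equilibrium as a stationary point; it is returned as such with a
warning. A squared dosage-correlation estimator is provided as a fast
composite-LD alternative. Pairs are gated on MAF ≥ 0.01 after pairwise
missing-data removal, binned by distance (10 kb bins to 500 kb), and
averaged per population with pair counts reported. D′ is not computed.

PCA imputes missing dosages to the site mean, standardises each site by
√(2p̂(1−p̂)), drops zero-variance sites, and eigendecomposes the
sample-sample relationship matrix XᵀX/m. Coordinates are the orthonormal
eigenvectors; variance fractions are eigenvalue over trace, making them
invariant to any overall rescaling of the standardisation.

## Enrichment and reporting

Gene-set p-values are exact hypergeometric upper tails P(X ≥ k) with BH
adjustment. The universe defaults to the union of supplied set members
(the convention of pathway-annotation tools); sets with zero candidate
hits are excluded *before* adjustment, which changes m and hence adjusted
values — stated here prominently because other tools differ. Shared-SNP
fractions are intersection over union of per-population site sets; the
bundled published pooled counts reproduce the printed percentage when
computed, as printed, from the rounded-million counts. Report aggregates
round to 2 decimals; full precision is kept internally.

## Synthetic cohorts

The generator reproduces exactly the structure the scan consumes, nothing
more. Background alternate-allele frequencies are drawn per site from a
symmetric U-shaped Beta(0.3, 0.3) (clipped away from 0/1), stressing the
major/minor bookkeeping from both tails. Population frequencies come from
the Balding–Nichols model with drift parameter F = `divergence_scale`
(default 0.15, breed-level divergence; F = 0 short-circuits to the shared
background). Inside a planted sweep interval, each site is, with
probability `sweep_fixation_prob`, driven near fixation *of the allele
minor in the background* (ε ~ Beta(1, 50) from the boundary) in the focal
population only — simultaneously depressing focal Hp and inflating
focal-vs-rest Fst, which is the joint signature the scan thresholds on.
Genotypes are Hardy–Weinberg binomial draws per individual; per-genotype
depth is gamma–Poisson (mean 6.5, shape 3) summed per site; RMS MQ is
normal (50 ± 8, rounded to the 2 decimals the VCF carries); genotypes go
missing independently (2%); 5% of sites are emitted as ±1 bp InDels. The
default cohort is 3 × 6 diploids on one 5 Mb chromosome at 1 SNP/kb,
giving ~490 evaluated 100-kb windows — large enough for stable empirical
tails, small enough that the full recovery experiment runs in seconds.

What the generator does *not* emulate: haplotype structure, recombination
and genealogical correlation between sites (sites are exchangeable given
their frequencies), relatedness between individuals, reference-genome
sequence (so simulated VCF reference bases are arbitrary except where a
test plants them), and depth/MQ correlation with genotype quality.
Passing recovery tests therefore demonstrate the scan's behaviour under
its own model assumptions — frequency-level signals in unlinked sites —
not robustness to LD, relatedness or calling artefacts in real data. LD
decay curves on these cohorts are flat apart from drift-induced
background association; only bookkeeping, not decay shape, is asserted.

Gene models are toy three-exon genes (~4.9 kb footprint) tiled every
500 kb, alternating strand; each chromosome additionally carries a
plus-strand gene patterned on *Fgf5* — 702 bp CDS over three exons with a
TTA/TTG leucine codon at position 191 and the variant-bearing third exon —
placed inside the first planted sweep interval when one exists, so the
c.572 T>C → p.L191S worked example and region–gene assignment are
exercised end to end. Only TTA/TTG satisfy the example's constraint (a
second-position T>C in a leucine codon yielding serine), by codon-table
enumeration.

## Numerical and degenerate-input choices

Zero-spread Z-transform inputs raise; empirical cutoffs require ≥ 20
evaluated windows; an all-missing pool yields counts (0, 0) and an
undefined allele frequency (raised on request); empty filter input returns
an empty table with a zeroed report; a fully fixed window has Hp = 0
(defined) but an undefined Fst denominator, so it is excluded from the
tails. Equality of genotype tables tolerates 1e-3 on MQ, the
serialisation precision of the VCF writer (2 decimals, read back as
float32). Multiallelic VCF records are split one record per alternate
allele, with other alternates treated as reference in each split record.

## Problem sizes used in validation

Recovery experiments use 10 seeds of the default 5 Mb / 1 SNP-per-kb
cohort with one 200 kb sweep at full fixation probability; the null
counterpart permutes sample→population labels before the scan. Enrichment
calibration uses 1,000 uniform-candidate replicates against 10 random
20-gene sets in a 200-gene universe; the type-I rate sits below the
nominal 0.05 because exact hypergeometric tails are conservative on
discrete counts. Structure checks use 10 seeds of a two-population,
F = 0.4, 6+6-sample cohort (PCA separation) and 1,000 independent locus
pairs at frequency 0.5 with n = 100 (mean r² near the ~1/(2n) small-sample
floor). These sizes make the whole suite and the acceptance script run in
seconds while leaving hundreds of windows and thousands of replicates
behind every asserted rate.

## Known limitations

The Fst estimator is the two-deme Weir–Cockerham form only; pairwise
multi-population contrasts and other estimators (Hudson, Nei) are out of
scope. EM r² is quadratic in SNP count across a window and intended for
curve estimation on thinned or desk-scale data; the dosage estimator is
the fast path. Consequence annotation requires CDS sequences on the gene
models. The simulator's planted signal is frequency-level by design;
haplotype-based statistics (iHS, XP-EHH) cannot be validated against it
and are not implemented.
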