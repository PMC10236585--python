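import numpy as np
import pytest

from sweepscan.variants import MISSING, GenotypeTable, SampleGroups


def table_from_dosages(dosages, positions=None, chrom="chr1", depths=None,
                       mqs=None, is_indel=None, samples=None, refs=None,
                       alts=None):
    """Build a GenotypeTable from a (sites x samples) dosage array.

    Dosage 0/1/2 maps to 0/0, 0/1, 1/1; negative dosage marks a missing
    genotype (./.) — convenient shorthand for small hand-built fixtures.
    """
    dosages = np.asarray(dosages)
    n_sites, n_samples = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    gt = np.zeros((n_sites, n_samples, 2), dtype=np.int8)
    gt[:, :, 0] = dosages >= 1
    gt[:, :, 1] = dosages == 2
    gt[dosages < 0] = MISSING
    return GenotypeTable(
        chromosomes=[chrom] * n_sites,
        positions=positions,
        refs=refs if refs is not None else ["A"] * n_sites,
        alts=alts if alts is not None else ["T"] * n_sites,
        is_indel=is_indel if is_indel is not None else [False] * n_sites,
        depths=depths if depths is not None else [100] * n_sites,
        mqs=mqs if mqs is not None else [50.0] * n_sites,
        genotypes=gt,
        samples=samples)


def two_pop_groups(samples, n_focal):
    return SampleGroups(
        {s: ("focal" if i < n_focal else "rest")
         for i, s in enumerate(samples)}, ["focal", "rest"])


@pytest.fixture
def three_pop_groups():
    labels = []
    for pop, n in (("Angora", 6), ("NewZealand", 6), ("Rex", 6)):
        labels.extend((f"{pop}_{i + 1}", pop) for i in range(n))
    return SampleGroups(dict(labels), ["Angora", "NewZealand", "Rex"])
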