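import numpy as np
import pytest

from genepair import (
    GenomicRegion,
    PhasedCohort,
    PopulationSpec,
    SamplePanel,
    Site,
    StructureSpec,
    simulate_cohort,
)


def build_cohort(allele_rows, positions=None, chromosome="1", refs=None, alts=None):
    """Small hand-built cohort: allele_rows is a list of chromatid rows."""
    mat = np.asarray(allele_rows, dtype=np.int16)
    n_chrom, n_sites = mat.shape
    assert n_chrom % 2 == 0
    if positions is None:
        positions = list(range(100, 100 + 10 * n_sites, 10))
    refs = refs or ["A"] * n_sites
    alts = alts or ["G"] * n_sites
    sites = [
        Site(chromosome, positions[j], f"rs{j}", refs[j], (alts[j],))
        for j in range(n_sites)
    ]
    samples = [f"s{i}" for i in range(n_chrom // 2)]
    return PhasedCohort(samples, sites, mat)


def two_pop_panel(cohort, split=None):
    """Assign first half of samples to YRI/AFR, rest to CEU/EUR."""
    panel = SamplePanel()
    split = split if split is not None else cohort.n_samples // 2
    for i, s in enumerate(cohort.samples):
        if i < split:
            panel.add(s, "YRI", "AFR", "male" if i % 2 == 0 else "female")
        else:
            panel.add(s, "CEU", "EUR", "male" if i % 2 == 0 else "female")
    return panel


@pytest.fixture
def small_cohort():
    # 3 samples, 4 sites; column alt counts 1, 3, 0, 6
    rows = [
        [1, 0, 0, 1],
        [0, 1, 0, 1],
        [0, 1, 0, 1],
        [0, 0, 0, 1],
        [0, 1, 0, 1],
        [0, 0, 0, 1],
    ]
    return build_cohort(rows)


@pytest.fixture
def neutral_cohort():
    spec = StructureSpec(
        region=GenomicRegion("1", 1, 100_000),
        n_sites=200,
        populations=[
            PopulationSpec("YRI", "AFR", 40),
            PopulationSpec("CEU", "EUR", 40),
        ],
        F=0.05,
        seed=7,
    )
    return simulate_cohort(spec)
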