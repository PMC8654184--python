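"""Weir-Cockerham FST: variance components, pairwise matrices, PCA.

The per-site estimator is the diploid Weir & Cockerham (1984) analysis of
variance with components a (among populations), b (among individuals
within populations) and c (within individuals), using observed
heterozygote frequencies:

    n_bar = mean sample size,  n_c = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
    p_bar = weighted mean allele frequency, s2 = weighted among-pop variance
    h_bar = weighted mean heterozygote frequency

    a = n_bar/n_c [ s2 - (p_bar(1-p_bar) - s2 (r-1)/r - h_bar/4) / (n_bar - 1) ]
    b = n_bar/(n_bar-1) [ p_bar(1-p_bar) - s2 (r-1)/r - h_bar (2 n_bar - 1)/(4 n_bar) ]
    c = h_bar / 2

The multi-site estimate is the ratio of averages theta = sum a / sum
(a+b+c); negative estimates are reported as computed (clamping would bias
averaged comparisons). Gene-level estimates can be compared against a
genome-wide benchmark band (mean +/- k sd) with a two-tailed one-sample
t-test, and a matrix of pairwise theta values can be mapped by PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import PhasedCohort, SamplePanel, filter_sites


@dataclass
class FstComponents:
    """Per-site Weir-Cockerham variance components over informative sites."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    site_index: np.ndarray  # indices into the source cohort's sites

    @property
    def per_site_theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


@dataclass
class FstMatrix:
    """Symmetric pairwise differentiation between groups; zero diagonal."""

    groups: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.groups), len(self.groups)):
            raise ValueError("matrix shape does not match group count")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("pairwise FST matrix must be symmetric")
        if not np.all(np.diag(v) == 0.0):
            raise ValueError("pairwise FST matrix diagonal must be 0")
        self.values = v

    def get(self, g1: str, g2: str) -> float:
        return float(self.values[self.groups.index(g1), self.groups.index(g2)])


@dataclass
class BenchmarkBand:
    """A genome-wide differentiation benchmark: mean +/- k standard deviations."""

    mean: float = 0.124
    sd: float = 0.006
    k: float = 2.0

    @property
    def lower(self) -> float:
        return self.mean - self.k * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.k * self.sd

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @classmethod
    def from_values(cls, values: Sequence[float], k: float = 2.0) -> "BenchmarkBand":
        """Build the band from literature genome-wide estimates (ddof=1 sd)."""
        arr = np.asarray(values, dtype=float)
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), k=k)


def _group_genotypes(
    cohort: PhasedCohort, panel: SamplePanel, group: str, sex: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    members = panel.members(group, sex=sex)
    if not members:
        raise ValueError(f"group {group!r} (sex={sex}) is empty")
    idx = np.array([cohort.sample_index(s) for s in members], dtype=np.intp)
    a = (cohort.alleles[2 * idx, :] > 0).astype(np.int8)
    b = (cohort.alleles[2 * idx + 1, :] > 0).astype(np.int8)
    return a, b


def wc_fst_per_site(
    cohort: PhasedCohort,
    panel: SamplePanel,
    grouping: Sequence[str] | Sequence[tuple[str, str | None]],
) -> FstComponents:
    """Per-site a, b, c components for >= 2 groups.

    ``grouping`` lists group selectors (population/supergroup codes, or
    ``(group, sex)`` pairs for sex-stratified contrasts). Sites
    monomorphic across all groups pooled are excluded as uninformative.
    """
    if len(grouping) < 2:
        raise ValueError("need at least two groups for FST")
    specs = [g if isinstance(g, tuple) else (g, None) for g in grouping]
    geno = [_group_genotypes(cohort, panel, g, sex) for g, sex in specs]
    r = len(geno)
    n_i = np.array([g[0].shape[0] for g in geno], dtype=float)  # diploid counts
    p_i = np.stack([(a.sum(0) + b.sum(0)) / (2.0 * n) for (a, b), n in zip(geno, n_i)])
    h_i = np.stack([(a != b).sum(0) / n for (a, b), n in zip(geno, n_i)])

    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    w = n_i[:, None] / (r * n_bar)
    p_bar = (w * p_i).sum(axis=0)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (w * h_i).sum(axis=0)

    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4.0 * n_bar)
    )
    c = h_bar / 2.0

    informative = (p_bar > 0.0) & (p_bar < 1.0)
    return FstComponents(
        a=a[informative],
        b=b[informative],
        c=c[informative],
        site_index=np.flatnonzero(informative),
    )


def wc_fst_overall(components: FstComponents) -> float:
    """Multi-site theta as the ratio of averages sum a / sum (a+b+c).

    Returns NaN (undefined flag) when the denominator is 0. Negative
    estimates are reported as computed, never clamped.
    """
    if components.a.size == 0:
        return float("nan")
    denom = (components.a + components.b + components.c).sum()
    if denom == 0.0:
        return float("nan")
    return float(components.a.sum() / denom)


def fst_between(
    cohort: PhasedCohort,
    panel: SamplePanel,
    grouping: Sequence[str] | Sequence[tuple[str, str | None]],
) -> float:
    """Convenience: overall Weir-Cockerham theta for a grouping."""
    return wc_fst_overall(wc_fst_per_site(cohort, panel, grouping))


def pairwise_fst_matrix(
    cohort: PhasedCohort,
    panel: SamplePanel,
    groups: Sequence[str],
    maf_min: float = 0.05,
) -> FstMatrix:
    """All pairwise overall theta values between the given groups.

    The MAF filter is applied once on the pooled cohort (all samples,
    matching the convention of filtering the entire dataset) before pair
    extraction; each entry is then the two-group overall theta.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    filtered = filter_sites(cohort, keep_biallelic_snv=True, maf_min=maf_min)
    k = len(groups)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            theta = fst_between(filtered, panel, [groups[i], groups[j]])
            mat[i, j] = mat[j, i] = theta
    return FstMatrix(list(groups), mat)


@dataclass
class BenchmarkComparison:
    verdicts: list[bool]  # True = within band
    t: float | None
    p: float | None
    mean: float
    sd: float
    n: int


def one_sample_t_from_summary(
    mean: float, sd: float, n: int, mu: float
) -> tuple[float, float]:
    """Two-tailed one-sample t-test from summary statistics.

    t = (mean - mu) / (sd / sqrt(n)), df = n - 1.
    """
    if n < 2:
        raise ValueError("need n >= 2 for a t-test")
    if sd == 0.0:
        raise ValueError("t undefined for constant values (sd = 0)")
    t = (mean - mu) / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p


def benchmark_compare(
    values: Sequence[float], band: BenchmarkBand | None = None
) -> BenchmarkComparison:
    """Compare gene-level pairwise theta values against the benchmark band.

    Each value gets a within/outside verdict against mean +/- k sd, and
    the set is tested against the benchmark mean with a two-tailed
    one-sample t-test. Constant values flag t as undefined (p = 1 when
    the constant equals the benchmark mean exactly).
    """
    if band is None:
        band = BenchmarkBand()
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values for the t-test")
    verdicts = [band.contains(v) for v in arr]
    mean, sd = float(arr.mean()), float(arr.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == band.mean else None
        return BenchmarkComparison(verdicts, None, p, mean, sd, arr.size)
    t, p = one_sample_t_from_summary(mean, sd, arr.size, band.mean)
    return BenchmarkComparison(verdicts, t, p, mean, sd, arr.size)


@dataclass
class PcaResult:
    groups: list[str]
    coordinates: np.ndarray  # groups x components
    variance_fractions: np.ndarray


def fst_pca(matrix: FstMatrix, standardize: bool = False) -> PcaResult:
    """PCA of the pairwise-theta profile of each group.

    Each group's feature vector is its row of pairwise theta values to
    all groups. Columns are centered (and scaled to unit variance when
    ``standardize``), the covariance is eigendecomposed, and the sign of
    each component is fixed so its largest-magnitude loading is positive
    (deterministic across reruns). Variance fractions are non-increasing
    and sum to 1. A rank-0 (identical rows) matrix yields all-zero
    coordinates.
    """
    if len(matrix.groups) < 3:
        raise ValueError("need at least three groups for PCA")
    X = matrix.values.astype(float).copy()
    X -= X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        nonzero = sd > 0
        X[:, nonzero] /= sd[nonzero]
    if not np.any(np.abs(X) > 1e-15):
        k = len(matrix.groups)
        return PcaResult(
            matrix.groups, np.zeros((k, k - 1)), np.full(k - 1, np.nan)
        )
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each PC positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u * s
    var = s**2
    fractions = var / var.sum()
    return PcaResult(matrix.groups, coords, fractions)
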