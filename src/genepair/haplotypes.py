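"""Haplotype inference, linkage disequilibrium and cross-gene analysis.

Marker loci are biallelic SNVs passing a minor-allele-frequency screen
and an exact Hardy-Weinberg screen (loci out of equilibrium are excluded
from LD calculation and haplotype inference). Haplotype frequencies are
counted directly from phased chromatids; a two-locus EM estimator is
provided for unphased genotype tables, mirroring the classic
phase-by-maximum-likelihood approach.

LD between two biallelic loci uses the standard measures

    D  = p_AB - p_A p_B
    D' = D / D_max   (sign-appropriate maximum)
    r2 = D^2 / (p_A (1-p_A) p_B (1-p_B))

The cross-gene analysis asks whether two genes' haplotypes co-occur on
the same chromatid more often than expected under independent assortment:
observed co-occurrence frequencies are compared with the products of the
single-gene frequencies, and the table is tested with an exact Wilcoxon
matched-pairs signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats  # noqa: F401  (cross-check in tests)

from .cohort import PhasedCohort, SamplePanel, site_maf
from .site_stats import genotype_counts, hwe_exact


@dataclass
class MarkerSet:
    """Ordered biallelic marker loci with the thresholds that selected them."""

    site_indices: list[int]  # columns in the source cohort
    rsids: list[str]
    positions: list[int]
    alleles: list[tuple[str, str]]  # (ref, alt) per marker
    maf_min: float
    hwe_p_min: float

    def __len__(self) -> int:
        return len(self.site_indices)


@dataclass
class HaplotypeTable:
    """Per-group haplotype frequencies over a marker set."""

    group: str
    sex: str | None
    n_chromatids: int
    frequencies: dict[str, float]  # haplotype string -> frequency

    def top(self, k: int = 5) -> list[tuple[str, float]]:
        return sorted(self.frequencies.items(), key=lambda kv: -kv[1])[:k]

    def reported(self, threshold: float = 0.01) -> dict[str, float]:
        """Strings at or above the reporting threshold (rare ones pooled)."""
        out = {h: f for h, f in self.frequencies.items() if f >= threshold}
        rest = 1.0 - sum(out.values())
        if rest > 1e-12:
            out["other"] = rest
        return out


@dataclass
class LDResult:
    D: float
    D_prime: float
    r2: float
    mode: str = "phased-direct"


@dataclass
class CombinedHaplotypeRow:
    hap_a: str
    hap_b: str
    freq_a: float
    freq_b: float
    expected: float  # freq_a * freq_b exactly
    observed: float  # chromatid co-occurrence fraction


def select_markers(
    cohort: PhasedCohort,
    panel: SamplePanel,
    group: str = "ALL",
    maf_min: float = 0.05,
    hwe_p_min: float = 0.01,
) -> MarkerSet:
    """Marker loci: biallelic SNVs with MAF >= ``maf_min`` (pooled cohort)
    and exact HWE p-value > ``hwe_p_min`` within ``group``.

    MAF is computed on the entire dataset pooled (the convention for
    finding haplotypes shared across groups); the HWE screen is applied
    in the group being analyzed. An empty marker set is allowed.
    """
    maf = site_maf(cohort)
    members = panel.members(group)
    hr, he, ha = genotype_counts(cohort, members)
    indices, rsids, positions, alleles = [], [], [], []
    for j, site in enumerate(cohort.sites):
        if not site.is_biallelic_snv:
            continue
        if maf[j] < maf_min:
            continue
        if hwe_exact(int(hr[j]), int(he[j]), int(ha[j])) <= hwe_p_min:
            continue
        indices.append(j)
        rsids.append(site.rsid)
        positions.append(site.position)
        alleles.append((site.ref, site.alts[0]))
    return MarkerSet(indices, rsids, positions, alleles, maf_min, hwe_p_min)


def _chromatid_rows(
    cohort: PhasedCohort, panel: SamplePanel | None, group: str, sex: str | None
) -> np.ndarray:
    if panel is None or (group == "ALL" and sex is None):
        return np.arange(cohort.n_chromatids)
    return cohort.chromatid_rows(panel.members(group, sex=sex))


def haplotype_strings(cohort: PhasedCohort, markers: MarkerSet) -> list[str]:
    """The allele-letter string of every chromatid at the marker loci."""
    if len(markers) == 0:
        raise ValueError("marker set is empty")
    for j in markers.site_indices:
        if j >= cohort.n_sites:
            raise ValueError(f"marker column {j} absent from cohort")
    cols = cohort.alleles[:, markers.site_indices]
    letters = [
        np.array([ref, alt]) for ref, alt in markers.alleles
    ]
    out = []
    for row in cols:
        out.append("".join(letters[m][row[m]] for m in range(len(markers))))
    return out


def haplotype_frequencies(
    cohort: PhasedCohort,
    panel: SamplePanel | None,
    markers: MarkerSet,
    group: str = "ALL",
    sex: str | None = None,
) -> HaplotypeTable:
    """Count haplotype strings over the chromatids of a group (x sex).

    Frequencies over all distinct observed strings sum to 1 exactly
    (integer counting on phased chromatids).
    """
    rows = _chromatid_rows(cohort, panel, group, sex)
    strings = haplotype_strings(cohort, markers)
    counts: dict[str, int] = {}
    for r in rows:
        counts[strings[r]] = counts.get(strings[r], 0) + 1
    n = len(rows)
    freqs = {h: c / n for h, c in sorted(counts.items(), key=lambda kv: -kv[1])}
    return HaplotypeTable(group=group, sex=sex, n_chromatids=n, frequencies=freqs)


def ld_from_haplotype_freqs(
    p_ab: float, p_a: float, p_b: float
) -> LDResult:
    """D, D', r2 from the AB haplotype frequency and marginals."""
    D = p_ab - p_a * p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDResult(float("nan"), float("nan"), float("nan"))
    if D >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = D / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(float(D), float(d_prime), float(r2))


def ld_pair(
    cohort: PhasedCohort,
    locus_i: int,
    locus_j: int,
    panel: SamplePanel | None = None,
    group: str = "ALL",
) -> LDResult:
    """Phased-direct LD between two site columns within a group.

    Returns NaN fields (undefined flag) when either locus is monomorphic
    in the group.
    """
    rows = _chromatid_rows(cohort, panel, group, None)
    x = (cohort.alleles[rows, locus_i] > 0).astype(float)
    y = (cohort.alleles[rows, locus_j] > 0).astype(float)
    p_a, p_b = x.mean(), y.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDResult(float("nan"), float("nan"), float("nan"))
    p_ab = (x * y).mean()
    return ld_from_haplotype_freqs(p_ab, p_a, p_b)


def em_two_locus(
    genotype_table: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, bool, int]:
    """Two-locus haplotype frequency MLE by EM on unphased genotypes.

    ``genotype_table`` is the 3x3 count table of (genotype at locus A) x
    (genotype at locus B), coded 0/1/2 copies of the alt allele. Only the
    double heterozygote is phase-ambiguous; the EM splits it between the
    coupling (AB/ab) and repulsion (Ab/aB) resolutions in proportion to
    the current haplotype-frequency estimates.

    Returns (frequencies [p_AB, p_Ab, p_aB, p_ab] with A/B = alt alleles,
    converged flag, iterations). A non-converged run returns its last
    iterate flagged False.
    """
    t = np.asarray(genotype_table, dtype=float)
    if t.shape != (3, 3) or t.sum() < 1:
        raise ValueError("genotype_table must be 3x3 with at least one individual")
    n_hap = 2.0 * t.sum()
    # unambiguous haplotype counts; index: [a_copies][b_copies]
    # genotype (i alt copies at A, j at B) contributes known haplotypes except (1,1)
    base = np.zeros(4)  # AB, Ab, aB, ab
    contrib = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for (i, j), add in contrib.items():
        base += t[i, j] * np.asarray(add, dtype=float)
    dh = t[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    f = np.full(4, 0.25)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        total = coupling + repulsion
        frac = coupling / total if total > 0 else 0.5
        counts = base.copy()
        counts[0] += dh * frac
        counts[3] += dh * frac
        counts[1] += dh * (1 - frac)
        counts[2] += dh * (1 - frac)
        new = counts / n_hap
        if np.max(np.abs(new - f)) < tol:
            f = new
            converged = True
            break
        f = new
    return f, converged, it


def intergenic_max_r2(
    cohort_a: PhasedCohort,
    cohort_b: PhasedCohort,
    panel: SamplePanel | None = None,
    maf_min: float = 0.01,
    group: str = "ALL",
) -> tuple[float, tuple[int, int]] | None:
    """Maximum phased-direct r2 over all cross-gene SNP pairs.

    Both cohorts must carry the same samples in the same order (chromatid
    k of gene A pairs with chromatid k of gene B). Sites below ``maf_min``
    are excluded. Returns None (undefined) when either gene has no
    polymorphic site after filtering.
    """
    if cohort_a.samples != cohort_b.samples:
        raise ValueError("cohorts must share the same samples in the same order")
    rows = _chromatid_rows(cohort_a, panel, group, None)
    xa = (cohort_a.alleles[rows, :] > 0).astype(float)
    xb = (cohort_b.alleles[rows, :] > 0).astype(float)

    def _keep(x: np.ndarray) -> np.ndarray:
        p = x.mean(axis=0)
        maf = np.minimum(p, 1 - p)
        return np.flatnonzero(maf >= max(maf_min, 1e-12))

    ka, kb = _keep(xa), _keep(xb)
    if ka.size == 0 or kb.size == 0:
        return None
    a = xa[:, ka] - xa[:, ka].mean(axis=0)
    b = xb[:, kb] - xb[:, kb].mean(axis=0)
    cov = a.T @ b / a.shape[0]
    var_a = (a**2).mean(axis=0)
    var_b = (b**2).mean(axis=0)
    r2 = cov**2 / np.outer(var_a, var_b)
    i, j = np.unravel_index(np.argmax(r2), r2.shape)
    return float(r2[i, j]), (int(ka[i]), int(kb[j]))


def expected_combined_frequency(freq_a: float, freq_b: float) -> float:
    """Expected co-occurrence under independent assortment: the product."""
    return freq_a * freq_b


def combined_haplotypes(
    cohort_a: PhasedCohort,
    cohort_b: PhasedCohort,
    panel: SamplePanel | None,
    markers_a: MarkerSet,
    markers_b: MarkerSet,
    group: str = "ALL",
    sex: str | None = None,
    min_single_freq: float = 0.0,
) -> list[CombinedHaplotypeRow]:
    """Observed vs expected co-occurrence of cross-gene haplotype pairs.

    For every (haplotype_A, haplotype_B) pair with single-gene frequencies
    at or above ``min_single_freq``: expected = freq_A * freq_B exactly;
    observed = fraction of chromatids carrying both. Chromatid pairing
    requires identical sample order in the two cohorts.
    """
    if cohort_a.samples != cohort_b.samples:
        raise ValueError("cohorts must share the same samples in the same order")
    rows = _chromatid_rows(cohort_a, panel, group, sex)
    strings_a = haplotype_strings(cohort_a, markers_a)
    strings_b = haplotype_strings(cohort_b, markers_b)
    n = len(rows)
    freq_a: dict[str, int] = {}
    freq_b: dict[str, int] = {}
    joint: dict[tuple[str, str], int] = {}
    for r in rows:
        ha, hb = strings_a[r], strings_b[r]
        freq_a[ha] = freq_a.get(ha, 0) + 1
        freq_b[hb] = freq_b.get(hb, 0) + 1
        joint[(ha, hb)] = joint.get((ha, hb), 0) + 1
    out = []
    for ha, ca in sorted(freq_a.items(), key=lambda kv: -kv[1]):
        fa = ca / n
        if fa < min_single_freq:
            continue
        for hb, cb in sorted(freq_b.items(), key=lambda kv: -kv[1]):
            fb = cb / n
            if fb < min_single_freq:
                continue
            obs = joint.get((ha, hb), 0) / n
            out.append(
                CombinedHaplotypeRow(
                    hap_a=ha, hap_b=hb, freq_a=fa, freq_b=fb,
                    expected=expected_combined_frequency(fa, fb), observed=obs,
                )
            )
    return out


def wilcoxon_matched_pairs(
    observed: Sequence[float], expected: Sequence[float]
) -> float:
    """Exact two-tailed Wilcoxon matched-pairs signed-rank p-value.

    Zero differences are dropped before ranking (Wilcoxon's convention)
    and ties receive midranks. For up to 25 nonzero pairs the null
    distribution of W+ is computed exactly by dynamic programming over
    the (doubled, hence integer) midranks; beyond that a normal
    approximation with tie correction is used. All differences zero
    returns p = 1 by convention.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.size < 1:
        raise ValueError("observed and expected must be equal-length, non-empty")
    d = np.round(obs - exp, 12)  # canonicalize float noise so ties tie
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = _scipy_stats.rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        total = int(doubled.sum())
        # counts[k] = number of sign assignments with doubled W+ = k
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in doubled:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(round(2.0 * w_plus))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    tie_term = 0.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * _scipy_stats.norm.sf(abs(z))))


def write_linkage_format(
    cohort: PhasedCohort,
    panel: SamplePanel,
    markers: MarkerSet,
    ped_path: str,
    info_path: str,
) -> None:
    """Export markers in linkage format (.ped + .info) for external tools."""
    with open(info_path, "w") as fh:
        for rsid, pos in zip(markers.rsids, markers.positions):
            fh.write(f"{rsid}\t{pos}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(cohort.samples):
            sex_code = {"male": "1", "female": "2"}.get(panel.sex.get(sample, ""), "0")
            fields = [sample, sample, "0", "0", sex_code, "0"]
            for j in markers.site_indices:
                site = cohort.sites[j]
                a = site.alleles[cohort.alleles[2 * i, j]]
                b = site.alleles[cohort.alleles[2 * i + 1, j]]
                fields.extend([a, b])
            fh.write("\t".join(fields) + "\n")
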