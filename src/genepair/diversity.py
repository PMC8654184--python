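"""Nucleotide diversity, Watterson's theta and Tajima's D.

All estimators count over chromatids: a cohort of N diploid samples
contributes n = 2N sequences, the convention of phased population panels.

Tajima's D is the standardized difference between two estimators of the
scaled mutation rate — mean pairwise diversity pi and Watterson's
theta_W = S / a1 — using the standard constants derived from n:

    a1 = sum_{i<n} 1/i        a2 = sum_{i<n} 1/i^2
    b1 = (n+1)/(3(n-1))       b2 = 2(n^2+n+3)/(9n(n-1))
    c1 = b1 - 1/a1            c2 = b2 - (n+2)/(a1 n) + a2/a1^2
    e1 = c1/a1                e2 = c2/(a1^2 + a2)
    D  = (pi - S/a1) / sqrt(e1 S + e2 S (S-1))

Negative D signals an excess of rare variants (sweeps, expansion);
positive D an excess of intermediate-frequency variants (balancing
selection). D is undefined when S = 0 or n < 4 and is propagated as an
explicit flag, never as zero — averaging zeros into binned means would
bias them.

A gene-level statistic can be contextualized against a reference set of
genes with literature labels (neutral / balancing / positive): the value
is assigned to the class whose observed [min, max] range contains it,
ties and out-of-range values resolved by nearest class mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort import PhasedCohort, SamplePanel
from .regions import GenomicRegion


def tajima_constants(n: int) -> dict[str, float]:
    """Standard constants a1..e2 for a sample of n chromatids."""
    if n < 2:
        raise ValueError("need at least 2 chromatids")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


@dataclass
class DiversityResult:
    """Diversity summary for one group over one region."""

    n: int
    S: int
    pi: float  # mean pairwise differences over the region
    pi_per_site: float
    theta_w: float
    tajima_d: float | None  # None when undefined (S == 0 or n < 4)
    constants: Mapping[str, float]

    @property
    def defined(self) -> bool:
        return self.tajima_d is not None


def _group_matrix(
    cohort: PhasedCohort,
    panel: SamplePanel | None,
    group: str,
    region: GenomicRegion | None,
) -> tuple[np.ndarray, int]:
    sub = cohort if region is None else cohort.restrict_region(region)
    if group == "ALL" or panel is None:
        mat = sub.alleles
    else:
        mat = sub.alleles[sub.chromatid_rows(panel.members(group)), :]
    return mat, mat.shape[0]


def _pi_from_matrix(mat: np.ndarray) -> tuple[float, int]:
    """(sum over sites of 2p(1-p)n/(n-1), segregating count)."""
    n = mat.shape[0]
    alt = (mat > 0).sum(axis=0)
    seg = (alt > 0) & (alt < n)
    p = alt[seg] / n
    pi = float((2.0 * p * (1.0 - p) * n / (n - 1)).sum())
    return pi, int(seg.sum())


def nucleotide_diversity(
    cohort: PhasedCohort,
    panel: SamplePanel | None = None,
    group: str = "ALL",
    region: GenomicRegion | None = None,
    per_site: bool = False,
) -> float:
    """Mean pairwise difference pi = sum_sites 2p(1-p) n/(n-1).

    Equals the average Hamming distance over all chromatid pairs. With
    ``per_site`` the regional sum is divided by the region length (the
    region is required in that case).
    """
    mat, n = _group_matrix(cohort, panel, group, region)
    if n < 2:
        raise ValueError("need at least 2 chromatids for pi")
    pi, _ = _pi_from_matrix(mat)
    if per_site:
        if region is None:
            raise ValueError("per-site pi requires a region length")
        return pi / region.length
    return pi


def watterson_theta(
    cohort: PhasedCohort,
    panel: SamplePanel | None = None,
    group: str = "ALL",
    region: GenomicRegion | None = None,
) -> float:
    """Watterson's estimator theta_W = S / a1."""
    mat, n = _group_matrix(cohort, panel, group, region)
    if n < 2:
        raise ValueError("need at least 2 chromatids")
    _, S = _pi_from_matrix(mat)
    if S == 0:
        return 0.0
    return S / tajima_constants(n)["a1"]


def _tajima_d_from_counts(n: int, alt_counts: np.ndarray) -> DiversityResult:
    consts = tajima_constants(n) if n >= 2 else {}
    seg = (alt_counts > 0) & (alt_counts < n)
    S = int(seg.sum())
    p = alt_counts[seg] / n
    pi = float((2.0 * p * (1.0 - p) * n / (n - 1)).sum()) if n >= 2 else 0.0
    theta = S / consts["a1"] if S else 0.0
    if S == 0 or n < 4:
        d = None
    else:
        var = consts["e1"] * S + consts["e2"] * S * (S - 1)
        d = (pi - theta) / math.sqrt(var)
    return DiversityResult(
        n=n, S=S, pi=pi, pi_per_site=float("nan"), theta_w=theta,
        tajima_d=d, constants=consts,
    )


def tajimas_d(
    cohort: PhasedCohort,
    panel: SamplePanel | None = None,
    group: str = "ALL",
    region: GenomicRegion | None = None,
    mode: str = "whole",
    bin_bp: int = 100,
    maf_min: float = 0.0,
) -> DiversityResult:
    """Tajima's D for a group, whole-region or averaged over bins.

    ``mode="binned"`` computes D per ``bin_bp`` bin anchored at the region
    start and returns the unweighted mean over bins with at least one
    segregating site (bins where D is undefined are excluded; if none
    qualify the result is flagged undefined). ``maf_min`` drops sites
    below that minor-allele frequency (within the group) before counting
    S — the rare-allele-exclusion variant of the statistic.
    """
    sub = cohort if region is None else cohort.restrict_region(region)
    if group == "ALL" or panel is None:
        mat = sub.alleles
    else:
        mat = sub.alleles[sub.chromatid_rows(panel.members(group)), :]
    n = mat.shape[0]
    alt = (mat > 0).sum(axis=0)
    if maf_min > 0.0 and n > 0:
        p = alt / n
        keep = np.minimum(p, 1 - p) >= maf_min
        mat = mat[:, keep]
        alt = alt[keep]
        sub = sub.subset_sites(keep)
    if mode == "whole":
        res = _tajima_d_from_counts(n, alt)
        if region is not None:
            res.pi_per_site = res.pi / region.length
        return res
    if mode != "binned":
        raise ValueError(f"unknown mode {mode!r}")
    if region is None:
        raise ValueError("binned mode requires a region")
    pos = sub.positions
    bins = (pos - region.start) // bin_bp
    d_values = []
    S_total = 0
    for b in np.unique(bins):
        res = _tajima_d_from_counts(n, alt[bins == b])
        S_total += res.S
        if res.defined:
            d_values.append(res.tajima_d)
    consts = tajima_constants(n) if n >= 2 else {}
    mean_d = float(np.mean(d_values)) if d_values else None
    pi_all, _ = _pi_from_matrix(mat) if n >= 2 else (0.0, 0)
    out = DiversityResult(
        n=n, S=S_total, pi=pi_all, pi_per_site=pi_all / region.length,
        theta_w=(S_total / consts["a1"]) if S_total else 0.0,
        tajima_d=mean_d, constants=consts,
    )
    return out


# ---------------------------------------------------------------------------
# Reference-gene contextualization
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGene:
    name: str
    label: str  # "neutral" | "balancing" | "positive"
    value: float


@dataclass
class Classification:
    label: str
    extrapolated: bool


def classify_against_references(
    value: float, refs: Sequence[ReferenceGene]
) -> Classification:
    """Place a statistic among reference genes of known selection class.

    The label is the class whose observed [min, max] range contains the
    value; when several ranges contain it the nearest class mean wins;
    when none does, the nearest class mean is returned flagged
    ``extrapolated``. Every class must be populated.
    """
    classes: dict[str, list[float]] = {}
    for r in refs:
        classes.setdefault(r.label, []).append(r.value)
    for label in ("neutral", "balancing", "positive"):
        if not classes.get(label):
            raise ValueError(f"reference class {label!r} is empty")
    containing = [
        label
        for label, vals in classes.items()
        if min(vals) <= value <= max(vals)
    ]
    def dist(label: str) -> float:
        return abs(value - float(np.mean(classes[label])))
    if containing:
        return Classification(min(containing, key=dist), extrapolated=False)
    return Classification(min(classes, key=dist), extrapolated=True)


def read_reference_genes(path: str) -> list[ReferenceGene]:
    """Reference set as TSV with columns gene, class, value."""
    refs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        i_g, i_c, i_v = header.index("gene"), header.index("class"), header.index("value")
        for line in fh:
            if line.strip():
                f = line.rstrip("\n").split("\t")
                refs.append(ReferenceGene(f[i_g], f[i_c], float(f[i_v])))
    return refs


# ---------------------------------------------------------------------------
# VCF-based percent identity
# ---------------------------------------------------------------------------


def vcf_percent_identity(
    cohort: PhasedCohort,
    sample: str,
    region: GenomicRegion,
    chromatid_policy: str = "per-chromatid",
) -> float:
    """Percent identity of a sample to the reference over a region.

    identity = (L - m) / L * 100 with L the region length and m the
    number of mismatching positions, i.e. positions where the sample
    carries a non-reference allele. Policies for the diploid ambiguity:
    ``per-chromatid`` averages the two chromatids' identities;
    ``any-allele-differs`` counts a position if either chromatid is
    non-reference; ``both-alleles-differ`` only if both are.
    """
    if region.length < 1:
        raise ValueError("region length must be >= 1")
    i = cohort.sample_index(sample)
    sub = cohort.restrict_region(region)
    a = sub.alleles[2 * i, :] > 0
    b = sub.alleles[2 * i + 1, :] > 0
    L = region.length
    if chromatid_policy == "per-chromatid":
        ident = ((L - a.sum()) / L + (L - b.sum()) / L) / 2.0
    elif chromatid_policy == "any-allele-differs":
        ident = (L - (a | b).sum()) / L
    elif chromatid_policy == "both-alleles-differ":
        ident = (L - (a & b).sum()) / L
    else:
        raise ValueError(f"unknown chromatid_policy {chromatid_policy!r}")
    return float(ident * 100.0)
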