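"""Per-site statistics: allele frequencies, SNV density, Hardy-Weinberg.

The Hardy-Weinberg test is the exact conditional test (Wigginton, Cutler &
Abecasis style recurrence over heterozygote counts given allele counts),
not the chi-square approximation; a chi-square variant is kept for
cross-checks. A Wahlund-pattern detector flags loci that fail HWE in a
merged group while every constituent subgroup is in equilibrium — the
signature of population stratification that motivates analyzing East and
South Asian cohorts separately rather than as one "ASI" group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import PhasedCohort, SamplePanel
from .regions import GenomicRegion


def allele_frequencies(
    cohort: PhasedCohort, panel: SamplePanel | None = None, group: str = "ALL"
) -> np.ndarray:
    """Per-site alt-allele frequency over the chromatids of ``group``.

    frequency = alt chromatid count / group chromatid count. With
    ``group="ALL"`` (or no panel) all samples are pooled.
    """
    if group == "ALL" or panel is None:
        rows = None
        n_chrom = cohort.n_chromatids
    else:
        members = panel.members(group)
        if not members:
            raise ValueError(f"group {group!r} is empty")
        rows = cohort.chromatid_rows(members)
        n_chrom = rows.size
    if n_chrom == 0:
        raise ValueError("no chromatids in group")
    mat = cohort.alleles if rows is None else cohort.alleles[rows, :]
    return (mat > 0).sum(axis=0) / n_chrom


def genotype_counts(
    cohort: PhasedCohort, samples: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hom-ref, het, hom-alt) counts per site over the given samples."""
    idx = np.array([cohort.sample_index(s) for s in samples], dtype=np.intp)
    a = cohort.alleles[2 * idx, :] > 0
    b = cohort.alleles[2 * idx + 1, :] > 0
    total = a.astype(np.int64) + b.astype(np.int64)
    hom_ref = (total == 0).sum(axis=0)
    het = (total == 1).sum(axis=0)
    hom_alt = (total == 2).sum(axis=0)
    return hom_ref, het, hom_alt


def hwe_exact(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact Hardy-Weinberg p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed
    one. Symmetric in the allele labels. A site with no minor alleles
    returns p = 1.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = 2 * min(hom_ref, hom_alt) + het  # minor allele count
    if rare == 0:
        return 1.0
    # feasible het counts share the parity of the minor allele count
    hets = list(range(rare % 2, rare + 1, 2))
    probs = np.zeros(len(hets))
    # start from the largest het count and recurse downward:
    # P(het-2)/P(het) = het*(het-1) / (4*(hom_rare+1)*(hom_common+1))
    i_start = len(hets) - 1
    probs[i_start] = 1.0
    for i in range(i_start, 0, -1):
        h = hets[i]
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[i - 1] = probs[i] * h * (h - 1) / (
            4.0 * (hom_rare + 1) * (hom_common + 1)
        )
    probs /= probs.sum()
    obs = probs[hets.index(het)]  # het always shares rare's parity
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def hwe_chi2(hom_ref: int, het: int, hom_alt: int) -> float:
    """Chi-square HWE p-value (1 df), kept as a cross-check."""
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * hom_ref + het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([hom_ref, het, hom_alt], dtype=float)
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(
    cohort: PhasedCohort, panel: SamplePanel, group: str = "ALL"
) -> np.ndarray:
    """Exact HWE p-value per site for the samples of ``group``."""
    members = panel.members(group)
    if not members:
        raise ValueError(f"group {group!r} is empty")
    hr, he, ha = genotype_counts(cohort, members)
    return np.array(
        [hwe_exact(int(a), int(b), int(c)) for a, b, c in zip(hr, he, ha)]
    )


@dataclass
class DensityProfile:
    """SNV counts per genomic bin at several MAF cutoffs."""

    region: GenomicRegion
    bin_bp: int
    bin_starts: np.ndarray  # 1-based inclusive
    bin_ends: np.ndarray
    counts: dict[float, np.ndarray]  # cutoff -> per-bin counts
    last_bin_partial: bool

    def mean(self, cutoff: float) -> float:
        return float(self.counts[cutoff].mean())


def snv_density(
    cohort: PhasedCohort,
    region: GenomicRegion,
    bin_bp: int = 100,
    cutoffs: Sequence[float] = (0.0, 0.01, 0.05),
) -> DensityProfile:
    """Count biallelic SNVs per ``bin_bp`` bin at each MAF cutoff.

    Bins tile the region from its start; a final partial bin is included
    and flagged. Cutoff 0 counts every biallelic SNV; stricter cutoffs are
    bin-wise subsets of looser ones by construction.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    edges = np.arange(region.start, region.end + 1, bin_bp)
    starts = edges
    ends = np.minimum(edges + bin_bp - 1, region.end)
    snv = np.array(
        [
            s.is_biallelic_snv and region.contains(s.chromosome, s.position)
            for s in cohort.sites
        ]
    )
    pos = cohort.positions
    freqs = allele_frequencies(cohort)
    maf = np.minimum(freqs, 1.0 - freqs)
    counts: dict[float, np.ndarray] = {}
    for cut in cutoffs:
        keep = snv & (maf >= cut) if cut > 0 else snv
        if keep.any():
            bins = (pos[keep] - region.start) // bin_bp
            counts[cut] = np.bincount(bins, minlength=len(starts)).astype(np.int64)
        else:
            counts[cut] = np.zeros(len(starts), dtype=np.int64)
    return DensityProfile(
        region=region,
        bin_bp=bin_bp,
        bin_starts=starts,
        bin_ends=ends,
        counts=counts,
        last_bin_partial=(region.length % bin_bp != 0),
    )


def detect_stratification(
    cohort: PhasedCohort,
    panel: SamplePanel,
    merged_group: str,
    subgroups: Sequence[str],
    p_threshold: float = 0.01,
) -> list[int]:
    """Flag loci showing the Wahlund pattern in a merged group.

    A locus is flagged when the merged group's exact HWE p-value is at or
    below ``p_threshold`` while every subgroup's p-value is above it —
    heterozygote deficit created purely by pooling differentiated
    subpopulations. The subgroups must partition the merged group.
    """
    merged = set(panel.members(merged_group))
    seen: set[str] = set()
    for g in subgroups:
        members = set(panel.members(g))
        if members & seen:
            raise ValueError(f"subgroup {g!r} overlaps another subgroup")
        seen |= members
    if seen != merged:
        raise ValueError("subgroups do not partition the merged group")
    p_merged = hwe_pvalues(cohort, panel, merged_group)
    p_subs = [hwe_pvalues(cohort, panel, g) for g in subgroups]
    flagged = []
    for j in range(cohort.n_sites):
        if p_merged[j] <= p_threshold and all(p[j] > p_threshold for p in p_subs):
            flagged.append(j)
    return flagged
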