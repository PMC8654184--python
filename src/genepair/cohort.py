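"""Core containers: phased cohorts and sample panels.

A :class:`PhasedCohort` holds the phased allele matrix for a set of diploid
samples: one row per chromatid (two per sample, phase order preserved) and
one column per variant site. A cohort of N samples therefore has 2N
chromatids, the unit in which every statistic downstream counts alleles.

A :class:`SamplePanel` assigns each sample a population code, a supergroup
(continental) code derived from the population, and a sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .regions import GenomicRegion

#: 1000 Genomes phase 3 population -> continental supergroup.
DEFAULT_SUPERGROUPS: dict[str, str] = {
    # African
    "ACB": "AFR", "ASW": "AFR", "ESN": "AFR", "GWD": "AFR",
    "LWK": "AFR", "MSL": "AFR", "YRI": "AFR",
    # American
    "CLM": "AMR", "MXL": "AMR", "PEL": "AMR", "PUR": "AMR",
    # East Asian
    "CDX": "EAS", "CHB": "EAS", "CHS": "EAS", "JPT": "EAS", "KHV": "EAS",
    # European
    "CEU": "EUR", "FIN": "EUR", "GBR": "EUR", "IBS": "EUR", "TSI": "EUR",
    # South Asian
    "BEB": "SAS", "GIH": "SAS", "ITU": "SAS", "PJL": "SAS", "STU": "SAS",
}

SUPERGROUP_CODES = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass(frozen=True)
class Site:
    """One variant record: position, identifiers and allele list."""

    chromosome: str
    position: int
    rsid: str
    ref: str
    alts: tuple[str, ...]

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def is_snv(self) -> bool:
        return all(len(a) == 1 for a in self.alleles)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_biallelic_snv(self) -> bool:
        return self.is_biallelic and self.is_snv

    @property
    def variant_class(self) -> str:
        if not self.is_biallelic:
            return "multiallelic"
        return "SNV" if self.is_snv else "indel"


class PhasedCohort:
    """Phased allele matrix plus site and sample metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    sites
        Ordered :class:`Site` records; positions must be non-decreasing
        within each chromosome.
    alleles
        Integer matrix of allele indices, shape ``(2 * n_samples, n_sites)``.
        Rows ``2i`` and ``2i + 1`` are the two chromatids of sample ``i`` in
        the phase order of the source file.
    """

    def __init__(
        self,
        samples: Sequence[str],
        sites: Sequence[Site],
        alleles: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.sites = list(sites)
        alleles = np.asarray(alleles, dtype=np.int16)
        if alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-dimensional")
        if alleles.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError(
                f"allele matrix shape {alleles.shape} does not match "
                f"{2 * len(self.samples)} chromatids x {len(self.sites)} sites"
            )
        for j, site in enumerate(self.sites):
            col = alleles[:, j]
            if col.size and (col.min() < 0 or col.max() >= len(site.alleles)):
                raise ValueError(
                    f"allele index out of range at {site.chromosome}:{site.position}"
                )
        self._check_sorted()
        self.alleles = alleles

    def _check_sorted(self) -> None:
        last: dict[str, int] = {}
        for site in self.sites:
            prev = last.get(site.chromosome)
            if prev is not None and site.position < prev:
                raise ValueError(
                    f"site positions not sorted at {site.chromosome}:{site.position}"
                )
            last[site.chromosome] = site.position

    # -- basic shape ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_chromatids(self) -> int:
        return 2 * len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in cohort") from None

    def chromatid_rows(self, samples: Iterable[str]) -> np.ndarray:
        """Row indices of both chromatids of the given samples, phase order kept."""
        rows = []
        for s in samples:
            i = self.sample_index(s)
            rows.extend((2 * i, 2 * i + 1))
        return np.array(rows, dtype=np.intp)

    # -- subsetting -----------------------------------------------------
    def subset_samples(self, samples: Sequence[str]) -> "PhasedCohort":
        """Restrict to the given samples; per-site allele lists are untouched."""
        rows = self.chromatid_rows(samples)
        return PhasedCohort(list(samples), self.sites, self.alleles[rows, :])

    def subset_sites(self, keep: np.ndarray) -> "PhasedCohort":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep.astype(np.intp)
        sites = [self.sites[j] for j in idx]
        return PhasedCohort(self.samples, sites, self.alleles[:, idx])

    def restrict_region(self, region: GenomicRegion) -> "PhasedCohort":
        keep = np.array(
            [region.contains(s.chromosome, s.position) for s in self.sites],
            dtype=bool,
        )
        return self.subset_sites(keep)

    # -- equality (exact field equality, used by round-trip tests) ------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhasedCohort):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.sites == other.sites
            and np.array_equal(self.alleles, other.alleles)
        )

    def __repr__(self) -> str:
        return (
            f"PhasedCohort({self.n_samples} samples, {self.n_sites} sites)"
        )


@dataclass
class SamplePanel:
    """Sample -> (population, supergroup, sex) assignments."""

    population: dict[str, str] = field(default_factory=dict)
    supergroup: dict[str, str] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)

    def add(self, sample: str, population: str, supergroup: str, sex: str) -> None:
        if sample in self.population:
            raise ValueError(f"duplicate sample {sample!r} in panel")
        self.population[sample] = population
        self.supergroup[sample] = supergroup
        self.sex[sample] = sex

    @property
    def samples(self) -> list[str]:
        return list(self.population)

    def __len__(self) -> int:
        return len(self.population)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population.values():
            seen.setdefault(p)
        return list(seen)

    def supergroups(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.supergroup.values():
            seen.setdefault(p)
        return list(seen)

    def members(self, group: str = "ALL", sex: str | None = None) -> list[str]:
        """Samples in a group, optionally restricted by sex.

        ``group`` may be ``"ALL"``, a supergroup code, a population code, or
        a merger written ``"EAS+SAS"``.
        """
        parts = {g for g in group.split("+")} if group != "ALL" else None
        out = []
        for s in self.population:
            if parts is not None:
                if self.population[s] not in parts and self.supergroup[s] not in parts:
                    continue
            if sex is not None and self.sex[s] != sex:
                continue
            out.append(s)
        return out

    def subset(self, samples: Sequence[str]) -> "SamplePanel":
        sub = SamplePanel()
        for s in samples:
            sub.add(s, self.population[s], self.supergroup[s], self.sex[s])
        return sub


def allele_counts(
    cohort: PhasedCohort, rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt count, chromatid count) over the given chromatid rows.

    Sites must be biallelic for the alt count to be meaningful; multiallelic
    sites report the count of non-reference alleles.
    """
    mat = cohort.alleles if rows is None else cohort.alleles[rows, :]
    alt = (mat > 0).sum(axis=0)
    n = np.full(cohort.n_sites, mat.shape[0], dtype=np.int64)
    return alt, n


def site_maf(cohort: PhasedCohort, rows: np.ndarray | None = None) -> np.ndarray:
    """Minor allele frequency per site: min(p, 1 - p) of the non-ref index."""
    alt, n = allele_counts(cohort, rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, 0.0)
    return np.minimum(p, 1.0 - p)


def filter_sites(
    cohort: PhasedCohort,
    keep_biallelic_snv: bool = True,
    maf_min: float = 0.0,
    maf_group: str = "ALL",
    panel: SamplePanel | None = None,
) -> PhasedCohort:
    """Drop indel/multiallelic records and/or low-MAF sites.

    MAF is computed on the chromatids of ``maf_group`` (default: the whole
    cohort pooled) *before* thresholding, and sites with MAF strictly below
    ``maf_min`` are removed. Idempotent by construction.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if cohort.n_sites == 0:
        return cohort
    keep = np.ones(cohort.n_sites, dtype=bool)
    if keep_biallelic_snv:
        keep &= np.array([s.is_biallelic_snv for s in cohort.sites])
    if maf_min > 0.0:
        if maf_group == "ALL" or panel is None:
            rows = None
        else:
            rows = cohort.chromatid_rows(panel.members(maf_group))
        keep &= site_maf(cohort, rows) >= maf_min
    return cohort.subset_sites(keep)
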