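"""Synthetic phased cohorts with controlled population structure.

The generator stands in for a 1000-Genomes-like dataset: 26 populations
nested in 5 continental supergroups, phased diploid chromatids, and — on
top of a linkage-equilibrium Balding-Nichols baseline — implanted
multi-marker haplotype blocks with per-population frequencies, selective
sweep signatures (polymorphism thinning, SFS skew toward singletons and
near-fixed alleles, two-block LD around the sweep center) and balancing
signatures (clustered intermediate-frequency alleles correlated with a
core site). Matching outgroup and archaic single-genome fixtures can be
derived from any cohort.

Every function is a pure function of (spec, seed): identical seeds give
identical outputs.

Population structure follows the Balding-Nichols model: each population's
allele frequency at a site is drawn Beta(p(1-F)/F, (1-p)(1-F)/F) around
the ancestral frequency p, so that the dispersion parameter F maps
directly onto the expected Weir-Cockerham FST — giving a parameter
recovery test downstream. Two levels are supported (supergroup F, then
population-within-supergroup F) to emulate continental nesting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import DEFAULT_SUPERGROUPS, PhasedCohort, SamplePanel, Site
from .regions import GenomicRegion

#: 1000 Genomes phase 3 per-population sample counts (sum 2504).
THOUSAND_GENOMES_POP_SIZES: dict[str, int] = {
    "ACB": 96, "ASW": 61, "ESN": 99, "GWD": 113, "LWK": 99, "MSL": 85,
    "YRI": 108,
    "CLM": 94, "MXL": 64, "PEL": 85, "PUR": 104,
    "CDX": 93, "CHB": 103, "CHS": 105, "JPT": 104, "KHV": 99,
    "CEU": 99, "FIN": 99, "GBR": 91, "IBS": 107, "TSI": 107,
    "BEB": 86, "GIH": 103, "ITU": 102, "PJL": 96, "STU": 102,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PopulationSpec:
    code: str
    supergroup: str
    n_samples: int
    male_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"population {self.code}: n_samples must be >= 1")


@dataclass
class StructureSpec:
    """Cohort-level simulation parameters.

    ``F`` is the Balding-Nichols dispersion applied per population. When
    ``F_super`` is nonzero the draw is hierarchical: supergroup
    frequencies are drawn around the ancestral frequency with ``F_super``,
    then population frequencies around their supergroup's with ``F``.
    ``ancestral_freq_sampler`` is ``("uniform", lo, hi)`` or
    ``("beta", a, b)`` over (0, 1).
    """

    region: GenomicRegion
    n_sites: int
    populations: Sequence[PopulationSpec]
    F: float = 0.02
    F_super: float = 0.0
    ancestral_freq_sampler: tuple = ("uniform", 0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.F < 1.0 or not 0.0 <= self.F_super < 1.0:
            raise ValueError("F parameters must lie in [0, 1)")


@dataclass
class HaplotypeBlockSpec:
    """A multi-marker haplotype pool with per-group frequency vectors.

    ``markers``: ordered (position, rsID) pairs; ``pool``: allele strings of
    the same length as ``markers``; ``freqs``: group code (population,
    supergroup or "ALL") -> frequency vector over the pool, summing to 1.
    """

    markers: Sequence[tuple[int, str]]
    pool: Sequence[str]
    freqs: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        k = len(self.markers)
        for h in self.pool:
            if len(h) != k:
                raise ValueError(f"haplotype {h!r} length != {k} markers")
        for group, vec in self.freqs.items():
            if len(vec) != len(self.pool):
                raise ValueError(f"frequency vector for {group!r} wrong length")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(
                    f"frequency vector for {group!r} sums to {sum(vec)}, not 1"
                )


@dataclass
class SelectionSignatureSpec:
    """Parameters of an implanted sweep or balancing signature.

    Sweep intensities: ``thinning_frac`` removes that fraction of sites in
    the span; of the survivors, ``singleton_excess`` are redrawn to be
    singleton or near-fixed and ``ld_fraction`` are tied to two founder
    haplotypes per side of the center (high within-side LD, low cross-side
    LD). All three at 0 leave the cohort untouched.

    Balancing: ``concentration`` is the per-chromatid flip probability away
    from the core site's allele; smaller values concentrate folded
    frequencies more tightly around 0.5.
    """

    kind: str  # "sweep" | "balancing"
    center: int
    span: int
    thinning_frac: float = 0.8
    singleton_excess: float = 0.5
    ld_fraction: float = 0.5
    concentration: float = 0.1
    founder_freq: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("sweep", "balancing"):
            raise ValueError(f"unknown signature kind {self.kind!r}")
        if self.span <= 0:
            raise ValueError("span must be > 0")
        for name in ("thinning_frac", "singleton_excess", "ld_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.singleton_excess + self.ld_fraction > 1.0 + 1e-12:
            raise ValueError("singleton_excess + ld_fraction must be <= 1")
        if not 0.0 <= self.concentration <= 0.5:
            raise ValueError("concentration must lie in [0, 0.5]")


def thousand_genomes_populations(
    scale: float = 1.0, male_fraction: float = 0.5
) -> list[PopulationSpec]:
    """The 26 populations with phase-3 sample counts, optionally scaled down."""
    pops = []
    for code, n in THOUSAND_GENOMES_POP_SIZES.items():
        n_scaled = max(2, int(round(n * scale)))
        pops.append(
            PopulationSpec(code, DEFAULT_SUPERGROUPS[code], n_scaled, male_fraction)
        )
    return pops


def draw_subpop_freqs(
    p_anc: float, F: float, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies around ``p_anc``.

    Each of the K frequencies is Beta(p(1-F)/F, (1-p)(1-F)/F); the first
    two moments give E[p_k] = p and Var[p_k] = F p (1 - p), the property
    the FST parameter-recovery tests rely on. F = 0 returns ``p_anc``
    exactly for all K.
    """
    if not 0.0 < p_anc < 1.0:
        raise ValueError("p_anc must lie in (0, 1)")
    if not 0.0 <= F < 1.0:
        raise ValueError("F must lie in [0, 1)")
    if F == 0.0:
        return np.full(K, p_anc)
    scale = (1.0 - F) / F
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=K)


def _sample_ancestral(spec_tuple: tuple, size: int, rng: np.random.Generator):
    kind = spec_tuple[0]
    if kind == "uniform":
        _, lo, hi = spec_tuple
        return rng.uniform(lo, hi, size=size)
    if kind == "beta":
        _, a, b = spec_tuple
        p = rng.beta(a, b, size=size)
        return np.clip(p, 1e-6, 1.0 - 1e-6)
    raise ValueError(f"unknown ancestral_freq_sampler {spec_tuple!r}")


def simulate_cohort(spec: StructureSpec) -> tuple[PhasedCohort, SamplePanel]:
    """Draw a phased cohort + panel under the Balding-Nichols model.

    Chromatids are drawn independently per site from their population's
    frequency (linkage-equilibrium baseline), so genotypes are
    Hardy-Weinberg within populations by construction and any LD observed
    downstream is exactly what implants created. Sex is assigned
    independently of genotype.
    """
    rng = np.random.default_rng(spec.seed)
    pops = list(spec.populations)
    panel = SamplePanel()
    samples: list[str] = []
    for pop in pops:
        n_m = int(round(pop.n_samples * pop.male_fraction))
        sexes = np.array(["male"] * n_m + ["female"] * (pop.n_samples - n_m))
        rng.shuffle(sexes)
        for i in range(pop.n_samples):
            sid = f"{pop.code}{i:04d}"
            samples.append(sid)
            panel.add(sid, pop.code, pop.supergroup, str(sexes[i]))

    n_total = len(samples)
    if spec.n_sites == 0:
        empty = np.empty((2 * n_total, 0), dtype=np.int16)
        return PhasedCohort(samples, [], empty), panel

    if spec.n_sites > spec.region.length:
        raise ValueError("more sites requested than positions in region")
    positions = np.sort(
        rng.choice(spec.region.length, size=spec.n_sites, replace=False)
        + spec.region.start
    )
    p_anc = _sample_ancestral(spec.ancestral_freq_sampler, spec.n_sites, rng)

    supergroups = sorted({p.supergroup for p in pops})
    sg_index = {sg: i for i, sg in enumerate(supergroups)}
    # per-site frequency for each population, possibly nested
    pop_freqs = np.empty((len(pops), spec.n_sites))
    for j in range(spec.n_sites):
        if spec.F_super > 0.0:
            sg_p = draw_subpop_freqs(p_anc[j], spec.F_super, len(supergroups), rng)
            sg_p = np.clip(sg_p, 1e-9, 1.0 - 1e-9)
            for k, pop in enumerate(pops):
                base = sg_p[sg_index[pop.supergroup]]
                pop_freqs[k, j] = draw_subpop_freqs(base, spec.F, 1, rng)[0]
        else:
            pop_freqs[:, j] = draw_subpop_freqs(p_anc[j], spec.F, len(pops), rng)

    alleles = np.empty((2 * n_total, spec.n_sites), dtype=np.int16)
    row = 0
    for k, pop in enumerate(pops):
        n_chrom = 2 * pop.n_samples
        draws = rng.random((n_chrom, spec.n_sites)) < pop_freqs[k]
        alleles[row : row + n_chrom, :] = draws.astype(np.int16)
        row += n_chrom

    sites = []
    for j, pos in enumerate(positions):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        sites.append(Site(spec.region.chromosome, int(pos), f"rs_sim{j}", ref, (alt,)))
    return PhasedCohort(samples, sites, alleles), panel


def _group_freq_vector(
    block: HaplotypeBlockSpec, panel: SamplePanel, sample: str
) -> Sequence[float]:
    pop = panel.population[sample]
    sg = panel.supergroup[sample]
    for key in (pop, sg, "ALL"):
        if key in block.freqs:
            return block.freqs[key]
    raise KeyError(f"no haplotype frequency vector for sample {sample!r} ({pop}/{sg})")


def implant_haplotype_block(
    cohort: PhasedCohort,
    panel: SamplePanel,
    block: HaplotypeBlockSpec,
    rng: np.random.Generator,
) -> PhasedCohort:
    """Overwrite marker columns with haplotypes drawn per population.

    Each chromatid receives a pool haplotype drawn from its population's
    frequency vector; sites outside the marker set are untouched. The
    marker positions must already exist in the cohort and every pool
    allele letter must be a REF/ALT letter at its site.
    """
    pos_to_col = {s.position: j for j, s in enumerate(cohort.sites)}
    cols = []
    for pos, _rsid in block.markers:
        if pos not in pos_to_col:
            raise ValueError(f"marker position {pos} not present in cohort")
        cols.append(pos_to_col[pos])
    # map haplotype letters to allele indices per marker
    hap_indices = np.empty((len(block.pool), len(cols)), dtype=np.int16)
    for h, hap in enumerate(block.pool):
        for m, col in enumerate(cols):
            site = cohort.sites[col]
            try:
                hap_indices[h, m] = site.alleles.index(hap[m])
            except ValueError:
                raise ValueError(
                    f"haplotype letter {hap[m]!r} not an allele at "
                    f"{site.chromosome}:{site.position} ({site.alleles})"
                ) from None
    alleles = cohort.alleles.copy()
    for i, sample in enumerate(cohort.samples):
        vec = np.asarray(_group_freq_vector(block, panel, sample), dtype=float)
        for c in (2 * i, 2 * i + 1):
            h = rng.choice(len(block.pool), p=vec)
            alleles[c, cols] = hap_indices[h]
    return PhasedCohort(cohort.samples, cohort.sites, alleles)


def implant_selection_signature(
    cohort: PhasedCohort,
    spec: SelectionSignatureSpec,
    rng: np.random.Generator,
) -> PhasedCohort:
    """Implant a sweep or balancing signature inside ``spec``'s span.

    Sweep: sites are thinned, a fraction of survivors are redrawn to be
    singleton/near-fixed, and another fraction is tied to one of two
    founder haplotypes per side of the center so that LD is high for
    pairs on the same side of the center and low across it. Balancing:
    site density is preserved; frequencies are redrawn near 0.5 with
    alleles correlated to a core site at the center.
    """
    positions = cohort.positions
    lo = spec.center - spec.span // 2
    hi = spec.center + spec.span // 2
    if cohort.n_sites and (lo < positions.min() or hi > positions.max()):
        raise ValueError(
            f"signature span {lo}-{hi} exceeds cohort bounds "
            f"{positions.min()}-{positions.max()}"
        )
    inside = np.flatnonzero((positions >= lo) & (positions <= hi))
    n_chrom = cohort.n_chromatids

    if spec.kind == "sweep":
        if (
            spec.thinning_frac == 0.0
            and spec.singleton_excess == 0.0
            and spec.ld_fraction == 0.0
        ):
            return cohort
        keep_mask = np.ones(cohort.n_sites, dtype=bool)
        survivors = []
        for j in inside:
            if rng.random() < spec.thinning_frac:
                keep_mask[j] = False
            else:
                survivors.append(j)
        alleles = cohort.alleles.copy()
        # two founder haplotypes per side of the center
        left_label = (rng.random(n_chrom) < spec.founder_freq).astype(np.int16)
        right_label = (rng.random(n_chrom) < spec.founder_freq).astype(np.int16)
        for j in survivors:
            u = rng.random()
            if u < spec.singleton_excess:
                col = np.zeros(n_chrom, dtype=np.int16)
                carrier = rng.integers(n_chrom)
                if rng.random() < 0.5:
                    col[carrier] = 1  # singleton
                else:
                    col[:] = 1
                    col[carrier] = 0  # near-fixed
                alleles[:, j] = col
            elif u < spec.singleton_excess + spec.ld_fraction:
                label = left_label if positions[j] <= spec.center else right_label
                alleles[:, j] = label
            # else: untouched background site
        out = PhasedCohort(cohort.samples, cohort.sites, alleles)
        return out.subset_sites(keep_mask)

    # balancing: correlate alleles with a core site, frequencies near 0.5
    if inside.size == 0:
        return cohort
    core = inside[np.argmin(np.abs(positions[inside] - spec.center))]
    alleles = cohort.alleles.copy()
    z = np.zeros(n_chrom, dtype=np.int16)
    z[rng.permutation(n_chrom)[: n_chrom // 2]] = 1  # core folded freq = 0.5
    alleles[:, core] = z
    for j in inside:
        if j == core:
            continue
        flips = (rng.random(n_chrom) < spec.concentration).astype(np.int16)
        alleles[:, j] = z ^ flips
    return PhasedCohort(cohort.samples, cohort.sites, alleles)


# ---------------------------------------------------------------------------
# Outgroup and archaic fixtures
# ---------------------------------------------------------------------------


@dataclass
class OutgroupFixture:
    """A synthetic outgroup alignment with per-marker flanks.

    ``sequence`` covers ``region`` contiguously, embeds the cohort's
    reference allele at every cohort site, and the specified ancestral
    allele at each marker. ``flanks`` maps rsID -> (flank5, flank3), each
    flank unique in the sequence as a ``flank5·X·flank3`` context.
    """

    region: GenomicRegion
    sequence: str
    flanks: dict[str, tuple[str, str]] = field(default_factory=dict)

    def write_fasta(self, path: str | os.PathLike, name: str = "outgroup") -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write(f">{name} {self.region}\n")
            seq = self.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    def write_flanks(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write("rsid\tflank5\tflank3\n")
            for rsid, (f5, f3) in self.flanks.items():
                fh.write(f"{rsid}\t{f5}\t{f3}\n")


def _context_count(seq: str, f5: str, f3: str) -> int:
    """Occurrences of f5·X·f3 with X a single base."""
    count = 0
    start = 0
    while True:
        i = seq.find(f5, start)
        if i < 0:
            return count
        j = i + len(f5) + 1
        if seq[j : j + len(f3)] == f3:
            count += 1
        start = i + 1


def make_outgroup(
    cohort: PhasedCohort,
    markers: Sequence[tuple[int, str]],
    ancestral: str,
    region: GenomicRegion | None = None,
    flank: int = 20,
    rng: np.random.Generator | None = None,
    max_retries: int = 5,
) -> OutgroupFixture:
    """Build an outgroup sequence embedding ancestral alleles at markers.

    The background is random sequence carrying the cohort's REF letters at
    all cohort sites, so each marker's flanks are the cohort reference
    context. Flank uniqueness is verified; on collision the background is
    regenerated up to ``max_retries`` times.
    """
    if len(ancestral) != len(markers):
        raise ValueError("ancestral string length must equal marker count")
    if rng is None:
        rng = np.random.default_rng(0)
    if region is None:
        positions = cohort.positions
        chrom = cohort.sites[0].chromosome
        region = GenomicRegion(
            chrom, int(positions.min()) - flank - 5, int(positions.max()) + flank + 5
        )
    for _attempt in range(max_retries):
        seq = rng.choice(_BASES, size=region.length)
        for site in cohort.sites:
            if region.contains(site.chromosome, site.position) and len(site.ref) == 1:
                seq[site.position - region.start] = site.ref
        for (pos, _rsid), anc in zip(markers, ancestral):
            seq[pos - region.start] = anc
        text = "".join(seq)
        flanks: dict[str, tuple[str, str]] = {}
        ok = True
        for pos, rsid in markers:
            off = pos - region.start
            if off - flank < 0 or off + flank >= len(text):
                raise ValueError(f"marker {rsid} too close to region edge for flanks")
            f5 = text[off - flank : off]
            f3 = text[off + 1 : off + 1 + flank]
            if _context_count(text, f5, f3) != 1:
                ok = False
                break
            flanks[rsid] = (f5, f3)
        if ok:
            return OutgroupFixture(region, text, flanks)
    raise RuntimeError("could not build outgroup with unique flanks (retry budget)")


def write_archaic_vcf(
    path: str | os.PathLike,
    cohort: PhasedCohort,
    genotypes: Mapping[int, tuple[str, str]],
    sample_name: str = "archaic",
) -> None:
    """Write a single-genome diploid VCF at marker positions.

    ``genotypes`` maps position -> (allele letter, allele letter); markers
    absent from the mapping are simply not written (missing data is a
    state the lookup reports, not an error). Genotypes may be heterozygous
    and are written unphased, as archaic genomes are.
    """
    pos_to_site = {s.position: s for s in cohort.sites}
    with open(os.fspath(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genepair-synthetic-archaic\n")
        chroms: dict[str, None] = {}
        for pos in genotypes:
            chroms.setdefault(pos_to_site[pos].chromosome)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_name
            + "\n"
        )
        for pos in sorted(genotypes):
            site = pos_to_site[pos]
            a, b = genotypes[pos]
            letters = [site.ref]
            for x in (a, b):
                if x not in letters:
                    letters.append(x)
            alts = letters[1:] or [site.alts[0]]
            gt = f"{letters.index(a)}/{letters.index(b)}"
            fh.write(
                f"{site.chromosome}\t{pos}\t{site.rsid}\t{site.ref}\t"
                f"{','.join(alts)}\t.\tPASS\t.\tGT\t{gt}\n"
            )
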