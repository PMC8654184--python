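"""Config-driven end-to-end analysis of an interacting gene pair.

``run_genepair_analysis`` executes the full stage order — filter cascade,
site statistics, diversity/neutrality, differentiation + PCA, marker
selection, per-group haplotype tables, cross-gene combined haplotypes
with the Wilcoxon test, intergenic LD, chromosome scans, ancestral
polarization and archaic lookups — writing one TSV per table plus a JSON
manifest that records every threshold used (the thresholds the
literature leaves dual-valued, like the HWE p cutoff and the FST MAF
floor, are the main reproducibility risk, so provenance is explicit).

``make_demo_dataset`` emits a complete synthetic fixture: a
26-population / 5-supergroup cohort for each of two gene regions with
implanted haplotype pools, scan chromosomes with a sweep planted ~2 Mb
from one gene and a balanced locus at the other, plus outgroup and
archaic fixtures, and a ready-to-run YAML config. Every stage is seeded,
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import os
import traceback
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import PhasedCohort, SamplePanel, filter_sites
from .diversity import nucleotide_diversity, tajimas_d, watterson_theta
from .fst import (
    BenchmarkBand,
    benchmark_compare,
    fst_between,
    fst_pca,
    pairwise_fst_matrix,
)
from .haplotypes import (
    MarkerSet,
    combined_haplotypes,
    haplotype_frequencies,
    intergenic_max_r2,
    select_markers,
    wilcoxon_matched_pairs,
)
from .io import read_panel, read_phased_vcf, write_panel, write_vcf
from .regions import GenomicRegion
from .ancestry import (
    ancestral_haplotype,
    archaic_haplotype_lookup,
    count_derived,
    read_fasta_sequence,
    read_flanks_tsv,
)
from .scan import beta_scan, mu_scan
from .simulate import (
    HaplotypeBlockSpec,
    PopulationSpec,
    SelectionSignatureSpec,
    StructureSpec,
    implant_haplotype_block,
    implant_selection_signature,
    make_outgroup,
    simulate_cohort,
    thousand_genomes_populations,
    write_archaic_vcf,
)

SUPERGROUP_ORDER = ["AFR", "AMR", "EAS", "EUR", "SAS"]


@dataclass
class GeneConfig:
    name: str
    vcf: str
    region: GenomicRegion
    marker_rsids: list[str] = field(default_factory=list)
    focal_sex: str | None = None  # sex whose gametes express the gene
    outgroup_fasta: str | None = None
    outgroup_flanks: str | None = None


@dataclass
class ScanConfig:
    vcf: str
    kind: str  # "mu" | "beta"
    mask: list[GenomicRegion] = field(default_factory=list)
    marked_region: GenomicRegion | None = None
    window_snps: int = 50
    window_bp: int = 1000
    quantile: float = 0.9995


@dataclass
class RunConfig:
    panel: str
    gene_a: GeneConfig
    gene_b: GeneConfig
    out_dir: str
    seed: int = 0
    hap_maf_min: float = 0.05
    hwe_p_min: float = 0.01
    fst_maf_min: float = 0.05
    sex_fst_maf_min: float = 0.01
    intergenic_maf_min: float = 0.01
    scans: list[ScanConfig] = field(default_factory=list)
    archaic_vcfs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def _p(rel: str | None) -> str | None:
            if rel is None:
                return None
            return rel if os.path.isabs(rel) else os.path.join(base, rel)

        def _gene(d: dict) -> GeneConfig:
            return GeneConfig(
                name=d["name"],
                vcf=_p(d["vcf"]),
                region=GenomicRegion.parse(d["region"]),
                marker_rsids=list(d.get("marker_rsids", [])),
                focal_sex=d.get("focal_sex"),
                outgroup_fasta=_p(d.get("outgroup_fasta")),
                outgroup_flanks=_p(d.get("outgroup_flanks")),
            )

        scans = []
        for s in raw.get("scans", []):
            scans.append(
                ScanConfig(
                    vcf=_p(s["vcf"]),
                    kind=s["kind"],
                    mask=[GenomicRegion.parse(m) for m in s.get("mask", [])],
                    marked_region=(
                        GenomicRegion.parse(s["marked_region"])
                        if s.get("marked_region")
                        else None
                    ),
                    window_snps=int(s.get("window_snps", 50)),
                    window_bp=int(s.get("window_bp", 1000)),
                    quantile=float(
                        s.get("quantile", 0.9995 if s["kind"] == "mu" else 0.999)
                    ),
                )
            )
        thr = raw.get("thresholds", {})
        return cls(
            panel=_p(raw["panel"]),
            gene_a=_gene(raw["gene_a"]),
            gene_b=_gene(raw["gene_b"]),
            out_dir=_p(raw.get("out_dir", "results")),
            seed=int(raw.get("seed", 0)),
            hap_maf_min=float(thr.get("hap_maf_min", 0.05)),
            hwe_p_min=float(thr.get("hwe_p_min", 0.01)),
            fst_maf_min=float(thr.get("fst_maf_min", 0.05)),
            sex_fst_maf_min=float(thr.get("sex_fst_maf_min", 0.01)),
            intergenic_maf_min=float(thr.get("intergenic_maf_min", 0.01)),
            scans=scans,
            archaic_vcfs={
                k: _p(v) for k, v in raw.get("archaic_vcfs", {}).items()
            },
        )


@dataclass
class ReportBundle:
    """All stage outputs, in memory and on disk."""

    out_dir: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    manifest: dict[str, Any] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _write(bundle: ReportBundle, name: str, df: pd.DataFrame) -> None:
    df.to_csv(os.path.join(bundle.out_dir, f"{name}.tsv"), sep="\t", index=False)
    bundle.tables[name] = df


def _stage(bundle: ReportBundle, name: str):
    """Decorator-style stage runner: record failures, keep going."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                bundle.errors[name] = "".join(
                    traceback.format_exception_only(exc_type, exc)
                ).strip()
                return True
            return False

    return _Ctx()


def run_genepair_analysis(config: RunConfig) -> ReportBundle:
    """Execute all stages over the configured gene pair.

    Stage outputs are identical to invoking each module operation
    directly with the same inputs. A failed stage is recorded in the
    bundle's error manifest and later stages still run.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    bundle = ReportBundle(out_dir=config.out_dir)
    panel = read_panel(config.panel)
    genes = {"gene_a": config.gene_a, "gene_b": config.gene_b}
    cohorts: dict[str, PhasedCohort] = {}
    markers: dict[str, MarkerSet] = {}
    groups = [g for g in SUPERGROUP_ORDER if g in panel.supergroups()]

    with _stage(bundle, "load"):
        for key, gene in genes.items():
            cohorts[key] = read_phased_vcf(gene.vcf, region=gene.region)

    with _stage(bundle, "filter_cascade"):
        rows = []
        for key, gene in genes.items():
            snv = filter_sites(cohorts[key], keep_biallelic_snv=True)
            for group in groups + ["ALL"]:
                row = {"gene": gene.name, "population": group}
                row.update(_cascade_counts(
                    snv, panel, group, None, config.hap_maf_min,
                    config.hwe_p_min,
                ))
                if gene.focal_sex:
                    row["passing_focal_sex"] = _cascade_counts(
                        snv, panel, group, gene.focal_sex,
                        config.hap_maf_min, config.hwe_p_min,
                    )["passing_maf_and_hwe"]
                rows.append(row)
        _write(bundle, "filter_cascade", pd.DataFrame(rows))

    with _stage(bundle, "diversity"):
        rows = []
        for key, gene in genes.items():
            snv = filter_sites(cohorts[key], keep_biallelic_snv=True)
            for group in groups + ["ALL"]:
                res = tajimas_d(snv, panel, group, gene.region, mode="whole")
                res_b = tajimas_d(
                    snv, panel, group, gene.region, mode="binned", bin_bp=100
                )
                rows.append(
                    {
                        "gene": gene.name,
                        "population": group,
                        "n_chromatids": res.n,
                        "S": res.S,
                        "pi_region": res.pi,
                        "pi_per_site": res.pi / gene.region.length,
                        "theta_w": res.theta_w,
                        "tajima_d": res.tajima_d,
                        "tajima_d_binned_100bp": res_b.tajima_d,
                    }
                )
        _write(bundle, "diversity", pd.DataFrame(rows))

    with _stage(bundle, "differentiation"):
        band = BenchmarkBand()
        for key, gene in genes.items():
            snv = filter_sites(cohorts[key], keep_biallelic_snv=True)
            mat = pairwise_fst_matrix(snv, panel, groups, maf_min=config.fst_maf_min)
            df = pd.DataFrame(mat.values, index=groups, columns=groups)
            df.insert(0, "group", groups)
            _write(bundle, f"fst_supergroups_{gene.name}", df)
            pops = sorted(panel.populations())
            mat26 = pairwise_fst_matrix(snv, panel, pops, maf_min=config.fst_maf_min)
            df26 = pd.DataFrame(mat26.values, index=pops, columns=pops)
            df26.insert(0, "group", pops)
            _write(bundle, f"fst_populations_{gene.name}", df26)
            pca = fst_pca(mat26)
            dfp = pd.DataFrame(
                pca.coordinates[:, :2], columns=["PC1", "PC2"]
            )
            dfp.insert(0, "group", pops)
            dfp["pc1_variance_fraction"] = pca.variance_fractions[0]
            dfp["pc2_variance_fraction"] = pca.variance_fractions[1]
            _write(bundle, f"fst_pca_{gene.name}", dfp)
            # sex contrast: males vs females over all supergroups pooled
            sex_cohort = filter_sites(snv, maf_min=config.sex_fst_maf_min)
            theta_sex = fst_between(
                sex_cohort, panel, [("ALL", "male"), ("ALL", "female")]
            )
            bundle.scalars[f"sex_fst_{gene.name}"] = theta_sex
            # benchmark comparison of each group's pairwise values
            rows = []
            for g in groups:
                vals = [mat.get(g, h) for h in groups if h != g]
                cmp_res = benchmark_compare(vals, band)
                rows.append(
                    {
                        "gene": gene.name,
                        "group": g,
                        "mean_pairwise_fst": cmp_res.mean,
                        "sd": cmp_res.sd,
                        "within_band": sum(cmp_res.verdicts),
                        "n_pairs": cmp_res.n,
                        "t": cmp_res.t,
                        "p_two_tailed": cmp_res.p,
                    }
                )
            _write(bundle, f"fst_benchmark_{gene.name}", pd.DataFrame(rows))

    with _stage(bundle, "haplotypes"):
        for key, gene in genes.items():
            snv = filter_sites(cohorts[key], keep_biallelic_snv=True)
            mk = select_pair_markers(
                snv, panel, groups, config.hap_maf_min, config.hwe_p_min
            )
            if gene.marker_rsids:
                keep = [i for i, r in enumerate(mk.rsids) if r in gene.marker_rsids]
                mk = MarkerSet(
                    [mk.site_indices[i] for i in keep],
                    [mk.rsids[i] for i in keep],
                    [mk.positions[i] for i in keep],
                    [mk.alleles[i] for i in keep],
                    mk.maf_min, mk.hwe_p_min,
                )
            markers[key] = mk
            rows = []
            for group in groups + ["ALL"]:
                for sex in (None, "male", "female"):
                    table = haplotype_frequencies(snv, panel, mk, group, sex)
                    for hap, freq in table.reported(0.01).items():
                        rows.append(
                            {
                                "gene": gene.name,
                                "population": group,
                                "sex": sex or "all",
                                "haplotype": hap,
                                "frequency": round(freq, 2),
                                "frequency_raw": freq,
                                "n_chromatids": table.n_chromatids,
                            }
                        )
            _write(bundle, f"haplotypes_{gene.name}", pd.DataFrame(rows))

    with _stage(bundle, "combined_haplotypes"):
        snv_a = filter_sites(cohorts["gene_a"], keep_biallelic_snv=True)
        snv_b = filter_sites(cohorts["gene_b"], keep_biallelic_snv=True)
        table = combined_haplotypes(
            snv_a, snv_b, panel, markers["gene_a"], markers["gene_b"],
            group="ALL", min_single_freq=0.01,
        )
        df = pd.DataFrame(
            [
                {
                    "hap_a": r.hap_a,
                    "hap_b": r.hap_b,
                    "freq_a": round(r.freq_a, 2),
                    "freq_b": round(r.freq_b, 2),
                    "expected": round(r.expected, 2),
                    "observed": round(r.observed, 2),
                    "expected_raw": r.expected,
                    "observed_raw": r.observed,
                }
                for r in table
            ]
        )
        _write(bundle, "combined_haplotypes", df)
        p = wilcoxon_matched_pairs(
            [r.observed for r in table], [r.expected for r in table]
        )
        bundle.scalars["wilcoxon_combined_p"] = p
        res = intergenic_max_r2(
            snv_a, snv_b, panel, maf_min=config.intergenic_maf_min
        )
        bundle.scalars["intergenic_max_r2"] = res[0] if res else float("nan")

    with _stage(bundle, "scans"):
        for i, scfg in enumerate(config.scans):
            cohort = read_phased_vcf(scfg.vcf)
            cohort = filter_sites(cohort, keep_biallelic_snv=True)
            if scfg.kind == "mu":
                track = mu_scan(
                    cohort, window_snps=scfg.window_snps, mask=scfg.mask,
                    quantile=scfg.quantile,
                )
            else:
                track = beta_scan(
                    cohort, window_bp=scfg.window_bp, quantile=scfg.quantile,
                    mask=scfg.mask,
                )
            name = f"scan_{scfg.kind}_{i}"
            track.write_tsv(
                os.path.join(config.out_dir, f"{name}.tsv"),
                chromosome=cohort.sites[0].chromosome,
            )
            bundle.scalars[f"{name}_threshold"] = track.threshold
            bundle.scalars[f"{name}_n_flagged_intervals"] = len(track.flagged)
            if scfg.marked_region is not None:
                inside = [
                    (a, b)
                    for a, b in track.flagged
                    if a <= scfg.marked_region.end and b >= scfg.marked_region.start
                ]
                bundle.scalars[f"{name}_marked_region_flagged"] = float(
                    len(inside) > 0
                )

    with _stage(bundle, "ancestry"):
        rows = []
        for key, gene in genes.items():
            if not (gene.outgroup_fasta and gene.outgroup_flanks):
                continue
            seq = read_fasta_sequence(gene.outgroup_fasta)
            flanks = read_flanks_tsv(gene.outgroup_flanks)
            mk = markers[key]
            anc = ancestral_haplotype(seq, flanks, mk.rsids)
            bundle.scalars[f"ancestral_{gene.name}"] = anc
            snv = filter_sites(cohorts[key], keep_biallelic_snv=True)
            table = haplotype_frequencies(snv, None, mk, "ALL")
            for hap, freq in table.reported(0.01).items():
                if hap == "other":
                    continue
                rows.append(
                    {
                        "gene": gene.name,
                        "haplotype": hap,
                        "frequency_all": round(freq, 2),
                        "ancestral": anc,
                        "derived_alleles": count_derived(hap, anc),
                    }
                )
            for arch_name, arch_path in config.archaic_vcfs.items():
                call = archaic_haplotype_lookup(arch_path, mk.positions)
                hap = call.haplotype(mk.positions)
                rows.append(
                    {
                        "gene": gene.name,
                        "haplotype": hap
                        or "|".join(call.compatible_haplotypes(mk.positions)),
                        "frequency_all": float("nan"),
                        "ancestral": anc,
                        "derived_alleles": (
                            count_derived(hap, anc) if hap else None
                        ),
                        "archaic": arch_name,
                        "phase_unknown": call.phase_unknown,
                        "missing_markers": len(call.missing),
                    }
                )
        if rows:
            _write(bundle, "ancestry", pd.DataFrame(rows))

    bundle.manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "hap_maf_min": config.hap_maf_min,
            "hwe_p_min": config.hwe_p_min,
            "fst_maf_min": config.fst_maf_min,
            "sex_fst_maf_min": config.sex_fst_maf_min,
            "intergenic_maf_min": config.intergenic_maf_min,
        },
        "scalars": {
            k: v for k, v in bundle.scalars.items() if not isinstance(v, str)
        },
        "strings": {
            k: v for k, v in bundle.scalars.items() if isinstance(v, str)
        },
        "errors": bundle.errors,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    return bundle


def select_pair_markers(
    cohort: PhasedCohort,
    panel: SamplePanel,
    groups: list[str],
    maf_min: float,
    hwe_p_min: float,
) -> MarkerSet:
    """Markers passing the pooled MAF screen and the HWE screen in *every*
    supergroup separately.

    The pooled sample of differentiated populations fails HWE at
    stratified loci (Wahlund heterozygote deficit) even when each group
    is in equilibrium, so the equilibrium screen belongs at the group
    level; pooling it would discard exactly the differentiated markers
    the analysis is about.
    """
    per_group = [
        set(
            select_markers(cohort, panel, g, maf_min, hwe_p_min).site_indices
        )
        for g in groups
    ]
    keep = sorted(set.intersection(*per_group)) if per_group else []
    return MarkerSet(
        keep,
        [cohort.sites[j].rsid for j in keep],
        [cohort.sites[j].position for j in keep],
        [(cohort.sites[j].ref, cohort.sites[j].alts[0]) for j in keep],
        maf_min,
        hwe_p_min,
    )


def _cascade_counts(
    cohort: PhasedCohort,
    panel: SamplePanel,
    group: str,
    sex: str | None,
    maf_min: float,
    hwe_p_min: float,
) -> dict[str, int]:
    """Nested per-group counts: polymorphic -> MAF pass -> MAF+HWE pass.

    MAF is computed within the group here (the cascade reports what each
    population contributes), unlike marker selection which pools.
    """
    from .site_stats import hwe_exact as _hwe
    from .site_stats import genotype_counts as _gc

    members = panel.members(group, sex=sex)
    rows = cohort.chromatid_rows(members)
    mat = cohort.alleles[rows, :]
    alt = (mat > 0).sum(axis=0)
    n = mat.shape[0]
    p = alt / n
    maf = np.minimum(p, 1 - p)
    poly = maf > 0
    pass_maf = maf >= maf_min
    hr, he, ha = _gc(cohort.subset_samples(members), members)
    hwe_ok = np.array(
        [_hwe(int(a), int(b), int(c)) > hwe_p_min for a, b, c in zip(hr, he, ha)]
    )
    return {
        "total_snps": int(poly.sum()),
        "passing_maf": int(pass_maf.sum()),
        "passing_maf_and_hwe": int((pass_maf & hwe_ok).sum()),
    }


# ---------------------------------------------------------------------------
# Demo dataset
# ---------------------------------------------------------------------------

# Published-style haplotype pools for the two genes; frequency vectors are
# normalized per group (printed tables round to 2 decimals and need not sum
# to exactly 1).
_GENE_A_MARKERS = [
    ("rs2307018", ("C", "A")),
    ("rs2307019", ("G", "A")),
    ("rs838148", ("A", "G")),
]
_GENE_A_POOL = ["CGA", "AAG", "CGG"]
_GENE_A_FREQS = {
    "AFR": [0.35, 0.32, 0.33],
    "AMR": [0.16, 0.54, 0.29],
    "EUR": [0.09, 0.45, 0.46],
    "EAS": [0.14, 0.83, 0.01],
    "SAS": [0.29, 0.50, 0.22],
}
_GENE_B_MARKERS = [
    ("rs61742524", ("C", "G")),
    ("rs55784852", ("G", "A")),
    ("rs16920146", ("T", "C")),
    ("rs7925833", ("T", "G")),
    ("rs7935583", ("G", "A")),
]
_GENE_B_POOL = ["CGTTG", "GACGA", "GACTA"]
_GENE_B_FREQS = {
    "AFR": [0.69, 0.26, 0.05],
    "AMR": [0.97, 0.03, 0.0],
    "EUR": [0.99, 0.01, 0.0],
    "EAS": [0.99, 0.01, 0.0],
    "SAS": [0.97, 0.03, 0.0],
}
GENE_A_ANCESTRAL = "CGG"
GENE_B_ANCESTRAL = "GGCTG"
GENE_A_REGION = GenomicRegion("19", 49244073, 49250166)
GENE_B_REGION = GenomicRegion("11", 94038803, 94040858)


def _normalize(freqs: dict[str, list[float]]) -> dict[str, list[float]]:
    out = {}
    for g, v in freqs.items():
        arr = np.asarray(v, dtype=float)
        out[g] = list(arr / arr.sum())
    return out


def _marker_positions(region: GenomicRegion, k: int) -> list[int]:
    # evenly spaced, away from the edges so outgroup flanks always fit
    return [
        int(region.start + (i + 1) * region.length / (k + 1)) for i in range(k)
    ]


def _build_gene_cohort(
    region: GenomicRegion,
    n_sites: int,
    marker_defs: list[tuple[str, tuple[str, str]]],
    pool: list[str],
    freqs: dict[str, list[float]],
    pops: list[PopulationSpec],
    seed: int,
) -> tuple[PhasedCohort, SamplePanel, HaplotypeBlockSpec]:
    spec = StructureSpec(
        region=region, n_sites=n_sites, populations=pops,
        F=0.02, F_super=0.08,
        ancestral_freq_sampler=("beta", 0.3, 0.3), seed=seed,
    )
    cohort, panel = simulate_cohort(spec)
    # place markers at fixed positions with the published allele letters
    positions = _marker_positions(region, len(marker_defs))
    sites = list(cohort.sites)
    used = {s.position for s in sites}
    from .cohort import Site  # local to avoid a cycle at import time

    for pos, (rsid, (ref, alt)) in zip(positions, marker_defs):
        while pos in used:
            pos += 1
        used.add(pos)
        sites.append(Site(region.chromosome, pos, rsid, ref, (alt,)))
    order = np.argsort([s.position for s in sites], kind="stable")
    alleles = np.concatenate(
        [
            cohort.alleles,
            np.zeros((cohort.n_chromatids, len(marker_defs)), dtype=np.int16),
        ],
        axis=1,
    )[:, order]
    cohort = PhasedCohort(cohort.samples, [sites[i] for i in order], alleles)
    rsid_by_pos = {s.position: s.rsid for s in cohort.sites}
    block = HaplotypeBlockSpec(
        markers=[
            (pos, rsid_by_pos[pos])
            for pos in sorted(
                p for p in used
                if rsid_by_pos[p] in {r for r, _ in marker_defs}
            )
        ],
        pool=pool,
        freqs=_normalize(freqs),
    )
    rng = np.random.default_rng(seed + 1)
    cohort = implant_haplotype_block(cohort, panel, block, rng)
    return cohort, panel, block


def make_demo_dataset(
    seed: int, out_dir: str, scale: float = 0.1
) -> str:
    """Write a complete synthetic fixture and return the config path.

    The cohort reuses the 26 real population codes with sample counts
    scaled by ``scale`` (default ~250 individuals total). Scan
    chromosomes carry a sweep planted ~2 Mb from gene B's region and a
    balanced locus inside gene A's region. Byte-identical under a fixed
    seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    pops = thousand_genomes_populations(scale=scale)

    cohort_a, panel, _ = _build_gene_cohort(
        GENE_A_REGION, 80, _GENE_A_MARKERS, _GENE_A_POOL, _GENE_A_FREQS,
        pops, seed,
    )
    cohort_b, _, _ = _build_gene_cohort(
        GENE_B_REGION, 40, _GENE_B_MARKERS, _GENE_B_POOL, _GENE_B_FREQS,
        pops, seed + 1000,
    )
    write_vcf(cohort_a, os.path.join(out_dir, "gene_a.vcf"))
    write_vcf(cohort_b, os.path.join(out_dir, "gene_b.vcf"))
    write_panel(panel, os.path.join(out_dir, "panel.tsv"))

    # outgroup + flanks per gene
    marker_pos_a = [p for p, r in _gene_marker_positions(cohort_a, _GENE_A_MARKERS)]
    rsids_a = [r for p, r in _gene_marker_positions(cohort_a, _GENE_A_MARKERS)]
    out_a = make_outgroup(
        cohort_a, list(zip(marker_pos_a, rsids_a)), GENE_A_ANCESTRAL,
        rng=np.random.default_rng(seed + 2),
    )
    out_a.write_fasta(os.path.join(out_dir, "outgroup_gene_a.fasta"))
    out_a.write_flanks(os.path.join(out_dir, "outgroup_gene_a_flanks.tsv"))
    marker_pos_b = [p for p, r in _gene_marker_positions(cohort_b, _GENE_B_MARKERS)]
    rsids_b = [r for p, r in _gene_marker_positions(cohort_b, _GENE_B_MARKERS)]
    out_b = make_outgroup(
        cohort_b, list(zip(marker_pos_b, rsids_b)), GENE_B_ANCESTRAL,
        rng=np.random.default_rng(seed + 3),
    )
    out_b.write_fasta(os.path.join(out_dir, "outgroup_gene_b.fasta"))
    out_b.write_flanks(os.path.join(out_dir, "outgroup_gene_b_flanks.tsv"))

    # archaic fixtures: three genomes homozygous for gene B's CGTTG; one
    # heterozygous at gene A's first two markers, third marker absent
    for name in ("vindija", "altai", "denisova"):
        write_archaic_vcf(
            os.path.join(out_dir, f"archaic_{name}_gene_b.vcf"),
            cohort_b,
            {pos: (c, c) for pos, c in zip(marker_pos_b, "CGTTG")},
            sample_name=name,
        )
    write_archaic_vcf(
        os.path.join(out_dir, "archaic_vindija_gene_a.vcf"),
        cohort_a,
        {marker_pos_a[0]: ("C", "C"), marker_pos_a[1]: ("G", "G")},
        sample_name="vindija",
    )
    write_archaic_vcf(
        os.path.join(out_dir, "archaic_ustishim_gene_a.vcf"),
        cohort_a,
        {marker_pos_a[0]: ("C", "A"), marker_pos_a[1]: ("G", "A")},
        sample_name="ustishim",
    )

    # scan chromosomes: modest single-population cohorts
    scan_pops = [PopulationSpec("SCN", "AFR", 50)]
    sweep_region = GenomicRegion("11", 91000000, 95000000)
    sweep_spec = StructureSpec(
        region=sweep_region, n_sites=2500, populations=scan_pops,
        F=0.0, seed=seed + 10,
    )
    sweep_cohort, _ = simulate_cohort(sweep_spec)
    sweep_center = 92040000  # ~2 Mb from gene B's region
    sweep_cohort = implant_selection_signature(
        sweep_cohort,
        SelectionSignatureSpec("sweep", center=sweep_center, span=200000),
        np.random.default_rng(seed + 11),
    )
    write_vcf(sweep_cohort, os.path.join(out_dir, "scan_chr11.vcf"))

    beta_region = GenomicRegion("19", 48250000, 50250000)
    beta_spec = StructureSpec(
        region=beta_region, n_sites=6000, populations=scan_pops,
        F=0.0, seed=seed + 20,
    )
    beta_cohort, _ = simulate_cohort(beta_spec)
    beta_cohort = implant_selection_signature(
        beta_cohort,
        SelectionSignatureSpec(
            "balancing", center=(GENE_A_REGION.start + GENE_A_REGION.end) // 2,
            span=GENE_A_REGION.length, concentration=0.02,
        ),
        np.random.default_rng(seed + 21),
    )
    write_vcf(beta_cohort, os.path.join(out_dir, "scan_chr19.vcf"))

    config = {
        "seed": seed,
        "panel": "panel.tsv",
        "out_dir": "results",
        "gene_a": {
            "name": "IZUMO1_like",
            "vcf": "gene_a.vcf",
            "region": str(GENE_A_REGION),
            "marker_rsids": rsids_a,
            "focal_sex": "male",
            "outgroup_fasta": "outgroup_gene_a.fasta",
            "outgroup_flanks": "outgroup_gene_a_flanks.tsv",
        },
        "gene_b": {
            "name": "JUNO_like",
            "vcf": "gene_b.vcf",
            "region": str(GENE_B_REGION),
            "marker_rsids": rsids_b,
            "focal_sex": "female",
            "outgroup_fasta": "outgroup_gene_b.fasta",
            "outgroup_flanks": "outgroup_gene_b_flanks.tsv",
        },
        "thresholds": {
            "hap_maf_min": 0.05,
            "hwe_p_min": 0.01,
            "fst_maf_min": 0.05,
            "sex_fst_maf_min": 0.01,
            "intergenic_maf_min": 0.01,
        },
        "scans": [
            {
                "vcf": "scan_chr11.vcf",
                "kind": "mu",
                "window_snps": 50,
                "quantile": 0.9995,
                "marked_region": str(GENE_B_REGION),
            },
            {
                "vcf": "scan_chr19.vcf",
                "kind": "beta",
                "window_bp": 2000,
                "quantile": 0.999,
                "marked_region": str(GENE_A_REGION),
            },
        ],
        "archaic_vcfs": {},
    }
    cfg_path = os.path.join(out_dir, "config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path


def _gene_marker_positions(
    cohort: PhasedCohort, marker_defs: list[tuple[str, tuple[str, str]]]
) -> list[tuple[int, str]]:
    wanted = [r for r, _ in marker_defs]
    by_rsid = {s.rsid: s.position for s in cohort.sites}
    return [(by_rsid[r], r) for r in wanted]
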