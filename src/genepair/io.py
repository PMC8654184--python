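"""Reading and writing phased VCF regions and sample panels.

VCF parsing goes through :mod:`cyvcf2`. The loader is strict: every
genotype must be diploid, phased (``0|1`` style) and non-missing, because
every downstream statistic assumes complete chromatid data. Foreign files
with missing genotypes can be salvaged with ``drop_sites_with_missing``.

Panels follow the 1000 Genomes dialect: a TSV with header columns
``sample``, ``pop``, ``super_pop``, ``gender``. The supergroup is always
re-derived from the population code via a configurable mapping.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
from cyvcf2 import VCF

from .cohort import DEFAULT_SUPERGROUPS, PhasedCohort, SamplePanel, Site
from .regions import GenomicRegion


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed or violates loader preconditions."""


def read_phased_vcf(
    path: str | os.PathLike,
    region: GenomicRegion | None = None,
    drop_sites_with_missing: bool = False,
) -> PhasedCohort:
    """Load a phased multi-sample VCF, optionally restricted to a region.

    The region is a 1-based inclusive interval; only records whose POS
    falls inside it are retained. Phase order of the two chromatids per
    sample is preserved exactly as written.

    Raises
    ------
    VcfParseError
        On malformed records (reported with their record number), or on
        unphased/missing genotypes (reported with sample and site) unless
        ``drop_sites_with_missing`` is set.
    """
    path = os.fspath(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises plain Exception subclasses
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[Site] = []
    columns: list[np.ndarray] = []
    record_no = 0
    try:
        for variant in vcf:
            record_no += 1
            if region is not None and not region.contains(
                str(variant.CHROM), int(variant.POS)
            ):
                continue
            site = Site(
                chromosome=str(variant.CHROM),
                position=int(variant.POS),
                rsid=variant.ID or ".",
                ref=str(variant.REF),
                alts=tuple(str(a) for a in variant.ALT),
            )
            col = np.empty(2 * len(samples), dtype=np.int16)
            drop = False
            for i, gt in enumerate(variant.genotypes):
                a, b, phased = gt[0], gt[1], gt[-1]
                if a < 0 or b < 0:
                    if drop_sites_with_missing:
                        drop = True
                        break
                    raise VcfParseError(
                        f"missing genotype for sample {samples[i]!r} at "
                        f"{site.chromosome}:{site.position}"
                    )
                if not phased:
                    if drop_sites_with_missing:
                        drop = True
                        break
                    raise VcfParseError(
                        f"unphased genotype for sample {samples[i]!r} at "
                        f"{site.chromosome}:{site.position}"
                    )
                col[2 * i] = a
                col[2 * i + 1] = b
            if drop:
                continue
            sites.append(site)
            columns.append(col)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF {path!r} at record {record_no + 1}: {exc}"
        ) from exc
    finally:
        vcf.close()
    if columns:
        alleles = np.stack(columns, axis=1)
    else:
        alleles = np.empty((2 * len(samples), 0), dtype=np.int16)
    return PhasedCohort(samples, sites, alleles)


def write_vcf(cohort: PhasedCohort, path: str | os.PathLike) -> None:
    """Write a cohort as VCF 4.2 with phased GT fields.

    ``read_phased_vcf`` inverts this exactly (field-by-field round trip).
    """
    if cohort.n_samples < 1:
        raise ValueError("refusing to write a cohort with no samples")
    path = os.fspath(path)
    contigs: dict[str, None] = {}
    for s in cohort.sites:
        contigs.setdefault(s.chromosome)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genepair\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        for j, site in enumerate(cohort.sites):
            col = cohort.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(cohort.n_samples)
            )
            fh.write(
                f"{site.chromosome}\t{site.position}\t{site.rsid}\t{site.ref}\t"
                f"{','.join(site.alts)}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_panel(
    path: str | os.PathLike,
    supergroup_table: Mapping[str, str] = DEFAULT_SUPERGROUPS,
) -> SamplePanel:
    """Read a sample panel TSV (columns ``sample``, ``pop``, ``gender``).

    The supergroup is derived from the population code through
    ``supergroup_table``; an unknown population code is an error naming the
    code. Duplicate samples are errors.
    """
    panel = SamplePanel()
    with open(os.fspath(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_sample = header.index("sample")
            i_pop = header.index("pop")
        except ValueError as exc:
            raise ValueError(f"panel header missing required column: {exc}")
        i_sex = header.index("gender") if "gender" in header else None
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sample, pop = fields[i_sample], fields[i_pop]
            if pop not in supergroup_table:
                raise ValueError(
                    f"population code {pop!r} absent from supergroup table"
                )
            sex = fields[i_sex] if i_sex is not None else "unknown"
            panel.add(sample, pop, supergroup_table[pop], sex)
    return panel


def write_panel(panel: SamplePanel, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        fh.write("sample\tpop\tsuper_pop\tgender\n")
        for s in panel.samples:
            fh.write(
                f"{s}\t{panel.population[s]}\t{panel.supergroup[s]}\t{panel.sex[s]}\n"
            )
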