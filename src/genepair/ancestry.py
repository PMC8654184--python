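"""Ancestral-allele polarization and archaic genotype extraction.

Ancestral states come from an outgroup alignment by *flank matching*: the
bases flanking each marker are located in the outgroup sequence and the
single base in the gap is read off. Matching is exact and position-free,
so coordinate shifts between assemblies cannot mispolarize a marker; a
flank that matches nowhere reports "absent" and one matching more than
once reports "ambiguous" (no allele is guessed in either case).

Derived-allele counting is the Hamming distance between a haplotype
string and the ancestral string. Archaic single-genome VCFs are read for
the marker positions; heterozygous markers yield the set of compatible
haplotype strings flagged phase-unknown rather than a guess.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

from cyvcf2 import VCF


@dataclass
class FlankMatch:
    allele: str | None
    position: int | None  # 0-based offset of the gap base in the sequence
    confidence: str  # "unique" | "ambiguous" | "absent"


@dataclass
class AncestralMap:
    """Per-marker ancestral calls from flank matching."""

    calls: dict[str, FlankMatch]  # rsID -> match

    def haplotype(self, order: Sequence[str]) -> str:
        bad = [r for r in order if self.calls[r].confidence != "unique"]
        if bad:
            detail = ", ".join(f"{r}: {self.calls[r].confidence}" for r in bad)
            raise ValueError(f"non-unique ancestral calls: {detail}")
        return "".join(self.calls[r].allele for r in order)


def match_flank(sequence: str, flank5: str, flank3: str) -> FlankMatch:
    """Locate ``flank5 · X · flank3`` (X one base) in a sequence, exactly.

    Zero occurrences report "absent"; more than one, "ambiguous" with no
    allele returned.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    hits = []
    start = 0
    while True:
        i = sequence.find(flank5, start)
        if i < 0:
            break
        gap = i + len(flank5)
        if sequence[gap + 1 : gap + 1 + len(flank3)] == flank3:
            hits.append(gap)
        start = i + 1
    if len(hits) == 0:
        return FlankMatch(None, None, "absent")
    if len(hits) > 1:
        return FlankMatch(None, None, "ambiguous")
    return FlankMatch(sequence[hits[0]], hits[0], "unique")


def polarize(
    sequence: str, flanks: Mapping[str, tuple[str, str]]
) -> AncestralMap:
    """Flank-match every marker; no call is forced on failure."""
    return AncestralMap(
        {rsid: match_flank(sequence, f5, f3) for rsid, (f5, f3) in flanks.items()}
    )


def ancestral_haplotype(
    sequence: str,
    flanks: Mapping[str, tuple[str, str]],
    order: Sequence[str],
) -> str:
    """The ancestral allele string over markers in the given order.

    Any absent or ambiguous marker fails the whole string with a
    per-marker report.
    """
    return polarize(sequence, flanks).haplotype(order)


def count_derived(haplotype: str, ancestral: str) -> int:
    """Number of derived alleles: the Hamming distance to the ancestral string."""
    if len(haplotype) != len(ancestral):
        raise ValueError(
            f"length mismatch: {len(haplotype)} vs {len(ancestral)}"
        )
    return sum(a != b for a, b in zip(haplotype, ancestral))


def read_fasta_sequence(path: str | os.PathLike) -> str:
    """Single-record FASTA-like outgroup file -> sequence string."""
    seq: list[str] = []
    with open(os.fspath(path)) as fh:
        for line in fh:
            if line.startswith(">"):
                if seq:
                    break  # only the first record
                continue
            seq.append(line.strip())
    return "".join(seq)


def read_flanks_tsv(path: str | os.PathLike) -> dict[str, tuple[str, str]]:
    flanks: dict[str, tuple[str, str]] = {}
    with open(os.fspath(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        i_r = header.index("rsid")
        i_5 = header.index("flank5")
        i_3 = header.index("flank3")
        for line in fh:
            if line.strip():
                f = line.rstrip("\n").split("\t")
                flanks[f[i_r]] = (f[i_5], f[i_3])
    return flanks


@dataclass
class ArchaicCall:
    """Diploid alleles of one archaic genome at the marker loci."""

    alleles: dict[int, tuple[str, str] | None]  # position -> pair or None (absent)
    heterozygous: list[int]
    missing: list[int]

    @property
    def phase_unknown(self) -> bool:
        return len(self.heterozygous) > 0

    def haplotype(self, order: Sequence[int]) -> str | None:
        """Definite haplotype string when homozygous at all present markers."""
        if self.phase_unknown or self.missing:
            return None
        return "".join(self.alleles[p][0] for p in order)

    def compatible_haplotypes(self, order: Sequence[int]) -> list[str]:
        """All haplotype strings consistent with the unphased genotypes.

        Markers absent from the archaic genome contribute an ``N``.
        """
        choices = []
        for p in order:
            pair = self.alleles.get(p)
            if pair is None:
                choices.append(("N",))
            else:
                choices.append(tuple(sorted(set(pair))))
        return ["".join(c) for c in itertools.product(*choices)]


def archaic_haplotype_lookup(
    vcf_path: str | os.PathLike, positions: Sequence[int]
) -> ArchaicCall:
    """Extract a single archaic genome's alleles at marker positions.

    Missing markers are a state, not an error: they are reported and the
    remaining markers are still called. Heterozygous markers flag the
    call phase-unknown.
    """
    wanted = set(int(p) for p in positions)
    found: dict[int, tuple[str, str]] = {}
    vcf = VCF(os.fspath(vcf_path))
    try:
        if len(vcf.samples) != 1:
            raise ValueError(
                f"expected a single-genome VCF, found {len(vcf.samples)} samples"
            )
        for variant in vcf:
            pos = int(variant.POS)
            if pos not in wanted:
                continue
            gt = variant.genotypes[0]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue  # missing call == absent marker
            letters = [str(variant.REF)] + [str(x) for x in variant.ALT]
            found[pos] = (letters[a], letters[b])
    finally:
        vcf.close()
    alleles: dict[int, tuple[str, str] | None] = {}
    het, missing = [], []
    for p in sorted(wanted):
        pair = found.get(p)
        alleles[p] = pair
        if pair is None:
            missing.append(p)
        elif pair[0] != pair[1]:
            het.append(p)
    return ArchaicCall(alleles=alleles, heterozygous=het, missing=missing)
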