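# Methods

This note documents the models and estimators implemented in `genepair`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot show.

## Data model

A cohort is a matrix of phased chromatids: 2N rows for N diploid
samples (phase order preserved from the source VCF) by S variant sites.
Every statistic counts over chromatids, so n always means 2N. The
loader rejects unphased or missing genotypes by default because every
estimator downstream assumes complete chromatid data; an explicit
`drop_sites_with_missing` option exists for foreign files. Coordinates
are 1-based and inclusive everywhere (`CHR:START-END`); MAF of a
biallelic site is min(p, 1−p) on the 0/1 allele index; allele letters
are taken verbatim from REF/ALT with no reverse-complementing (strand
is a reporting concern, not a computation).

## Synthetic cohorts

The generator emulates a 1000-Genomes-like panel: 26 populations with
the real phase-3 codes and sample counts (2504 individuals total,
optionally scaled down), nested in 5 continental supergroups.

**Structure.** Per-population allele frequencies follow the
Balding–Nichols model: p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an
ancestral frequency p, giving E[p_k] = p and Var[p_k] = F·p(1−p), so
the dispersion F maps directly onto the expected Weir–Cockerham FST —
the basis of the parameter-recovery tests (estimated θ ≈ F). Because
the populations are *nested* in supergroups, the draw is optionally
two-level: supergroup frequencies around p with F_super (default 0.08
in the demo, chosen to land overall differentiation near the ~0.1
genome-wide scale), then population frequencies around their
supergroup's with a small within-continent F (default 0.02). The flat
single-level form is kept for parameter-recovery tests.

**Baseline independence.** Chromatids are drawn independently per site
(linkage equilibrium), so genotypes are Hardy–Weinberg within
populations by construction and any LD seen downstream is exactly what
an implant created. Sex is assigned independently of genotype — both
genes are autosomal — which makes male-vs-female FST ≈ 0 a null
property the pipeline can verify.

**Implants.**

* *Haplotype blocks*: each chromatid's alleles at the marker loci are
  overwritten by a pool haplotype drawn from its population's frequency
  vector; all other sites are untouched. Frequency vectors must sum
  to 1 (printed tables round to two decimals, so demo vectors are
  renormalized).
* *Sweep*: inside the span, sites are thinned (default 80%), a fraction
  of survivors (default 0.5) is redrawn to be singletons or
  near-fixed, and another fraction (default 0.5) is tied to one of two
  founder haplotypes per side of the center (founder frequency 0.15).
  This produces the three sweep footprints jointly: local polymorphism
  reduction, SFS skew to the spectrum's edges, and LD that is high for
  locus pairs on the same side of the center but low across it. All
  intensities at 0 reproduce the input bit-for-bit.
* *Balancing*: site density is preserved; a core site is set to folded
  frequency exactly 0.5 and every other site in the span becomes the
  core's allele vector XOR independent flips with probability
  `concentration` (default 0.1; 0.02 in the demo scan), yielding a
  cluster of correlated intermediate-frequency alleles around a
  "trans-species"-style core.

**Outgroup/archaic fixtures.** The outgroup sequence is random
background carrying the cohort's REF letters at all cohort sites and
the chosen ancestral allele at each marker; per-marker flanks (20 bp a
side) are checked for uniqueness as a `flank5·X·flank3` context, with
regeneration on collision. Archaic fixtures are single-sample diploid
VCFs, possibly heterozygous, possibly with markers absent; they assume
clean diploid calls (no quality masks).

**What the generator does not emulate.** Site frequencies come from a
Beta law, not a coalescent frequency spectrum, so absolute values of
SFS-shaped statistics (e.g. Tajima's D) on baseline data are not
centered where real neutral data would put them; recombination,
mutation-rate variation, linked selection and demography are absent.
Tests passing on this data therefore validate the *estimators and their
contrasts* (signs, orderings, parameter recovery, detection of planted
signals), not demographic realism.

## Estimators

**Exact HWE.** The conditional test enumerates heterozygote counts
compatible with the observed allele counts via the standard ratio
recurrence, summing probabilities ≤ the observed one (with a 1e-12
relative guard for ties). It is symmetric in allele labels and matches
a log-factorial enumeration oracle exhaustively for all compositions
with n ≤ 25. A χ² variant exists for cross-checks only. Two HWE
thresholds circulate for this kind of screen (0.01 and 0.001); the
pipeline exposes the threshold in config, defaults to 0.01 — the value
governing the headline haplotype tables — and records it in the
manifest.

**Diversity.** π = Σ_sites 2p(1−p)·n/(n−1) (equal to the mean pairwise
Hamming distance over chromatids); θ_W = S/a₁; Tajima's D uses the
standard constants kept in the result object for audit. D is undefined
when S = 0 or n < 4 and propagates as an explicit flag, never as 0 —
averaging zeros into binned means would bias them. Binned mode
averages per-bin D, unweighted, over bins with ≥ 1 segregating site;
bins anchor at the region start (the anchoring is not prescribed
anywhere authoritative, so it is documented here). Per-gene π is
emitted both per-region and per-site.

**Weir–Cockerham FST.** The diploid 1984 estimator with observed
heterozygote frequencies; multi-site θ is the ratio of averages
Σa/Σ(a+b+c). Negative estimates are reported as computed — clamping
would bias averaged comparisons; clamping is left to consumers.
Pairwise matrices apply the MAF screen once on the pooled cohort
before pair extraction. Two MAF floors coexist in practice: 0.05 for
gene-level pairwise matrices, 0.01 for the sex-contrast FST; both are
config parameters recorded in outputs. The benchmark band is
mean ± k·sd (default 0.124 ± 2×0.006, the mean/sd of three published
genome-wide estimates) and the comparison is a two-tailed one-sample
t-test, also available from summary statistics alone.

**PCA of FST profiles.** Each group's feature vector is its row of
pairwise θ values; columns are centered (standardization is off by
default — the upstream tooling convention is ambiguous, so both modes
exist and the choice is logged), decomposed by SVD, and the sign of
each component is fixed so its largest-magnitude loading is positive,
making reruns deterministic.

**Haplotypes and LD.** Frequencies are counted directly on phased
chromatids (the data are phased); the two-locus EM exists to mirror
phase-blind methodology and for unphased foreign data, resolving only
the double-heterozygote ambiguity (tolerance 1e-8, 1000 iterations,
non-convergence flagged with the last iterate). Rare strings below a
reporting threshold (default 0.01) are pooled into "other" in reports
but retained internally. Marker selection pools MAF across the whole
dataset and screens HWE within the analysis group; the pipeline's
pair-analysis variant requires the HWE pass in *every* supergroup
separately, because the pooled sample fails HWE at exactly the
stratified loci the analysis is about (Wahlund effect).

**Combined haplotypes.** Expected co-occurrence is the exact product
of single-gene frequencies; observed is the chromatid co-occurrence
fraction (chromatid k of gene A pairs with chromatid k of gene B
within an individual). The Wilcoxon matched-pairs test drops zero
differences, midranks ties, and computes the exact two-tailed null
distribution of W⁺ by dynamic programming over doubled midranks for up
to 25 nonzero pairs (normal approximation with tie correction beyond);
differences are rounded at 1e-12 so float noise cannot split ties.
p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))).

**Scans.** The sweep statistic is a documented variant faithful to the
three published sweep signatures, not a re-implementation of any
existing scanner's numerics: over sliding windows of W = 50 SNPs
(step 1, reported at the midpoint),
μ_var = span(w)/(W·L/S) (sparsity), μ_SFS = window fraction of
singleton/(n−1)-ton sites over its chromosome mean (derived counts
when polarized, folded fallback otherwise), and
μ_LD = mean within-half r² / (mean cross-half r² + ε), ε = 1e-6
guarding empty cross-LD at window edges; μ is their product. The
balancing statistic is frequency-similarity only (the published tool
additionally calibrates against substitution data, whose parameters
are not recoverable): s_i = 1 − |f̃_i − f̃_c|/0.5 over neighbors within
±1 kb (≥ 2 required; cores without enough neighbors are undefined),
standardized chromosome-wide. Thresholds are nearest-rank empirical
quantiles — exactly reproducible across platforms — with strictly-above
flagging and adjacent flagged points merged into intervals; masked
intervals (e.g. centromeres) are removed before windowing and so
produce no points. Note the strict-above rule needs > 1/(1−q) points
for any flag to exist (2000 points at q = 0.9995).

**Ancestral polarization.** Flank matching is exact with no mismatch
tolerance (tolerant matching risks silent mispolarization against a
curated alignment; a mismatch budget would be an explicit opt-in) and
position-free, so coordinate shifts between assemblies are harmless.
Ambiguous (multiple hits) or absent flanks yield no allele; an
ancestral haplotype string fails as a whole if any marker is
non-unique, with a per-marker report. Heterozygous archaic markers
return the compatible-haplotype set flagged phase-unknown rather than
a guess; absent markers are a reported state, not an error. Default
flank length is 20 bp per side.

## Pipeline and problem sizes

The pipeline runs stages in a fixed order (filter cascade → site stats
→ diversity → differentiation + PCA → marker selection → haplotype
tables by group and sex → combined haplotypes + Wilcoxon → intergenic
LD → scans → ancestry), writing one TSV per table and a JSON manifest
recording every threshold, the seed and the package version. Stage
outputs equal direct module calls with the same inputs (tested by
composition); a failed stage is recorded and later stages still run.
Thresholds live only in the config document — CLI flags cover paths,
seed and verbosity — because the dual-valued thresholds above make
provenance the main reproducibility risk.

The demo dataset scales the 26 real population counts by 0.1 (~250
samples), uses 80/40 sites for the two gene regions, and scan
chromosomes of 2500 sites over 4 Mb (sweep, planted 2 Mb from the
receptor gene's region) and 6000 sites over 2 Mb (balancing, planted at
the ligand gene's locus) with 50 samples — sizes chosen so the full
demo, test suite and acceptance script each run in well under a minute
on one CPU while every planted signal remains detectable at the
configured percentile thresholds. Acceptance-level positive controls
use 10–20 seeded replicates at these sizes.

## Known limitations

* The μ and β statistics are documented variants; numbers are not
  comparable to any specific published scanner's output, only the
  statistic's contrasts and threshold protocol are.
* The β variant uses polymorphism only (no substitution calibration),
  so absolute β values have no cross-dataset meaning; the percentile
  threshold is always taken from the scan's own distribution.
* The EM estimator handles two loci only; multi-locus phasing of
  unphased cohorts is out of scope.
* Reference-gene classification takes the reference set's class labels
  and statistic values as inputs; it does not re-derive literature
  classifications.
* The intergenic max-r² on strongly structured synthetic cohorts is
  inflated by stratification (population frequency differences at both
  genes), which is expected behavior of pooled-sample LD, not an
  artifact.
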