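"""Marker selection, haplotype counting, LD, EM and the Wilcoxon test."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from genepair import (
    GenomicRegion,
    HaplotypeBlockSpec,
    PhasedCohort,
    PopulationSpec,
    Site,
    StructureSpec,
    allele_frequencies,
    combined_haplotypes,
    em_two_locus,
    expected_combined_frequency,
    haplotype_frequencies,
    implant_haplotype_block,
    intergenic_max_r2,
    ld_pair,
    select_markers,
    simulate_cohort,
    wilcoxon_matched_pairs,
)
from genepair.haplotypes import ld_from_haplotype_freqs
from genepair.site_stats import hwe_exact, genotype_counts
from genepair.cohort import site_maf

from conftest import build_cohort, two_pop_panel


def _cohort_with_controlled_sites(maf_hwe_pairs, n_samples=200, seed=0):
    """Build sites with target (approximate MAF, exact-HWE pass/fail)."""
    rng = np.random.default_rng(seed)
    cols = []
    for maf, in_hwe in maf_hwe_pairs:
        n_alt = int(round(2 * n_samples * maf))
        if in_hwe:
            col = np.zeros(2 * n_samples, dtype=int)
            col[rng.permutation(2 * n_samples)[:n_alt]] = 1
        else:
            # all alt alleles packed into homozygotes: het deficit
            col = np.zeros(2 * n_samples, dtype=int)
            for k in range(n_alt // 2):
                col[2 * k] = col[2 * k + 1] = 1
        cols.append(col)
    return build_cohort(np.stack(cols, axis=1))


class TestSelectMarkers:
    def test_thresholds_applied(self):
        cohort = _cohort_with_controlled_sites(
            [(0.04, True), (0.30, False), (0.30, True)]
        )
        panel = two_pop_panel(cohort, split=cohort.n_samples)
        mk = select_markers(cohort, panel, "ALL", maf_min=0.05, hwe_p_min=0.01)
        assert mk.rsids == ["rs2"]

    def test_empty_marker_set_allowed(self):
        cohort = _cohort_with_controlled_sites([(0.01, True)])
        panel = two_pop_panel(cohort, split=cohort.n_samples)
        mk = select_markers(cohort, panel, "ALL")
        assert len(mk) == 0

    def test_survivors_equal_independent_filter_composition(self):
        cohort, panel = _random_two_gene_cohorts(seed=5)[0]
        mk = select_markers(cohort, panel, "ALL", 0.05, 0.01)
        maf = site_maf(cohort)
        hr, he, ha = genotype_counts(cohort, cohort.samples)
        expect = [
            j
            for j, s in enumerate(cohort.sites)
            if s.is_biallelic_snv
            and maf[j] >= 0.05
            and hwe_exact(int(hr[j]), int(he[j]), int(ha[j])) > 0.01
        ]
        assert mk.site_indices == expect


def _random_two_gene_cohorts(seed=0, n_samples=100, n_sites=12):
    out = []
    for k in range(2):
        spec = StructureSpec(
            GenomicRegion(str(11 + 8 * k), 1000, 500_000), n_sites,
            [PopulationSpec("YRI", "AFR", n_samples // 2),
             PopulationSpec("CEU", "EUR", n_samples - n_samples // 2)],
            F=0.02, ancestral_freq_sampler=("uniform", 0.1, 0.9),
            seed=seed + 101 * k,
        )
        out.append(simulate_cohort(spec))
    # identical sample IDs across genes: rename gene-2 samples to match
    (c1, p1), (c2, _p2) = out
    c2 = PhasedCohort(c1.samples, c2.sites, c2.alleles)
    return (c1, p1), c2


class TestHaplotypeFrequencies:
    def test_single_marker_equals_allele_frequencies(self):
        (cohort, panel), _ = _random_two_gene_cohorts(seed=3)
        mk = select_markers(cohort, panel, "ALL", maf_min=0.0, hwe_p_min=0.0)
        one = type(mk)(
            mk.site_indices[:1], mk.rsids[:1], mk.positions[:1],
            mk.alleles[:1], 0.0, 0.0,
        )
        table = haplotype_frequencies(cohort, panel, one, "ALL")
        ref, alt = one.alleles[0]
        p_alt = allele_frequencies(cohort)[one.site_indices[0]]
        assert table.frequencies.get(alt, 0.0) == pytest.approx(p_alt)
        assert table.frequencies.get(ref, 0.0) == pytest.approx(1 - p_alt)

    def test_counting_oracle_ten_chromatids(self):
        rows = np.array(
            [
                [0, 0], [0, 1], [1, 1], [1, 1], [0, 0],
                [1, 0], [0, 0], [1, 1], [0, 1], [0, 0],
            ]
        )
        cohort = build_cohort(rows, refs=["A", "C"], alts=["G", "T"])
        panel = two_pop_panel(cohort)
        mk = select_markers(cohort, panel, "ALL", maf_min=0.0, hwe_p_min=0.0)
        table = haplotype_frequencies(cohort, panel, mk, "ALL")
        strings = ["".join(["A", "C"][0] if r[0] == 0 else "G"
                           for r in [row]) +
                   ("T" if row[1] else "C") for row in rows]
        strings = [("A" if row[0] == 0 else "G") + ("T" if row[1] else "C")
                   for row in rows]
        for hap in set(strings):
            assert table.frequencies[hap] == pytest.approx(
                strings.count(hap) / 10
            )
        assert sum(table.frequencies.values()) == pytest.approx(1.0)

    def test_implanted_pool_recovered_at_panel_scale(self):
        # AFR pool {CGTTG 0.69, GACGA 0.26, GACTA 0.05} recovered within
        # binomial CI at n = 661 samples (1322 chromatids)
        spec = StructureSpec(
            GenomicRegion("11", 1, 100_000), 20,
            [PopulationSpec("YRI", "AFR", 661)], F=0.0, seed=6,
        )
        cohort, panel = simulate_cohort(spec)
        idx = [2, 5, 9, 13, 17]
        markers = [(cohort.sites[j].position, cohort.sites[j].rsid) for j in idx]
        letters = [cohort.sites[j].alleles for j in idx]
        pool = [
            "".join(letters[k][c] for k, c in enumerate(choice))
            for choice in ([0] * 5, [1] * 5, [1, 1, 1, 0, 1])
        ]
        block = HaplotypeBlockSpec(markers, pool, {"AFR": [0.69, 0.26, 0.05]})
        out = implant_haplotype_block(cohort, panel, block, np.random.default_rng(7))
        mk_all = select_markers(out, panel, "ALL", maf_min=0.0, hwe_p_min=0.0)
        keep = [i for i, j in enumerate(mk_all.site_indices) if j in idx]
        mk = type(mk_all)(
            [mk_all.site_indices[i] for i in keep],
            [mk_all.rsids[i] for i in keep],
            [mk_all.positions[i] for i in keep],
            [mk_all.alleles[i] for i in keep], 0.0, 0.0,
        )
        table = haplotype_frequencies(out, panel, mk, "AFR")
        n = table.n_chromatids
        for hap, f_spec in zip(pool, [0.69, 0.26, 0.05]):
            se = np.sqrt(f_spec * (1 - f_spec) / n)
            assert abs(table.frequencies.get(hap, 0.0) - f_spec) < 4 * se


class TestLD:
    def test_locus_with_itself(self):
        (cohort, panel), _ = _random_two_gene_cohorts(seed=2)
        res = ld_pair(cohort, 0, 0)
        assert res.D_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_perfect_coupling_closed_form(self):
        rows = np.array([[0, 0], [1, 1]] * 10)
        cohort = build_cohort(rows)
        res = ld_pair(cohort, 0, 1)
        assert res.D == pytest.approx(0.25)
        assert res.D_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_independent_loci(self):
        rows = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 5)
        cohort = build_cohort(rows)
        res = ld_pair(cohort, 0, 1)
        assert res.D == pytest.approx(0.0)
        assert res.r2 == pytest.approx(0.0)

    def test_monomorphic_undefined(self):
        rows = np.zeros((10, 2), dtype=int)
        rows[:5, 1] = 1
        cohort = build_cohort(rows)
        assert np.isnan(ld_pair(cohort, 0, 1).r2)

    def test_bounds_on_random_pairs(self):
        (cohort, _), _ = _random_two_gene_cohorts(seed=9)
        for i, j in itertools.combinations(range(min(8, cohort.n_sites)), 2):
            res = ld_pair(cohort, i, j)
            if not np.isnan(res.r2):
                assert 0.0 <= res.r2 <= 1.0 + 1e-12
                assert abs(res.D_prime) <= 1.0 + 1e-12

    def test_r2_identity_with_marginals(self):
        rows = np.array([[0, 0], [1, 1], [1, 0], [0, 0], [1, 1], [0, 1]] * 4)
        cohort = build_cohort(rows)
        res = ld_pair(cohort, 0, 1)
        x = rows[:, 0].mean()
        y = rows[:, 1].mean()
        assert res.r2 == pytest.approx(
            res.D**2 / (x * (1 - x) * y * (1 - y))
        )


class TestEmTwoLocus:
    def test_no_double_hets_equals_direct_count(self):
        table = np.array([[10, 4, 1], [3, 0, 2], [1, 5, 8]])
        f, converged, _ = em_two_locus(table)
        assert converged
        # direct unambiguous haplotype counts
        base = np.zeros(4)
        contrib = {
            (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
            (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
            (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
        }
        for (i, j), add in contrib.items():
            base += table[i, j] * np.asarray(add, float)
        assert np.allclose(f, base / base.sum())

    def test_fixed_point_matches_grid_search_mle(self):
        table = np.array([[6, 3, 1], [4, 8, 2], [1, 3, 5]])
        f, converged, _ = em_two_locus(table)
        assert converged

        def loglik(p_ab):
            # reparametrize: marginals fixed by allele counts, one free dof
            n = table.sum()
            pa = (2 * table[2].sum() + table[1].sum()) / (2 * n)
            pb = (2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n)
            hap = np.array(
                [p_ab, pa - p_ab, pb - p_ab, 1 - pa - pb + p_ab]
            )
            if np.any(hap < 0):
                return -np.inf
            ll = 0.0
            geno_prob = {
                (0, 0): hap[3] ** 2,
                (0, 1): 2 * hap[3] * hap[2],
                (0, 2): hap[2] ** 2,
                (1, 0): 2 * hap[3] * hap[1],
                (1, 1): 2 * hap[0] * hap[3] + 2 * hap[1] * hap[2],
                (1, 2): 2 * hap[0] * hap[2],
                (2, 0): hap[1] ** 2,
                (2, 1): 2 * hap[0] * hap[1],
                (2, 2): hap[0] ** 2,
            }
            for (i, j), pr in geno_prob.items():
                if table[i, j] > 0:
                    if pr <= 0:
                        return -np.inf
                    ll += table[i, j] * np.log(pr)
            return ll

        grid = np.arange(0.0, 1.0001, 1e-4)
        lls = np.array([loglik(g) for g in grid])
        best = grid[np.argmax(lls)]
        assert f[0] == pytest.approx(best, abs=2e-4)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(11)
        truth = np.array([0.5, 0.2, 0.2, 0.1])  # AB, Ab, aB, ab
        n = 1000
        haps = rng.choice(4, size=(n, 2), p=truth)
        a_copies = np.isin(haps, [0, 1]).sum(axis=1)
        b_copies = np.isin(haps, [0, 2]).sum(axis=1)
        table = np.zeros((3, 3), dtype=int)
        for i, j in zip(a_copies, b_copies):
            table[i, j] += 1
        f, converged, _ = em_two_locus(table)
        assert converged
        assert np.all(np.abs(f - truth) < 0.02)


class TestIntergenic:
    def test_monomorphic_gene_undefined(self):
        (c1, panel), c2 = _random_two_gene_cohorts(seed=4)
        mono = PhasedCohort(
            c2.samples, c2.sites, np.zeros_like(c2.alleles)
        )
        assert intergenic_max_r2(c1, mono, panel) is None

    def test_exhaustive_double_loop_oracle(self):
        (c1, panel), c2 = _random_two_gene_cohorts(seed=8, n_sites=5)
        res = intergenic_max_r2(c1, c2, panel, maf_min=0.0)
        assert res is not None
        best = -1.0
        for i in range(5):
            for j in range(5):
                x = (c1.alleles[:, i] > 0).astype(float)
                y = (c2.alleles[:, j] > 0).astype(float)
                if x.std() == 0 or y.std() == 0:
                    continue
                r2 = np.corrcoef(x, y)[0, 1] ** 2
                best = max(best, r2)
        assert res[0] == pytest.approx(best)

    def test_independent_genes_near_zero_max(self):
        # simulated genes share no linkage: max cross-gene r2 stays small
        for seed in range(20):
            (c1, panel), c2 = _random_two_gene_cohorts(
                seed=100 + seed, n_samples=500, n_sites=10
            )
            res = intergenic_max_r2(c1, c2, panel, maf_min=0.01)
            assert res is not None and res[0] < 0.05


class TestCombinedHaplotypes:
    def test_expected_is_product(self):
        # printed single-gene frequencies 0.51 and 0.90 -> expected 0.46
        assert round(expected_combined_frequency(0.51, 0.90), 2) == 0.46

    def test_monomorphic_pair_degenerate(self):
        rows = np.zeros((8, 1), dtype=int)
        c1 = build_cohort(rows)
        c2 = build_cohort(rows, refs=["C"], alts=["T"])
        panel = two_pop_panel(c1)
        from genepair import MarkerSet
        mk = MarkerSet([0], ["rs0"], [100], [("A", "G")], 0, 0)
        mk2 = MarkerSet([0], ["rs0"], [100], [("C", "T")], 0, 0)
        rows_out = combined_haplotypes(c1, c2, panel, mk, mk2)
        assert len(rows_out) == 1
        assert rows_out[0].expected == 1.0 and rows_out[0].observed == 1.0

    def test_observed_bounded_by_singles(self):
        (c1, panel), c2 = _random_two_gene_cohorts(seed=15, n_sites=6)
        mk1 = select_markers(c1, panel, "ALL", maf_min=0.0, hwe_p_min=0.0)
        mk2 = select_markers(c2, panel, "ALL", maf_min=0.0, hwe_p_min=0.0)
        for row in combined_haplotypes(c1, c2, panel, mk1, mk2):
            assert row.observed <= min(row.freq_a, row.freq_b) + 1e-12
            assert row.expected == pytest.approx(row.freq_a * row.freq_b)

    def test_sample_mismatch_rejected(self):
        (c1, panel), c2 = _random_two_gene_cohorts(seed=1)
        c2_renamed = PhasedCohort(
            [s + "x" for s in c2.samples], c2.sites, c2.alleles
        )
        from genepair import MarkerSet
        mk = MarkerSet([0], ["r"], [1], [("A", "G")], 0, 0)
        with pytest.raises(ValueError, match="same samples"):
            combined_haplotypes(c1, c2_renamed, panel, mk, mk)


class TestWilcoxon:
    def test_identical_vectors(self):
        assert wilcoxon_matched_pairs([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 1.0

    def test_symmetric_differences_exact_one(self):
        obs = [0.12, 0.08, 0.11, 0.09]
        exp = [0.10, 0.10, 0.10, 0.10]
        assert wilcoxon_matched_pairs(obs, exp) == pytest.approx(1.0)

    def test_five_positive_differences_closed_form(self):
        obs = [1.0, 2.0, 3.0, 4.0, 5.0]
        exp = [0.5, 1.4, 2.3, 3.2, 4.1]
        assert wilcoxon_matched_pairs(obs, exp) == pytest.approx(2 / 32)

    def test_matches_sign_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            d = np.round(rng.normal(size=n), 2)
            d = d[d != 0]
            if d.size == 0:
                continue
            obs = d
            exp = np.zeros_like(d)
            p = wilcoxon_matched_pairs(obs, exp)
            # brute force over all sign assignments
            ranks = sps.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            ws = []
            for signs in itertools.product([0, 1], repeat=d.size):
                ws.append(sum(r for s, r in zip(signs, ranks) if s))
            ws = np.array(ws)
            tol = 1e-9
            p_le = (ws <= w_obs + tol).mean()
            p_ge = (ws >= w_obs - tol).mean()
            assert p == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))

    def test_agrees_with_scipy_when_no_ties(self):
        d = np.array([0.5, -1.25, 2.0, 3.5, -4.75, 5.125, 6.0])
        p_ours = wilcoxon_matched_pairs(d, np.zeros_like(d))
        p_scipy = sps.wilcoxon(d, method="exact").pvalue
        assert p_ours == pytest.approx(p_scipy)

    def test_all_zero_differences_p_one(self):
        assert wilcoxon_matched_pairs([1.0], [1.0]) == 1.0
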