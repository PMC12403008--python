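"""Genotype container, F_grm, filters, pi, PCA, F_ST, error rate, LD-Ne."""

import numpy as np
import pandas as pd
import pytest

from spatid import (
    GenotypeMatrix,
    allele_frequencies,
    compute_fgrm,
    filter_genotypes,
    genotype_pca,
    ld_ne,
    pairwise_pi,
    replicate_error_rate,
    weir_cockerham_fst,
)
from spatid.genotypes import AlleleFrequencies, _hwe_het_excess_pvalue


def make_g(calls, sites=None, pos=None, chrom=None):
    calls = np.asarray(calls, dtype=float)
    n, L = calls.shape
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(n)],
        locus_ids=[f"l{k}" for k in range(L)],
        calls=calls,
        chrom=["chr1"] * L if chrom is None else chrom,
        pos_bp=np.arange(1, L + 1) * 200_000 if pos is None else pos,
        site_labels=["A"] * n if sites is None else sites,
    )


class TestAlleleFrequencies:
    def test_single_homozygote_gives_one(self):
        g = make_g([[2.0]])
        assert allele_frequencies(g).freq[0] == 1.0

    def test_three_genotype_mean(self):
        g = make_g([[0.0], [1.0], [2.0]])
        assert allele_frequencies(g).freq[0] == 0.5

    def test_missing_excluded_and_empty_subset_rejected(self):
        g = make_g([[np.nan], [1.0]])
        af = allele_frequencies(g)
        assert af.freq[0] == 0.5 and af.n_called[0] == 1
        with pytest.raises(ValueError):
            allele_frequencies(g, subset=[])

    def test_binomial_sampling_accuracy(self, rng):
        p = 0.3
        n = 50
        g = make_g(rng.binomial(2, p, size=(n, 1)))
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(allele_frequencies(g).freq[0] - p) < 3 * se


class TestFgrm:
    def test_printed_equation_forced_values(self):
        # one locus, p = 0.5: x = 2 -> +1, x = 1 -> -1
        g = make_g([[2.0], [1.0]])
        af = AlleleFrequencies(np.array([0.5]), np.array([2]), g.locus_ids)
        est = compute_fgrm(g, af)
        assert est.fgrm[0] == pytest.approx(1.0)
        assert est.fgrm[1] == pytest.approx(-1.0)
        assert list(est.n_loci_used) == [1, 1]

    def test_hwe_mean_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 400)
        calls = rng.binomial(2, p, size=(500, 400))
        g = make_g(calls)
        est = compute_fgrm(g, allele_frequencies(g))
        assert abs(np.nanmean(est.fgrm)) < 0.01

    def test_allele_label_swap_invariance(self, rng):
        calls = rng.binomial(2, 0.3, size=(40, 60)).astype(float)
        calls[rng.random(calls.shape) < 0.05] = np.nan
        g = make_g(calls)
        af = allele_frequencies(g)
        est = compute_fgrm(g, af)
        swapped = make_g(2.0 - calls)
        af_sw = AlleleFrequencies(1.0 - af.freq, af.n_called, g.locus_ids)
        est_sw = compute_fgrm(swapped, af_sw)
        np.testing.assert_allclose(est.fgrm, est_sw.fgrm, atol=1e-12)

    def test_monomorphic_locus_excluded(self):
        g = make_g([[2.0, 1.0], [2.0, 1.0]])
        est = compute_fgrm(g, allele_frequencies(g))
        # first locus monomorphic (p=1) -> dropped; second p=0.5 usable
        assert list(est.n_loci_used) == [1, 1]

    def test_zero_usable_loci_warns(self):
        g = make_g([[2.0], [2.0]])
        with pytest.warns(UserWarning):
            est = compute_fgrm(g, allele_frequencies(g))
        assert np.isnan(est.fgrm).all()


class TestFilter:
    def test_identity_thresholds_keep_everything(self, rng):
        calls = rng.binomial(2, 0.4, size=(20, 15)).astype(float)
        g = make_g(calls)
        out, report = filter_genotypes(
            g, max_locus_missing=1.0, max_indiv_missing=1.0, min_maf=0.0,
            het_excess_alpha=0.0, min_spacing_bp=0,
        )
        np.testing.assert_array_equal(out.calls, g.calls)

    def test_spacing_keeps_one_per_window_deterministically(self, rng):
        calls = rng.binomial(2, 0.4, size=(30, 10)).astype(float)
        pos = np.array([1 + 50_000 * k for k in range(10)])
        g = make_g(calls, pos=pos)
        out, _ = filter_genotypes(
            g, max_locus_missing=1.0, max_indiv_missing=1.0, min_maf=0.0,
            het_excess_alpha=0.0, min_spacing_bp=100_000, seed=7,
        )
        kept = np.sort(out.pos_bp)
        assert np.all(np.diff(kept) >= 100_000)
        out2, _ = filter_genotypes(
            g, max_locus_missing=1.0, max_indiv_missing=1.0, min_maf=0.0,
            het_excess_alpha=0.0, min_spacing_bp=100_000, seed=7,
        )
        assert list(out.locus_ids) == list(out2.locus_ids)

    def test_locus_missingness_threshold(self, rng):
        n = 100
        calls = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        calls[:5, 0] = np.nan   # 5% missing
        calls[:15, 1] = np.nan  # 15% missing
        g = make_g(calls)
        out, _ = filter_genotypes(
            g, max_locus_missing=0.10, max_indiv_missing=1.0, min_maf=0.0,
            het_excess_alpha=0.0, min_spacing_bp=0,
        )
        assert list(out.locus_ids) == ["l0"]

    def test_idempotent(self, rng):
        calls = rng.binomial(2, rng.uniform(0.05, 0.6, 40), size=(60, 40)).astype(float)
        calls[rng.random(calls.shape) < 0.03] = np.nan
        g = make_g(calls, pos=np.arange(1, 41) * 60_000)
        once, _ = filter_genotypes(g, seed=3)
        twice, _ = filter_genotypes(once, seed=3)
        assert list(once.locus_ids) == list(twice.locus_ids)
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_het_excess_filter_removes_all_het_locus(self, rng):
        n = 80
        good = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        bad = np.ones((n, 1))  # every individual heterozygous
        g = make_g(np.hstack([good, bad]))
        out, _ = filter_genotypes(
            g, max_locus_missing=1.0, max_indiv_missing=1.0, min_maf=0.0,
            het_excess_alpha=0.05, min_spacing_bp=0,
        )
        assert "l1" not in list(out.locus_ids)

    def test_all_removed_names_offending_step(self):
        g = make_g([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="locus_missingness"):
            filter_genotypes(g)


def test_hwe_exact_pvalue_matches_enumeration():
    # brute-force: all genotype configurations with n=5, n_alt=4
    # P(h | n_alt, n) proportional to 2^h * n! / (naa! h! nbb!)
    from math import comb, factorial

    n, n_alt = 5, 4
    configs = []
    for h in range(0, n_alt + 1):
        if (n_alt - h) % 2:
            continue
        naa = (n_alt - h) // 2
        nbb = n - h - naa
        if nbb < 0:
            continue
        w = 2.0**h * factorial(n) / (
            factorial(naa) * factorial(h) * factorial(nbb)
        )
        configs.append((h, w))
    tot = sum(w for _, w in configs)
    for h_obs, _ in configs:
        expect = sum(w for h, w in configs if h >= h_obs) / tot
        assert _hwe_het_excess_pvalue(h_obs, n_alt, n) == pytest.approx(expect)


class TestPairwisePi:
    def test_identical_and_opposite_homozygotes(self):
        g = make_g([[0, 0, 0], [0, 0, 0], [2, 2, 2]])
        pi = pairwise_pi(g)
        assert pi.iloc[0, 1] == 0.0
        assert pi.iloc[0, 2] == 1.0
        assert np.isnan(pi.iloc[0, 0])

    def test_toy_table_matches_allele_draw_enumeration(self, rng):
        calls = rng.integers(0, 3, size=(3, 4)).astype(float)
        g = make_g(calls)
        pi = pairwise_pi(g)
        # oracle: enumerate the four allele-draw combinations per locus
        for i in range(3):
            for j in range(i + 1, 3):
                per_locus = []
                for l in range(4):
                    ai = [1] * int(calls[i, l]) + [0] * (2 - int(calls[i, l]))
                    aj = [1] * int(calls[j, l]) + [0] * (2 - int(calls[j, l]))
                    mism = np.mean([[int(a != b) for b in aj] for a in ai])
                    per_locus.append(mism)
                assert pi.iloc[i, j] == pytest.approx(np.mean(per_locus))

    def test_missing_pairwise_deletion(self):
        g = make_g([[0, np.nan], [2, 2]])
        assert pairwise_pi(g).iloc[0, 1] == 1.0


class TestPCA:
    def test_two_demes_separate_on_pc1(self, rng):
        pa = rng.uniform(0.05, 0.3, 80)
        pb = rng.uniform(0.7, 0.95, 80)
        calls = np.vstack(
            [rng.binomial(2, pa, size=(30, 80)), rng.binomial(2, pb, size=(30, 80))]
        )
        g = make_g(calls, sites=["A"] * 30 + ["B"] * 30)
        scores, varfrac = genotype_pca(g)
        a = scores.iloc[:30, 0]
        b = scores.iloc[30:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or a.max() < b.min() or b.max() < a.min()
        assert varfrac[0] > 0.2

    def test_identical_rows_zero_variance(self):
        g = make_g(np.tile([1.0, 0.0, 2.0, 1.0], (5, 1)))
        _, varfrac = genotype_pca(g)
        assert np.all(varfrac < 1e-12)

    def test_deterministic_repeat(self, rng):
        g = make_g(rng.binomial(2, 0.4, size=(25, 40)))
        s1, v1 = genotype_pca(g)
        s2, v2 = genotype_pca(g)
        pd.testing.assert_frame_equal(s1, s2)


class TestFst:
    def test_identical_frequencies_near_zero(self, rng):
        p = rng.uniform(0.2, 0.8, 150)
        calls = rng.binomial(2, p, size=(400, 150))
        g = make_g(calls, sites=["A"] * 200 + ["B"] * 200)
        assert abs(weir_cockerham_fst(g)) < 0.01

    def test_fixed_demes_give_one(self):
        calls = np.vstack([np.zeros((20, 30)), np.full((20, 30), 2.0)])
        g = make_g(calls, sites=["A"] * 20 + ["B"] * 20)
        assert weir_cockerham_fst(g) == pytest.approx(1.0)

    def test_monomorphic_dataset_nan(self):
        g = make_g(np.zeros((10, 5)), sites=["A"] * 5 + ["B"] * 5)
        assert np.isnan(weir_cockerham_fst(g))

    def test_island_model_expected_value(self, rng):
        # two demes drifted from a common ancestral frequency:
        # p_i = p0 +/- delta chosen to give E[Fst] ~ 0.05
        L, n = 400, 200
        p0 = rng.uniform(0.3, 0.7, L)
        sd = np.sqrt(0.053 * p0 * (1 - p0))
        pa = np.clip(p0 + rng.normal(0, sd), 0.01, 0.99)
        pb = np.clip(p0 + rng.normal(0, sd), 0.01, 0.99)
        calls = np.vstack(
            [rng.binomial(2, pa, size=(n, L)), rng.binomial(2, pb, size=(n, L))]
        )
        g = make_g(calls, sites=["A"] * n + ["B"] * n)
        assert weir_cockerham_fst(g) == pytest.approx(0.05, abs=0.02)


class TestReplicateError:
    def test_identical_replicates_zero(self, rng):
        calls = rng.binomial(2, 0.4, size=(3, 100)).astype(float)
        g = make_g(np.vstack([calls, calls]))
        pairs = [(f"i{k}", f"i{k + 3}") for k in range(3)]
        est = replicate_error_rate(g, pairs)
        assert est.rate == 0.0 and est.ci_low == 0.0 and est.ci_high == 0.0

    def test_single_discordance_exact_rate(self, rng):
        calls = rng.binomial(2, 0.4, size=(2, 500)).astype(float)
        dup = calls.copy()
        dup[0, 0] = 2.0 - dup[0, 0] if dup[0, 0] != 1 else 0.0
        g = make_g(np.vstack([calls, dup]))
        est = replicate_error_rate(g, [("i0", "i2"), ("i1", "i3")])
        assert est.rate == pytest.approx(1 / 1000)
        assert est.n_compared == 1000

    def test_simulated_error_rate_within_ci(self, rng):
        n_pairs, L, err = 30, 800, 0.001
        base = rng.binomial(2, 0.4, size=(n_pairs, L)).astype(float)
        dup = base.copy()
        flips = rng.random(dup.shape) < err
        dup[flips] = (dup[flips] + 1 + rng.integers(0, 2, int(flips.sum()))) % 3
        g = make_g(np.vstack([base, dup]))
        pairs = [(f"i{k}", f"i{k + n_pairs}") for k in range(n_pairs)]
        est = replicate_error_rate(g, pairs)
        assert est.ci_low <= err <= est.ci_high


class TestLdNe:
    def test_duplicated_loci_rejected(self, rng):
        col = rng.binomial(2, 0.5, size=(20, 1)).astype(float)
        g = make_g(
            np.hstack([col, col]),
            pos=np.array([100, 200]),  # same chromosome, closer than the window
        )
        with pytest.raises(ValueError, match="pair"):
            ld_ne(g, [f"i{k}" for k in range(20)])

    def test_wright_fisher_recovery(self, rng):
        # individual-based WF population, true Ne = 50; sample everyone.
        # random parent draws each generation create the LD the estimator reads.
        true_ne, L, gens = 50, 400, 20
        est_ratio = []
        for rep in range(8):
            r = np.random.default_rng(100 + rep)
            G = r.binomial(2, r.uniform(0.3, 0.7, L), size=(true_ne, L)).astype(float)
            for _ in range(gens):
                dams = r.integers(0, true_ne, true_ne)
                sires = r.integers(0, true_ne, true_ne)
                G = (
                    (r.random((true_ne, L)) < G[dams] / 2.0).astype(float)
                    + (r.random((true_ne, L)) < G[sires] / 2.0)
                )
            g = make_g(G, chrom=[f"c{k}" for k in range(L)], pos=np.ones(L, int))
            ne = ld_ne(g, [f"i{k}" for k in range(true_ne)], min_maf=0.05).ne
            est_ratio.append(ne / true_ne)
        assert abs(np.median(est_ratio) - 1.0) < 0.3

    def test_huge_population_reports_infinite(self, rng):
        # weak drift signal at tiny sample sizes -> drift component <= 0
        L = 100
        inf_count = 0
        for rep in range(5):
            r = np.random.default_rng(200 + rep)
            calls = r.binomial(2, r.uniform(0.3, 0.7, L), size=(12, L))
            g = make_g(calls, chrom=[f"c{k}" for k in range(L)], pos=np.ones(L, int))
            ne = ld_ne(g, [f"i{k}" for k in range(12)], min_maf=0.1).ne
            if not np.isfinite(ne) or ne > 5000:
                inf_count += 1
        assert inf_count >= 3
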