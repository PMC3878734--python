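import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refgene_select.io import RunConfig, ValidationError
from refgene_select.simulate import SimConfig, generate_count_matrix
from refgene_select.stats import gene_stats
from refgene_select.thresholds import (CVMeanSelector, PseudoGeneSet,
                                       order_statistic_index,
                                       percentile_thresholds, select_candidates,
                                       simulate_pseudo_genes, threshold_sweep)

from conftest import make_count_matrix


def _pseudo_from(values_mean, values_cv, seed=0):
    return PseudoGeneSet(means=np.asarray(values_mean, dtype=float),
                         cvs=np.asarray(values_cv, dtype=float),
                         source_shape=(1, 1), seed=seed)


class TestPseudoGeneSimulation:
    def test_constant_pool_degenerate(self):
        cm = make_count_matrix(np.full((3, 4), 7))
        pseudo = simulate_pseudo_genes(cm, n_pseudo=50, seed=1)
        assert np.all(pseudo.means == 7)
        assert np.all(pseudo.cvs == 0)

    def test_default_scale_ten_thousand_pseudo_genes(self):
        cm = make_count_matrix(np.arange(2 * 47).reshape(2, 47))
        pseudo = simulate_pseudo_genes(cm, n_pseudo=RunConfig().n_pseudo, seed=1)
        assert pseudo.n_pseudo == 10_000
        assert pseudo.source_shape == (2, 47)

    def test_reproducible_and_matches_independent_redraw(self):
        cm = make_count_matrix([[1, 5], [9, 2]])
        a = simulate_pseudo_genes(cm, n_pseudo=20, seed=3)
        b = simulate_pseudo_genes(cm, n_pseudo=20, seed=3)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.cvs, b.cvs)

    def test_pseudo_mean_expectation_is_pooled_mean(self):
        rng = np.random.default_rng(5)
        cm = make_count_matrix(rng.poisson(300, size=(10, 12)))
        pool = cm.counts.to_numpy().ravel()
        pseudo = simulate_pseudo_genes(cm, n_pseudo=10_000, seed=5)
        se = pool.std() / np.sqrt(12 * 10_000)
        assert abs(pseudo.means.mean() - pool.mean()) < 3 * se

    def test_n_pseudo_below_one_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError):
            simulate_pseudo_genes(tiny_matrix, n_pseudo=0)


class TestOrderStatistics:
    def test_study_scale_indices(self):
        # N = 10,000: 97.5% -> 9,750-th value; 2.5% -> 250-th value
        assert order_statistic_index(0.975, 10_000) == 9_750
        assert order_statistic_index(0.025, 10_000) == 250

    def test_small_exact_order_statistic(self):
        pseudo = _pseudo_from(range(1, 9), np.linspace(0.1, 0.8, 8))
        cv_thr, mu_thr = percentile_thresholds(pseudo, 0.25, 0.975)
        assert cv_thr == pytest.approx(0.2)  # 2nd of 8 sorted CVs
        assert mu_thr == 8  # round(0.975*8)=8 -> max

    def test_thresholds_equal_full_sort_oracle(self):
        rng = np.random.default_rng(9)
        pseudo = _pseudo_from(rng.gamma(5, 100, 777), rng.uniform(0.1, 1, 777))
        cv_thr, mu_thr = percentile_thresholds(pseudo, 0.025, 0.975)
        assert mu_thr == np.sort(pseudo.means)[round(0.975 * 777) - 1]
        assert cv_thr == np.sort(pseudo.cvs)[round(0.025 * 777) - 1]

    @given(p_lo=st.floats(0.01, 0.4), p_hi=st.floats(0.6, 0.99),
           shift=st.floats(0.05, 0.3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_thresholds_monotone_in_percentile(self, p_lo, p_hi, shift):
        rng = np.random.default_rng(13)
        pseudo = _pseudo_from(rng.gamma(5, 100, 500), rng.uniform(0.1, 1, 500))
        cv1, mu1 = percentile_thresholds(pseudo, p_lo, p_hi)
        cv2, mu2 = percentile_thresholds(pseudo, min(p_lo + shift, 0.49),
                                         min(p_hi + shift, 0.995))
        assert cv2 >= cv1 and mu2 >= mu1

    def test_invalid_percentile_order_rejected(self):
        pseudo = _pseudo_from([1, 2], [0.1, 0.2])
        with pytest.raises(ValidationError):
            percentile_thresholds(pseudo, 0.975, 0.025)


class TestSelection:
    def test_strict_rule_on_published_style_thresholds(self):
        # thresholds (cv 0.513, mu 1208.2): mean must be strictly above,
        # CV strictly below
        stats = pd.DataFrame({"mean": [1300.0, 1100.0], "cv": [0.40, 0.40]},
                             index=["hi", "lo"])
        res = select_candidates(stats, (0.513, 1208.2))
        assert res.selected == ["hi"]
        assert res.n_selected == 1

    def test_vacuous_threshold_above_all_means(self):
        stats = pd.DataFrame({"mean": [10.0, 20.0], "cv": [0.1, 0.2]},
                             index=["a", "b"])
        assert select_candidates(stats, (0.5, 1e9)).selected == []

    def test_vacuous_complement_selects_all(self):
        stats = pd.DataFrame({"mean": [10.0, 20.0], "cv": [0.1, 0.2]},
                             index=["a", "b"])
        assert set(select_candidates(stats, (np.inf, 0.0)).selected) == {"a", "b"}

    def test_result_ordered_by_ascending_cv(self):
        stats = pd.DataFrame({"mean": [10.0, 20.0, 30.0], "cv": [0.3, 0.1, 0.2]},
                             index=["a", "b", "c"])
        assert select_candidates(stats, (np.inf, 0.0)).selected == ["b", "c", "a"]


class TestThresholdSweep:
    def test_constant_matrix_selects_nothing(self):
        cm = make_count_matrix(np.full((4, 6), 500))
        cfg = RunConfig(n_pseudo=200, seed=2)
        sweep = threshold_sweep(cm, gene_stats(cm), cfg)
        assert all(r.n_selected == 0 for r in sweep)

    def test_nested_selections_and_weakly_decreasing_counts(self):
        cfg_sim = SimConfig(n_samples=47, n_stable=20, n_de=30, n_noisy=150,
                            seed=17)
        cm, _ = generate_count_matrix(cfg_sim)
        cfg = RunConfig(n_pseudo=2_000, seed=17)
        sweep = threshold_sweep(cm, gene_stats(cm), cfg)
        sets = [set(r.selected) for r in sweep]  # loosest -> tightest pairs
        for tighter, looser in zip(sets[1:], sets):
            assert tighter <= looser
        counts = [r.n_selected for r in sweep]
        assert counts == sorted(counts, reverse=True)

    def test_same_seed_identical_counts(self):
        cm, _ = generate_count_matrix(SimConfig(n_samples=12, n_stable=5,
                                                n_de=5, n_noisy=10, seed=4))
        cfg = RunConfig(n_pseudo=500, seed=4)
        st_tab = gene_stats(cm)
        a = [r.n_selected for r in threshold_sweep(cm, st_tab, cfg)]
        b = [r.n_selected for r in threshold_sweep(cm, st_tab, cfg)]
        assert a == b


class TestCVMeanSelectorEstimator:
    def test_planted_stable_selected_over_matched_noisy(self):
        # power property: among genes of the same (high) mean embedded in a
        # realistic pool, low-dispersion genes pass the joint rule more often
        # than high-dispersion ones
        rng = np.random.default_rng(19)
        n_bg, n_each, ns = 140, 30, 47

        def nb(mu, phi, shape):
            size = 1 / phi
            return rng.negative_binomial(size, size / (size + mu), size=shape)

        bg_mu = np.exp(rng.uniform(np.log(330), np.log(3700), n_bg))[:, None]
        bg = nb(bg_mu, 0.05, (n_bg, ns))
        stable = nb(3000.0, 0.05, (n_each, ns))
        noisy = nb(3000.0, 0.6, (n_each, ns))
        names = ([f"bg{i}" for i in range(n_bg)]
                 + [f"stable{i}" for i in range(n_each)]
                 + [f"noisy{i}" for i in range(n_each)])
        X = pd.DataFrame(np.vstack([bg, stable, noisy]).T, columns=names)
        sel = CVMeanSelector(n_pseudo=2_000, random_state=19).fit(X)
        chosen = set(sel.selected_genes_)
        stable_rate = sum(g.startswith("stable") for g in chosen) / n_each
        noisy_rate = sum(g.startswith("noisy") for g in chosen) / n_each
        assert stable_rate > noisy_rate

    def test_fitted_attributes_and_support(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.poisson(400, (12, 8)),
                         columns=[f"g{i}" for i in range(8)])
        sel = CVMeanSelector(n_pseudo=300, random_state=0).fit(X)
        assert hasattr(sel, "cv_threshold_") and hasattr(sel, "mu_threshold_")
        assert sel.get_support().shape == (8,)
        assert sel.pseudo_.n_pseudo == 300
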