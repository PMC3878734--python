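import numpy as np
import pandas as pd
import pytest

from refgene_select.genorm import (GeNormRanker, ct_preprocess, m_value,
                                   pairwise_sd, pairwise_variation,
                                   stepwise_ranking)
from refgene_select.io import ValidationError

from conftest import make_ct_table


def naive_stepwise(q: pd.DataFrame):
    """Independent re-implementation: literal loops, no shared code."""
    def naive_v(x, y):
        r = [np.log2(a / b) for a, b in zip(x, y)]
        mean = sum(r) / len(r)
        return (sum((v - mean) ** 2 for v in r) / (len(r) - 1)) ** 0.5

    remaining = {g: list(q.loc[g]) for g in q.index}
    order = []
    while len(remaining) > 2:
        m = {}
        for g in remaining:
            vs = [naive_v(remaining[g], remaining[k]) for k in remaining if k != g]
            m[g] = sum(vs) / len(vs)
        worst = sorted([g for g in m if m[g] == max(m.values())])[0]
        order.append(worst)
        del remaining[worst]
    return order, tuple(sorted(remaining))


class TestPairwiseSD:
    def test_proportional_genes_have_zero_variation(self):
        q = pd.DataFrame([[1.0, 2.0, 3.0], [2.5, 5.0, 7.5]], index=["a", "b"])
        assert pairwise_sd(q, "a", "b") == 0.0

    def test_hand_computed_value(self):
        # log2 ratios (0, 1, 2) -> sample SD 1
        q = pd.DataFrame([[1.0, 2.0, 4.0], [1.0, 1.0, 1.0]], index=["a", "b"])
        assert pairwise_sd(q, "a", "b") == pytest.approx(1.0)

    def test_matches_direct_formula(self, quantities_4x5):
        q = quantities_4x5
        ratios = np.log2(q.loc["a"].to_numpy() / q.loc["b"].to_numpy())
        direct = np.sqrt(((ratios - ratios.mean()) ** 2).sum() / (len(ratios) - 1))
        assert pairwise_sd(q, "a", "b") == pytest.approx(direct, abs=1e-12)

    def test_non_positive_quantity_rejected(self):
        q = pd.DataFrame([[1.0, 0.0], [1.0, 1.0]], index=["a", "b"])
        with pytest.raises(ValidationError):
            pairwise_sd(q, "a", "b")


class TestMValue:
    def test_pairwise_proportional_panel_gives_zero(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        q = pd.DataFrame([base, 2 * base, 0.5 * base], index=list("abc"))
        for g in "abc":
            assert m_value(q, g) == pytest.approx(0.0, abs=1e-12)

    def test_per_sample_scaling_invariance(self, quantities_4x5):
        q = quantities_4x5
        scaled = q.copy()
        scaled.iloc[:, 1] *= 10.0  # one sample globally rescaled
        for g in q.index:
            assert m_value(scaled, g) == pytest.approx(m_value(q, g), abs=1e-12)

    def test_equals_brute_force_average(self, quantities_4x5):
        q = quantities_4x5
        for g in q.index:
            brute = np.mean([pairwise_sd(q, g, k) for k in q.index if k != g])
            assert m_value(q, g) == pytest.approx(brute, abs=1e-12)

    def test_single_gene_rejected(self):
        q = pd.DataFrame([[1.0, 2.0]], index=["a"])
        with pytest.raises(ValidationError):
            m_value(q, "a")


class TestStepwiseRanking:
    def test_noise_dominated_gene_excluded_first(self):
        rng = np.random.default_rng(3)
        base = np.exp(rng.normal(0, 0.1, 12))
        q = pd.DataFrame(
            [base, base * 1.5, base * np.exp(rng.normal(0, 2.0, 12))],
            index=["a", "b", "c"])
        ranking = stepwise_ranking(q)
        assert ranking.exclusion_order[0] == "c"
        assert ranking.final_pair == ("a", "b")

    def test_number_of_rounds(self, quantities_4x5):
        ranking = stepwise_ranking(quantities_4x5)
        assert len(ranking.exclusion_order) == 4 - 2
        assert len(ranking.rounds) == 4 - 1  # includes the final 2-gene round
        assert len(ranking.rounds[-1].remaining) == 2

    def test_fewer_than_three_genes_rejected(self):
        q = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"])
        with pytest.raises(ValidationError):
            stepwise_ranking(q)

    @pytest.mark.parametrize("n_genes", [3, 4, 5])
    def test_equals_naive_implementation(self, n_genes):
        rng = np.random.default_rng(100 + n_genes)
        q = pd.DataFrame(np.exp(rng.normal(0, 0.7, (n_genes, 7))),
                         index=[f"g{i}" for i in range(n_genes)])
        ranking = stepwise_ranking(q)
        naive_order, naive_pair = naive_stepwise(q)
        assert ranking.exclusion_order == naive_order
        assert ranking.final_pair == naive_pair

    def test_final_pair_m_values_identical(self, quantities_4x5):
        last = stepwise_ranking(quantities_4x5).rounds[-1]
        vals = list(last.m_values.values())
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)

    def test_excluded_gene_has_maximal_m_each_round(self, quantities_4x5):
        for rnd in stepwise_ranking(quantities_4x5).rounds[:-1]:
            assert rnd.m_values[rnd.excluded] == max(rnd.m_values.values())

    def test_added_noise_weakly_increases_m_in_expectation(self):
        # over 200 replicates, spiking one gene's log-quantities with extra
        # i.i.d. noise raises its first-round M on average
        rng = np.random.default_rng(77)
        deltas = []
        for _ in range(200):
            logq = rng.normal(0, 0.3, (4, 6))
            q = pd.DataFrame(np.exp(logq), index=list("abcd"))
            noisy = q.copy()
            noisy.loc["a"] *= np.exp(rng.normal(0, 0.5, 6))
            deltas.append(m_value(noisy, "a") - m_value(q, "a"))
        assert np.mean(deltas) > 0

    def test_m_trace_shape(self, quantities_4x5):
        trace = stepwise_ranking(quantities_4x5).m_trace()
        assert trace.shape == (4, 3)
        assert trace["round1"].notna().all()


class TestCtPreprocess:
    def test_calibrator_sample_gets_quantity_one(self):
        ct = make_ct_table([[20.0, 22.0, 24.0]], efficiency=1.0)
        q = ct_preprocess(ct)
        assert q.loc["g1", "s1"] == pytest.approx(1.0)

    def test_two_fold_per_cycle_at_perfect_efficiency(self):
        ct = make_ct_table([[20.0, 22.0]], efficiency=1.0)
        assert ct_preprocess(ct).loc["g1", "s2"] == pytest.approx(0.25)

    def test_efficiency_0p9_three_cycles(self):
        ct = make_ct_table([[20.0, 23.0]], efficiency=0.9)
        assert ct_preprocess(ct).loc["g1", "s2"] == pytest.approx(1 / 1.9**3,
                                                                  rel=1e-9)

    def test_missing_ct_drops_sample_with_warning(self, caplog):
        ct = make_ct_table([[20.0, np.nan, 21.0], [19.0, 19.5, 20.0]],
                           efficiency=1.0)
        with caplog.at_level("WARNING", logger="refgene_select"):
            q = ct_preprocess(ct)
        assert list(q.columns) == ["s1", "s3"]
        assert "missing Ct" in caplog.text

    def test_gene_with_single_ct_excluded(self, caplog):
        ct = make_ct_table([[20.0, np.nan, np.nan], [19.0, 19.5, 20.0]],
                           efficiency=1.0)
        with caplog.at_level("WARNING", logger="refgene_select"):
            q = ct_preprocess(ct)
        assert list(q.index) == ["g2"]


class TestPairwiseVariation:
    def test_keys_and_non_negativity(self, quantities_4x5):
        ranking = stepwise_ranking(quantities_4x5)
        v = pairwise_variation(quantities_4x5, ranking)
        assert list(v.index) == ["V2/3", "V3/4"]
        assert (v >= 0).all()


class TestGeNormRankerEstimator:
    def test_matches_function_path(self, quantities_4x5):
        ranker = GeNormRanker().fit(quantities_4x5.T)  # samples x genes
        ranking = stepwise_ranking(quantities_4x5)
        assert ranker.final_pair_ == ranking.final_pair
        assert ranker.exclusion_order_ == ranking.exclusion_order

    def test_get_params(self):
        assert GeNormRanker(ddof=0).get_params() == {"ddof": 0}
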