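"""Binomial enrichment test, Bonferroni correction and the alert scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alertminer import (
    CategoricalAlertMiner,
    FixtureSpec,
    binomial_tail_pvalue,
    bonferroni_correct,
    derive_alerts_categorical,
    fragment_marker_ids,
    generate_categorical_set,
    probe_set,
)
from alertminer.alerts_categorical import results_to_frame


def binomial_tail_oracle(n, m, n_s, m_s_act):
    """Independent term-by-term summation of the upper binomial tail."""
    p = m / n
    return sum(math.comb(n_s, i) * p**i * (1 - p) ** (n_s - i)
               for i in range(m_s_act, n_s + 1))


class TestBinomialTail:
    def test_zero_observed_actives_gives_one(self):
        assert binomial_tail_pvalue(100, 30, 10, 0) == 1.0

    def test_degenerate_all_active(self):
        assert binomial_tail_pvalue(50, 50, 7, 7) == pytest.approx(1.0)

    def test_three_term_example_matches_oracle(self):
        # n=100, m=20, n_S=10, m_S_act=8: the tail has three terms
        expected = (math.comb(10, 8) * 0.2**8 * 0.8**2
                    + math.comb(10, 9) * 0.2**9 * 0.8 + 0.2**10)
        assert expected == pytest.approx(7.79264e-05, rel=1e-6)
        value = binomial_tail_pvalue(100, 20, 10, 8)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_oracle_equivalence_grid(self):
        for frac in np.arange(0.1, 0.95, 0.1):
            n, m = 1000, int(round(1000 * frac))
            for n_s in (1, 5, 12, 25):
                for m_s_act in range(n_s + 1):
                    assert binomial_tail_pvalue(n, m, n_s, m_s_act) == \
                        pytest.approx(binomial_tail_oracle(n, m, n_s, m_s_act),
                                      rel=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(1, 400), st.data())
    def test_monotone_in_observed_actives(self, n, data):
        m = data.draw(st.integers(0, n))
        n_s = data.draw(st.integers(1, min(n, 30)))
        values = [binomial_tail_pvalue(n, m, n_s, k) for k in range(n_s + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_complement_identity_in_oracle(self):
        n, m, n_s = 80, 30, 12
        for k in range(1, n_s + 1):
            upper = binomial_tail_oracle(n, m, n_s, k)
            lower = sum(math.comb(n_s, i) * (m / n) ** i
                        * (1 - m / n) ** (n_s - i) for i in range(k))
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_precondition_violations(self):
        with pytest.raises(ValueError):
            binomial_tail_pvalue(0, 0, 5, 2)
        with pytest.raises(ValueError):
            binomial_tail_pvalue(10, 11, 5, 2)
        with pytest.raises(ValueError):
            binomial_tail_pvalue(10, 5, 5, 6)


class TestBonferroni:
    def test_single_test_is_identity(self):
        assert bonferroni_correct([0.01]).tolist() == [0.01]

    def test_multiplication_and_clamp(self):
        assert bonferroni_correct([0.01, 0.2, 0.5]).tolist() == \
            pytest.approx([0.03, 0.6, 1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_equivalent_to_alpha_over_k(self, p_values):
        alpha = 0.05
        corrected = bonferroni_correct(p_values)
        k = len(p_values)
        for raw, cor in zip(p_values, corrected):
            assert cor >= raw
            if cor < 1.0:
                assert (cor < alpha) == (raw < alpha / k)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni_correct([0.5, 1.5])


class TestCategoricalScan:
    def test_planted_fragment_flagged(self, categorical_spec,
                                      categorical_train):
        results = derive_alerts_categorical(
            probe_set(categorical_spec, 1), categorical_train,
            radii=(1, 2), min_support=5, min_frequency=0.7, alpha=0.05)
        markers = fragment_marker_ids(categorical_spec, radii=(1,))
        flagged = {r.identifier for r in results if r.significant}
        assert flagged & markers
        frame = results_to_frame(results)
        assert list(frame.columns[:5]) == ["identifier", "smiles", "radius",
                                           "n_S", "m_S_act"]

    def test_disjoint_test_set_yields_nothing(self, categorical_train):
        results = derive_alerts_categorical(
            ["BrC(Br)(Br)[Si](I)(I)I"], categorical_train,
            radii=(1, 2), min_support=5, min_frequency=0.7)
        assert results == []

    def test_gate_correctness(self, categorical_spec, categorical_train):
        min_support, min_frequency = 5, 0.7
        miner = CategoricalAlertMiner(radii=(1, 2), min_support=min_support,
                                      min_frequency=min_frequency)
        miner.fit(categorical_train)
        results = miner.derive(probe_set(categorical_spec, 3))
        assert results  # sanity: something was evaluated
        for res in results:
            assert res.n_s >= min_support
            assert res.m_s_act / res.n_s >= min_frequency

    def test_suppression_and_uniqueness(self, categorical_spec,
                                        categorical_train):
        test_set = probe_set(categorical_spec, 3)
        miner = CategoricalAlertMiner(radii=(0, 1, 2), min_support=3,
                                      min_frequency=0.0, alpha=0.05)
        miner.fit(categorical_train)
        results = miner.derive(test_set)
        identifiers = [r.identifier for r in results]
        assert len(identifiers) == len(set(identifiers))
        # no larger-radius environment at a root where an alert fired
        flagged_raw = {(r.example, r.radius) for r in results
                       if r.p_value < 0.05}
        for (example, radius) in flagged_raw:
            for res in results:
                if res.example == example:
                    assert res.radius <= radius or res.p_value >= 0.05

    def test_ordering_alerts_first_by_corrected_p(self, categorical_spec,
                                                  categorical_train):
        results = derive_alerts_categorical(
            probe_set(categorical_spec, 2), categorical_train,
            radii=(0, 1, 2), min_support=5, min_frequency=0.3)
        significant = [r.significant for r in results]
        assert significant == sorted(significant, reverse=True)
        sig_p = [r.p_value_corrected for r in results if r.significant]
        assert sig_p == sorted(sig_p)

    def test_corrected_pvalues_consistent(self, categorical_spec,
                                          categorical_train):
        results = derive_alerts_categorical(
            probe_set(categorical_spec, 1), categorical_train,
            radii=(1, 2), min_support=5, min_frequency=0.3)
        k = len(results)
        for res in results:
            assert res.p_value_corrected == \
                pytest.approx(min(res.p_value * k, 1.0))
            assert res.significant == (res.p_value_corrected < 0.05)

    def test_no_bonferroni_keeps_raw(self, categorical_spec,
                                     categorical_train):
        results = derive_alerts_categorical(
            probe_set(categorical_spec, 1), categorical_train,
            radii=(1, 2), min_support=5, min_frequency=0.3, bonferroni=False)
        for res in results:
            assert res.p_value_corrected == res.p_value

    def test_radii_mismatch_fatal(self, categorical_spec, categorical_train):
        miner = CategoricalAlertMiner(radii=(1, 2), min_support=5,
                                      min_frequency=0.7)
        miner.fit(categorical_train)
        miner.set_params(radii=(0, 1))
        with pytest.raises(ValueError):
            miner.derive(probe_set(categorical_spec, 1))

    def test_required_parameters(self, categorical_train):
        with pytest.raises(ValueError):
            CategoricalAlertMiner(radii=None, min_frequency=0.7).fit(
                categorical_train)
        with pytest.raises(ValueError):
            CategoricalAlertMiner(radii=(1,), min_frequency=None).fit(
                categorical_train)

    def test_sklearn_params_round_trip(self):
        miner = CategoricalAlertMiner(radii=(1, 2), min_frequency=0.7)
        params = miner.get_params()
        assert params["min_support"] == 5 and params["alpha"] == 0.05
        clone = CategoricalAlertMiner(**params)
        assert clone.get_params() == params

    def test_defaults_match_published_values(self):
        miner = CategoricalAlertMiner()
        assert miner.min_support == 5
        assert miner.alpha == 0.05
        assert miner.bonferroni is True


def test_fixture_example_pvalue_far_below_threshold():
    # 200 train, 100 active, fragment in ~40 actives / ~2 inactives:
    # the oracle tail is many orders of magnitude below alpha/k
    p = binomial_tail_oracle(200, 100, 42, 40)
    assert p < 1e-8


def test_during_scan_bonferroni_mode(categorical_spec, categorical_train):
    miner = CategoricalAlertMiner(radii=(1, 2), min_support=5,
                                  min_frequency=0.7,
                                  bonferroni_during_scan=True)
    miner.fit(categorical_train)
    results = miner.derive(probe_set(categorical_spec, 1))
    markers = fragment_marker_ids(categorical_spec, radii=(1,))
    assert {r.identifier for r in results if r.significant} & markers
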