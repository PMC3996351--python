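"""PSA economics: NHB, paired increments, percentile summaries, CEAC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from activecea.config import InterventionSpec
from activecea.economics import ceac, net_health_benefit, run_psa, summarise_psa
from activecea.inputs import TrialEffect


@pytest.fixture(scope="module")
def psa_result(small_inputs):
    return run_psa(
        small_inputs,
        InterventionSpec(duration_years=5),
        n_simulations=20,
        master_seed=11,
    )


class TestNetHealthBenefit:
    def test_worked_examples(self):
        assert round(float(net_health_benefit(5.9, 80_744, 30_000)), 1) == 3.2
        assert round(float(net_health_benefit(9.8, 144_469, 30_000)), 1) == 5.0

    def test_zero_cost_returns_qalys(self):
        assert float(net_health_benefit(7.3, 0.0, 20_000)) == 7.3

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            net_health_benefit(1.0, 1.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        dq=st.floats(1e-6, 50),
        dc=st.floats(-1e5, 1e5),
        lam=st.floats(100, 1e5),
    )
    def test_sign_identity_with_icer(self, dq, dc, lam):
        # for positive QALY gains: NHB > 0 iff the cost per QALY is below lambda
        nhb = float(net_health_benefit(dq, dc, lam))
        assert (nhb > 0) == (dc / dq < lam)


class TestRunPsa:
    def test_reproducible_under_seed(self, small_inputs):
        spec = InterventionSpec(duration_years=5)
        a = run_psa(small_inputs, spec, n_simulations=4, master_seed=5)
        b = run_psa(small_inputs, spec, n_simulations=4, master_seed=5)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)
        assert np.array_equal(a.delta_cost_total, b.delta_cost_total)
        c = run_psa(small_inputs, spec, n_simulations=4, master_seed=6)
        assert not np.array_equal(a.delta_qaly, c.delta_qaly)

    def test_null_intervention_differs_only_by_intervention_cost(self, small_inputs):
        null = small_inputs.copy()
        null.trial = TrialEffect(odds_ratio=1.0, ci_low=1.0, ci_high=1.0)
        spec = InterventionSpec(duration_years=5)
        res = run_psa(null, spec, n_simulations=5, master_seed=2)
        assert np.all(res.delta_qaly == 0.0)
        assert np.all(res.delta_cost_utilisation == 0.0)
        int_cost = res.increments("cost_intervention_total")
        # identical traces: the cost difference is the intervention cost up to
        # floating-point summation order
        np.testing.assert_allclose(res.delta_cost_total, int_cost, rtol=1e-12)
        assert np.all(int_cost > 0)

    def test_increments_are_paired(self, psa_result):
        assert len(psa_result.intervention) == len(psa_result.control) == 20
        # common random numbers: paired spread far below either arm's spread
        qi = np.array([s.qalys_discounted for s in psa_result.intervention])
        assert psa_result.delta_qaly.std() < qi.std()


class TestSummaries:
    def test_percentiles_match_sort_oracle(self, psa_result):
        tables = summarise_psa(psa_result, np.arange(1000, 50_001, 1000.0))
        d = psa_result.increments("life_years_disease_free")
        row = tables["table3"].set_index("outcome").loc["life_years_disease_free"]
        srt = np.sort(d)
        assert row["mean"] == pytest.approx(d.mean())
        assert row["ci_low"] == pytest.approx(np.percentile(srt, 2.5))
        assert row["ci_high"] == pytest.approx(np.percentile(srt, 97.5))
        assert row["probability_pct"] == pytest.approx(100 * np.mean(d > 0))

    def test_constant_increments_collapse_interval(self, small_inputs):
        null = small_inputs.copy()
        null.trial = TrialEffect(odds_ratio=1.0, ci_low=1.0, ci_high=1.0)
        res = run_psa(null, InterventionSpec(duration_years=5), n_simulations=4, master_seed=2)
        tables = summarise_psa(res, np.array([30_000.0]))
        row = tables["table3"].set_index("outcome").loc["life_years_disease_free"]
        assert row["ci_low"] == row["ci_high"] == row["mean"] == 0.0

    def test_ceac_limits_and_monotonicity(self, psa_result):
        grid = np.arange(1000.0, 100_001.0, 1000.0)
        curve = ceac(psa_result, grid)
        p = curve["probability_cost_effective"].to_numpy()
        assert np.all((p >= 0) & (p <= 1))
        if np.all(psa_result.delta_cost_total > 0):
            assert np.all(np.diff(p) >= 0)
        # at very large thresholds the curve approaches P(delta QALY > 0)
        huge = ceac(psa_result, np.array([1e12]))
        assert huge["probability_cost_effective"].iloc[0] == pytest.approx(
            np.mean(psa_result.delta_qaly > 0)
        )

    def test_ceac_rejects_unsorted_grid(self, psa_result):
        with pytest.raises(ValueError):
            ceac(psa_result, np.array([2.0, 1.0]))

    def test_probability_cost_effective_equals_ceac_at_threshold(self, psa_result):
        tables = summarise_psa(psa_result, np.array([10_000.0, 30_000.0]))
        t4 = tables["table4"].set_index("outcome")
        p_table = t4.loc["probability_cost_effective_at_30000", "mean"]
        p_curve = tables["ceac"].set_index("threshold").loc[
            30_000.0, "probability_cost_effective"
        ]
        assert p_table == pytest.approx(100 * p_curve)

    def test_lower_discount_raises_nhb_when_qalys_positive(self, psa_result):
        # later benefits are up-weighted at 1.5 %: in every simulation with a
        # QALY gain, the sensitivity-discounted gain is at least as large
        alt = psa_result.increments("qalys_discounted_alt")
        base = psa_result.delta_qaly
        gain = base > 0
        assert np.all(alt[gain] >= base[gain])

    def test_ellipse_centred_on_means(self, psa_result):
        tables = summarise_psa(psa_result, np.array([30_000.0]))
        e = tables["ellipse"].iloc[0]
        assert e.centre_qaly == pytest.approx(psa_result.delta_qaly.mean())
        assert e.centre_cost == pytest.approx(psa_result.delta_cost_total.mean())
        assert e.half_axis_major >= e.half_axis_minor >= 0
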