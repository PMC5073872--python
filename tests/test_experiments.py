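"""Scenario transforms, replication statistics, scenario comparison and
historical validation arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioflow.experiments import (HIGH_COST_NAMES,
                                    ReplicationSummary, apply_scenario,
                                    compare_scenarios, mser_warmup,
                                    run_replications, validate_against_history)


class TestApplyScenario:
    def test_baseline_is_identity(self, base_config):
        assert apply_scenario(base_config, "baseline") == base_config

    def test_no_complications_zeroes_everything(self, base_config):
        cfg = apply_scenario(base_config, "no_complications")
        assert all(c.prevalence == 0.0 for c in cfg.complications)
        assert cfg.complication_any_prob == 0.0

    def test_no_high_cost_zeroes_exactly_four(self, base_config):
        cfg = apply_scenario(base_config, "no_high_cost")
        zeroed = {c.name for c in cfg.complications if c.prevalence == 0.0}
        assert zeroed == set(HIGH_COST_NAMES)
        # the cut-off is the 75th-percentile marginal charge, 1057.48 USD
        by_name = base_config.complications_by_name
        assert all(by_name[n].marginal_cost_usd >= 1057.48 for n in zeroed)

    def test_no_infections_zeroes_the_infection_category(self, base_config):
        cfg = apply_scenario(base_config, "no_infections")
        for c in cfg.complications:
            if c.category == "infection":
                assert c.prevalence == 0.0
            else:
                assert c.prevalence > 0.0

    def test_surviving_types_keep_absolute_assignment_probability(self, base_config):
        """Eliminating one type must not re-weight the others."""
        from cardioflow.hospital import CardiacUnitModel
        base_probs = {}
        acc = 0.0
        for threshold, c in CardiacUnitModel(base_config, 0)._comp_cum:
            base_probs[c.name] = threshold - acc
            acc = threshold
        cfg = apply_scenario(base_config, "no_infections")
        acc = 0.0
        for threshold, c in CardiacUnitModel(cfg, 0)._comp_cum:
            width = threshold - acc
            acc = threshold
            if c.category != "infection":
                assert width == pytest.approx(base_probs[c.name])
            else:
                assert width == 0.0

    def test_structural_scenarios(self, base_config):
        assert apply_scenario(base_config, "more_or_days").or_days == (0, 1, 2, 3, 4)
        assert apply_scenario(base_config, "extra_cicu_bed").cicu_beds == 6
        assert apply_scenario(base_config, "shorter_ward_los").ward_postop_scale \
            == pytest.approx(0.6)

    def test_septicaemia_half(self, base_config):
        cfg = apply_scenario(base_config, "septicaemia_half")
        assert cfg.complication("Septicaemia").prevalence == pytest.approx(
            base_config.complication("Septicaemia").prevalence / 2)
        # applying twice keeps halving (not idempotent, by design)
        again = apply_scenario(cfg, "septicaemia_half")
        assert again.complication("Septicaemia").prevalence == pytest.approx(
            base_config.complication("Septicaemia").prevalence / 4)

    def test_unknown_scenario_raises(self, base_config):
        with pytest.raises(ValueError):
            apply_scenario(base_config, "warp_drive")


class TestReplicationSummary:
    def test_t_interval_closed_form(self):
        summary = ReplicationSummary(pd.DataFrame({"kpi": [1.0, 2.0, 3.0]}), 3)
        lo, hi = summary.ci95("kpi")
        half = stats.t.ppf(0.975, 2) * 1.0 / math.sqrt(3)  # sd({1,2,3}) = 1
        assert half == pytest.approx(4.302653 / math.sqrt(3), abs=1e-4)
        assert summary.mean("kpi") == 2.0
        assert (hi - lo) / 2 == pytest.approx(half)
        assert lo < summary.mean("kpi") < hi

    def test_same_seed_gives_identical_summary(self, base_config):
        kwargs = dict(n_reps=3, seed=5, warmup_hours=500.0, horizon_hours=500.0 + 4380.0)
        a = run_replications(base_config, **kwargs)
        b = run_replications(base_config, **kwargs)
        pd.testing.assert_frame_equal(a.per_replication, b.per_replication)

    def test_too_few_replications_rejected(self, base_config):
        with pytest.raises(ValueError):
            run_replications(base_config, n_reps=1)

    def test_horizon_must_exceed_warmup(self, base_config):
        with pytest.raises(ValueError):
            run_replications(base_config, n_reps=3, warmup_hours=100.0,
                             horizon_hours=50.0)


class TestCompareScenarios:
    @staticmethod
    def _summary(value):
        return ReplicationSummary(pd.DataFrame({"kpi": [value, value]}), 2)

    def test_published_waiting_time_change(self):
        chg = compare_scenarios(self._summary(5.0), self._summary(1.36))
        assert chg.loc["kpi", "pct_change"] == pytest.approx(-72.8)

    def test_published_throughput_change(self):
        chg = compare_scenarios(self._summary(174.0), self._summary(197.0))
        assert chg.loc["kpi", "pct_change"] == pytest.approx(13.22, abs=0.005)

    def test_identical_summaries_change_zero(self):
        chg = compare_scenarios(self._summary(7.0), self._summary(7.0))
        assert chg.loc["kpi", "pct_change"] == 0.0

    def test_zero_reference_not_available(self):
        chg = compare_scenarios(self._summary(0.0), self._summary(3.0))
        assert math.isnan(chg.loc["kpi", "pct_change"])


class TestValidation:
    def test_variance_pct_completed_surgeries(self, rng):
        samples = 193.0 + rng.normal(0, 40, size=30)
        samples = samples - samples.mean() + 193.0  # pin the mean exactly
        res = validate_against_history("completed_surgeries", 164.0, samples)
        assert res.variance_pct == pytest.approx(17.68, abs=0.01)

    def test_variance_pct_waiting_time(self, rng):
        samples = 9.0 + rng.normal(0, 4, size=30)
        samples = samples - samples.mean() + 9.0
        res = validate_against_history("waiting_time", 11.0, samples)
        assert res.variance_pct == pytest.approx(-18.18, abs=0.01)

    def test_exact_match_accepts_with_zero_t(self):
        res = validate_against_history("x", 5.0, [5.0] * 10)
        assert res.t_statistic == 0.0 and res.decision == "accept"

    def test_constant_mismatch_rejects_with_p_zero(self):
        res = validate_against_history("x", 5.0, [6.0] * 10)
        assert res.p_value == 0.0 and res.decision == "reject"

    def test_decision_consistent_with_p(self, rng):
        samples = rng.normal(10, 1, 30)
        res = validate_against_history("x", 10.2, samples)
        assert (res.decision == "accept") == (res.p_value >= 0.05)


def test_mser_warmup_flags_initial_transient():
    series = np.r_[np.linspace(40, 10, 60), 10 + np.zeros(240)]
    cut = mser_warmup(series, batch=5)
    assert 20 <= cut <= 80
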