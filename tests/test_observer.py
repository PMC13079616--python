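import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gazemae import (ObserverParams, ParameterError, PopulationSpec,
                     build_schedule, population_preset, preset,
                     response_probability, simulate_cohort, simulate_subject)
from gazemae.observer import draw_observers
from gazemae.screening import easiest_accuracy


class TestResponseProbability:
    @pytest.mark.parametrize("lapse", [0.0, 0.1, 0.4])
    def test_half_at_the_central_point(self, lapse):
        p = ObserverParams(pse_mu=1.36, slope_b=8, lapse=lapse)
        assert response_probability(p, 1.36) == pytest.approx(0.5)

    def test_three_quarters_at_b_ln3_above_center(self):
        p = ObserverParams(pse_mu=0.0, slope_b=8.0)
        assert response_probability(p, 8.0 * math.log(3)) == pytest.approx(0.75)

    def test_lapse_ceiling(self):
        p = ObserverParams(pse_mu=0.0, slope_b=1.0, lapse=0.1)
        assert response_probability(p, 1e6) == pytest.approx(0.95)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            ObserverParams(pse_mu=0, slope_b=0)
        with pytest.raises(ParameterError):
            ObserverParams(pse_mu=0, slope_b=1, lapse=0.6)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(pse=st.floats(-10, 10), b=st.floats(0.5, 50), lapse=st.floats(0, 0.5),
           c1=st.floats(-30, 30), c2=st.floats(-30, 30))
    def test_monotone_and_bounded(self, pse, b, lapse, c1, c2):
        p = ObserverParams(pse_mu=pse, slope_b=b, lapse=lapse)
        lo, hi = sorted([c1, c2])
        f_lo, f_hi = response_probability(p, lo), response_probability(p, hi)
        assert f_lo <= f_hi
        assert lapse / 2 - 1e-12 <= f_lo and f_hi <= 1 - lapse / 2 + 1e-12


class TestSimulateSubject:
    def test_saturated_conditions_answered_toward(self, default_config):
        sched = build_schedule(default_config, seed=0)
        params = ObserverParams(pse_mu=0.0, slope_b=1.0)
        trials = simulate_subject(params, sched, seed=1)
        at30 = trials[trials["coherence_signed"] == 30]
        assert (at30["response"] == "toward").all()

    def test_noncompliant_accuracy_near_half(self, default_config):
        cfg = preset("1c", trials_per_condition=100, blocks=1)
        sched = build_schedule(cfg, seed=0)
        params = ObserverParams(pse_mu=0.0, slope_b=8.0, compliant=False)
        trials = simulate_subject(params, sched, seed=2)
        acc = easiest_accuracy(trials)  # 200 coin flips
        assert acc == pytest.approx(0.5, abs=3 * math.sqrt(0.25 / 200))

    def test_condensed_proportions_within_binomial_envelope(self, default_config):
        """Per-condition toward-counts stay inside the exact 99% binomial
        envelope implied by the generative response probabilities."""
        sched = build_schedule(default_config, seed=3)
        params = ObserverParams(pse_mu=1.36, slope_b=8.0)
        trials = simulate_subject(params, sched, seed=4)
        for lvl, sub in trials.groupby("coherence_signed"):
            k = int((sub["response"] == "toward").sum())
            p = response_probability(params, lvl)
            assert stats.binom.ppf(0.005, 10, p) <= k <= stats.binom.ppf(0.995, 10, p)

    def test_imc_flag_propagates(self, default_config):
        sched = build_schedule(default_config, seed=0)
        trials = simulate_subject(ObserverParams(0, 8, imc_pass=False), sched, seed=0)
        assert not trials["imc_pass"].any()


class TestSimulateCohort:
    def test_single_clean_subject_yields_70_rows(self, default_config):
        pop = PopulationSpec(frac_noncompliant=0, frac_imc_fail=0)
        trials = simulate_cohort(default_config, pop, 1, seed=0)
        assert len(trials) == 70
        assert trials["subject_id"].nunique() == 1

    def test_degenerate_population_shares_the_mean_shift(self, default_config):
        pop = PopulationSpec(mean_shift=1.36, between_subject_sd=0.0,
                             frac_noncompliant=0, frac_imc_fail=0)
        _, params = simulate_cohort(default_config, pop, 5, seed=1, return_params=True)
        assert all(p.pse_mu == pytest.approx(1.36) for p in params)

    def test_configured_fractions_are_exact(self):
        pop = PopulationSpec(frac_noncompliant=0.35, frac_imc_fail=0.06)
        obs = draw_observers(pop, 100, np.random.default_rng(0))
        assert sum(not o.compliant for o in obs) == 35
        assert sum(not o.imc_pass for o in obs) == 6
        assert all(o.slope_b > 0 for o in obs)

    def test_reproducible_under_seed(self, default_config):
        pop = PopulationSpec()
        a = simulate_cohort(default_config, pop, 4, seed=9)
        b = simulate_cohort(default_config, pop, 4, seed=9)
        assert a.equals(b)

    def test_preset_shift_only_on_line_of_sight_of_sighted_agent(self):
        assert population_preset("sighted", 0).mean_shift == 1.36
        assert population_preset("sighted", 230).mean_shift == 0.0
        assert population_preset("blindfolded", 0).mean_shift == 0.0
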