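"""Schedule generation, choice behavior, and value-state dynamics."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fscvda as f
from fscvda.task import DegenerateScheduleError


class TestScheduleGeneration:
    def test_default_design_counts(self, default_config):
        """The default session realises the printed task design exactly."""
        sched = f.generate_schedule(default_config, "baseline_A", seed=0)
        c = sched.counts()
        assert c["n_trials"] == 120
        assert c["n_forced"] == 80 and c["n_choice"] == 40
        assert c["switch_forced"] == 8    # 10% of forced
        assert c["more_forced"] == 4      # 5% of forced
        assert c["switch_choice"] == 2    # 5% of choice

    def test_single_block_degenerate_case(self):
        cfg = f.TaskConfig(n_blocks=1, p_switch_forced=0.2,
                           p_more_forced=0.2, p_switch_choice=0.3)
        sched = f.generate_schedule(cfg, "baseline_A", seed=3)
        df = sched.to_frame()
        assert len(df) == 12
        assert (df.trial_class == "forced_food").sum() == 4
        assert (df.trial_class == "forced_sucrose").sum() == 4

    def test_block_composition_every_block(self, default_config):
        for seed in range(50):
            df = f.generate_schedule(default_config, "baseline_A", seed).to_frame()
            per_block = df[df.trial_class.str.startswith("forced")] \
                .groupby(["block", "trial_class"]).size()
            assert (per_block == default_config.forced_per_lever).all()

    def test_same_seed_identical_different_seed_same_counts(self, default_config):
        a = f.generate_schedule(default_config, "baseline_A", 7).to_frame()
        b = f.generate_schedule(default_config, "baseline_A", 7).to_frame()
        c = f.generate_schedule(default_config, "baseline_A", 8).to_frame()
        assert a.equals(b)
        assert not a.equals(c)
        assert f.generate_schedule(default_config, "baseline_A", 8).counts() \
            == f.generate_schedule(default_config, "baseline_A", 7).counts()

    def test_event_ordering_and_timing(self, default_config):
        sched = f.generate_schedule(default_config, "baseline_A", 1)
        for t in sched.trials:
            assert t.lever_extension == pytest.approx(t.cue_onset + 5.0)

    def test_degenerate_surprise_rate_rejected(self):
        cfg = f.TaskConfig(p_more_forced=0.001)  # rounds to 0 of 80
        with pytest.raises(DegenerateScheduleError):
            f.generate_schedule(cfg, "baseline_A", 0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            f.TaskConfig(forced_per_block=6)  # != 2 * forced_per_lever
        with pytest.raises(ValueError):
            f.TaskConfig(p_switch_forced=1.2)
        with pytest.raises(ValueError):
            f.TaskConfig(more_multiplier=1.0)

    def test_unknown_session_kind_rejected(self, default_config):
        with pytest.raises(ValueError):
            f.generate_schedule(default_config, "devalue_water", 0)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_counts_invariant_across_seeds(self, seed):
        sched = f.generate_schedule(f.TaskConfig(), "baseline_A", seed)
        c = sched.counts()
        assert (c["switch_forced"], c["more_forced"], c["switch_choice"]) \
            == (8, 4, 2)

    def test_tsv_round_trip(self, tmp_path, default_config):
        sched = f.generate_schedule(default_config, "baseline_A", 5)
        sim = f.simulate_behavior(sched, f.ValueState(), 6)
        p = tmp_path / "events.tsv"
        sim.schedule.to_tsv(p)
        back = f.SessionSchedule.from_tsv(p)
        orig = sim.schedule.to_frame()
        got = back.to_frame()
        assert got.trial_class.tolist() == orig.trial_class.tolist()
        assert got.outcome_class.tolist() == orig.outcome_class.tolist()
        np.testing.assert_allclose(got.cue_onset, orig.cue_onset, atol=5e-4)
        assert (got.missed == orig.missed).all()


class TestBehavior:
    def test_equal_values_give_indifference(self, default_config):
        """Symmetric values -> food-choice proportion 0.5 within binomial error."""
        chosen = []
        for seed in range(30):
            sched = f.generate_schedule(default_config, "baseline_A", seed)
            sim = f.simulate_behavior(sched, f.ValueState(alpha=0.0), seed + 1000)
            df = sim.schedule.to_frame()
            ch = df[(df.trial_class == "choice") & ~df.missed]
            chosen.append((ch.chosen_option == "food_lever").mean())
        assert abs(np.mean(chosen) - 0.5) < 0.05

    def test_greedy_limit_always_picks_higher_value(self, default_config):
        state = f.ValueState(v_food=1.0, v_sucrose=0.5, beta=0.0, alpha=0.0)
        sched = f.generate_schedule(default_config, "baseline_A", 2)
        sim = f.simulate_behavior(sched, state, 3)
        df = sim.schedule.to_frame()
        ch = df[(df.trial_class == "choice") & ~df.missed]
        assert (ch.chosen_option == "food_lever").all()

    def test_softmax_matches_analytic_logistic(self):
        state = f.ValueState(v_food=1.0, v_sucrose=0.6, beta=0.25)
        expected = 1.0 / (1.0 + math.exp(-(1.0 - 0.6) / 0.25))
        assert state.p_food() == pytest.approx(expected)
        # empirical convergence over many choice trials
        picks = []
        for seed in range(40):
            sched = f.generate_schedule(f.TaskConfig(), "baseline_A", seed)
            sim = f.simulate_behavior(sched, dataclasses.replace(state, alpha=0.0),
                                      seed + 500)
            df = sim.schedule.to_frame()
            ch = df[(df.trial_class == "choice") & ~df.missed]
            picks.append((ch.chosen_option == "food_lever").mean())
        assert np.mean(picks) == pytest.approx(expected, abs=0.04)

    def test_devalued_option_miss_rate_inflated(self, default_config):
        """Monte-Carlo check of the configured miss-inflation factor."""
        dev_miss, val_miss = [], []
        state = f.apply_satiation(f.ValueState(), "food")
        for seed in range(100):
            sched = f.generate_schedule(default_config, "devalue_food", seed)
            sim = f.simulate_behavior(sched, state, seed + 9000)
            df = sim.schedule.to_frame()
            dev_miss.append(df[df.trial_class == "forced_food"].missed.mean())
            val_miss.append(df[df.trial_class == "forced_sucrose"].missed.mean())
        assert np.mean(dev_miss) > np.mean(val_miss)
        # inflation factor 4 on base rate 0.02
        assert np.mean(dev_miss) == pytest.approx(0.08, abs=0.02)
        assert np.mean(val_miss) == pytest.approx(0.02, abs=0.01)

    def test_latency_positive_and_before_reward(self, baseline_session):
        df = baseline_session[0].schedule.to_frame()
        ok = df[~df.missed]
        assert (ok.latency > 0).all()
        rewarded = ok[np.isfinite(ok.reward_delivery)]
        assert (rewarded.reward_delivery > rewarded.response_time).all()
        assert (rewarded.response_time > rewarded.lever_extension).all()


class TestValueState:
    def test_delta_rule_from_zero(self):
        s = f.ValueState(v_food=0.0, alpha=0.1)
        s2 = f.update_values(s, "food", 1.0)
        assert s2.v_food == pytest.approx(0.1)
        assert s2.v_sucrose == s.v_sucrose

    def test_no_learning_limit(self):
        s = f.ValueState(v_food=0.4, v_sucrose=0.7, alpha=0.0)
        s2 = f.update_values(s, "sucrose", 4.0)
        assert (s2.v_food, s2.v_sucrose) == (0.4, 0.7)

    @pytest.mark.parametrize("alpha", [0.05, 0.3, 0.9])
    def test_geometric_convergence_matches_closed_form(self, alpha):
        """Error after k standard rewards decays as (1 - alpha)^k."""
        s = f.ValueState(v_food=0.0, alpha=alpha)
        for k in range(1, 15):
            s = f.update_values(s, "food", 1.0)
            assert 1.0 - s.v_food == pytest.approx((1.0 - alpha) ** k)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            f.update_values(f.ValueState(), "food", -1.0)

    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            f.ValueState(alpha=1.5)
        with pytest.raises(ValueError):
            f.ValueState(v_food=float("nan"))

    def test_full_devaluation(self):
        s = f.apply_satiation(f.ValueState(), "sucrose", devaluation_factor=0.0)
        assert s.u_sucrose == 0.0 and s.u_food == 1.0

    def test_null_satiation_is_identity_on_values(self):
        s0 = f.ValueState()
        s = f.apply_satiation(s0, "food", devaluation_factor=1.0,
                              gain_factor=1.0, boost_valued_sucrose=False)
        assert (s.u_food, s.u_sucrose, s.general_gain) == (1.0, 1.0, 1.0)

    def test_selective_scaling_without_boost(self):
        s = f.apply_satiation(f.ValueState(), "food", devaluation_factor=0.3,
                              boost_valued_sucrose=False)
        assert s.u_food == pytest.approx(0.3)
        assert s.u_sucrose == 1.0
        assert s.devalued == "food"
        # learned predictions untouched until experienced
        assert (s.v_food, s.v_sucrose) == (1.0, 1.0)

    def test_satiation_reduces_gain_and_optionally_boosts_sucrose(self):
        s = f.apply_satiation(f.ValueState(), "food")
        assert s.general_gain == pytest.approx(0.7)
        assert s.u_sucrose == pytest.approx(1.4)
        s2 = f.apply_satiation(f.ValueState(), "sucrose")
        assert s2.u_food == 1.0  # asymmetry: no boost for valued food
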