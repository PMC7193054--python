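"""Behavioral summaries, stage proxies, toxicity and the hit rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfscreen import (
    BehaviorParams,
    SimulationConfig,
    assess_toxicity,
    call_behavior,
    classify_stage,
    mean_velocity,
    percent_change,
)
from zfscreen.errors import ExcludedWellsError, InputError, UndefinedChangeError
from zfscreen.locomotion import total_distance
from zfscreen.synthetic import TreatmentState, simulate_velocity_pair

from conftest import child_seed, constant_pairs, constant_velocity_trace


class TestSummaries:
    @pytest.mark.parametrize(
        "samples,expected",
        [(np.full(100, 3.0), 3.0), (np.zeros(100), 0.0),
         (np.r_[np.zeros(50), np.full(50, 4.0)], 2.0)],
    )
    def test_mean_velocity(self, samples, expected):
        from zfscreen import VelocityTrace

        trace = VelocityTrace("W0", "f0", "experimental", 25.0, samples)
        assert mean_velocity(trace) == expected

    @pytest.mark.parametrize(
        "vb,ve,expected", [(10.0, 6.0, -40.0), (5.0, 5.0, 0.0), (4.0, 6.0, 50.0)]
    )
    def test_percent_change(self, vb, ve, expected):
        assert percent_change(vb, ve) == pytest.approx(expected)

    def test_zero_baseline_is_undefined(self):
        with pytest.raises(UndefinedChangeError):
            percent_change(0.0, 5.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(InputError):
            mean_velocity(constant_velocity_trace(1.0, duration=0.0))


class TestStages:
    def test_immobile_is_stage_0(self):
        assert classify_stage(constant_velocity_trace(0.0)).stage == 0

    def test_moderate_swim_is_stage_I(self):
        assert classify_stage(constant_velocity_trace(2.0)).stage == 1

    def test_sustained_fast_swim_is_stage_II(self):
        assert classify_stage(constant_velocity_trace(10.0)).stage == 2

    def test_untreated_mutant_is_stage_III(self, cfg):
        _, exp = simulate_velocity_pair(cfg, TreatmentState.untreated(), seed=child_seed(40, 0))
        call = classify_stage(exp)
        assert call.stage == 3
        assert call.burst_count >= 3
        assert call.peak_velocity > 20.0


class TestToxicity:
    def _traces(self, n_immobile, n_total=6):
        return [
            constant_velocity_trace(0.0 if i < n_immobile else 2.0, fish_id=f"f{i}")
            for i in range(n_total)
        ]

    @pytest.mark.parametrize("n_immobile,expected", [(0, False), (2, False),
                                                     (3, True), (4, True), (6, True)])
    def test_half_or_more_immobile_is_toxic(self, n_immobile, expected):
        assert assess_toxicity(self._traces(n_immobile)) is expected

    def test_immobility_uses_total_distance(self):
        # 0.001 mm/s for 600 s = 0.6 mm < 1 mm threshold
        barely = constant_velocity_trace(0.001)
        assert total_distance(barely) < 1.0
        assert assess_toxicity([barely] * 6) is True


class TestHitRule:
    def test_clear_hit(self):
        call = call_behavior("X", 250.0, constant_pairs(10.0, 5.5))
        assert call.mean_pct_change == pytest.approx(-45.0)
        assert call.stage0_or_I_fraction == 1.0
        assert not call.toxic
        assert call.hit

    def test_just_below_threshold_is_not_a_hit(self):
        call = call_behavior("X", 250.0, constant_pairs(10.0, 6.01))
        assert call.mean_pct_change == pytest.approx(-39.9)
        assert not call.hit

    def test_stage_fraction_below_half_blocks_hit(self):
        # deep velocity drop but 4/6 fish remain convulsive (stage III)
        rng = np.random.default_rng(1)
        convulsive = np.zeros(15000)
        convulsive[rng.choice(15000, 200, replace=False)] = 30.0
        pairs = constant_pairs(10.0, 4.0)
        for i in range(4):
            base, _ = pairs[i]
            pairs[i] = (base, type(base)("W0", f"f{i}", "experimental", 25.0, convulsive))
        call = call_behavior("X", 250.0, pairs)
        assert call.stage0_or_I_fraction == pytest.approx(2 / 6)
        assert not call.hit

    def test_toxic_compound_is_never_a_hit(self):
        call = call_behavior("X", 250.0, constant_pairs(10.0, 0.0))
        assert call.toxic and not call.hit
        assert call.mean_pct_change == pytest.approx(-100.0)

    def test_hit_flips_exactly_at_the_40pct_reduction(self):
        """Scanning integer reductions, the first hit is exactly 40%."""
        first_hit = None
        for r in range(101):
            call = call_behavior("X", 250.0, constant_pairs(10.0, (100.0 - r) / 10.0))
            if call.hit:
                first_hit = r
                break
        assert first_hit == 40

    @given(reduction=st.floats(min_value=0.0, max_value=99.0))
    @settings(max_examples=40, deadline=None)
    def test_hit_iff_reduction_at_least_cut(self, reduction):
        call = call_behavior(
            "X", 250.0, constant_pairs(10.0, (100.0 - reduction) / 10.0), BehaviorParams()
        )
        assert call.hit == (reduction >= 40.0)

    def test_zero_baseline_fish_excluded_but_counted(self):
        pairs = constant_pairs(10.0, 5.5, n_fish=5)
        pairs.append(
            (constant_velocity_trace(0.0, "baseline", fish_id="dead"),
             constant_velocity_trace(0.0, "experimental", fish_id="dead"))
        )
        call = call_behavior("X", 250.0, pairs)
        assert call.excluded_fish == ("dead",)
        assert len(call.per_fish_pct_change) == 5
        assert call.n_fish == 6

    def test_all_baselines_zero_aborts_with_report(self):
        pairs = constant_pairs(0.0, 0.0)
        with pytest.raises(ExcludedWellsError) as err:
            call_behavior("X", 250.0, pairs)
        assert len(err.value.excluded) == 6

    def test_vehicle_null_hit_rate_bounded_by_gaussian_tail(self, cfg):
        """Single-well false-positive rate under vehicle stays below the
        tail a -40% cut implies for a zero-mean, s.d.-17.83 distribution."""
        from scipy.stats import norm

        from zfscreen.locomotion import mean_velocity as mv

        n_below = 0
        n = 1000
        for i in range(n):
            base, exp = simulate_velocity_pair(
                cfg, TreatmentState.treated(0.0), seed=child_seed(41, i)
            )
            if percent_change(mv(base), mv(exp)) <= -40.0:
                n_below += 1
        bound = norm.cdf(-40.0 / cfg.control_pct_change_sd)
        assert n_below / n <= 1.5 * bound
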