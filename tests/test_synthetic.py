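"""Generator self-consistency: seeded reproducibility, calibrated statistics,
ground-truth integrity."""

import numpy as np
import pytest

from zfscreen import SimulationConfig, estimate_noise
from zfscreen.errors import ConfigError, InputError
from zfscreen.locomotion import mean_velocity, percent_change, total_distance
from zfscreen.synthetic import (
    TreatmentState,
    simulate_lfp_trace,
    simulate_screen,
    simulate_velocity_pair,
    simulate_velocity_trace,
)

from conftest import child_seed


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lfp_sampling_rate": 0.0},
            {"epoch_duration": -1.0},
            {"interictal_duration_sd": 0.0},
            {"vehicle_interictal_count_range": (200, 100)},
            {"interictal_amp_factor": 2.5},  # undetectable at the 3x rule
            {"ictal_amp_factor": 4.0},       # below the 5x rule
            {"fish_per_well_group": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_roundtrip_dict(self, cfg):
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestLFPGenerator:
    def test_identical_seed_is_bit_identical(self, cfg):
        a, _ = simulate_lfp_trace(cfg, seed=123)
        b, _ = simulate_lfp_trace(cfg, seed=123)
        assert np.array_equal(a.samples, b.samples)

    def test_vehicle_counts_within_published_ranges(self, cfg):
        for i in range(5):
            _, gt = simulate_lfp_trace(cfg, seed=child_seed(10, i))
            assert 107 <= gt.interictal_count <= 453
            assert 1 <= gt.ictal_count <= 10

    def test_full_suppression_removes_all_events(self, cfg):
        trace, gt = simulate_lfp_trace(cfg, suppression=1.0, seed=7)
        assert gt.events == []
        # trace is then pure noise at the configured sigma
        assert estimate_noise(trace).sigma == pytest.approx(cfg.noise_sigma, abs=0.01)

    def test_truth_intervals_sorted_disjoint_and_in_bounds(self, cfg):
        _, gt = simulate_lfp_trace(cfg, seed=99)
        ends = 0.0
        for ev in gt.events:
            assert 0.0 <= ev.start < ev.end <= cfg.epoch_duration
            assert ev.start >= ends
            ends = ev.end

    def test_count_overrides_respected(self, cfg):
        _, gt = simulate_lfp_trace(cfg, seed=3, interictal_count=200, ictal_count=4)
        assert gt.interictal_count == 200
        assert gt.ictal_count == 4

    def test_noise_recovery_on_event_free_traces(self, cfg):
        """Robust sigma recovers noise_sigma within 3 s.e. over 50 replicates."""
        sigmas = [
            estimate_noise(
                simulate_lfp_trace(cfg, suppression=1.0, seed=child_seed(11, i))[0]
            ).sigma
            for i in range(50)
        ]
        se = np.std(sigmas, ddof=1) / np.sqrt(len(sigmas))
        assert abs(np.mean(sigmas) - cfg.noise_sigma) < 3 * max(se, 1e-4)

    def test_infeasible_event_load_raises(self):
        cfg = SimulationConfig(
            epoch_duration=60.0, vehicle_interictal_count_range=(400, 400)
        )
        with pytest.raises(ConfigError):
            simulate_lfp_trace(cfg, seed=0)


class TestVelocityGenerator:
    def test_identical_seed_is_bit_identical(self, cfg):
        a = simulate_velocity_trace(cfg, TreatmentState.untreated(), "baseline", seed=5)
        b = simulate_velocity_trace(cfg, TreatmentState.untreated(), "baseline", seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_invalid_state_and_epoch_rejected(self, cfg):
        with pytest.raises(InputError):
            TreatmentState("sedated")
        with pytest.raises(InputError):
            TreatmentState.treated(1.5)
        with pytest.raises(InputError):
            simulate_velocity_trace(cfg, TreatmentState.untreated(), "recovery", seed=0)

    def test_toxic_wells_are_immobile(self, cfg):
        _, exp = simulate_velocity_pair(cfg, TreatmentState.toxic(), seed=4)
        assert total_distance(exp) < 1.0

    def test_vehicle_percent_change_calibration(self, cfg):
        """Vehicle wells: mean ~ 0 (within 3 s.e.), s.d. within 15% of 17.83."""
        pct = []
        for i in range(200):
            base, exp = simulate_velocity_pair(
                cfg, TreatmentState.treated(0.0), seed=child_seed(20, i)
            )
            pct.append(percent_change(mean_velocity(base), mean_velocity(exp)))
        pct = np.asarray(pct)
        se = pct.std(ddof=1) / np.sqrt(pct.size)
        assert abs(pct.mean()) < 3 * se
        assert pct.std(ddof=1) == pytest.approx(cfg.control_pct_change_sd, rel=0.15)

    def test_suppression_sets_mean_percent_change(self, cfg):
        """treated(0.6) gives mean percent change ~ -60 over 200 replicates."""
        pct = [
            percent_change(
                *map(
                    mean_velocity,
                    simulate_velocity_pair(
                        cfg, TreatmentState.treated(0.6), seed=child_seed(21, i)
                    ),
                )
            )
            for i in range(200)
        ]
        se = np.std(pct, ddof=1) / np.sqrt(len(pct))
        assert np.mean(pct) == pytest.approx(-60.0, abs=max(3 * se, 1.5))


class TestScreenDataset:
    def test_truth_mix_counts_and_monotone_doses(self, cfg):
        ds = simulate_screen(cfg, 20, (0.25, 0.5, 0.25), seed=42)
        classes = [t.klass for t in ds.truth.values()]
        assert classes.count("suppressor") == 5
        assert classes.count("inert") == 10
        assert classes.count("toxic") == 5
        for t in ds.truth.values():
            if t.klass == "suppressor":
                effects = [t.effect(c) for c in (1.0, 10.0, 100.0)]
                assert effects == sorted(effects)
                assert 0.6 <= t.e_max <= 0.95

    def test_every_plate_has_the_internal_controls(self, cfg):
        ds = simulate_screen(cfg, 33, seed=1)
        for layout in ds.layouts:
            assert len(layout["vehicle_wells"]) == cfg.controls_per_plate

    def test_manifest_covers_all_compounds_once(self, cfg):
        ds = simulate_screen(cfg, 17, seed=2)
        assert ds.manifest["compound_id"].is_unique
        assert len(ds.manifest) == 17

    def test_invalid_mix_rejected(self, cfg):
        with pytest.raises(ConfigError):
            simulate_screen(cfg, 10, (0.5, 0.5, 0.5), seed=0)
        with pytest.raises(ConfigError):
            simulate_screen(cfg, 0, seed=0)

    def test_wells_regenerate_identically(self, fast_cfg):
        ds = simulate_screen(fast_cfg, 4, seed=9)
        cid = ds.compound_ids[0]
        a = ds.velocity_pairs(cid, 10.0)
        b = ds.velocity_pairs(cid, 10.0)
        assert np.array_equal(a[0][1].samples, b[0][1].samples)
        la = ds.lfp_traces("vehicle", None, 2)
        lb = ds.lfp_traces("vehicle", None, 2)
        assert np.array_equal(la[1][0].samples, lb[1][0].samples)
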