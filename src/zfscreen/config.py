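"""Configuration objects for simulation, detection, hit calling and screening.

Every threshold used by the pipeline lives here so that a single YAML/JSON
file can drive a full screen: the 40% velocity-reduction cut, the 50%
stage-fraction and toxicity fractions, the 3x/5x amplitude factors of the
LFP event detector, behavioral stage thresholds, and the significance level
of the confirmation statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from typing import Any

from .errors import ConfigError


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic locomotion/LFP generator.

    Defaults encode the measured quantities of the scn1lab screening assays:
    1 kHz LFP acquisition over 10-min epochs, baseline noise 0.35 mV,
    interictal events of 0.47 +/- 0.02 s at >3x noise, ictal poly-spike
    events of 3.09 +/- 1.01 s at >5x noise, vehicle event loads of 107-453
    interictal and 1-10 ictal events per 10 min, a vehicle percent-velocity-
    change s.d. of 17.83, six fish per drug and six vehicle controls per
    96-well plate.
    """

    # --- LFP ---
    lfp_sampling_rate: float = 1000.0  # Hz
    epoch_duration: float = 600.0      # s
    noise_sigma: float = 0.35          # mV
    interictal_duration_mean: float = 0.47  # s
    interictal_duration_sd: float = 0.02    # s
    ictal_duration_mean: float = 3.09       # s
    ictal_duration_sd: float = 1.01         # s
    vehicle_interictal_count_range: tuple[int, int] = (107, 453)  # events / 10 min
    vehicle_ictal_count_range: tuple[int, int] = (1, 10)          # events / 10 min
    interictal_amp_factor: float = 4.0  # x noise_sigma
    ictal_amp_factor: float = 6.0       # x noise_sigma
    min_event_gap: float = 0.4          # s between injected event supports

    # --- behavior ---
    behavior_sampling_rate: float = 25.0  # Hz
    control_pct_change_sd: float = 17.83  # % (vehicle wells)
    fish_per_well_group: int = 6
    controls_per_plate: int = 6

    # Convulsive-burst process behind the velocity traces.  These are
    # generator-internal choices (the assay reports only summary behavior);
    # they are set so an untreated mutant shows frequent high-velocity
    # (stage III) bursts over a slow baseline swim.
    burst_rate_per_epoch: float = 90.0   # mean bursts / 10-min epoch
    burst_peak_mean: float = 28.0        # mm/s
    burst_peak_cv: float = 0.15
    burst_duration: float = 1.0          # s (Gaussian-bell support ~ +/-3 tau)
    baseline_swim_mean: float = 0.8      # mm/s
    baseline_swim_sigma: float = 0.6     # lognormal shape

    def __post_init__(self) -> None:
        pos = {
            "lfp_sampling_rate": self.lfp_sampling_rate,
            "epoch_duration": self.epoch_duration,
            "interictal_duration_mean": self.interictal_duration_mean,
            "interictal_duration_sd": self.interictal_duration_sd,
            "ictal_duration_mean": self.ictal_duration_mean,
            "ictal_duration_sd": self.ictal_duration_sd,
            "interictal_amp_factor": self.interictal_amp_factor,
            "ictal_amp_factor": self.ictal_amp_factor,
            "behavior_sampling_rate": self.behavior_sampling_rate,
            "control_pct_change_sd": self.control_pct_change_sd,
            "burst_rate_per_epoch": self.burst_rate_per_epoch,
            "burst_peak_mean": self.burst_peak_mean,
            "burst_duration": self.burst_duration,
            "baseline_swim_mean": self.baseline_swim_mean,
            "min_event_gap": self.min_event_gap,
        }
        for name, value in pos.items():
            _require(value > 0, f"{name} must be strictly positive, got {value!r}")
        _require(self.noise_sigma >= 0, "noise_sigma must be non-negative")
        _require(self.fish_per_well_group >= 1, "fish_per_well_group must be >= 1")
        _require(self.controls_per_plate >= 0, "controls_per_plate must be >= 0")
        for name in ("vehicle_interictal_count_range", "vehicle_ictal_count_range"):
            lo, hi = getattr(self, name)
            _require(lo >= 0 and hi >= lo, f"{name} must satisfy 0 <= low <= high")
        # Injected amplitudes must clear the detector's classification rules,
        # otherwise ground truth is undetectable by construction.
        _require(self.interictal_amp_factor > 3.0,
                 "interictal_amp_factor must exceed the 3x detection threshold")
        _require(self.ictal_amp_factor > 5.0,
                 "ictal_amp_factor must exceed the 5x ictal threshold")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["vehicle_interictal_count_range"] = list(self.vehicle_interictal_count_range)
        d["vehicle_ictal_count_range"] = list(self.vehicle_ictal_count_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        kwargs = dict(d)
        for name in ("vehicle_interictal_count_range", "vehicle_ictal_count_range"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass(frozen=True)
class DetectionParams:
    """Threshold-detector settings for epileptiform events.

    The 3x/5x amplitude factors are the assay's published rules; the
    refractory gap, merge gap, ictal duration threshold and poly-spike
    count are detector defaults chosen to keep the published interictal
    (0.47 s) and ictal (3.09 s) durations far from the class boundary.
    """

    threshold_factor: float = 3.0   # x noise sigma, spike threshold
    ictal_factor: float = 5.0       # x noise sigma, ictal amplitude rule
    merge_gap_s: float = 0.35       # spikes closer than this join one event
    refractory_s: float = 0.02      # minimum spacing between counted spikes
    ictal_duration_s: float = 1.0   # long-duration route to the ictal class
    polyspike_min: int = 3          # poly-spike route to the ictal class
    smooth_ms: float = 20.0         # boxcar pre-smoothing of the trace

    def __post_init__(self) -> None:
        _require(self.threshold_factor > 0, "threshold_factor must be positive")
        _require(self.ictal_factor >= self.threshold_factor,
                 "ictal_factor must be >= threshold_factor")
        _require(self.merge_gap_s >= 0, "merge_gap_s must be non-negative")
        _require(self.refractory_s >= 0, "refractory_s must be non-negative")
        _require(self.ictal_duration_s > 0, "ictal_duration_s must be positive")
        _require(self.polyspike_min >= 1, "polyspike_min must be >= 1")
        _require(self.smooth_ms >= 0, "smooth_ms must be non-negative")


@dataclass(frozen=True)
class StageThresholds:
    """Velocity-feature proxies for behavioral seizure stages 0-III.

    The staging scale is behavioral (video-scored); these thresholds map it
    onto velocity features: stage III = repeated convulsive high-velocity
    bursts, stage II = sustained elevated swim, stage I = ordinary activity,
    stage 0 = little or no movement.
    """

    activity_velocity: float = 0.5         # mm/s, counts a sample as "active"
    immobile_active_fraction: float = 0.05  # below this active fraction -> stage 0
    stage2_sustained_velocity: float = 8.0  # mm/s mean velocity -> stage II
    convulsive_peak_velocity: float = 20.0  # mm/s burst threshold for stage III
    convulsive_burst_min: int = 3           # bursts above peak for stage III

    def __post_init__(self) -> None:
        _require(self.activity_velocity > 0, "activity_velocity must be positive")
        _require(0 < self.immobile_active_fraction < 1,
                 "immobile_active_fraction must be in (0, 1)")
        _require(self.stage2_sustained_velocity > 0,
                 "stage2_sustained_velocity must be positive")
        _require(self.convulsive_peak_velocity > 0,
                 "convulsive_peak_velocity must be positive")
        _require(self.convulsive_burst_min >= 1, "convulsive_burst_min must be >= 1")


@dataclass(frozen=True)
class BehaviorParams:
    """Hit-calling and toxicity rules of the locomotion assay."""

    velocity_reduction_cut_pct: float = 40.0  # hit needs mean change <= -this
    stage_fraction_min: float = 0.5           # fraction of fish at stage 0/I
    toxic_fraction_min: float = 0.5           # fraction immobile -> toxic
    immobility_distance_mm: float = 1.0       # total distance below this = immobile
    stages: StageThresholds = field(default_factory=StageThresholds)

    def __post_init__(self) -> None:
        _require(self.velocity_reduction_cut_pct > 0,
                 "velocity_reduction_cut_pct must be positive")
        _require(0 < self.stage_fraction_min <= 1,
                 "stage_fraction_min must be in (0, 1]")
        _require(0 < self.toxic_fraction_min <= 1,
                 "toxic_fraction_min must be in (0, 1]")
        _require(self.immobility_distance_mm > 0,
                 "immobility_distance_mm must be positive")


@dataclass(frozen=True)
class ScreenConfig:
    """Everything a full screening cascade needs."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    primary_concentrations: tuple[float, float] = (250.0, 10.0)  # uM
    dose_response_concentrations: tuple[float, ...] = (1.0, 10.0, 100.0)  # uM
    dose_monotonicity_tol_pct: float = 5.0  # allowed noise-level increase
    alpha: float = 0.05
    n_lfp_subjects: int = 10          # per treated group in confirmation
    n_vehicle_lfp_subjects: int = 10
    dunnett_draws: int = 200_000

    def __post_init__(self) -> None:
        _require(len(self.primary_concentrations) == 2,
                 "primary_concentrations must hold exactly two concentrations")
        for c in (*self.primary_concentrations, *self.dose_response_concentrations):
            _require(c > 0, "concentrations must be positive")
        _require(len(set(self.dose_response_concentrations)) ==
                 len(self.dose_response_concentrations) >= 2,
                 "dose_response_concentrations must be >= 2 distinct values")
        _require(0 < self.alpha < 1, "alpha must be in (0, 1)")
        _require(self.dose_monotonicity_tol_pct >= 0,
                 "dose_monotonicity_tol_pct must be non-negative")
        _require(self.n_lfp_subjects >= 2 and self.n_vehicle_lfp_subjects >= 2,
                 "confirmation needs >= 2 subjects per group")
        _require(self.dunnett_draws >= 1000, "dunnett_draws must be >= 1000")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["primary_concentrations"] = list(self.primary_concentrations)
        d["dose_response_concentrations"] = list(self.dose_response_concentrations)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScreenConfig":
        kwargs = dict(d)
        if "sim" in kwargs:
            kwargs["sim"] = SimulationConfig.from_dict(kwargs["sim"])
        if "detection" in kwargs:
            kwargs["detection"] = DetectionParams(**kwargs["detection"])
        if "behavior" in kwargs:
            b = dict(kwargs["behavior"])
            if "stages" in b:
                b["stages"] = StageThresholds(**b["stages"])
            kwargs["behavior"] = BehaviorParams(**b)
        for name in ("primary_concentrations", "dose_response_concentrations"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown screen config keys: {sorted(unknown)}")
        try:
            return cls(**kwargs)
        except TypeError as exc:  # wrong nested types etc.
            raise ConfigError(str(exc)) from exc
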