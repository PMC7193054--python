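"""Behavioral summaries and hit calling for the 96-well locomotion assay.

Each fish contributes a 10-min "baseline" and a 10-min "experimental"
velocity trace.  A compound is a positive behavioral hit when

1. the mean (across fish) percent change in mean swim velocity is a
   decrease of at least 40% — a cut chosen against a vehicle-control
   percent-change s.d. of 17.83, and
2. at least 50% of the fish are reduced to stage 0 or stage I seizure
   behavior in the experimental epoch, and
3. the compound is not acutely toxic (at least 50% of fish immobile).

Stage assignment is proxied from velocity features since the original
staging scale is video-scored; the thresholds are configurable defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import BehaviorParams, StageThresholds
from .errors import ExcludedWellsError, InputError, UndefinedChangeError

log = logging.getLogger(__name__)


@dataclass
class VelocityTrace:
    """Per-fish swim velocity (mm/s) over one recording epoch."""

    well_id: str
    fish_id: str
    epoch: str  # "baseline" | "experimental"
    sampling_rate: float  # Hz
    samples: np.ndarray   # mm/s

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        if self.epoch not in ("baseline", "experimental"):
            raise InputError(f"unknown epoch {self.epoch!r}")
        if self.samples.ndim != 1:
            raise InputError("samples must be one-dimensional")
        if self.samples.size:
            if not np.all(np.isfinite(self.samples)):
                raise InputError("samples contain non-finite values")
            if self.samples.min() < 0:
                raise InputError("velocities must be non-negative")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class StageCall:
    """Behavioral stage (0-III) with the velocity features behind it."""

    stage: int
    mean_velocity: float
    active_fraction: float
    burst_count: int
    peak_velocity: float


@dataclass(frozen=True)
class BehaviorCall:
    """Per-compound behavioral outcome at one concentration."""

    compound_id: str
    concentration: float  # uM
    per_fish_pct_change: tuple[float, ...]
    mean_pct_change: float
    stage0_or_I_fraction: float
    toxic: bool
    hit: bool
    n_fish: int
    excluded_fish: tuple[str, ...] = ()


def mean_velocity(trace: VelocityTrace) -> float:
    """Arithmetic mean velocity (mm/s) over the epoch."""
    if trace.samples.size == 0:
        raise InputError("cannot average an empty trace")
    return float(trace.samples.mean())


def total_distance(trace: VelocityTrace) -> float:
    """Total distance moved (mm) over the epoch."""
    if trace.samples.size == 0:
        raise InputError("cannot integrate an empty trace")
    return float(trace.samples.sum() / trace.sampling_rate)


def percent_change(v_base: float, v_exp: float) -> float:
    """Percent change of mean velocity from baseline: 100*(v_exp-v_base)/v_base."""
    if v_base <= 0:
        raise UndefinedChangeError(
            "percent change undefined for zero baseline velocity (well excluded)"
        )
    return 100.0 * (v_exp - v_base) / v_base


def classify_stage(
    trace: VelocityTrace, thresholds: StageThresholds = StageThresholds()
) -> StageCall:
    """Assign a behavioral seizure stage from velocity features.

    Stage III: at least ``convulsive_burst_min`` excursions above the
    convulsive peak velocity.  Stage II: sustained elevated mean velocity.
    Stage I: active but below the stage II/III thresholds.  Stage 0:
    active fraction below the immobility threshold.
    """
    if trace.samples.size == 0:
        raise InputError("cannot stage an empty trace")
    v = trace.samples
    mean_v = float(v.mean())
    peak = float(v.max())
    active_fraction = float(np.mean(v > thresholds.activity_velocity))
    above = (v > thresholds.convulsive_peak_velocity).astype(np.int8)
    burst_count = int(np.sum(np.diff(np.concatenate(([0], above))) == 1)) if above.any() else 0

    if burst_count >= thresholds.convulsive_burst_min:
        stage = 3
    elif mean_v >= thresholds.stage2_sustained_velocity:
        stage = 2
    elif active_fraction >= thresholds.immobile_active_fraction:
        stage = 1
    else:
        stage = 0
    return StageCall(
        stage=stage,
        mean_velocity=mean_v,
        active_fraction=active_fraction,
        burst_count=burst_count,
        peak_velocity=peak,
    )


def assess_toxicity(
    experimental: list[VelocityTrace], params: BehaviorParams = BehaviorParams()
) -> bool:
    """Acute-toxicity flag: immobile fraction >= toxic_fraction_min.

    A fish counts as immobile when its total distance moved in the
    experimental epoch falls below ``immobility_distance_mm`` (default 1 mm
    over 10 min), the velocity proxy for "no movement in response to
    external stimulation".
    """
    if not experimental:
        raise InputError("need at least one experimental trace")
    immobile = [total_distance(t) < params.immobility_distance_mm for t in experimental]
    return float(np.mean(immobile)) >= params.toxic_fraction_min


def call_behavior(
    compound_id: str,
    concentration: float,
    pairs: list[tuple[VelocityTrace, VelocityTrace]],
    params: BehaviorParams = BehaviorParams(),
) -> BehaviorCall:
    """Apply the full behavioral hit rule to one compound's paired traces.

    ``pairs`` holds (baseline, experimental) traces per fish.  Fish whose
    baseline mean velocity is zero are excluded from the percent-change
    mean (their change is undefined) but still count toward toxicity and
    the stage fraction.  Raises :class:`ExcludedWellsError` when no fish
    survives exclusion.
    """
    if not pairs:
        raise InputError("need at least one (baseline, experimental) pair")
    pct: list[float] = []
    excluded: list[str] = []
    for base, exp in pairs:
        if base.epoch != "baseline" or exp.epoch != "experimental":
            raise InputError("pairs must be ordered (baseline, experimental)")
        vb = mean_velocity(base)
        if vb <= 0:
            excluded.append(base.fish_id)
            continue
        pct.append(percent_change(vb, mean_velocity(exp)))
    if excluded:
        log.warning(
            "compound %s @ %g uM: excluded %d fish with zero baseline: %s",
            compound_id, concentration, len(excluded), excluded,
        )
    if not pct:
        raise ExcludedWellsError(
            f"compound {compound_id}: all baselines zero, behavioral call aborted",
            excluded,
        )
    experimental = [exp for _, exp in pairs]
    toxic = assess_toxicity(experimental, params)
    stages = [classify_stage(t, params.stages).stage for t in experimental]
    stage_fraction = float(np.mean([s <= 1 for s in stages]))
    mean_pct = float(np.mean(pct))
    hit = (
        (mean_pct <= -params.velocity_reduction_cut_pct)
        and (stage_fraction >= params.stage_fraction_min)
        and not toxic
    )
    return BehaviorCall(
        compound_id=compound_id,
        concentration=concentration,
        per_fish_pct_change=tuple(pct),
        mean_pct_change=mean_pct,
        stage0_or_I_fraction=stage_fraction,
        toxic=toxic,
        hit=hit,
        n_fish=len(pairs),
        excluded_fish=tuple(excluded),
    )
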