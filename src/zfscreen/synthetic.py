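"""Ground-truthed synthetic locomotion plates and LFP traces.

No raw data from the screen are deposited, so every downstream stage is
exercised on simulated data carrying the assay's stated signal structure:

* LFP traces are Gaussian noise (sigma = 0.35 mV) plus injected biphasic
  interictal transients (~0.47 s, 4x noise by default) and multi-spike
  ictal bursts (~3.09 s, 6x noise), with vehicle event counts drawn
  uniformly from the published ranges (107-453 and 1-10 per 10 min) and
  thinned binomially under drug suppression.
* Velocity traces are a slow lognormal baseline swim plus a Poisson train
  of high-velocity convulsive bursts; treatment scales the experimental
  epoch by (1 - suppression) times a lognormal session factor calibrated
  so vehicle wells show the published percent-change s.d. of 17.83.
* ``simulate_screen`` assembles a full multi-plate screen (manifest,
  plate layouts, traces at every required concentration, LFP subjects)
  with per-compound ground-truth labels.

All randomness flows from integer seeds through ``numpy.random.SeedSequence``
so any subset of a dataset is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigError, InputError
from .lfp import LFPTrace
from .locomotion import VelocityTrace

#: Amplitude factor at which the downstream detector places event bounds.
#: Injected interictal spans are widened so that the 3x-threshold-crossing
#: duration recovers the configured duration (see ``_span_factor``).
DETECTION_FACTOR = 3.0

#: Concentration (uM) at and above which a "toxic"-class compound kills.
TOXIC_MIN_CONC = 10.0

# stream tags for SeedSequence spawning
_VEL, _LFP, _TRUTH = 1, 2, 3


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# treatment states & ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentState:
    """Behavioral state of a well: untreated mutant, treated, or toxic."""

    kind: str  # "untreated" | "treated" | "toxic"
    suppression: float = 0.0  # fractional velocity suppression in [0, 1]

    def __post_init__(self) -> None:
        if self.kind not in ("untreated", "treated", "toxic"):
            raise InputError(f"unknown behavior state {self.kind!r}")
        if not 0.0 <= self.suppression <= 1.0:
            raise InputError("suppression must lie in [0, 1]")

    @staticmethod
    def untreated() -> "TreatmentState":
        return TreatmentState("untreated", 0.0)

    @staticmethod
    def treated(suppression: float) -> "TreatmentState":
        return TreatmentState("treated", suppression)

    @staticmethod
    def toxic() -> "TreatmentState":
        return TreatmentState("toxic", 0.0)


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth injected event interval with its class."""

    start: float
    end: float
    event_class: str  # "interictal" | "ictal"


@dataclass
class TraceGroundTruth:
    """True events of one LFP trace."""

    events: list[TrueEvent] = field(default_factory=list)

    @property
    def interictal_count(self) -> int:
        return sum(1 for e in self.events if e.event_class == "interictal")

    @property
    def ictal_count(self) -> int:
        return sum(1 for e in self.events if e.event_class == "ictal")


@dataclass(frozen=True)
class CompoundTruth:
    """Hidden label of a screened compound.

    ``e_max`` is the asymptotic fractional suppression (of swim velocity
    and of epileptiform event rates alike); the concentration-response is
    a monotone hyperbolic (Hill coefficient 1) curve, so dose effects
    increase with log-concentration by construction.
    """

    compound_id: str
    klass: str  # "suppressor" | "inert" | "toxic"
    e_max: float = 0.0
    ec50: float = 1.0  # uM

    def __post_init__(self) -> None:
        if self.klass not in ("suppressor", "inert", "toxic"):
            raise InputError(f"unknown compound class {self.klass!r}")
        if not 0.0 <= self.e_max <= 1.0:
            raise InputError("e_max must lie in [0, 1]")

    def effect(self, concentration: float) -> float:
        """Fractional suppression at a concentration (uM)."""
        if self.klass != "suppressor":
            return 0.0
        return self.e_max * concentration / (concentration + self.ec50)

    def toxic_at(self, concentration: float) -> bool:
        return self.klass == "toxic" and concentration >= TOXIC_MIN_CONC

    def state_at(self, concentration: float) -> TreatmentState:
        if self.toxic_at(concentration):
            return TreatmentState.toxic()
        return TreatmentState.treated(self.effect(concentration))


# --------------------------------------------------------------------------
# LFP generation
# --------------------------------------------------------------------------

def _span_factor(amp_factor: float) -> float:
    """Fraction of a biphasic half-sine pair's span above the 3x threshold.

    For a pair of half-sine lobes of peak a*sigma, the first/last crossings
    of the 3*sigma level trim asin(3/a)/pi of the span; injected spans are
    divided by this factor so the detector's threshold-crossing duration
    matches the drawn duration.
    """
    r = min(1.0, DETECTION_FACTOR / amp_factor)
    return 1.0 - math.asin(r) / math.pi


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, low: float
) -> np.ndarray:
    """Normal draws redrawn until all exceed ``low`` (rejection sampling)."""
    out = rng.normal(mean, sd, n)
    bad = out <= low
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= low
    return out


def _biphasic(span: float, amp: float, fs: float) -> np.ndarray:
    """Biphasic transient: one positive and one negative half-sine lobe."""
    m = max(4, int(round(span * fs)))
    t = np.arange(m) / fs
    return amp * np.sin(2.0 * np.pi * t / span)


def _polyspike(duration: float, amp: float, fs: float) -> np.ndarray:
    """Train of >=3 biphasic spikes with inter-spike gaps <= 150 ms.

    The first and last spikes touch the burst edges so the detector's
    threshold-crossing span recovers the drawn duration.
    """
    spike_span = min(0.2, duration / 3.0)
    n_spikes = max(3, int(math.ceil((duration + 0.15) / 0.35)))
    gap = max(0.0, (duration - n_spikes * spike_span) / max(1, n_spikes - 1))
    wave = np.zeros(int(round(duration * fs)))
    spike = _biphasic(spike_span, amp, fs)
    for k in range(n_spikes):
        i0 = int(round(k * (spike_span + gap) * fs))
        i0 = max(0, min(i0, wave.size - spike.size))
        wave[i0:i0 + spike.size] += spike
    return wave


def _place_events(
    spans: np.ndarray, total: float, gap: float, rng: np.random.Generator
) -> np.ndarray:
    """Random non-overlapping start times with a minimum separation."""
    n = spans.size
    if n == 0:
        return np.empty(0)
    occupied = float(spans.sum())
    free = total - occupied - (n + 1) * gap
    if free < 0:
        gap = 0.9 * (total - occupied) / (n + 1)
        free = total - occupied - (n + 1) * gap
        if gap <= 0 or free < 0:
            raise ConfigError(
                f"event load ({occupied:.1f} s) does not fit in a "
                f"{total:.0f} s epoch"
            )
    slack = rng.dirichlet(np.ones(n + 1)) * free
    starts = gap * (np.arange(n) + 1) + np.cumsum(slack[:-1]) + np.concatenate(
        ([0.0], np.cumsum(spans[:-1]))
    )
    return starts


def simulate_lfp_trace(
    cfg: SimulationConfig,
    condition: str = "vehicle",
    suppression: float = 0.0,
    seed=0,
    interictal_count: int | None = None,
    ictal_count: int | None = None,
    subject_id: str = "sim",
) -> tuple[LFPTrace, TraceGroundTruth]:
    """Simulate one 10-min LFP epoch with known injected events.

    Vehicle event counts are drawn uniformly from the configured ranges
    (overridable via ``interictal_count``/``ictal_count``), then thinned
    binomially by ``suppression``.  Durations follow the configured normal
    laws truncated to positive values; amplitudes are the configured
    factors times the noise sigma, with random polarity.
    """
    if not 0.0 <= suppression <= 1.0:
        raise InputError("suppression must lie in [0, 1]")
    rng = _rng(seed)
    fs = cfg.lfp_sampling_rate
    n = int(round(cfg.epoch_duration * fs))

    lo, hi = cfg.vehicle_interictal_count_range
    n_inter = int(rng.integers(lo, hi + 1)) if interictal_count is None else int(interictal_count)
    lo2, hi2 = cfg.vehicle_ictal_count_range
    n_ictal = int(rng.integers(lo2, hi2 + 1)) if ictal_count is None else int(ictal_count)
    if suppression > 0.0:
        n_inter = int(rng.binomial(n_inter, 1.0 - suppression))
        n_ictal = int(rng.binomial(n_ictal, 1.0 - suppression))

    inter_dur = _truncated_normal(
        rng, n_inter, cfg.interictal_duration_mean, cfg.interictal_duration_sd, low=0.05
    )
    ictal_dur = _truncated_normal(
        rng, n_ictal, cfg.ictal_duration_mean, cfg.ictal_duration_sd, low=0.6
    )
    inter_span = inter_dur / _span_factor(cfg.interictal_amp_factor)

    spans = np.concatenate([inter_span, ictal_dur])
    classes = np.array(["interictal"] * n_inter + ["ictal"] * n_ictal)
    order = rng.permutation(spans.size)
    spans, classes = spans[order], classes[order]
    starts = _place_events(spans, cfg.epoch_duration, cfg.min_event_gap, rng)

    x = rng.standard_normal(n) * cfg.noise_sigma
    truth = TraceGroundTruth()
    amp_inter = cfg.interictal_amp_factor * cfg.noise_sigma
    amp_ictal = cfg.ictal_amp_factor * cfg.noise_sigma
    for start, span, klass in zip(starts, spans, classes):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if klass == "interictal":
            wave = sign * _biphasic(span, amp_inter, fs)
        else:
            wave = sign * _polyspike(span, amp_ictal, fs)
        i0 = int(round(start * fs))
        i1 = min(i0 + wave.size, n)
        x[i0:i1] += wave[: i1 - i0]
        truth.events.append(TrueEvent(start=i0 / fs, end=i1 / fs, event_class=str(klass)))
    truth.events.sort(key=lambda e: e.start)

    trace = LFPTrace(
        subject_id=subject_id, condition=condition, sampling_rate=fs, samples=x
    )
    return trace, truth


# --------------------------------------------------------------------------
# velocity generation
# --------------------------------------------------------------------------

def _epoch_mean_relvar(cfg: SimulationConfig) -> float:
    """Relative variance of the epoch-mean velocity of the base process.

    The burst train is compound Poisson: each burst adds a Gaussian bell of
    random peak, so Var(sum) = lambda * E[(peak * shape_sum)^2] with
    shape_sum = sqrt(2*pi)*tau*fs the per-burst sample mass.
    """
    fs = cfg.behavior_sampling_rate
    n = round(cfg.epoch_duration * fs)
    tau = cfg.burst_duration / 6.0
    shape_sum = math.sqrt(2.0 * math.pi) * tau * fs
    cv2 = cfg.burst_peak_cv ** 2
    e_peak = cfg.burst_peak_mean
    e_peak2 = e_peak ** 2 * (1.0 + cv2)
    lam = cfg.burst_rate_per_epoch * cfg.epoch_duration / 600.0
    burst_var = lam * e_peak2 * shape_sum ** 2 / n ** 2
    s2 = cfg.baseline_swim_sigma ** 2
    base_var = (cfg.baseline_swim_mean ** 2) * (math.exp(s2) - 1.0) / n
    mean = cfg.baseline_swim_mean + lam * e_peak * shape_sum / n
    return (burst_var + base_var) / mean ** 2


def _session_noise_sigma(cfg: SimulationConfig) -> tuple[float, float]:
    """Lognormal sigma of the per-well session factor G.

    Calibrated so the vehicle percent-change coefficient of variation equals
    control_pct_change_sd/100 once the sampling variability of the two
    epoch means is accounted for:  (1+vG)(1+ve)^2 = 1 + cv_target^2.
    """
    cv_t = cfg.control_pct_change_sd / 100.0
    ve = _epoch_mean_relvar(cfg)
    s2 = math.log((1.0 + cv_t ** 2) / (1.0 + ve) ** 2)
    return (math.sqrt(s2) if s2 > 0 else 0.0), ve


def _base_velocity(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Untreated-mutant velocity: lognormal swim + Poisson convulsive bursts."""
    fs = cfg.behavior_sampling_rate
    n = round(cfg.epoch_duration * fs)
    sig = cfg.baseline_swim_sigma
    mu = math.log(cfg.baseline_swim_mean) - sig ** 2 / 2.0
    v = rng.lognormal(mu, sig, n)

    # the configured rate refers to a 10-min epoch
    n_bursts = rng.poisson(cfg.burst_rate_per_epoch * cfg.epoch_duration / 600.0)
    sp = math.sqrt(math.log(1.0 + cfg.burst_peak_cv ** 2))
    mp = math.log(cfg.burst_peak_mean) - sp ** 2 / 2.0
    peaks = rng.lognormal(mp, sp, n_bursts)
    # a fish has one convulsion at a time: bursts never overlap
    starts = _place_events(
        np.full(n_bursts, cfg.burst_duration), cfg.epoch_duration, 0.2, rng
    )
    centers = starts + cfg.burst_duration / 2.0
    tau = cfg.burst_duration / 6.0
    half = int(math.ceil(4.0 * tau * fs))
    t_rel = np.arange(-half, half + 1) / fs
    bell = np.exp(-(t_rel ** 2) / (2.0 * tau ** 2))
    for c, p in zip(centers, peaks):
        ic = int(round(c * fs))
        i0, i1 = max(0, ic - half), min(n, ic + half + 1)
        v[i0:i1] += p * bell[i0 - (ic - half): i1 - (ic - half)]
    return v


def simulate_velocity_trace(
    cfg: SimulationConfig,
    state: TreatmentState,
    epoch: str,
    seed=0,
    well_id: str = "W0",
    fish_id: str = "f0",
) -> VelocityTrace:
    """Simulate one 10-min velocity epoch for one fish.

    The baseline epoch is always the untreated process.  The experimental
    epoch is the process scaled by (1 - suppression) * G, with G a
    calibrated lognormal session factor (mean 1 after bias correction), so
    per-fish percent change has mean -100*suppression and, under vehicle
    (suppression 0), s.d. ~= ``control_pct_change_sd``.  Toxic wells are
    immobile (zero velocity) in the experimental epoch.
    """
    if epoch not in ("baseline", "experimental"):
        raise InputError(f"unknown epoch {epoch!r}")
    rng = _rng(seed)
    if epoch == "experimental" and state.kind == "toxic":
        n = round(cfg.epoch_duration * cfg.behavior_sampling_rate)
        v = np.zeros(n)
    else:
        v = _base_velocity(cfg, rng)
        if epoch == "experimental":
            sg, ve = _session_noise_sigma(cfg)
            g = math.exp(rng.normal(-sg ** 2 / 2.0, sg)) / (1.0 + ve)
            v = v * (1.0 - state.suppression) * g
    return VelocityTrace(
        well_id=well_id,
        fish_id=fish_id,
        epoch=epoch,
        sampling_rate=cfg.behavior_sampling_rate,
        samples=v,
    )


def simulate_velocity_pair(
    cfg: SimulationConfig,
    state: TreatmentState,
    seed=0,
    well_id: str = "W0",
    fish_id: str = "f0",
) -> tuple[VelocityTrace, VelocityTrace]:
    """Paired (baseline, experimental) traces for one fish."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_base, s_exp = ss.spawn(2)
    base = simulate_velocity_trace(
        cfg, state, "baseline", np.random.default_rng(s_base), well_id, fish_id
    )
    exp = simulate_velocity_trace(
        cfg, state, "experimental", np.random.default_rng(s_exp), well_id, fish_id
    )
    return base, exp


# --------------------------------------------------------------------------
# whole-screen dataset
# --------------------------------------------------------------------------

_WELL_ROWS = "ABCDEFGH"


def _plate_layouts(
    compound_ids: Sequence[str], controls_per_plate: int, fish_per_group: int
) -> list[dict]:
    """Assign compounds to 96-well plates, reserving vehicle wells per plate.

    Each compound occupies ``fish_per_group`` wells; each plate carries
    ``controls_per_plate`` vehicle wells.
    """
    per_plate = max(1, (96 - controls_per_plate) // fish_per_group)
    layouts: list[dict] = []
    for p in range(0, len(compound_ids), per_plate):
        chunk = compound_ids[p: p + per_plate]
        wells = [f"{r}{c}" for r in _WELL_ROWS for c in range(1, 13)]
        assignment: dict[str, list[str]] = {}
        idx = 0
        for cid in chunk:
            assignment[cid] = wells[idx: idx + fish_per_group]
            idx += fish_per_group
        vehicle_wells = wells[idx: idx + controls_per_plate]
        layouts.append(
            {
                "plate": len(layouts),
                "compound_wells": assignment,
                "vehicle_wells": vehicle_wells,
            }
        )
    return layouts


class ScreenDataset:
    """A full synthetic screen: manifest, layouts, traces and ground truth.

    Traces are generated lazily and deterministically from the master seed,
    so a dataset object is cheap to hold and any well can be regenerated in
    isolation (``velocity_pairs``, ``vehicle_pairs``, ``lfp_traces``).
    """

    def __init__(
        self,
        cfg: SimulationConfig,
        manifest: pd.DataFrame,
        layouts: list[dict],
        truth: dict[str, CompoundTruth],
        seed: int,
    ):
        self.cfg = cfg
        self.manifest = manifest
        self.layouts = layouts
        self.truth = truth
        self.seed = int(seed)
        self._index = {cid: i for i, cid in enumerate(manifest["compound_id"])}

    @property
    def compound_ids(self) -> list[str]:
        return list(self.manifest["compound_id"])

    def _conc_key(self, concentration: float) -> int:
        return int(round(concentration * 1000))

    def state_at(self, compound_id: str, concentration: float) -> TreatmentState:
        return self.truth[compound_id].state_at(concentration)

    def velocity_pairs(
        self, compound_id: str, concentration: float
    ) -> list[tuple[VelocityTrace, VelocityTrace]]:
        """Paired traces for every fish of a compound at one concentration."""
        if compound_id not in self._index:
            raise InputError(f"unknown compound {compound_id!r}")
        idx = self._index[compound_id]
        state = self.state_at(compound_id, concentration)
        pairs = []
        for fish in range(self.cfg.fish_per_well_group):
            ss = np.random.SeedSequence(
                [self.seed, _VEL, idx, self._conc_key(concentration), fish]
            )
            pairs.append(
                simulate_velocity_pair(
                    self.cfg, state, ss,
                    well_id=f"{compound_id}:{fish}", fish_id=f"{compound_id}-f{fish}",
                )
            )
        return pairs

    def vehicle_pairs(
        self, plate: int, concentration_key: float = 0.0
    ) -> list[tuple[VelocityTrace, VelocityTrace]]:
        """Paired traces for the internal vehicle controls of one plate."""
        state = TreatmentState.treated(0.0)
        pairs = []
        for k in range(self.cfg.controls_per_plate):
            ss = np.random.SeedSequence(
                [self.seed, _VEL, 10_000_000 + plate, self._conc_key(concentration_key), k]
            )
            pairs.append(
                simulate_velocity_pair(
                    self.cfg, state, ss,
                    well_id=f"P{plate}-veh{k}", fish_id=f"P{plate}-veh{k}",
                )
            )
        return pairs

    def lfp_traces(
        self, group: str, concentration: float | None, n_subjects: int
    ) -> list[tuple[LFPTrace, TraceGroundTruth]]:
        """LFP recordings for one confirmation group.

        ``group`` is a compound id (suppression = its effect at the given
        concentration) or ``"vehicle"`` (suppression 0).
        """
        if group == "vehicle":
            suppression, idx = 0.0, -1
        else:
            if group not in self._index:
                raise InputError(f"unknown compound {group!r}")
            if concentration is None:
                raise InputError("treated LFP group needs a concentration")
            suppression = self.truth[group].effect(concentration)
            idx = self._index[group]
        out = []
        for subj in range(n_subjects):
            ss = np.random.SeedSequence([self.seed, _LFP, idx + 1, subj])
            out.append(
                simulate_lfp_trace(
                    self.cfg,
                    condition=group if group == "vehicle" else f"{group}@{concentration}",
                    suppression=suppression,
                    seed=np.random.default_rng(ss),
                    subject_id=f"{group}-s{subj}",
                )
            )
        return out


def _class_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n compounds to the truth classes."""
    raw = [n * p for p in proportions]
    base = [int(math.floor(r)) for r in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def simulate_screen(
    cfg: SimulationConfig,
    n_compounds: int,
    truth_mix: Sequence[float] = (0.25, 0.55, 0.20),
    seed: int = 0,
) -> ScreenDataset:
    """Build a ground-truthed synthetic screen of ``n_compounds`` compounds.

    ``truth_mix`` gives the (suppressor, inert, toxic) proportions and must
    sum to one.  Suppressors draw e_max ~ U[0.6, 0.95] and EC50 ~ U[0.3, 1]
    uM, giving monotone log-concentration effects that clear the behavioral
    hit threshold at both primary concentrations.
    """
    if n_compounds < 1:
        raise ConfigError("n_compounds must be >= 1")
    mix = list(truth_mix)
    if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
        raise ConfigError("truth_mix must be 3 non-negative proportions summing to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TRUTH]))
    n_sup, n_inert, n_toxic = _class_counts(n_compounds, mix)
    classes = (["suppressor"] * n_sup + ["inert"] * n_inert + ["toxic"] * n_toxic)
    rng.shuffle(classes)

    records = []
    truth: dict[str, CompoundTruth] = {}
    class_tags = ["indole", "indazole", "other"]
    for i, klass in enumerate(classes):
        cid = f"C{i:04d}"
        if klass == "suppressor":
            ct = CompoundTruth(
                compound_id=cid,
                klass=klass,
                e_max=float(rng.uniform(0.6, 0.95)),
                ec50=float(rng.uniform(0.3, 1.0)),
            )
        else:
            ct = CompoundTruth(compound_id=cid, klass=klass)
        truth[cid] = ct
        records.append(
            {
                "compound_id": cid,
                "name": f"SC-{1000 + i}",
                "class_tag": class_tags[int(rng.integers(0, len(class_tags)))],
            }
        )
    manifest = pd.DataFrame.from_records(records)
    layouts = _plate_layouts(
        list(manifest["compound_id"]), cfg.controls_per_plate, cfg.fish_per_well_group
    )
    return ScreenDataset(cfg=cfg, manifest=manifest, layouts=layouts, truth=truth, seed=seed)
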