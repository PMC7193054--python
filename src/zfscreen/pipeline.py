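"""The two-stage screening cascade and its audit-trail report.

Stages mirror the screening funnel: a dual-concentration primary
behavioral screen (250 and 10 uM), intersection of the positive sets,
concentration-response re-testing at 1/10/100 uM, and electrophysiological
confirmation (LFP event detection + one-way ANOVA with Dunnett comparisons
against vehicle).  ``run_screen`` chains the stages; ``compile_report``
assembles per-stage tables, funnel counts and the final hit rate.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .errors import InputError
from . import lfp as lfp_mod
from .locomotion import BehaviorCall, call_behavior, mean_velocity, percent_change
from .stats import StatTestResult, anova_dunnett
from .synthetic import ScreenDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageTable:
    """One primary-screen stage: per-compound calls plus vehicle summary."""

    concentration: float
    calls: pd.DataFrame        # one row per compound
    vehicle: pd.DataFrame      # one row per plate of internal controls

    @property
    def positives(self) -> list[str]:
        df = self.calls
        return sorted(df.loc[df["hit"] & ~df["toxic"], "compound_id"])

    @property
    def toxic(self) -> list[str]:
        return sorted(self.calls.loc[self.calls["toxic"], "compound_id"])


@dataclass(frozen=True)
class DoseResponsePanel:
    """Concentration-response outcome of one candidate."""

    compound_id: str
    calls: dict[float, BehaviorCall]
    toxic_concentrations: tuple[float, ...]
    concentration_dependent: bool
    incomplete: bool = False


@dataclass
class ScreenResult:
    """Full audit trail of a screen."""

    n_screened: int
    stage_tables: dict[str, pd.DataFrame]
    intersection: list[str]
    dose_panels: dict[str, DoseResponsePanel]
    confirmation_candidates: list[str]
    final_hits: list[str]
    final_hit_rate: float           # %, full precision
    final_hit_rate_display: str     # %, truncated to one decimal
    stage_rates: dict[str, float]   # % positive / % toxic per primary stage
    stat_result: StatTestResult | None
    seed: int | None = None
    config_digest: str | None = None
    funnel: dict[str, int] = field(default_factory=dict)


def truncate_rate(rate_pct: float, decimals: int = 1) -> str:
    """Truncate (not round) a percentage for display, e.g. 1.351 -> '1.3'."""
    scale = 10 ** decimals
    return f"{math.floor(rate_pct * scale + 1e-9) / scale:.{decimals}f}"


def _calls_frame(calls: list[BehaviorCall], not_tested: list[str]) -> pd.DataFrame:
    rows = [
        {
            "compound_id": c.compound_id,
            "concentration": c.concentration,
            "mean_pct_change": c.mean_pct_change,
            "stage0_or_I_fraction": c.stage0_or_I_fraction,
            "toxic": c.toxic,
            "hit": c.hit,
            "n_fish": c.n_fish,
            "n_excluded": len(c.excluded_fish),
            "tested": True,
        }
        for c in calls
    ]
    for cid in not_tested:
        rows.append(
            {
                "compound_id": cid, "concentration": float("nan"),
                "mean_pct_change": float("nan"), "stage0_or_I_fraction": float("nan"),
                "toxic": False, "hit": False, "n_fish": 0, "n_excluded": 0,
                "tested": False,
            }
        )
    return pd.DataFrame(rows).sort_values("compound_id").reset_index(drop=True)


def run_primary_stage(
    ds: ScreenDataset, concentration: float, cfg: ScreenConfig
) -> StageTable:
    """Behavioral calls for every manifest compound at one concentration.

    Compounds whose traces cannot be produced are recorded as not-tested
    with a warning.  Per-plate internal vehicle controls are summarized
    alongside (mean and s.d. of their percent changes).
    """
    calls: list[BehaviorCall] = []
    not_tested: list[str] = []
    for cid in ds.compound_ids:
        try:
            pairs = ds.velocity_pairs(cid, concentration)
            calls.append(call_behavior(cid, concentration, pairs, cfg.behavior))
        except InputError as exc:
            log.warning("compound %s not tested at %g uM: %s", cid, concentration, exc)
            not_tested.append(cid)
    veh_rows = []
    for layout in ds.layouts:
        pcts = []
        for base, exp in ds.vehicle_pairs(layout["plate"], concentration):
            vb = mean_velocity(base)
            if vb > 0:
                pcts.append(percent_change(vb, mean_velocity(exp)))
        veh_rows.append(
            {
                "plate": layout["plate"],
                "concentration": concentration,
                "n_controls": len(pcts),
                "mean_pct_change": float(np.mean(pcts)) if pcts else float("nan"),
                "sd_pct_change": float(np.std(pcts, ddof=1)) if len(pcts) > 1 else float("nan"),
            }
        )
    return StageTable(
        concentration=concentration,
        calls=_calls_frame(calls, not_tested),
        vehicle=pd.DataFrame(veh_rows),
    )


def intersect_primary(t_hi: StageTable, t_lo: StageTable) -> list[str]:
    """Compounds positive and non-toxic at both primary concentrations."""
    ids_hi = set(t_hi.calls["compound_id"])
    ids_lo = set(t_lo.calls["compound_id"])
    if ids_hi != ids_lo:
        raise InputError("primary stage tables cover different manifests")
    return sorted(set(t_hi.positives) & set(t_lo.positives))


def assess_dose_response(
    compound_id: str,
    calls_by_conc: dict[float, BehaviorCall],
    tol_pct: float = 5.0,
    expected_concentrations=None,
) -> DoseResponsePanel:
    """Flag a concentration-dependent response from per-concentration calls.

    The response is concentration dependent when, across non-toxic
    concentrations in increasing order, the mean percent change never
    increases by more than ``tol_pct`` (a noise allowance against the
    vehicle variability of the assay) and at least one concentration is a
    hit.  Toxic concentrations are annotated and skipped in the
    monotonicity check.
    """
    incomplete = False
    if expected_concentrations is not None:
        incomplete = any(c not in calls_by_conc for c in expected_concentrations)
    concs = sorted(calls_by_conc)
    toxic = tuple(c for c in concs if calls_by_conc[c].toxic)
    usable = [c for c in concs if not calls_by_conc[c].toxic]
    pct = [calls_by_conc[c].mean_pct_change for c in usable]
    monotone = all(b <= a + tol_pct for a, b in zip(pct, pct[1:]))
    any_hit = any(calls_by_conc[c].hit for c in usable)
    return DoseResponsePanel(
        compound_id=compound_id,
        calls=dict(calls_by_conc),
        toxic_concentrations=toxic,
        concentration_dependent=bool(monotone and any_hit and len(usable) >= 2),
        incomplete=incomplete,
    )


def run_dose_response(
    ds: ScreenDataset, candidates: list[str], cfg: ScreenConfig
) -> dict[str, DoseResponsePanel]:
    """Concentration-response re-test of the intersection candidates."""
    panels: dict[str, DoseResponsePanel] = {}
    for cid in candidates:
        calls: dict[float, BehaviorCall] = {}
        for conc in cfg.dose_response_concentrations:
            try:
                pairs = ds.velocity_pairs(cid, conc)
                calls[conc] = call_behavior(cid, conc, pairs, cfg.behavior)
            except InputError as exc:
                log.warning("candidate %s missing %g uM: %s", cid, conc, exc)
        panels[cid] = assess_dose_response(
            cid, calls, cfg.dose_monotonicity_tol_pct,
            expected_concentrations=cfg.dose_response_concentrations,
        )
    return panels


def confirmation_concentration(panel: DoseResponsePanel) -> float | None:
    """Highest non-toxic hit concentration of a panel (None if no hit)."""
    hits = [
        c for c, call in panel.calls.items()
        if call.hit and c not in panel.toxic_concentrations
    ]
    return max(hits) if hits else None


def _total_event_rate(
    trace: lfp_mod.LFPTrace, cfg: ScreenConfig
) -> float:
    noise = lfp_mod.estimate_noise(trace)
    events = lfp_mod.detect_events(trace, noise, cfg.detection)
    return lfp_mod.summarize_ep(events, trace.duration).total_count


def run_ep_confirmation(
    ds: ScreenDataset,
    candidates: dict[str, float],
    cfg: ScreenConfig,
    seed: int = 0,
) -> tuple[list[str], StatTestResult | None, pd.DataFrame]:
    """Electrophysiological confirmation of behavioral candidates.

    ``candidates`` maps compound id -> test concentration (uM).  Every
    subject's trace is run through noise estimation, event detection and
    per-10-min summarization; total event frequencies are compared across
    vehicle + candidate groups by ANOVA and Dunnett.  A candidate is a
    final hit when its Dunnett-adjusted p is below alpha AND its mean event
    frequency lies below the vehicle mean.
    """
    rows = []
    veh = [
        _total_event_rate(tr, cfg)
        for tr, _ in ds.lfp_traces("vehicle", None, cfg.n_vehicle_lfp_subjects)
    ]
    for rate in veh:
        rows.append({"group": "vehicle", "total_events_per_10min": rate})
    groups = [veh]
    ids = ["vehicle"]
    unconfirmable: list[str] = []
    for cid, conc in candidates.items():
        rates = [
            _total_event_rate(tr, cfg)
            for tr, _ in ds.lfp_traces(cid, conc, cfg.n_lfp_subjects)
        ]
        for rate in rates:
            rows.append({"group": cid, "total_events_per_10min": rate})
        if len(rates) < 2:
            log.warning("candidate %s unconfirmable (n=%d subjects)", cid, len(rates))
            unconfirmable.append(cid)
            continue
        groups.append(rates)
        ids.append(cid)
    table = pd.DataFrame(rows)
    if len(groups) < 2 or len(veh) < 2:
        return [], None, table
    result = anova_dunnett(
        groups, control_index=0, alpha=cfg.alpha,
        n_draws=cfg.dunnett_draws, seed=seed, ids=ids,
    )
    veh_mean = float(np.mean(veh))
    final = sorted(
        g.group_id
        for g in result.per_group
        if g.group_id != "vehicle" and g.significant and g.mean < veh_mean
    )
    return final, result, table


def compile_report(
    t_hi: StageTable,
    t_lo: StageTable,
    intersection: list[str],
    dose_panels: dict[str, DoseResponsePanel],
    confirmation_candidates: list[str],
    final_hits: list[str],
    stat_result: StatTestResult | None,
    n_screened: int,
    ep_table: pd.DataFrame | None = None,
    seed: int | None = None,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Assemble the funnel report.

    Rates are stored at full precision; the final hit rate is additionally
    rendered truncated to one decimal, the convention used when 5 confirmed
    hits of 370 screened are reported as 1.3%.
    """
    if n_screened < 1:
        raise InputError("n_screened must be >= 1")
    rate = 100.0 * len(final_hits) / n_screened

    def _pct(mask_sum: int) -> float:
        return 100.0 * mask_sum / n_screened

    stage_rates = {
        f"positive_{t.concentration:g}uM": _pct(len(t.positives))
        for t in (t_hi, t_lo)
    }
    stage_rates.update(
        {f"toxic_{t.concentration:g}uM": _pct(len(t.toxic)) for t in (t_hi, t_lo)}
    )
    dr_rows = []
    for cid, panel in dose_panels.items():
        for conc in sorted(panel.calls):
            call = panel.calls[conc]
            dr_rows.append(
                {
                    "compound_id": cid,
                    "concentration": conc,
                    "mean_pct_change": call.mean_pct_change,
                    "toxic": call.toxic,
                    "hit": call.hit,
                    "concentration_dependent": panel.concentration_dependent,
                }
            )
    dr_table = pd.DataFrame(
        dr_rows,
        columns=[
            "compound_id", "concentration", "mean_pct_change",
            "toxic", "hit", "concentration_dependent",
        ],
    )
    tables = {
        f"primary_{t_hi.concentration:g}uM": t_hi.calls,
        f"primary_{t_lo.concentration:g}uM": t_lo.calls,
        f"vehicle_{t_hi.concentration:g}uM": t_hi.vehicle,
        f"vehicle_{t_lo.concentration:g}uM": t_lo.vehicle,
        "dose_response": dr_table,
    }
    if ep_table is not None:
        tables["ep_confirmation"] = ep_table
    digest = None
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
    return ScreenResult(
        n_screened=n_screened,
        stage_tables=tables,
        intersection=sorted(intersection),
        dose_panels=dose_panels,
        confirmation_candidates=sorted(confirmation_candidates),
        final_hits=sorted(final_hits),
        final_hit_rate=rate,
        final_hit_rate_display=truncate_rate(rate),
        stage_rates=stage_rates,
        stat_result=stat_result,
        seed=seed,
        config_digest=digest,
        funnel={
            "screened": n_screened,
            f"positive_{t_hi.concentration:g}uM": len(t_hi.positives),
            f"positive_{t_lo.concentration:g}uM": len(t_lo.positives),
            "intersection": len(intersection),
            "dose_response_confirmed": len(confirmation_candidates),
            "final_hits": len(final_hits),
        },
    )


def run_screen(ds: ScreenDataset, cfg: ScreenConfig, seed: int = 0) -> ScreenResult:
    """Run the full cascade on a dataset and compile the report."""
    hi, lo = cfg.primary_concentrations
    t_hi = run_primary_stage(ds, hi, cfg)
    t_lo = run_primary_stage(ds, lo, cfg)
    intersection = intersect_primary(t_hi, t_lo)
    log.info("primary intersection: %d candidates", len(intersection))
    panels = run_dose_response(ds, intersection, cfg)
    candidates: dict[str, float] = {}
    for cid, panel in panels.items():
        if not panel.concentration_dependent:
            continue
        conc = confirmation_concentration(panel)
        if conc is not None:
            candidates[cid] = conc
    final, stat, ep_table = run_ep_confirmation(ds, candidates, cfg, seed=seed)
    return compile_report(
        t_hi, t_lo, intersection, panels, sorted(candidates), final, stat,
        n_screened=len(ds.compound_ids), ep_table=ep_table, seed=seed, config=cfg,
    )
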