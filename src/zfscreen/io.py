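"""Readers and writers for on-disk artifacts.

Formats are deliberately plain: traces as two-column CSV (time_s, value),
plate maps and ground truth as JSON, manifests as CSV, configuration as
YAML/JSON.  Units follow the assays: seconds, mm/s for velocity, mV for
LFP.  Readers validate rather than coerce; writers are deterministic given
identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ScreenConfig, SimulationConfig
from .errors import FormatError, InputError
from .lfp import EPStats, EpileptiformEvent, LFPTrace
from .locomotion import VelocityTrace
from .pipeline import ScreenResult
from .synthetic import CompoundTruth, ScreenDataset


@dataclass(frozen=True)
class CompoundRecord:
    """One manifest row.  ``compound_id`` may be a blinding code."""

    compound_id: str
    name: str
    class_tag: str | None = None
    notes: str | None = None


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def _infer_sampling_rate(time_s: np.ndarray, path: Path) -> float:
    dt = np.diff(time_s)
    if dt.size == 0:
        raise FormatError(f"{path}: trace needs at least two samples")
    ref = float(np.median(dt))
    if ref <= 0:
        bad = int(np.argmax(dt <= 0)) + 2  # 1-based data row after header
        raise FormatError(f"{path}: non-increasing time step at row {bad}")
    rel = np.abs(dt - ref) / ref
    if rel.max() > 1e-6:
        bad = int(np.argmax(rel > 1e-6)) + 2
        raise FormatError(f"{path}: non-uniform time step at row {bad}")
    # snap to 9 significant digits so rewriting reproduces the time column
    return float(f"{1.0 / ref:.9g}")


def read_trace_csv(path, kind: str, **meta) -> VelocityTrace | LFPTrace:
    """Read a two-column (time_s, value) trace CSV.

    ``kind`` is ``"velocity"`` (mm/s, must be non-negative) or ``"lfp"``
    (mV).  The sampling rate is inferred from the time column, which must
    be uniform to within 1e-6 relative tolerance.
    """
    path = Path(path)
    if kind not in ("velocity", "lfp"):
        raise InputError(f"unknown trace kind {kind!r}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns, got {df.shape[1]}")
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s'")
    try:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric values: {exc}") from exc
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise FormatError(f"{path}: non-finite values in trace")
    fs = _infer_sampling_rate(t, path)
    if kind == "velocity":
        if v.size and v.min() < 0:
            bad = int(np.argmax(v < 0)) + 2
            raise FormatError(f"{path}: negative velocity at row {bad}")
        return VelocityTrace(
            well_id=meta.get("well_id", path.stem),
            fish_id=meta.get("fish_id", path.stem),
            epoch=meta.get("epoch", "experimental"),
            sampling_rate=fs,
            samples=v,
        )
    return LFPTrace(
        subject_id=meta.get("subject_id", path.stem),
        condition=meta.get("condition", "unknown"),
        sampling_rate=fs,
        samples=v,
    )


def write_trace_csv(trace: VelocityTrace | LFPTrace, path) -> Path:
    """Write a trace as (time_s, value) CSV; deterministic formatting."""
    path = Path(path)
    n = trace.samples.size
    t = np.arange(n) / trace.sampling_rate
    pd.DataFrame({"time_s": t, "value": trace.samples}).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# manifest / plate map / config
# --------------------------------------------------------------------------

def read_manifest(path) -> list[CompoundRecord]:
    """Read a compound manifest CSV (compound_id, name[, class_tag, notes])."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in ("compound_id", "name"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df["compound_id"][df["compound_id"].duplicated()]
    if not dup.empty:
        raise FormatError(
            f"{path}: duplicate compound_id(s): {sorted(dup.unique())}"
        )
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            CompoundRecord(
                compound_id=d["compound_id"],
                name=d["name"],
                class_tag=d.get("class_tag"),
                notes=d.get("notes"),
            )
        )
    return records


def read_platemap(
    path,
    manifest: list[CompoundRecord] | None = None,
    controls_per_plate: int = 6,
    strict: bool = False,
) -> list[dict]:
    """Read plate layouts (JSON) and cross-validate against a manifest.

    Unknown compounds are an error listing the offenders; a plate with
    fewer vehicle wells than expected warns (errors in strict mode).
    """
    path = Path(path)
    try:
        layouts = json.loads(path.read_text())
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not isinstance(layouts, list):
        raise FormatError(f"{path}: plate map must be a JSON list of plates")
    known = {r.compound_id for r in manifest} if manifest is not None else None
    for plate in layouts:
        for key in ("plate", "compound_wells", "vehicle_wells"):
            if key not in plate:
                raise FormatError(f"{path}: plate entry missing key {key!r}")
        if known is not None:
            offenders = sorted(set(plate["compound_wells"]) - known)
            if offenders:
                raise FormatError(
                    f"{path}: plate {plate['plate']} references unknown "
                    f"compounds: {offenders}"
                )
        if len(plate["vehicle_wells"]) < controls_per_plate:
            msg = (
                f"{path}: plate {plate['plate']} has "
                f"{len(plate['vehicle_wells'])} vehicle wells, expected "
                f"{controls_per_plate}"
            )
            if strict:
                raise FormatError(msg)
            warnings.warn(msg, stacklevel=2)
    return layouts


def read_config(path) -> ScreenConfig:
    """Read and validate a screen configuration from YAML or JSON."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return ScreenConfig.from_dict(data)


# --------------------------------------------------------------------------
# events / stats
# --------------------------------------------------------------------------

def write_events_csv(events: list[EpileptiformEvent], subject_id: str, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "subject_id": subject_id,
                "start_s": ev.start,
                "end_s": ev.end,
                "peak_mV": ev.peak_amplitude,
                "n_spikes": ev.n_spikes,
                "class": ev.event_class,
            }
            for ev in events
        ],
        columns=["subject_id", "start_s", "end_s", "peak_mV", "n_spikes", "class"],
    ).to_csv(path, index=False)
    return path


def write_ep_stats_json(stats: EPStats, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(stats), indent=2, sort_keys=True))
    return path


# --------------------------------------------------------------------------
# screen results
# --------------------------------------------------------------------------

def result_to_dict(result: ScreenResult) -> dict:
    """Machine-readable, full-precision view of a ScreenResult."""
    d = {
        "n_screened": result.n_screened,
        "intersection": result.intersection,
        "confirmation_candidates": result.confirmation_candidates,
        "final_hits": result.final_hits,
        "final_hit_rate": result.final_hit_rate,
        "final_hit_rate_display": result.final_hit_rate_display,
        "stage_rates": result.stage_rates,
        "funnel": result.funnel,
        "seed": result.seed,
        "config_digest": result.config_digest,
        "tables": {
            name: df.to_dict(orient="list") for name, df in result.stage_tables.items()
        },
        "dose_panels": {
            cid: {
                "concentration_dependent": p.concentration_dependent,
                "toxic_concentrations": list(p.toxic_concentrations),
                "incomplete": p.incomplete,
            }
            for cid, p in result.dose_panels.items()
        },
    }
    if result.stat_result is not None:
        sr = result.stat_result
        d["stats"] = {
            "F": sr.F,
            "df_between": sr.df_between,
            "df_within": sr.df_within,
            "p_value": sr.p_value,
            "per_group": [dataclasses.asdict(g) for g in sr.per_group],
        }
    return d


def write_result(result: ScreenResult, outdir, formats=("json", "csv")) -> list[Path]:
    """Write a ScreenResult as JSON (full precision) and per-stage CSVs."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create {outdir}: {exc}") from exc
    written: list[Path] = []
    if "json" in formats:
        p = outdir / "screen_result.json"
        p.write_text(json.dumps(result_to_dict(result), indent=2, sort_keys=True))
        written.append(p)
    if "csv" in formats:
        for name, df in result.stage_tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
    return written


def read_result(path) -> dict:
    """Read back a screen-result JSON as a plain dict."""
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def apply_decode_map(df: pd.DataFrame, decode_csv, column: str = "compound_id") -> pd.DataFrame:
    """Replace blinded compound codes with decoded identities at report time."""
    mapping = pd.read_csv(decode_csv, dtype=str)
    for col in ("coded_id", "decoded_id"):
        if col not in mapping.columns:
            raise FormatError(f"{decode_csv}: missing column {col!r}")
    lut = dict(zip(mapping["coded_id"], mapping["decoded_id"]))
    out = df.copy()
    out[column] = out[column].map(lambda c: lut.get(c, c))
    return out


# --------------------------------------------------------------------------
# dataset spec (simulate CLI round trip)
# --------------------------------------------------------------------------

def write_dataset(ds: ScreenDataset, outdir) -> Path:
    """Persist a synthetic dataset spec: config, seed, manifest, layouts, truth.

    Traces are not materialized (a full screen is hundreds of MB of text);
    they regenerate deterministically from the seed via ``load_dataset``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.manifest.to_csv(outdir / "manifest.csv", index=False)
    (outdir / "platemap.json").write_text(json.dumps(ds.layouts, indent=2))
    truth = {
        cid: {"class": t.klass, "e_max": t.e_max, "ec50": t.ec50}
        for cid, t in ds.truth.items()
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    spec = {"seed": ds.seed, "sim_config": ds.cfg.to_dict()}
    p = outdir / "dataset.json"
    p.write_text(json.dumps(spec, indent=2, sort_keys=True))
    return p


def load_dataset(outdir) -> ScreenDataset:
    """Rebuild a ScreenDataset from a directory written by ``write_dataset``."""
    outdir = Path(outdir)
    try:
        spec = json.loads((outdir / "dataset.json").read_text())
        layouts = json.loads((outdir / "platemap.json").read_text())
        truth_raw = json.loads((outdir / "ground_truth.json").read_text())
        manifest = pd.read_csv(outdir / "manifest.csv", dtype=str)
    except Exception as exc:
        raise FormatError(f"{outdir}: {exc}") from exc
    cfg = SimulationConfig.from_dict(spec["sim_config"])
    truth = {
        cid: CompoundTruth(
            compound_id=cid, klass=d["class"], e_max=d["e_max"], ec50=d["ec50"]
        )
        for cid, d in truth_raw.items()
    }
    return ScreenDataset(
        cfg=cfg, manifest=manifest, layouts=layouts, truth=truth, seed=spec["seed"]
    )


def save_pct_change_heatmap(dr_table: pd.DataFrame, path) -> Path:
    """Heat-map-style figure of percent change by compound x concentration."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = dr_table.pivot_table(
        index="compound_id", columns="concentration", values="mean_pct_change"
    )
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(pivot))))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdBu", vmin=-100, vmax=100)
    ax.set_xticks(range(pivot.shape[1]), [f"{c:g}" for c in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_xlabel("concentration (uM)")
    fig.colorbar(im, ax=ax, label="% change in mean velocity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
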