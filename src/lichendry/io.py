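"""Delimited-text readers and writers for instrument logs and results.

Schemas (UTF-8 CSV, decimal point, header required):

* isotherm points: ``sample_id, species, time_min, psi_MPa, fw_mg, f0, fm``
  (``f0``/``fm`` may be empty), one row per measurement in drying order;
* dry weights: ``sample_id, dw_mg``;
* acoustic hits: ``channel, time_s, amplitude_dB, energy_aJ`` where the
  channel is the monitored sample's id, mirroring common AE-system exports;
* acoustic sample metadata: ``sample_id, species, vitality, gel_mass_mg,
  fw_with_gel_mg, fw_without_gel_mg``;
* drying checkpoints: ``sample_id, time_min, fw_mg``.

JSON reports are deterministic (sorted keys) and versioned.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustic_events import AEHit, AETrace, DryingSeries, UAETrajectory
from .errors import InvalidInputError, PairingError
from .water_relations import IsothermPoint, IsothermRecord, WaterRelationParams

REPORT_SCHEMA_VERSION = "1.0"

ISO_COLUMNS = ["sample_id", "species", "time_min", "psi_MPa", "fw_mg", "f0", "fm"]
DW_COLUMNS = ["sample_id", "dw_mg"]
HIT_COLUMNS = ["channel", "time_s", "amplitude_dB", "energy_aJ"]
AE_SAMPLE_COLUMNS = [
    "sample_id",
    "species",
    "vitality",
    "gel_mass_mg",
    "fw_with_gel_mg",
    "fw_without_gel_mg",
]
DRYING_COLUMNS = ["sample_id", "time_min", "fw_mg"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required column(s) {missing}")


def _read_dw_table(dw_path) -> dict[str, float]:
    df = pd.read_csv(dw_path)
    _require_columns(df, DW_COLUMNS, dw_path)
    return {str(r.sample_id): float(r.dw_mg) for r in df.itertuples()}


# --------------------------------------------------------------------------
# isotherm logs


def write_isotherm_csv(records: list[IsothermRecord], points_path, dw_path) -> None:
    rows = []
    for rec in records:
        for p in rec.points:
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "species": rec.species,
                    "time_min": p.time,
                    "psi_MPa": p.psi,
                    "fw_mg": p.fw,
                    "f0": p.f0,
                    "fm": p.fm,
                }
            )
    pd.DataFrame(rows, columns=ISO_COLUMNS).to_csv(points_path, index=False)
    pd.DataFrame(
        [{"sample_id": r.sample_id, "dw_mg": r.dw} for r in records], columns=DW_COLUMNS
    ).to_csv(dw_path, index=False)


def read_isotherm_records(points_path, dw_path) -> list[IsothermRecord]:
    df = pd.read_csv(points_path)
    _require_columns(df, ISO_COLUMNS, points_path)
    dw = _read_dw_table(dw_path)
    if df.empty:
        raise InvalidInputError(f"{points_path}: no measurements")
    records = []
    for sid, grp in df.groupby("sample_id", sort=False):
        sid = str(sid)
        if sid not in dw:
            raise PairingError(f"sample {sid!r} has no dry weight in {dw_path}")
        points = tuple(
            IsothermPoint(
                time=float(r.time_min),
                psi=float(r.psi_MPa),
                fw=float(r.fw_mg),
                f0=None if pd.isna(r.f0) else float(r.f0),
                fm=None if pd.isna(r.fm) else float(r.fm),
            )
            for r in grp.itertuples()
        )
        records.append(
            IsothermRecord(
                sample_id=sid, species=str(grp.species.iloc[0]), points=points, dw=dw[sid]
            )
        )
    return records


def write_params_csv(params: dict[str, WaterRelationParams], path) -> None:
    """One row per sample of derived water-relation parameters."""
    rows = []
    for sid, p in params.items():
        rows.append(
            {
                "sample_id": sid,
                "ifw_mg": p.ifw,
                "wl_tlp_mg": p.wl_tlp,
                "fw_tlp_mg": p.fw_tlp,
                "psi_tlp_MPa": p.psi_tlp,
                "rwc_tlp_pct": p.rwc_tlp,
                "exp_a_MPa": p.exp_fit.a,
                "exp_b_per_mg": p.exp_fit.b,
                "exp_adj_r2": p.exp_fit.adj_r2,
                "inv_slope_per_MPa_mg": p.osmotic_line.slope,
                "inv_intercept_per_MPa": p.osmotic_line.intercept,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# acoustic logs


def write_ae_csv(traces: list[AETrace], hits_path, samples_path) -> None:
    rows = [
        {
            "channel": tr.sample_id,
            "time_s": h.time,
            "amplitude_dB": h.amplitude,
            "energy_aJ": h.energy,
        }
        for tr in traces
        for h in tr.hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(hits_path, index=False)
    pd.DataFrame(
        [
            {
                "sample_id": tr.sample_id,
                "species": tr.species,
                "vitality": tr.vitality,
                "gel_mass_mg": tr.gel_mass,
                "fw_with_gel_mg": tr.fw_with_gel,
                "fw_without_gel_mg": tr.fw_without_gel,
            }
            for tr in traces
        ],
        columns=AE_SAMPLE_COLUMNS,
    ).to_csv(samples_path, index=False)


def read_ae_traces(hits_path, samples_path) -> list[AETrace]:
    hits = pd.read_csv(hits_path)
    _require_columns(hits, HIT_COLUMNS, hits_path)
    meta = pd.read_csv(samples_path)
    _require_columns(meta, AE_SAMPLE_COLUMNS, samples_path)
    traces = []
    by_channel = dict(tuple(hits.groupby("channel", sort=False)))
    for r in meta.itertuples():
        sid = str(r.sample_id)
        grp = by_channel.get(sid)
        if grp is None:
            hit_tuple: tuple[AEHit, ...] = ()
        else:
            grp = grp.sort_values("time_s")
            hit_tuple = tuple(
                AEHit(time=float(h.time_s), amplitude=float(h.amplitude_dB), energy=float(h.energy_aJ))
                for h in grp.itertuples()
            )
        traces.append(
            AETrace(
                sample_id=sid,
                species=str(r.species),
                vitality=str(r.vitality),
                hits=hit_tuple,
                gel_mass=None if pd.isna(r.gel_mass_mg) else float(r.gel_mass_mg),
                fw_with_gel=None if pd.isna(r.fw_with_gel_mg) else float(r.fw_with_gel_mg),
                fw_without_gel=None if pd.isna(r.fw_without_gel_mg) else float(r.fw_without_gel_mg),
            )
        )
    return traces


def write_drying_csv(series: list[DryingSeries], drying_path, dw_path) -> None:
    rows = [
        {"sample_id": s.sample_id, "time_min": t, "fw_mg": fw}
        for s in series
        for t, fw in s.checkpoints
    ]
    pd.DataFrame(rows, columns=DRYING_COLUMNS).to_csv(drying_path, index=False)
    pd.DataFrame(
        [{"sample_id": s.sample_id, "dw_mg": s.dw} for s in series], columns=DW_COLUMNS
    ).to_csv(dw_path, index=False)


def read_drying_series(drying_path, dw_path) -> dict[str, DryingSeries]:
    df = pd.read_csv(drying_path)
    _require_columns(df, DRYING_COLUMNS, drying_path)
    dw = _read_dw_table(dw_path)
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        sid = str(sid)
        if sid not in dw:
            raise PairingError(f"sample {sid!r} has no dry weight in {dw_path}")
        grp = grp.sort_values("time_min")
        out[sid] = DryingSeries(
            sample_id=sid,
            checkpoints=tuple((float(r.time_min), float(r.fw_mg)) for r in grp.itertuples()),
            dw=dw[sid],
        )
    return out


def write_trajectories_csv(trajectories: list[UAETrajectory], path) -> None:
    rows = []
    for tr in trajectories:
        for i in range(len(tr.time_min)):
            rows.append(
                {
                    "sample_id": tr.sample_id,
                    "time_min": tr.time_min[i],
                    "rwc_pct": tr.rwc[i],
                    "cum_uae": tr.cum_uae[i],
                    "rc_uae_pct": tr.rc_uae[i],
                    "glassy_band": bool(tr.glassy[i]) if tr.glassy is not None else None,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# JSON reports


class _ReportEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_report(path, payload: dict) -> None:
    """Write a versioned, deterministic (sorted-key) JSON report."""
    body = {"schema_version": REPORT_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True, cls=_ReportEncoder) + "\n")
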