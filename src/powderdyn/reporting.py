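"""Summary artifacts: residue profiles, hydropathy-class statistics, reports.

Terminal residues are excluded from hydropathy-class statistics: their large
fluctuations come from being bonded to a single neighbour, not from their
hydropathy.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, is_dataclass
from pathlib import Path
from typing import Mapping

import math

import numpy as np
import pandas as pd

from .core_model import HydropathyTable, MSFResult, TemperatureSeries, classify_residue

REPORT_SCHEMA_VERSION = 1

_PROFILE_COLUMNS = ["residue_index", "residue_name", "hydropathy_class",
                    "temperature", "msf", "se"]


def residue_profile_table(msf_results: Mapping[float, MSFResult],
                          hydropathy: HydropathyTable | None = None,
                          sequence: str = "") -> pd.DataFrame:
    """Long-format per-residue MSF table across temperatures.

    ``msf_results`` maps temperature (K) to an :class:`MSFResult`; residue
    values are averaged over protein units.  Rows are sorted by residue then
    temperature.  Residues missing at some temperature are omitted with a
    warning.
    """
    if hydropathy is None:
        hydropathy = HydropathyTable.eisenberg()
    rows = []
    all_residues = sorted({r for res in msf_results.values()
                           for (_, r) in res.per_residue.index})
    for t in sorted(msf_results):
        res = msf_results[t]
        by_res = res.per_residue.groupby(level="residue").mean()
        se = None
        if res.block_se is not None:
            se = res.block_se["per_residue"].groupby(level="residue").mean()
        for r in all_residues:
            if r not in by_res.index:
                warnings.warn(f"residue {r} missing at T = {t} K; row omitted")
                continue
            code = sequence[r - 1] if sequence else "?"
            rows.append({
                "residue_index": r, "residue_name": code,
                "hydropathy_class": classify_residue(code, hydropathy) if sequence else "",
                "temperature": float(t), "msf": float(by_res[r]),
                "se": float(se[r]) if se is not None else float("nan")})
    df = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    return df.sort_values(["residue_index", "temperature"]).reset_index(drop=True)


def profile_from_series(series_map: Mapping[int, TemperatureSeries],
                        hydropathy: HydropathyTable | None = None,
                        sequence: str = "") -> pd.DataFrame:
    """Same long-format profile, built from per-residue temperature series."""
    if hydropathy is None:
        hydropathy = HydropathyTable.eisenberg()
    rows = []
    for r in sorted(series_map):
        s = series_map[r]
        code = sequence[r - 1] if sequence else "?"
        cls = classify_residue(code, hydropathy) if sequence else ""
        err = s.errors if s.errors is not None else np.full(len(s), np.nan)
        for t, v, e in zip(s.temperatures, s.values, err):
            rows.append({"residue_index": r, "residue_name": code,
                         "hydropathy_class": cls, "temperature": float(t),
                         "msf": float(v), "se": float(e)})
    df = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    return df.sort_values(["residue_index", "temperature"]).reset_index(drop=True)


@dataclass
class EnhancementResult:
    """Hydrophilic-to-hydrophobic ratio of class-mean MSF growth."""
    ratio: float
    status: str               # "ok" | "undefined" | "infinite"
    hydrophilic_growth: float
    hydrophobic_growth: float


def enhancement_ratio(profile: pd.DataFrame, t_ref: float, t_hot: float) -> EnhancementResult:
    """Ratio of class-mean MSF growth between two temperatures.

    Growth is MSF(t_hot) − MSF(t_ref) per residue, averaged within the
    hydrophilic and hydrophobic classes (termini excluded); the ratio is
    hydrophilic over hydrophobic.  Degenerate cases are flagged rather than
    raised: identical temperatures give ``"undefined"``, zero hydrophobic
    growth gives ``"infinite"``.
    """
    for t in (t_ref, t_hot):
        if not (profile["temperature"] == t).any():
            raise ValueError(f"temperature {t} K not present in profile")
    if t_hot == t_ref:
        return EnhancementResult(float("nan"), "undefined", float("nan"), float("nan"))
    lo, hi = profile["residue_index"].min(), profile["residue_index"].max()
    core = profile[(profile["residue_index"] != lo) & (profile["residue_index"] != hi)]
    ref = core[core["temperature"] == t_ref].set_index("residue_index")
    hot = core[core["temperature"] == t_hot].set_index("residue_index")
    growth = (hot["msf"] - ref["msf"]).dropna()
    cls = ref["hydropathy_class"]
    g_philic = float(growth[cls == "hydrophilic"].mean())
    g_phobic = float(growth[cls == "hydrophobic"].mean())
    if g_phobic == 0:
        return EnhancementResult(float("inf"), "infinite", g_philic, g_phobic)
    return EnhancementResult(g_philic / g_phobic, "ok", g_philic, g_phobic)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not math.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def full_report(out_dir: str | Path, *, tlow_fit=None, td_enthalpy=None,
                td_msf=None, residue_reports=None, profile: pd.DataFrame | None = None,
                metadata: Mapping | None = None) -> Path:
    """Write a machine-readable analysis bundle (JSON summary + CSV tables).

    The JSON is schema-versioned, key-sorted, and timestamp-free, so a rerun
    with identical inputs reproduces it byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "t_low": _jsonable(tlow_fit),
        "t_d_enthalpy": _jsonable(td_enthalpy),
        "t_d_msf": _jsonable(td_msf),
        "residue_transitions": _jsonable(residue_reports),
        "metadata": _jsonable(dict(metadata) if metadata else {}),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if profile is not None:
        profile.to_csv(out_dir / "residue_profile.csv", index=False,
                       float_format="%.6g")
    return report_path
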