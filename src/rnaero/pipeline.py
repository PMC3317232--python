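"""End-to-end orchestration: read instrument CSVs, align streams, derive
metrics, summarize quiescent windows and event windows, and compare the
measured unattached fraction against the classical inverse-concentration
predictor."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import progeny_metrics as pm
from . import size_distribution as sd
from .nuclide_chain import InvalidInputError

__all__ = [
    "RunConfig",
    "AlignmentError",
    "read_eqf_csv",
    "derive_metric_series",
    "smps_summary_series",
    "summary_table",
    "segment_events",
    "analyze",
]

EQF_COLUMNS = ["C_Rn", "C_Po218_un", "C_Pb214_un", "C_Bi214_un",
               "C_Po218_att", "C_Pb214_att", "C_Bi214_att"]

#: the nine canonical indoor summary parameters
SUMMARY_PARAMETERS = ["C_tot", "d_GM", "x_lt10", "x_lt20",
                      "C_Rn", "EEC", "F", "f_un", "x_un"]


class AlignmentError(RuntimeError):
    """No overlapping time coverage between the input streams."""


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    smps_path: Optional[str] = None
    eqf_path: Optional[str] = None
    outdir: str = "rnaero_out"
    cuts: tuple[float, ...] = (10.0, 20.0)
    screen_cutoff_nm: float = 5.0
    bi214_coefficient: float = pm.E_ALPHA_COEFFS[2]
    align_bin: str = "2h"
    quiescent_windows: tuple[tuple[str, str], ...] = ()
    event_annotations: tuple[tuple[str, str, str], ...] = ()  # (label, start, end)

    def __post_init__(self) -> None:
        if list(self.cuts) != sorted(set(self.cuts)):
            raise InvalidInputError("cuts must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("smps_path", "eqf_path", "outdir", "align_bin",
                    "screen_cutoff_nm", "bi214_coefficient"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cuts" in raw:
            kwargs["cuts"] = tuple(float(c) for c in raw["cuts"])
        if "quiescent_windows" in raw:
            kwargs["quiescent_windows"] = tuple(
                (str(a), str(b)) for a, b in raw["quiescent_windows"])
        if "event_annotations" in raw:
            kwargs["event_annotations"] = tuple(
                (str(l), str(a), str(b)) for l, a, b in raw["event_annotations"])
        return cls(**kwargs)


def read_eqf_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, parse_dates=True)
    missing = [c for c in EQF_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"EQF CSV missing columns: {missing}")
    return df[EQF_COLUMNS]


def derive_metric_series(eqf: pd.DataFrame, *,
                         bi214_coefficient: float = pm.E_ALPHA_COEFFS[2],
                         record_hours: float = 2.0) -> pd.DataFrame:
    """Per-record derived metrics plus cumulative exposure.

    Records whose progeny activities are all zero yield NaN metrics and are
    counted, not silently zeroed.
    """
    rows = []
    for ts, row in eqf.iterrows():
        rec = pm.ProgenyRecord(
            timestamp=ts, c_rn=row["C_Rn"],
            c_po218_un=row["C_Po218_un"], c_pb214_un=row["C_Pb214_un"],
            c_bi214_un=row["C_Bi214_un"], c_po218_att=row["C_Po218_att"],
            c_pb214_att=row["C_Pb214_att"], c_bi214_att=row["C_Bi214_att"],
        )
        tot = rec.totals
        eec_tot = pm.eec(*tot)
        try:
            f_un, x_un = pm.unattached_fractions(rec)
            dcf = pm.dose_conversion_empirical(min(f_un, 1.0))
        except pm.UndefinedMetricError:
            f_un = x_un = dcf = np.nan
        rows.append({
            "EEC": eec_tot,
            "EEC_un": pm.eec(rec.c_po218_un, rec.c_pb214_un, rec.c_bi214_un),
            "F": eec_tot / rec.c_rn if rec.c_rn > 0 else np.nan,
            "f_un": f_un, "x_un": x_un,
            "E_alpha": pm.potential_alpha_energy(
                *tot, bi214_coefficient=bi214_coefficient),
            "D_CF": dcf,
        })
    out = pd.DataFrame(rows, index=eqf.index)
    e = out["E_alpha"].fillna(0.0).to_numpy()
    out["WLM_cum"] = np.cumsum(e * record_hours) / (
        pm.WLM_REFERENCE_HOURS * pm.WLM_REFERENCE_MEV_M3)
    return out


def smps_summary_series(grid: sd.SizeGrid, smps: pd.DataFrame,
                        cuts: Sequence[float] = (10.0, 20.0)) -> pd.DataFrame:
    """C_tot, d_GM and sub-cut fractions for every spectrum record."""
    rows, index = [], []
    for ts, row in smps.iterrows():
        dist = sd.SizeDistribution(timestamp=ts, grid=grid,
                                   n=row.to_numpy(dtype=float))
        try:
            s = sd.summarize(dist, cuts=cuts)
        except sd.UndefinedSummaryError:
            continue
        entry = {"C_tot": s.c_tot, "d_GM": s.d_gm}
        for c in cuts:
            entry[f"x_lt{int(c)}"] = s.x_below[float(c)]
        rows.append(entry)
        index.append(ts)
    return pd.DataFrame(rows, index=pd.DatetimeIndex(index, name="timestamp"))


def qc_report(frame: pd.DataFrame, expected_cadence: Optional[pd.Timedelta] = None) -> dict:
    """Gap and sign report: every record is used or accounted for here."""
    idx = frame.index
    if expected_cadence is None and len(idx) > 1:
        expected_cadence = pd.Series(idx).diff().median()
    gaps = []
    if expected_cadence is not None and len(idx) > 1:
        deltas = pd.Series(idx).diff().iloc[1:]
        for pos, delta in deltas.items():
            if delta > 1.5 * expected_cadence:
                gaps.append({"after": str(idx[pos - 1]), "gap": str(delta)})
    vals = frame.select_dtypes(include=[np.number])
    return {
        "n_records": int(len(frame)),
        "cadence": str(expected_cadence),
        "gaps": gaps,
        "n_negative_values": int((vals < 0).to_numpy().sum()),
        "n_zero_records": int((vals.sum(axis=1) == 0).sum()),
    }


def _window_slice(frame: pd.DataFrame, start, end) -> pd.DataFrame:
    # half-open [start, end)
    return frame[(frame.index >= pd.Timestamp(start)) & (frame.index < pd.Timestamp(end))]


def summary_table(metrics: pd.DataFrame,
                  windows: Sequence[tuple[str, str]] = ()) -> pd.DataFrame:
    """Min/max/GM/GSD rows per column, restricted to the given windows.

    With no windows the whole series is summarized. Layout mirrors the
    standard campaign tables: one row per parameter.
    """
    if windows:
        parts = [_window_slice(metrics, a, b) for a, b in windows]
        data = pd.concat(parts) if parts else metrics
    else:
        data = metrics
    rows = []
    for col in data.columns:
        series = data[col].dropna()
        try:
            st = sd.gm_gsd(series)
        except InvalidInputError:
            continue
        rows.append({"parameter": col, "min": st.minimum, "max": st.maximum,
                     "GM": st.gm, "GSD": st.gsd, "n": st.n_used,
                     "n_dropped": st.n_dropped})
    return pd.DataFrame(rows).set_index("parameter")


def segment_events(series: pd.DataFrame,
                   annotations: Sequence[tuple[str, str, str]],
                   pad: pd.Timedelta = pd.Timedelta(hours=2)) -> pd.DataFrame:
    """Before/during/after GMs of every metric around each annotated event.

    ``annotations`` are (label, start, end) with ISO timestamps. Windows:
    before = [start − pad, start), during = [start, end), after =
    [end, end + pad). Annotations outside the series span are skipped.
    """
    import warnings

    rows = []
    lo, hi = series.index.min(), series.index.max()
    for label, start, end in annotations:
        t1, t2 = pd.Timestamp(start), pd.Timestamp(end)
        if t2 < lo or t1 > hi:
            warnings.warn(f"annotation {label!r} outside data coverage; skipped",
                          stacklevel=2)
            continue
        for phase, (a, b) in {
            "before": (t1 - pad, t1), "during": (t1, t2), "after": (t2, t2 + pad),
        }.items():
            window = _window_slice(series, a, b)
            for col in series.columns:
                vals = window[col].dropna()
                vals = vals[vals > 0]
                gm = float(np.exp(np.log(vals).mean())) if len(vals) else np.nan
                rows.append({"event": label, "phase": phase, "parameter": col,
                             "GM": gm, "n": int(len(vals))})
    return pd.DataFrame(rows, columns=["event", "phase", "parameter", "GM", "n"])


def analyze(cfg: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``cfg.outdir``.

    Returns the report dictionary (paths plus QC), also saved as
    ``report.json``. Raises :class:`AlignmentError` when the configured
    streams share no time coverage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"outputs": {}, "qc": {}}

    smps_sum = eqf_metrics = None
    grid = None

    if cfg.smps_path:
        grid, smps = sd.read_smps_csv(cfg.smps_path)
        report["qc"]["smps"] = qc_report(smps)
        smps_sum = smps_summary_series(grid, smps, cuts=cfg.cuts)
        smps_sum.to_csv(out / "smps_summary.csv", float_format="%.8g")
        report["outputs"]["smps_summary"] = "smps_summary.csv"

    if cfg.eqf_path:
        eqf = read_eqf_csv(cfg.eqf_path)
        report["qc"]["eqf"] = qc_report(eqf)
        eqf_metrics = derive_metric_series(
            eqf, bi214_coefficient=cfg.bi214_coefficient)
        eqf_metrics.insert(0, "C_Rn", eqf["C_Rn"])
        eqf_metrics.to_csv(out / "progeny_metrics.csv", float_format="%.8g")
        report["outputs"]["progeny_metrics"] = "progeny_metrics.csv"

    if smps_sum is None and eqf_metrics is None:
        raise AlignmentError("no input stream configured")

    # joint table on the coarse (progeny) grid
    if smps_sum is not None and eqf_metrics is not None:
        coarse = smps_sum.resample(cfg.align_bin, label="left").mean()
        joint = coarse.join(eqf_metrics, how="inner")
        if joint.empty:
            raise AlignmentError("streams share no overlapping time coverage")
        # measured f_un vs the inverse-concentration predictor
        pred = joint["C_tot"].map(
            lambda c: pm.predicted_fun(c) if c > 0 else np.nan)
        joint["f_un_predicted"] = pred
        joint["f_un_residual"] = joint["f_un"] - pred
        joint.to_csv(out / "joint_metrics.csv", float_format="%.8g")
        report["outputs"]["joint_metrics"] = "joint_metrics.csv"
        table_source = joint
    else:
        table_source = smps_sum if smps_sum is not None else eqf_metrics

    cols = [c for c in SUMMARY_PARAMETERS if c in table_source.columns]
    table = summary_table(table_source[cols], windows=cfg.quiescent_windows)
    table.to_csv(out / "summary_table.csv", float_format="%.6g")
    report["outputs"]["summary_table"] = "summary_table.csv"

    if cfg.event_annotations:
        seg = segment_events(table_source, cfg.event_annotations)
        seg.to_csv(out / "event_windows.csv", index=False, float_format="%.6g")
        report["outputs"]["event_windows"] = "event_windows.csv"

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
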