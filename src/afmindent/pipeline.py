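"""Orchestration over a manifest: calibration -> indentation -> relaxation.

Runs the per-curve analyses over every file listed in a manifest CSV,
collects per-curve result tables, aggregates medians and ranges per cell and
participant, and writes machine-readable reports (CSV) plus histogram /
flow-curve figures.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from afmindent import core_io
from afmindent.calibration import TipProfile, calibrate_tip
from afmindent.config import CalibrationConfig
from afmindent.elastoplastic import analyze_unloading
from afmindent.exceptions import AfmIndentError
from afmindent.viscoplastic import analyze_relaxation, plastic_strain_rate, stress_series

__all__ = [
    "PipelineResult",
    "SummaryStats",
    "calibrate_from_manifest",
    "run_pipeline",
    "aggregate",
    "report",
]

INDENT_METRICS = ["E", "H", "sigma_y_static", "h_max", "h_c", "h_f", "s0"]
RELAX_METRICS = ["tau1", "tau2", "h0", "h_inf"]
HB_METRICS = ["sigma_y", "k", "j"]


@dataclass
class SummaryStats:
    """Median and range of one metric at one aggregation level."""

    level: str
    group: str
    metric: str
    median: float
    min: float
    max: float
    n: int


@dataclass
class PipelineResult:
    """Bundle of per-curve tables and rejection accounting."""

    indent: pd.DataFrame
    relax: pd.DataFrame
    hb: pd.DataFrame
    rejections: pd.DataFrame
    n_curves: int
    config: CalibrationConfig
    tip: TipProfile

    @property
    def n_rejected(self) -> int:
        return self.rejections["curve_id"].nunique() if len(self.rejections) else 0


def calibrate_from_manifest(
    manifest_path: str | Path, config: CalibrationConfig | None = None
) -> TipProfile:
    """Tip calibration from a manifest of reference-material curves."""
    config = config or CalibrationConfig()
    curves = core_io.read_force_curves(manifest_path)
    indents = []
    for rc in curves:
        if rc.needs_conversion:
            rc = core_io.convert_raw_signal(
                rc, rc.metadata["sensitivity"], rc.metadata["spring_constant"]
            )
        z0, f0 = core_io.detect_contact_point(rc, deep_refine=True)
        indents.append(core_io.to_indentation(rc, z0, f0))
    return calibrate_tip(indents, config).tip


def _process_one(
    row: pd.Series,
    tip: TipProfile,
    config: CalibrationConfig,
) -> tuple[dict | None, dict | None, dict | None, list[dict]]:
    """Analyse a single manifest row; returns (indent, relax, hb, rejections)."""
    rejections: list[dict] = []
    curve_id = str(row.get("curve_id", Path(row["curve_path"]).stem))
    meta = {
        "curve_id": curve_id,
        "participant": row.get("participant", 0),
        "cell": row.get("cell", 0),
    }
    try:
        raw = core_io.read_force_curve(row["curve_path"])
        if raw.needs_conversion:
            raw = core_io.convert_raw_signal(
                raw, raw.metadata["sensitivity"], raw.metadata["spring_constant"]
            )
        z0, f0 = core_io.detect_contact_point(raw)
        ind = core_io.to_indentation(raw, z0, f0, nominal_dwell=config.nominal_dwell)
    except (AfmIndentError, OSError, KeyError) as exc:
        rejections.append({**meta, "stage": "io/contact", "reason": str(exc)})
        return None, None, None, rejections

    try:
        unload = analyze_unloading(ind, tip, config)
    except AfmIndentError as exc:
        rejections.append({**meta, "stage": "unloading", "reason": str(exc)})
        return None, None, None, rejections
    indent_rec = {**meta, **dataclasses.asdict(unload)}
    indent_rec["flags"] = ";".join(unload.flags)
    indent_rec.pop("curve_id", None)
    indent_rec["curve_id"] = curve_id

    relax_rec = hb_rec = None
    if np.count_nonzero(ind.seg_mask("pause")) >= 6 and "short_pause" not in ind.flags:
        try:
            relax, hb = analyze_relaxation(ind, a=unload.a, E=unload.E, config=config)
            relax_rec = {**meta, **dataclasses.asdict(relax)}
            relax_rec["flags"] = ";".join(relax.flags)
            relax_rec.pop("curve_id", None)
            relax_rec["curve_id"] = curve_id
            if hb is not None:
                hb_rec = {**meta, **dataclasses.asdict(hb)}
            else:
                rejections.append(
                    {**meta, "stage": "herschel-bulkley",
                     "reason": "prony fit below acceptance threshold"}
                )
        except AfmIndentError as exc:
            rejections.append({**meta, "stage": "relaxation", "reason": str(exc)})
    elif "short_pause" in ind.flags:
        rejections.append({**meta, "stage": "relaxation", "reason": "short pause"})
    return indent_rec, relax_rec, hb_rec, rejections


def run_pipeline(
    manifest_path: str | Path,
    tip: TipProfile,
    config: CalibrationConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the indentation + relaxation analysis over a manifest.

    Deterministic for fixed inputs.  When ``out_dir`` is given, per-curve
    CSVs, summary CSVs, a rejection log and a provenance block are written.
    """
    config = config or CalibrationConfig()
    manifest = core_io.read_manifest(manifest_path)
    indent_rows, relax_rows, hb_rows, rejection_rows = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, row in manifest.iterrows():
            ind, rel, hb, rej = _process_one(row, tip, config)
            if ind:
                indent_rows.append(ind)
            if rel:
                relax_rows.append(rel)
            if hb:
                hb_rows.append(hb)
            rejection_rows.extend(rej)

    result = PipelineResult(
        indent=pd.DataFrame(indent_rows),
        relax=pd.DataFrame(relax_rows),
        hb=pd.DataFrame(hb_rows),
        rejections=pd.DataFrame(
            rejection_rows, columns=["curve_id", "participant", "cell", "stage", "reason"]
        ),
        n_curves=len(manifest),
        config=config,
        tip=tip,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.indent.to_csv(out_dir / "indent_results.csv", index=False, float_format="%.10g")
    result.relax.to_csv(out_dir / "relax_results.csv", index=False, float_format="%.10g")
    result.hb.to_csv(out_dir / "hb_results.csv", index=False, float_format="%.10g")
    result.rejections.to_csv(out_dir / "rejections.csv", index=False)
    summary = summarize(result)
    summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.10g")
    provenance = {
        "config": result.config.to_dict(),
        "config_hash": result.config.content_hash(),
        "n_curves": result.n_curves,
        "n_rejected": result.n_rejected,
        "tip": result.tip.to_dict(),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))


def aggregate(
    df: pd.DataFrame,
    level: str = "participant",
    metrics: list[str] | None = None,
    method: str = "pooled",
) -> pd.DataFrame:
    """Median / min / max per metric at the cell or participant level.

    ``method='pooled'`` (default) takes the participant median over all
    accepted curves; ``method='cell-median'`` takes the median of cell
    medians.
    """
    if df.empty:
        return pd.DataFrame(columns=["level", "group", "metric", "median", "min", "max", "n"])
    if level == "cell":
        keys = ["participant", "cell"]
    elif level == "participant":
        keys = ["participant"]
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    metrics = metrics or [
        m for m in INDENT_METRICS + RELAX_METRICS + HB_METRICS if m in df.columns
    ]
    rows = []
    for group_key, sub in df.groupby(keys):
        group = "/".join(str(g) for g in (group_key if isinstance(group_key, tuple) else (group_key,)))
        for metric in metrics:
            vals = sub[metric].dropna()
            if vals.empty:
                continue
            if level == "participant" and method == "cell-median":
                med = float(vals.groupby(sub.loc[vals.index, "cell"]).median().median())
            else:
                med = float(vals.median())
            rows.append(
                SummaryStats(
                    level=level, group=group, metric=metric,
                    median=med, min=float(vals.min()), max=float(vals.max()), n=len(vals),
                )
            )
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def summarize(result: PipelineResult, method: str = "pooled") -> pd.DataFrame:
    """Cell- and participant-level summary over all result tables."""
    frames = []
    for df in (result.indent, result.relax, result.hb):
        if df is None or df.empty:
            continue
        for level in ("cell", "participant"):
            frames.append(aggregate(df, level=level, method=method))
    if not frames:
        return pd.DataFrame(columns=["level", "group", "metric", "median", "min", "max", "n"])
    return pd.concat(frames, ignore_index=True)


def report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write per-cell histograms, flow-curve overlays and summary tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _hist(df, column, label, stem):
        for (p, c), sub in df.groupby(["participant", "cell"]):
            vals = sub[column].dropna() / 1e6
            if vals.empty:
                continue
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.hist(vals, bins=15, color="0.5", edgecolor="black")
            ax.set_xlabel(f"{label} (MPa)")
            ax.set_ylabel("count")
            ax.set_title(f"participant {p}, cell {c} (n={len(vals)})")
            fig.tight_layout()
            path = out_dir / f"{stem}_P{p}_C{c}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)

    if not result.indent.empty:
        _hist(result.indent, "E", "Young's modulus", "hist_E")
    if not result.hb.empty and not result.relax.empty:
        _hist(result.hb.merge(result.relax[["curve_id"]], on="curve_id", how="inner"),
              "sigma_y", "yield stress", "hist_sigma_y")
        written.extend(_hb_overlays(result, out_dir, plt))
    elif result.hb.empty:
        note = out_dir / "NOTE.txt"
        note.write_text("no accepted relaxation/HB results; HB section omitted\n")
        written.append(note)

    summary = summarize(result)
    spath = out_dir / "summary_tables.csv"
    summary.to_csv(spath, index=False, float_format="%.6g")
    written.append(spath)
    return written


def _hb_overlays(result: PipelineResult, out_dir: Path, plt) -> list[Path]:
    """One flow-curve overlay per cell: relaxation locus solid, HB fit dashed."""
    written = []
    merged = result.hb.merge(
        result.relax[["curve_id", "c0", "c1", "c2", "tau1", "tau2"]], on="curve_id"
    )
    psi = result.config.psi
    for (p, c), sub in merged.groupby(["participant", "cell"]):
        row = sub.iloc[0]
        t = np.geomspace(1e-2, 4.0, 200)
        sigma = stress_series(row.c0, row.c1, row.c2, row.tau1, row.tau2, psi, t)
        rate = plastic_strain_rate(row.c1, row.c2, row.tau1, row.tau2, row.e_used, t)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(rate, sigma / 1e6, "-", color="black", label="relaxation locus")
        ax.plot(rate, (row.sigma_y + row.k * rate**row.j) / 1e6, "--", color="red",
                label="Herschel-Bulkley fit")
        ax.set_xlabel("plastic strain rate (1/s)")
        ax.set_ylabel("stress (MPa)")
        ax.set_xscale("log")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"hb_fit_P{p}_C{c}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
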