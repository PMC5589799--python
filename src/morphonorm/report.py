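"""Standardized per-patient result presentation.

A report compiles, for every feature, the measured value with its
scan-rescan uncertainty ("2.1 ± 0.2 ml" style), the normative prediction
at the patient's age, the raw and normalized p-values and a flag color:
*yellow* for uncorrected significance p < 0.01 and *red* for deviations
surviving FDR correction. Region detections are listed sorted by their
condensed score. TSV and JSON outputs are the contract; per-feature
age-trend figures (patient point over the normative band, background
colored by flag) are optional and headless-safe.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fingerprint import region_scores
from .normative import (
    FLAG_FDR,
    FLAG_UNCORRECTED,
    AbnormalityProfile,
    NormativeModel,
)

FLAG_COLORS = {"none": "none", FLAG_UNCORRECTED: "yellow", FLAG_FDR: "red"}

_UNITS = {
    "volume": "ml",
    "grayvol": "ml",
    "surfarea": "mm^2",
    "thickness": "mm",
    "thicknessstd": "mm",
    "meancurv": "1/mm",
    "gausscurv": "1/mm^2",
    "curvind": "",
    "foldind": "",
    "pctmean": "%",
}


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def format_measurement(value: float, uncertainty: float, unit: str = "", p: float | None = None) -> str:
    """Render "value ± uncertainty unit, p = ..." with the uncertainty to
    one significant digit and the value rounded to match."""
    if uncertainty > 0 and np.isfinite(uncertainty):
        u = _round_sig(uncertainty, 1)
        from math import floor, log10

        digits = max(0, -int(floor(log10(u))))
        text = f"{value:.{digits}f} ± {u:.{digits}f}"
    else:
        text = f"{value:g}"
    if unit:
        text += f" {unit}"
    if p is not None:
        text += f", p = {p:.3g}"
    return text


def config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def report_table(profile: AbnormalityProfile) -> pd.DataFrame:
    """Flat per-feature report rows with flag colors and formatted text."""
    tab = profile.table
    rows = pd.DataFrame(
        {
            "feature": tab.index,
            "value_raw": tab["value_raw"],
            "uncertainty": tab["measurement_sd_raw"],
            "predicted_raw": tab["pred_raw"],
            "value_normalized": tab["value_normalized"],
            "predicted_normalized": tab["pred_normalized"],
            "p_raw": tab["p_raw"],
            "p_normalized": tab["p_normalized"],
            "flag_raw": tab["flag_raw"].map(FLAG_COLORS),
            "flag_normalized": tab["flag_normalized"].map(FLAG_COLORS),
        }
    ).reset_index(drop=True)
    units = [_UNITS.get(f.split("|")[1], "") if f.split("|")[2] != "asymmetry" else "" for f in rows["feature"]]
    rows["display"] = [
        format_measurement(v, u, unit, p)
        for v, u, unit, p in zip(rows["value_raw"], rows["uncertainty"], units, rows["p_normalized"])
    ]
    return rows


def render_report(
    profile: AbnormalityProfile,
    model: NormativeModel,
    out_dir: str | Path,
    formats: Sequence[str] = ("tsv", "json"),
    plots: bool = False,
    plot_features: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write the standardized report for one scored scan.

    Always-on outputs: ``report.tsv`` (per-feature rows) and
    ``report.json`` (full-precision numbers, detections, provenance).
    With ``plots=True`` an age-trend figure is written per requested
    feature (defaults to the flagged ones, capped at 12).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    scores = region_scores(profile, model)
    detections = [s for s in scores if s.detected]
    rows = report_table(profile)

    if "tsv" in formats:
        path = out_dir / f"{profile.dataset_id}_report.tsv"
        rows.to_csv(path, sep="\t", index=False)
        written["tsv"] = path
        dpath = out_dir / f"{profile.dataset_id}_detections.tsv"
        pd.DataFrame(
            [
                {"region": s.region, "hemisphere": s.hemisphere or "", "L_r": s.L_r}
                for s in detections
            ],
            columns=["region", "hemisphere", "L_r"],
        ).to_csv(dpath, sep="\t", index=False)
        written["detections_tsv"] = dpath
    if "json" in formats:
        payload = {
            "dataset_id": profile.dataset_id,
            "subject_id": profile.subject_id,
            "age": profile.age,
            "extrapolated": profile.extrapolated,
            "provenance": {
                "package_version": __version__,
                "model_version": model.version,
                "model_n_scans": model.n_scans,
                "alpha": model.alpha,
                "fdr_q": model.fdr_q,
                "config_hash": config_hash(
                    {"alpha": model.alpha, "fdr_q": model.fdr_q, "max_order": model.max_order}
                ),
            },
            "detections": [
                {"region": s.region, "hemisphere": s.hemisphere, "L_r": s.L_r} for s in detections
            ],
            "features": {
                "index": list(profile.table.index),
                "columns": list(profile.table.columns),
                "data": [
                    [None if isinstance(x, float) and np.isnan(x) else x for x in row]
                    for row in profile.table.to_numpy().tolist()
                ],
            },
        }
        path = out_dir / f"{profile.dataset_id}_report.json"
        with open(path, "w") as fh:
            json.dump(payload, fh)
        written["json"] = path
    if plots:
        written["plots"] = _age_trend_plots(profile, model, out_dir, plot_features)
    return written


def _age_trend_plots(profile, model, out_dir: Path, features: Sequence[str] | None) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if features is None:
        flagged = profile.table.index[profile.table["flag_normalized"] != "none"]
        features = list(flagged[:12])
    plot_dir = out_dir / "plots"
    plot_dir.mkdir(exist_ok=True)
    ages = np.linspace(model.age_min, model.age_max, 120)
    for fid in features:
        fm = model.feature_model(fid, "normalized")
        pred = np.asarray(fm.predict(ages), dtype=float)
        width = float(np.hypot(fm.population_sd, fm.measurement_sd))
        fig, ax = plt.subplots(figsize=(4, 3))
        flag = FLAG_COLORS.get(profile.table.loc[fid, "flag_normalized"], "none")
        if flag == "yellow":
            ax.set_facecolor("#fff7cc")
        elif flag == "red":
            ax.set_facecolor("#ffd9d9")
        ax.plot(ages, pred, color="k", lw=1)
        ax.fill_between(ages, pred - 2.576 * width, pred + 2.576 * width, alpha=0.2, color="gray")
        ax.plot([profile.age], [profile.table.loc[fid, "value_normalized"]], "o", color="crimson")
        ax.set_title(fid, fontsize=7)
        ax.set_xlabel("age (y)")
        fig.tight_layout()
        fig.savefig(plot_dir / (fid.replace("|", "_").replace("/", "_") + ".png"), dpi=100)
        plt.close(fig)
    return plot_dir
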