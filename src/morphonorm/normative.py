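"""Normative age-trend model and single-scan abnormality scoring.

For every feature of the catalog (raw and eTIV-normalized variant) a low
order polynomial age trend is fitted to the control cohort by least squares
with the order (0..3) selected by BIC. The model stores, per feature:

* trend coefficients (in a centered/scaled age basis for conditioning),
* ``population_sd`` -- the between-subject spread around the trend,
* ``measurement_sd`` -- scan-rescan error estimated from repeated controls
  scanned within a three-year window (SD of detrended within-pair
  differences divided by sqrt(2)),
* artifact probability and the odds for a valid (vs. artifactual)
  measurement, from a robust outlier rule on the control residuals.

A patient value x at age a is scored by the residual r = x - trend(a). The
null spread of r is sqrt(population_sd^2 + measurement_sd^2); because the
control residual variance itself decomposes into between-subject plus
measurement variance, ``population_sd`` is stored as the between-subject
component, so the combination reproduces the control residual spread
exactly. The two-sided p-value uses the prediction-interval
standardization: z = r / (s * sqrt(1 + h)) with h the design leverage at
the patient's age, referred to a Student-t distribution with the residual
degrees of freedom. This keeps the per-feature type-I rate at the nominal
level with finite control cohorts; with ~300 controls the t and Gaussian
tails differ by ~5% at p = 0.01, which matters when calibration is
checked over half a million tests. ``abnormality_p`` with ``df=None``
reduces to the plain Gaussian tail.

Flags: ``uncorrected`` for p < 0.01 and ``fdr`` for features surviving
Benjamini-Hochberg FDR at q = 0.01 over the per-dataset family of 2,976
tests of one variant (asymmetry features belong to both families).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import normalization as nrm
from .schema import (
    ASYMMETRY,
    FeatureKey,
    MorphometricRecord,
    assemble_schema,
    records_to_frame,
)

logger = logging.getLogger(__name__)

ALPHA = 0.01  #: uncorrected per-feature decision threshold
FDR_Q = 0.01  #: Benjamini-Hochberg level over the per-dataset family
MAX_TREND_ORDER = 3
REPEAT_WINDOW_YEARS = 3.0
OUTLIER_FLAG_Z = 3.5  #: robust-z threshold entering the artifact odds
OUTLIER_EXCLUDE_Z = 5.0  #: wider fence for exclusion from the trend/SD refit
VARIANTS = ("raw", "normalized")

FLAG_NONE = "none"
FLAG_UNCORRECTED = "uncorrected"
FLAG_FDR = "fdr"


# ---------------------------------------------------------------------------
# Single-feature primitives
# ---------------------------------------------------------------------------


@dataclass
class TrendFit:
    """Least-squares polynomial age trend for one feature."""

    coefficients: np.ndarray  # ascending powers, raw-age basis
    population_sd: float  # residual SD (ddof = order + 1)
    order: int
    df: int

    def predict(self, ages) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(ages, dtype=float), self.coefficients)


def _fit_poly_bic(
    t: np.ndarray, y: np.ndarray, max_order: int, extra: np.ndarray | None = None
) -> tuple[np.ndarray, float, int, float | None]:
    """BIC-selected polynomial fit in the scaled-age basis ``t``.

    Returns (coefficients padded to max_order+1, residual SD, order,
    extra-covariate coefficient or None).
    """
    n = len(t)
    if n < max_order + 2:
        raise ValueError(f"need at least {max_order + 2} points, got {n}")
    V = np.vander(t, max_order + 1, increasing=True)
    best = None
    for order in range(max_order + 1):
        X = V[:, : order + 1]
        if extra is not None:
            X = np.column_stack([X, extra])
        p = X.shape[1]
        if n <= p:
            break
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        # floor relative to the data scale so numerically-zero residuals of
        # different orders compare as ties (the penalty then decides)
        floor = n * (float(np.mean(y * y)) + 1e-300) * 1e-24
        bic = n * np.log(max(rss, floor) / n) + p * np.log(n)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, order, beta, rss, p)
    assert best is not None
    _, order, beta, rss, p = best
    dof = n - p
    sd = float(np.sqrt(rss / dof)) if dof > 0 else 0.0
    coeffs = np.zeros(max_order + 1)
    coeffs[: order + 1] = beta[: order + 1]
    extra_coef = float(beta[order + 1]) if extra is not None else None
    return coeffs, sd, order, extra_coef


def fit_age_trend(ages, values, max_order: int = MAX_TREND_ORDER) -> TrendFit:
    """Fit a BIC-selected polynomial age trend (order <= ``max_order``).

    The residual SD uses a degrees-of-freedom correction (ddof = order+1).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(ages)) < max_order + 2:
        raise ValueError("too few distinct ages for the requested maximum order")
    center, scale = float(ages.mean()), float(ages.std() or 1.0)
    t = (ages - center) / scale
    coeffs_t, sd, order, _ = _fit_poly_bic(t, values, max_order)
    # convert scaled-basis coefficients to the raw-age basis
    poly = np.polynomial.Polynomial(coeffs_t[: order + 1])
    raw = poly(np.polynomial.Polynomial([-center / scale, 1.0 / scale]))
    coefficients = np.zeros(order + 1)
    coefficients[: len(raw.coef)] = raw.coef
    return TrendFit(coefficients=coefficients, population_sd=sd, order=order, df=len(ages) - order - 1)


def estimate_measurement_error(pair_differences) -> np.ndarray | float:
    """Measurement SD from detrended within-pair differences.

    ``pair_differences`` holds, per repeat pair, the difference of the two
    scans' trend-detrended values (subject effects cancel, so a pair
    difference is the difference of two independent measurement errors with
    known zero mean). The estimator is the RMS of the differences divided
    by sqrt(2). Shape (n_pairs,) or (n_pairs, n_features); zero with a
    warning when no pairs are available.
    """
    d = np.atleast_1d(np.asarray(pair_differences, dtype=float))
    if d.shape[0] == 0:
        warnings.warn("no repeat pairs available; measurement_sd set to 0")
        return 0.0 if d.ndim == 1 else np.zeros(d.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.sqrt(np.nanmean(d**2, axis=0) / 2.0)
    sd = np.nan_to_num(sd)
    return float(sd) if np.ndim(sd) == 0 else sd


def robust_z(values) -> np.ndarray:
    """|value - median| / (1.4826 * MAD), signed; SD fallback for zero MAD."""
    values = np.asarray(values, dtype=float)
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.nanstd(values)
    if scale == 0:
        return np.zeros_like(values)
    return (values - med) / scale


def estimate_artifact_odds(control_values, flag_z: float = OUTLIER_FLAG_Z) -> tuple[float, float]:
    """Artifact probability and valid-vs-artifact odds for one feature.

    Outliers are flagged at |robust z| > ``flag_z`` (median/MAD rule); the
    artifact probability uses Haldane-style +1/2 smoothing so the odds are
    always finite and positive: p = (k + 1/2) / (n + 1), odds = (1-p)/p.
    """
    values = np.asarray(control_values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 20:
        warnings.warn(f"artifact odds estimated from only {n} scans")
    k = int(np.sum(np.abs(robust_z(values)) > flag_z))
    p_art = (k + 0.5) / (n + 1.0)
    return p_art, (1.0 - p_art) / p_art


@dataclass
class FeatureModel:
    """Fitted null model of a single feature (one variant)."""

    coefficients: np.ndarray  # scaled-age basis, ascending, padded
    age_center: float
    age_scale: float
    population_sd: float
    measurement_sd: float
    order: int
    df: float | None = None  # None -> Gaussian tails
    gram_inv: np.ndarray | None = None  # leverage; scaled-age basis
    odds_valid: float = np.inf
    artifact_probability: float = 0.0
    sex_coef: float = 0.0

    def predict(self, age, sex_value: float = 0.0) -> float:
        t = (np.asarray(age, dtype=float) - self.age_center) / self.age_scale
        return np.polynomial.polynomial.polyval(t, self.coefficients) + self.sex_coef * sex_value

    def leverage(self, age) -> float:
        if self.gram_inv is None:
            return 0.0
        t = (float(age) - self.age_center) / self.age_scale
        v = t ** np.arange(self.gram_inv.shape[0])
        return float(v @ self.gram_inv @ v)


def abnormality_p(value: float, age: float, feature_model: FeatureModel) -> tuple[int, float]:
    """Two-sided abnormality p-value and residual sign for one measurement.

    z = (value - trend(age)) / (sqrt(population_sd^2 + measurement_sd^2) *
    sqrt(1 + leverage)); the tail is Student-t with ``df`` degrees of
    freedom, or Gaussian when ``df`` is None.
    """
    fm = feature_model
    residual = float(value) - float(fm.predict(age))
    width = float(np.hypot(fm.population_sd, fm.measurement_sd))
    if width == 0:
        return (int(np.sign(residual)), 1.0 if residual == 0 else np.finfo(float).tiny)
    z = residual / (width * np.sqrt(1.0 + fm.leverage(age)))
    if fm.df is None or not np.isfinite(fm.df):
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        p = 2.0 * sps.t.sf(abs(z), fm.df)
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return int(np.sign(residual)), p


def fdr_flag(p_values, q: float = FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up flags at level ``q`` (boolean per test)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# Cohort-level model
# ---------------------------------------------------------------------------


def _sex_value(sex) -> np.ndarray:
    return (np.asarray(sex) == "male").astype(float) - 0.5


def _asymmetry_scales(
    raw_frame: pd.DataFrame, ids: Sequence[str], size_ref: pd.Series | None = None
) -> tuple[np.ndarray, pd.Series]:
    """Per-scan scale factors s = (L + R) / normative mean bilateral size
    for asymmetry features (1 elsewhere).

    The asymmetry index AI = (R - L)/(R + L) of a structure of bilateral
    size S has null spread proportional to 1/S; multiplying the AI residual
    by s removes this size-induced heteroscedasticity, so a single Gaussian
    null width is exact rather than approximate. ``size_ref`` (the
    normative mean of L + R per feature, head-size-normalized values so the
    eTIV factor does not re-enter) is learned at model build and reused at
    scoring time.
    """
    schema = assemble_schema()
    scales = np.ones((len(raw_frame), len(ids)))
    ref: dict[str, float] = {}
    have_ref = size_ref is not None
    for j, fid in enumerate(ids):
        key = FeatureKey.from_id(fid)
        if key.side != ASYMMETRY:
            continue
        lid = FeatureKey(key.region, key.parameter, "left").id
        rid = FeatureKey(key.region, key.parameter, "right").id
        if lid not in raw_frame.columns or rid not in raw_frame.columns:
            continue
        S = raw_frame[lid].to_numpy(dtype=float) + raw_frame[rid].to_numpy(dtype=float)
        sbar = float(size_ref.get(fid, np.nan)) if have_ref else float(np.nanmean(S))
        if not np.isfinite(sbar) or sbar <= 0:
            continue
        ref[fid] = sbar
        with np.errstate(invalid="ignore"):
            s = np.clip(S / sbar, 0.2, 5.0)
        scales[:, j] = np.where(np.isfinite(s), s, 1.0)
    return scales, pd.Series(ref, dtype=float)


@dataclass
class NormativeModel:
    """Per-feature normative models for the raw and normalized variants.

    ``tables[variant]`` is a DataFrame indexed by feature id with columns
    c0..c3 (scaled-age trend coefficients), order, population_sd,
    measurement_sd, artifact_probability, odds_valid, n_used, df and, when
    sex is modeled, sex_coef.
    """

    spec: nrm.NormalizationSpec
    tables: dict[str, pd.DataFrame]
    age_center: float
    age_scale: float
    age_min: float
    age_max: float
    n_scans: int
    n_subjects: int
    gram_inv: dict[int, np.ndarray]
    include_sex: bool = False
    alpha: float = ALPHA
    fdr_q: float = FDR_Q
    max_order: int = MAX_TREND_ORDER
    version: str = "1"
    asym_size_ref: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    # -- scoring ------------------------------------------------------------

    def feature_model(self, feature_id: str, variant: str = "normalized") -> FeatureModel:
        row = self.tables[variant].loc[feature_id]
        order = int(row["order"])
        return FeatureModel(
            coefficients=row[[f"c{i}" for i in range(self.max_order + 1)]].to_numpy(dtype=float),
            age_center=self.age_center,
            age_scale=self.age_scale,
            population_sd=float(row["population_sd"]),
            measurement_sd=float(row["measurement_sd"]),
            order=order,
            df=float(row["df"]),
            gram_inv=self.gram_inv[order],
            odds_valid=float(row["odds_valid"]),
            artifact_probability=float(row["artifact_probability"]),
            sex_coef=float(row.get("sex_coef", 0.0)),
        )

    def odds(self, variant: str = "normalized") -> pd.Series:
        return self.tables[variant]["odds_valid"]

    def score_frame(self, frame: pd.DataFrame) -> list["AbnormalityProfile"]:
        """Score each row (scan) of a cohort table against the model."""
        schema = assemble_schema()
        ids = schema.ids()
        raw = nrm.compute_asymmetry_columns(frame)
        normalized = nrm.compute_asymmetry_columns(nrm.normalize_frame(frame, self.spec))
        asym_scale, _ = _asymmetry_scales(normalized, ids, size_ref=self.asym_size_ref)
        # finite-sample leverage of the learned contrast group means
        contrast_h = np.zeros((len(frame), len(ids)))
        counts = self.spec.contrast_group_counts
        if counts:
            inv_n = np.array(
                [1.0 / counts.get(str(g), np.inf) for g in frame["scanner_sequence"]]
            )
            is_contrast = np.array(
                [FeatureKey.from_id(fid).parameter == "pctmean" for fid in ids]
            )
            contrast_h[:, is_contrast] = inv_n[:, None]
        ages = frame["age"].to_numpy(dtype=float)
        sexv = _sex_value(frame["sex"]) if self.include_sex else np.zeros(len(frame))
        t = (ages - self.age_center) / self.age_scale
        V = np.vander(t, self.max_order + 1, increasing=True)
        # leverage per order, per scan
        h_by_order = np.empty((len(frame), self.max_order + 1))
        for o in range(self.max_order + 1):
            G = self.gram_inv[o]
            rows = np.column_stack([V[:, : o + 1], sexv[:, None]]) if self.include_sex else V[:, : o + 1]
            h_by_order[:, o] = np.einsum("ij,jk,ik->i", rows, G, rows)

        variant_data = {}
        for variant, table in (("raw", raw), ("normalized", normalized)):
            model_tab = self.tables[variant]
            coeffs = model_tab[[f"c{i}" for i in range(self.max_order + 1)]].to_numpy(dtype=float)
            orders = model_tab["order"].to_numpy(dtype=int)
            values = table.reindex(columns=ids).to_numpy(dtype=float)
            pred = V @ coeffs.T
            if self.include_sex:
                pred = pred + np.outer(sexv, model_tab["sex_coef"].to_numpy(dtype=float))
            resid = (values - pred) * asym_scale
            width = np.hypot(
                model_tab["population_sd"].to_numpy(dtype=float),
                model_tab["measurement_sd"].to_numpy(dtype=float),
            )
            width = np.where(width > 0, width, np.inf)
            h = h_by_order[:, orders] + contrast_h
            z = resid / (width[None, :] * np.sqrt(1.0 + h))
            df = model_tab["df"].to_numpy(dtype=float)
            p = 2.0 * sps.t.sf(np.abs(z), df[None, :])
            p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
            p[~np.isfinite(values)] = np.nan
            variant_data[variant] = (values, pred, resid, p)

        profiles = []
        for i in range(len(frame)):
            cols: dict[str, object] = {}
            for variant in VARIANTS:
                values, pred, resid, p = variant_data[variant]
                pv = p[i]
                finite = np.isfinite(pv)
                unc = finite & (pv < self.alpha)
                fdr = np.zeros(len(ids), dtype=bool)
                if finite.any():
                    fdr[finite] = fdr_flag(pv[finite], self.fdr_q)
                flags = np.where(fdr, FLAG_FDR, np.where(unc, FLAG_UNCORRECTED, FLAG_NONE))
                cols[f"value_{variant}"] = values[i]
                cols[f"pred_{variant}"] = pred[i]
                cols[f"sign_{variant}"] = np.sign(resid[i])
                cols[f"p_{variant}"] = pv
                cols[f"flag_{variant}"] = flags
                cols[f"odds_{variant}"] = self.tables[variant]["odds_valid"].to_numpy(dtype=float)
            cols["measurement_sd_raw"] = self.tables["raw"]["measurement_sd"].to_numpy(dtype=float)
            row = frame.iloc[i]
            profiles.append(
                AbnormalityProfile(
                    dataset_id=str(row.get("session_id", i)),
                    subject_id=str(row.get("subject_id", "")),
                    age=float(row["age"]),
                    table=pd.DataFrame(cols, index=ids),
                    extrapolated=bool(ages[i] < self.age_min or ages[i] > self.age_max),
                )
            )
        return profiles

    def score_record(self, record: MorphometricRecord) -> "AbnormalityProfile":
        return self.score_frame(records_to_frame([record]))[0]

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "spec": self.spec.to_dict(),
            "age_center": self.age_center,
            "age_scale": self.age_scale,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "n_scans": self.n_scans,
            "n_subjects": self.n_subjects,
            "include_sex": self.include_sex,
            "alpha": self.alpha,
            "fdr_q": self.fdr_q,
            "max_order": self.max_order,
            "asym_size_ref": {k: float(v) for k, v in self.asym_size_ref.items()},
            "gram_inv": {str(o): g.tolist() for o, g in self.gram_inv.items()},
            "tables": {
                v: {
                    "index": list(tab.index),
                    "columns": list(tab.columns),
                    "data": tab.to_numpy().tolist(),
                }
                for v, tab in self.tables.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModel":
        with open(path) as fh:
            payload = json.load(fh)
        tables = {
            v: pd.DataFrame(t["data"], index=t["index"], columns=t["columns"])
            for v, t in payload["tables"].items()
        }
        return cls(
            spec=nrm.NormalizationSpec.from_dict(payload["spec"]),
            tables=tables,
            age_center=payload["age_center"],
            age_scale=payload["age_scale"],
            age_min=payload["age_min"],
            age_max=payload["age_max"],
            n_scans=payload["n_scans"],
            n_subjects=payload["n_subjects"],
            gram_inv={int(o): np.asarray(g) for o, g in payload["gram_inv"].items()},
            include_sex=payload["include_sex"],
            alpha=payload["alpha"],
            fdr_q=payload["fdr_q"],
            max_order=payload["max_order"],
            version=payload["version"],
            asym_size_ref=pd.Series(payload.get("asym_size_ref", {}), dtype=float),
        )

    def coefficient_table(self) -> pd.DataFrame:
        """Flat per-feature coefficient/SD table (TSV companion format)."""
        parts = []
        for variant, tab in self.tables.items():
            part = tab.copy()
            part.insert(0, "variant", variant)
            part.insert(0, "feature", part.index)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


@dataclass
class AbnormalityProfile:
    """Per-feature abnormality scores for one scored scan."""

    dataset_id: str
    age: float
    table: pd.DataFrame
    subject_id: str = ""
    extrapolated: bool = False

    def flags(self, variant: str = "normalized") -> pd.Series:
        return self.table[f"flag_{variant}"]

    def p_values(self, variant: str = "normalized") -> pd.Series:
        return self.table[f"p_{variant}"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dataset_id": self.dataset_id,
            "subject_id": self.subject_id,
            "age": self.age,
            "extrapolated": self.extrapolated,
            "index": list(self.table.index),
            "columns": list(self.table.columns),
            "data": [
                [None if isinstance(x, float) and np.isnan(x) else x for x in row]
                for row in self.table.to_numpy().tolist()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "AbnormalityProfile":
        with open(path) as fh:
            payload = json.load(fh)
        table = pd.DataFrame(payload["data"], index=payload["index"], columns=payload["columns"])
        return cls(
            dataset_id=payload["dataset_id"],
            subject_id=payload["subject_id"],
            age=payload["age"],
            table=table,
            extrapolated=payload["extrapolated"],
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "feature", out.index)
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------


def _repeat_pairs(frame: pd.DataFrame, window_years: float = REPEAT_WINDOW_YEARS) -> list[tuple[int, int]]:
    """Row-index pairs of same-subject scans within the repeat window."""
    pairs = []
    for _, group in frame.groupby("subject_id"):
        if len(group) < 2:
            continue
        idx = group.sort_values("age").index.to_list()
        positions = [frame.index.get_loc(i) for i in idx]
        ages = group.sort_values("age")["age"].to_numpy(dtype=float)
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                if abs(ages[b] - ages[a]) < window_years:
                    pairs.append((positions[a], positions[b]))
    return pairs


def build_normative_model(
    frame: pd.DataFrame,
    max_order: int = MAX_TREND_ORDER,
    include_sex: bool = False,
    alpha: float = ALPHA,
    fdr_q: float = FDR_Q,
    flag_z: float = OUTLIER_FLAG_Z,
    exclude_z: float = OUTLIER_EXCLUDE_Z,
) -> NormativeModel:
    """Fit the full normative model from a control cohort table.

    The cohort table has one row per scan with the metadata columns and one
    column per measured feature; repeated scans are discovered from
    ``subject_id`` (pairs within a three-year age window).
    """
    schema = assemble_schema()
    ids = schema.ids()
    spec = nrm.NormalizationSpec(reference_etiv=nrm.reference_etiv_of(frame["etiv"]))
    spec.contrast_reference, spec.contrast_group_means = nrm.fit_contrast_reference(frame)
    spec.contrast_group_counts = {
        str(g): int(n) for g, n in frame.groupby("scanner_sequence").size().items()
    }

    raw = nrm.compute_asymmetry_columns(frame)
    normalized = nrm.compute_asymmetry_columns(nrm.normalize_frame(frame, spec))
    asym_scale, asym_size_ref = _asymmetry_scales(normalized, ids)

    ages = frame["age"].to_numpy(dtype=float)
    center, scale = float(ages.mean()), float(ages.std() or 1.0)
    t = (ages - center) / scale
    V = np.vander(t, max_order + 1, increasing=True)
    sexv = _sex_value(frame["sex"]) if include_sex else None

    gram_inv = {}
    for o in range(max_order + 1):
        X = V[:, : o + 1] if sexv is None else np.column_stack([V[:, : o + 1], sexv])
        gram_inv[o] = np.linalg.inv(X.T @ X)

    pairs = _repeat_pairs(frame)
    if not pairs:
        logger.warning("no repeat pairs in cohort; measurement SDs will be zero")
    pair_a = np.array([p[0] for p in pairs], dtype=int)
    pair_b = np.array([p[1] for p in pairs], dtype=int)

    tables = {}
    for variant, data in (("raw", raw), ("normalized", normalized)):
        Y = data.reindex(columns=ids).to_numpy(dtype=float)
        n, m = Y.shape
        # preliminary common fit (order 2) for the outlier pass
        o_pre = min(2, max_order)
        Xp = V[:, : o_pre + 1] if sexv is None else np.column_stack([V[:, : o_pre + 1], sexv])
        Yf = np.where(np.isfinite(Y), Y, np.nanmean(Y, axis=0, keepdims=True))
        beta_pre, *_ = np.linalg.lstsq(Xp, Yf, rcond=None)
        resid_pre = Yf - Xp @ beta_pre
        med = np.median(resid_pre, axis=0)
        mad = np.median(np.abs(resid_pre - med), axis=0)
        mad_scale = 1.4826 * mad
        fallback = resid_pre.std(axis=0)
        mad_scale = np.where(mad_scale > 0, mad_scale, np.where(fallback > 0, fallback, 1.0))
        rz = (resid_pre - med) / mad_scale
        flagged = np.abs(rz) > flag_z
        flagged[~np.isfinite(Y)] = False
        excluded = (np.abs(rz) > exclude_z) | ~np.isfinite(Y)

        n_valid = np.sum(np.isfinite(Y), axis=0)
        k_flagged = flagged.sum(axis=0)
        p_art = (k_flagged + 0.5) / (n_valid + 1.0)
        odds = (1.0 - p_art) / p_art

        coeffs = np.zeros((m, max_order + 1))
        sex_coefs = np.zeros(m)
        resid_sd = np.zeros(m)
        orders = np.zeros(m, dtype=int)
        dfs = np.zeros(m)
        n_used = np.zeros(m, dtype=int)
        for j in range(m):
            keep = ~excluded[:, j]
            yj = Y[keep, j]
            tj = t[keep]
            if len(yj) < max_order + 2:
                raise ValueError(f"feature {ids[j]}: too few usable control scans")
            extra = sexv[keep, None] if sexv is not None else None
            cj, sd, order, sx = _fit_poly_bic(tj, yj, max_order, extra=extra)
            sc_j = asym_scale[keep, j]
            if not np.all(sc_j == 1.0):
                pred_j = np.polynomial.polynomial.polyval(tj, cj[: order + 1])
                if sx is not None:
                    pred_j = pred_j + sx * sexv[keep]
                r = (yj - pred_j) * sc_j
                dof = len(yj) - (order + 1) - (1 if include_sex else 0)
                sd = float(np.sqrt(r @ r / dof)) if dof > 0 else 0.0
            coeffs[j] = cj
            resid_sd[j] = sd
            orders[j] = order
            sex_coefs[j] = sx or 0.0
            n_used[j] = len(yj)
            dfs[j] = len(yj) - (order + 1) - (1 if include_sex else 0)

        # measurement error from detrended repeat pairs
        pred = V @ coeffs.T
        if sexv is not None:
            pred = pred + np.outer(sexv, sex_coefs)
        detrended = np.where(excluded, np.nan, (Y - pred) * asym_scale)
        if len(pairs):
            diffs = detrended[pair_a] - detrended[pair_b]
            meas_sd = estimate_measurement_error(diffs)
        else:
            meas_sd = np.zeros(m)
        meas_sd = np.minimum(np.asarray(meas_sd), np.sqrt(0.9) * resid_sd)
        pop_sd = np.sqrt(np.maximum(resid_sd**2 - meas_sd**2, 0.0))

        tab = pd.DataFrame(
            {f"c{i}": coeffs[:, i] for i in range(max_order + 1)}
            | {
                "order": orders,
                "population_sd": pop_sd,
                "measurement_sd": meas_sd,
                "artifact_probability": p_art,
                "odds_valid": odds,
                "n_used": n_used,
                "df": dfs,
            },
            index=ids,
        )
        if include_sex:
            tab["sex_coef"] = sex_coefs
        tables[variant] = tab

    return NormativeModel(
        spec=spec,
        tables=tables,
        age_center=center,
        age_scale=scale,
        age_min=float(ages.min()),
        age_max=float(ages.max()),
        n_scans=len(frame),
        n_subjects=int(frame["subject_id"].nunique()),
        gram_inv=gram_inv,
        include_sex=include_sex,
        alpha=alpha,
        fdr_q=fdr_q,
        max_order=max_order,
        asym_size_ref=asym_size_ref,
    )
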