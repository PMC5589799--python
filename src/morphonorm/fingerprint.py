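"""Signed log-p abnormality fingerprints and regional condensation.

Every feature's two-sided p-value and residual sign are converted into a
signed decadic log score

    L = -log10(p)   if the residual is positive (observation above trend),
    L = +log10(p)   if the residual is negative,

so large positive L means "abnormally large" and large negative L
"abnormally small"; p = 1 gives L = 0. The full vector of 2,976 L values is
the scan's morphometric fingerprint.

For comparison with region-level ground truth the per-parameter scores are
condensed into one statement per region and hemisphere with an
odds-squared-weighted root mean square,

    L_region = sqrt( sum_m w_m L_m^2 odds_m^2 / sum_m w_m odds_m^2 ) >= 0,

where the odds express confidence that the measurement is valid rather
than artifactual, so dubious measurements are suppressed. Each cortical
hemisphere pools its 9 surface parameters with weight 1 plus the region's
9 asymmetry-index scores with weight 1/2 (asymmetries count half for each
hemisphere); a bilateral volume structure pools volume (weight 1) and its
asymmetry (weight 1/2); midline/global volumes stand alone. A region is a
*detection* when L_region >= 2 (i.e. pooled evidence at the p ~ 0.01
scale); detections are ranked by L_region, ties broken lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .normative import AbnormalityProfile, NormativeModel
from .schema import (
    ASYMMETRY,
    BILATERAL_VOLUME_REGIONS,
    GLOBAL,
    GLOBAL_VOLUME_REGIONS,
    HEMISPHERES,
    SURFACE_PARAMETERS,
    SURFACE_REGIONS,
    VOLUME,
    FeatureKey,
)

P_FLOOR = 1e-16  #: p-values below this are clipped before taking log10
LR_THRESHOLD = 2.0  #: detection threshold on the condensed region score
ASYMMETRY_WEIGHT = 0.5


def signed_log_feature(p: float, sign: float, floor: float = P_FLOOR) -> float:
    """Eq.-style signed decadic log score of one feature's p-value."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p == 0:
        import warnings

        warnings.warn(f"p == 0 clipped to {floor}")
        p = floor
    p = max(p, floor)
    if p == 1.0 or sign == 0:
        return 0.0
    magnitude = -np.log10(p)
    return float(magnitude if sign > 0 else -magnitude)


def feature_vector(profile: AbnormalityProfile, variant: str = "normalized") -> pd.Series:
    """Full signed log-p fingerprint (length 2,976) of a scored scan."""
    p = np.clip(profile.table[f"p_{variant}"].to_numpy(dtype=float), P_FLOOR, 1.0)
    sign = profile.table[f"sign_{variant}"].to_numpy(dtype=float)
    # sign > 0 -> positive L; sign < 0 -> negative L; sign == 0 -> 0
    L = np.where(sign > 0, -np.log10(p), np.where(sign < 0, np.log10(p), 0.0))
    L = np.where(np.isfinite(profile.table[f"p_{variant}"].to_numpy(dtype=float)), L, np.nan)
    return pd.Series(L, index=profile.table.index, name=profile.dataset_id)


def condense_region(L_values, odds_values, weights=None) -> float:
    """Odds^2-weighted RMS of |L| over a region's contributing features."""
    L = np.asarray(L_values, dtype=float)
    odds = np.asarray(odds_values, dtype=float)
    if L.size == 0:
        return float("nan")
    if np.any(odds <= 0):
        raise ValueError("odds must be positive")
    w = np.ones_like(L) if weights is None else np.asarray(weights, dtype=float)
    keep = np.isfinite(L)
    if not keep.any():
        return float("nan")
    L, odds, w = L[keep], odds[keep], w[keep]
    denom = float(np.sum(w * odds**2))
    return float(np.sqrt(np.sum(w * L**2 * odds**2) / denom))


@dataclass
class RegionScore:
    """Condensed abnormality statement for one region/hemisphere."""

    region: str
    hemisphere: str | None  # None for midline/global structures
    L_r: float
    contributors: tuple[tuple[str, float, float], ...] = ()  # (feature id, L, odds)
    threshold: float = LR_THRESHOLD

    @property
    def detected(self) -> bool:
        return bool(np.isfinite(self.L_r) and self.L_r >= self.threshold)

    @property
    def label(self) -> str:
        return self.region if self.hemisphere is None else f"{self.hemisphere} {self.region}"


def _pool(region: str, parameters: Sequence[str], hemisphere: str | None,
          L: pd.Series, odds: pd.Series, threshold: float) -> RegionScore:
    ids, weights = [], []
    for parameter in parameters:
        if hemisphere is not None:
            ids.append(FeatureKey(region, parameter, hemisphere).id)
            weights.append(1.0)
            ids.append(FeatureKey(region, parameter, ASYMMETRY).id)
            weights.append(ASYMMETRY_WEIGHT)
        else:
            ids.append(FeatureKey(region, parameter, GLOBAL).id)
            weights.append(1.0)
    Lv = L.reindex(ids).to_numpy(dtype=float)
    ov = odds.reindex(ids).to_numpy(dtype=float)
    score = condense_region(Lv, ov, weights)
    contributors = tuple(
        (fid, float(lv), float(o)) for fid, lv, o in zip(ids, Lv, ov) if np.isfinite(lv)
    )
    return RegionScore(region=region, hemisphere=hemisphere, L_r=score,
                       contributors=contributors, threshold=threshold)


def region_scores(
    profile: AbnormalityProfile,
    model: NormativeModel,
    variant: str = "normalized",
    threshold: float = LR_THRESHOLD,
) -> list[RegionScore]:
    """Condensed scores for every region/hemisphere of the catalog.

    Sorted by descending L_r with lexicographic (region, hemisphere)
    tie-breaking; includes non-detections (use :func:`detect_regions` for
    the detection list).
    """
    L = feature_vector(profile, variant)
    odds = model.odds(variant)
    scores: list[RegionScore] = []
    for region in SURFACE_REGIONS:
        for hemisphere in HEMISPHERES:
            scores.append(_pool(region, SURFACE_PARAMETERS, hemisphere, L, odds, threshold))
    for region in BILATERAL_VOLUME_REGIONS:
        for hemisphere in HEMISPHERES:
            scores.append(_pool(region, (VOLUME,), hemisphere, L, odds, threshold))
    for region in GLOBAL_VOLUME_REGIONS:
        scores.append(_pool(region, (VOLUME,), None, L, odds, threshold))
    scores.sort(key=lambda s: (-(s.L_r if np.isfinite(s.L_r) else -np.inf), s.region, s.hemisphere or ""))
    return scores


def detect_regions(
    profile: AbnormalityProfile,
    model: NormativeModel,
    variant: str = "normalized",
    threshold: float = LR_THRESHOLD,
) -> list[RegionScore]:
    """Regions with pooled abnormality L_r >= threshold, most prominent first."""
    return [s for s in region_scores(profile, model, variant, threshold) if s.detected]


def top_k(scores: Sequence[RegionScore], k: int = 3) -> list[RegionScore]:
    """The k most prominent detections (input assumed sorted as returned)."""
    return list(scores[: max(k, 0)])
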