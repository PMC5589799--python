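"""Head-size and scanner normalization and asymmetry indices.

Head size is removed by isometric normalization to the estimated total
intracranial volume (eTIV): a measurement x with length-dimension scaling
exponent n is replaced by ``x * (reference_etiv / etiv) ** n``, with n = 1
for volumes, 2/3 for surface areas, 1/3 for thicknesses, -1/3 for mean
curvature (units 1/length), -2/3 for Gaussian curvature (1/length^2) and 0
for the dimensionless curvature and folding indices. Multiplying by the
reference ratio (rather than dividing by etiv^n) keeps physical units, so
normalized values stay comparable with raw plots.

Grey-white percent contrast depends on the MR sequence rather than on head
size, and is instead rescaled so that each (feature, scanner-sequence)
group mean matches the grand normative mean of that feature.

Asymmetry of a bilateral measure is summarized by the asymmetry index
AI = (R - L) / (R + L), in [-1, +1]: -1 for extremely left-dominated, +1
for extremely right-dominated, 0 for complete morphological symmetry. AIs
are computed from raw (un-normalized) values; the eTIV factor cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import ASYMMETRY, LEFT, RIGHT, FeatureKey, assemble_schema

#: eTIV scaling exponent per morphometric parameter. Grey-white contrast is
#: handled by the scanner-group pathway and deliberately absent here.
DEFAULT_EXPONENTS: dict[str, float] = {
    "volume": 1.0,
    "grayvol": 1.0,
    "surfarea": 2.0 / 3.0,
    "thickness": 1.0 / 3.0,
    "thicknessstd": 1.0 / 3.0,
    "meancurv": -1.0 / 3.0,
    "gausscurv": -2.0 / 3.0,
    "curvind": 0.0,
    "foldind": 0.0,
}


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationSpec:
    """Learned normalization parameters, stored inside the normative model.

    ``contrast_reference`` maps contrast feature id -> grand normative mean;
    ``contrast_group_means`` maps feature id -> {scanner_sequence: group mean}.
    """

    reference_etiv: float
    exponent_by_parameter: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPONENTS)
    )
    contrast_reference: dict[str, float] = field(default_factory=dict)
    contrast_group_means: dict[str, dict[str, float]] = field(default_factory=dict)
    contrast_group_counts: dict[str, int] = field(default_factory=dict)

    def exponent(self, parameter: str) -> float:
        return self.exponent_by_parameter.get(parameter, 0.0)

    def to_dict(self) -> dict:
        return {
            "reference_etiv": self.reference_etiv,
            "exponent_by_parameter": self.exponent_by_parameter,
            "contrast_reference": self.contrast_reference,
            "contrast_group_means": self.contrast_group_means,
            "contrast_group_counts": self.contrast_group_counts,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "NormalizationSpec":
        return cls(
            reference_etiv=float(data["reference_etiv"]),
            exponent_by_parameter={k: float(v) for k, v in data["exponent_by_parameter"].items()},
            contrast_reference={k: float(v) for k, v in data["contrast_reference"].items()},
            contrast_group_means={
                k: {g: float(m) for g, m in v.items()}
                for k, v in data["contrast_group_means"].items()
            },
            contrast_group_counts={
                g: int(n) for g, n in data.get("contrast_group_counts", {}).items()
            },
        )


def normalize_to_etiv(value, etiv, n: float, reference_etiv: float):
    """Isometric head-size normalization ``value * (reference_etiv/etiv)**n``."""
    etiv = np.asarray(etiv, dtype=float)
    if np.any(etiv <= 0) or reference_etiv <= 0:
        raise NormalizationError("etiv and reference_etiv must be positive")
    return np.asarray(value, dtype=float) * (reference_etiv / etiv) ** n


def asymmetry_index(left, right):
    """AI = (R - L) / (R + L); antisymmetric under hemisphere swap.

    Undefined (NaN) where both sides are zero.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise NormalizationError("asymmetry index requires nonnegative inputs")
    total = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(total > 0, (right - left) / np.where(total > 0, total, 1.0), np.nan)
    if ai.ndim == 0:
        return float(ai)
    return ai


def reference_etiv_of(etivs) -> float:
    """Reference head size = geometric mean of normative eTIVs."""
    etivs = np.asarray(etivs, dtype=float)
    if np.any(etivs <= 0):
        raise NormalizationError("eTIVs must be positive")
    return float(np.exp(np.mean(np.log(etivs))))


def compute_asymmetry_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Append AI columns for every bilateral feature present left and right.

    Entries with invalid inputs (negative or zero-total sides) become NaN
    rather than failing the whole cohort.
    """
    schema = assemble_schema()
    out = {}
    for key in schema.asymmetry_keys:
        lid = FeatureKey(key.region, key.parameter, LEFT).id
        rid = FeatureKey(key.region, key.parameter, RIGHT).id
        if lid in frame.columns and rid in frame.columns:
            left = frame[lid].to_numpy(dtype=float)
            right = frame[rid].to_numpy(dtype=float)
            valid = (left >= 0) & (right >= 0) & (left + right > 0)
            total = np.where(valid, left + right, 1.0)
            out[key.id] = np.where(valid, (right - left) / total, np.nan)
    result = frame.copy()
    if out:
        result = pd.concat([result, pd.DataFrame(out, index=frame.index)], axis=1)
    return result


def fit_contrast_reference(
    frame: pd.DataFrame, min_group_size: int = 2
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Learn grand and per-scanner-sequence means of all contrast features."""
    schema = assemble_schema()
    contrast_ids = [
        k.id for k in schema.contrast_keys() if k.side != ASYMMETRY and k.id in frame.columns
    ]
    reference: dict[str, float] = {}
    group_means: dict[str, dict[str, float]] = {}
    groups = frame.groupby("scanner_sequence")
    sizes = groups.size()
    small = sizes[sizes < min_group_size]
    if len(small):
        import logging

        logging.getLogger(__name__).warning(
            "scanner-sequence groups with < %d scans: %s", min_group_size, list(small.index)
        )
    for fid in contrast_ids:
        reference[fid] = float(frame[fid].mean())
        group_means[fid] = {str(g): float(v) for g, v in groups[fid].mean().items()}
    return reference, group_means


def contrast_normalize(
    values, feature_id: str, scanner_sequence, spec: NormalizationSpec
):
    """Rescale contrast values so each scanner-sequence group mean matches
    the grand normative mean of the feature.

    At scoring time an unseen scanner_sequence raises, advising a
    closest-group fallback flag rather than silently mis-normalizing.
    """
    if feature_id not in spec.contrast_reference:
        raise NormalizationError(f"no contrast reference for {feature_id}")
    reference = spec.contrast_reference[feature_id]
    groups = spec.contrast_group_means[feature_id]
    values = np.asarray(values, dtype=float)
    seq = np.asarray(scanner_sequence)
    if seq.ndim == 0:
        seq = seq.reshape(1)
        scalar = True
    else:
        scalar = False
    out = np.empty(len(seq) if values.ndim else 1, dtype=float)
    vals = np.broadcast_to(values, out.shape)
    for i, g in enumerate(seq):
        g = str(g)
        if g not in groups:
            raise NormalizationError(
                f"unseen scanner_sequence {g!r} for {feature_id}; re-fit the model "
                "with this group or map the scan to the closest known group and "
                "flag the report"
            )
        mean = groups[g]
        out[i] = vals[i] * (reference / mean if mean != 0 else 1.0)
    return float(out[0]) if scalar else out


def normalize_frame(frame: pd.DataFrame, spec: NormalizationSpec) -> pd.DataFrame:
    """eTIV-/contrast-normalize all measured feature columns of a cohort table.

    Asymmetry columns, if present, are carried through unchanged (AIs are
    scale-free by construction).
    """
    schema = assemble_schema()
    etiv = frame["etiv"].to_numpy(dtype=float)
    out = frame.copy()
    for col in frame.columns:
        if "|" not in col:
            continue
        key = FeatureKey.from_id(col)
        if key.side == ASYMMETRY:
            continue
        if key.parameter == "pctmean":
            out[col] = contrast_normalize(
                frame[col].to_numpy(dtype=float),
                col,
                frame["scanner_sequence"].to_numpy(),
                spec,
            )
        else:
            out[col] = normalize_to_etiv(
                frame[col].to_numpy(dtype=float), etiv, spec.exponent(key.parameter), spec.reference_etiv
            )
    return out
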