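"""Evaluation of automated detections against expert, surgery and EEG
ground truth.

Per dataset, the morphometric detections (regions with condensed score
L_r >= 2) are compared with each available ground-truth source:

* counted *sensitive* when at least one detection is consistent with a
  lesional expert-MRI finding, the resection site (favorable surgical
  outcome, Engel I-II, >= 6 months follow-up) or the EEG lateralization;
* counted *specific*, more strictly, when any of the three most prominent
  detections is consistent.

Consistency can be required at the sublobar (label), lobar or hemispheric
level; the parcellation -> lobe -> hemisphere lookup is a static table
shipped with this module. Overall sensitivities/specificities are the
fraction of consistent datasets among evaluable ones, and per-region
2x2 tables are summarized by the diagnostic odds ratio
DOR = LR+/LR- = (TP*TN)/(FP*FN) (with a +1/2 continuity correction when a
cell is empty) and the prevalence-dependent predictive values PPV/NPV.

Group comparisons use randomization tests (label permutation, default
N = 10,000 resamplings), Fisher's exact test, exact binomial tail tests
against a reference rate, and sequential Kruskal-Wallis followed by
pairwise Mann-Whitney-Wilcoxon tests.

A reference per-dataset match-indicator table from a published 47-scan
temporal-lobe-epilepsy evaluation is bundled for regression testing of the
aggregation arithmetic (:func:`load_reference_match_table`).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fingerprint import RegionScore, top_k
from .schema import GroundTruth

logger = logging.getLogger(__name__)

N_RESAMPLES = 10_000
MATCH_LEVELS = ("sublobar", "lobar", "hemispheric")

# ---------------------------------------------------------------------------
# Static parcellation -> lobe lookup
# ---------------------------------------------------------------------------

LOBES = ("frontal", "temporal", "parietal", "occipital", "insula", "cingulate", "subcortical")

_DK_LOBES = {
    "bankssts": "temporal",
    "caudalanteriorcingulate": "cingulate",
    "caudalmiddlefrontal": "frontal",
    "cuneus": "occipital",
    "entorhinal": "temporal",
    "fusiform": "temporal",
    "inferiorparietal": "parietal",
    "inferiortemporal": "temporal",
    "isthmuscingulate": "cingulate",
    "lateraloccipital": "occipital",
    "lateralorbitofrontal": "frontal",
    "lingual": "occipital",
    "medialorbitofrontal": "frontal",
    "middletemporal": "temporal",
    "parahippocampal": "temporal",
    "paracentral": "frontal",
    "parsopercularis": "frontal",
    "parsorbitalis": "frontal",
    "parstriangularis": "frontal",
    "pericalcarine": "occipital",
    "postcentral": "parietal",
    "posteriorcingulate": "cingulate",
    "precentral": "frontal",
    "precuneus": "parietal",
    "rostralanteriorcingulate": "cingulate",
    "rostralmiddlefrontal": "frontal",
    "superiorfrontal": "frontal",
    "superiorparietal": "parietal",
    "superiortemporal": "temporal",
    "supramarginal": "parietal",
    "frontalpole": "frontal",
    "temporalpole": "temporal",
    "transversetemporal": "temporal",
    "insula": "insula",
}

_DESTRIEUX_LOBES = {
    "G_and_S_frontomargin": "frontal",
    "G_and_S_occipital_inf": "occipital",
    "G_and_S_paracentral": "frontal",
    "G_and_S_subcentral": "frontal",
    "G_and_S_transv_frontopol": "frontal",
    "G_and_S_cingul-Ant": "cingulate",
    "G_and_S_cingul-Mid-Ant": "cingulate",
    "G_and_S_cingul-Mid-Post": "cingulate",
    "G_cingul-Post-dorsal": "cingulate",
    "G_cingul-Post-ventral": "cingulate",
    "G_cuneus": "occipital",
    "G_front_inf-Opercular": "frontal",
    "G_front_inf-Orbital": "frontal",
    "G_front_inf-Triangul": "frontal",
    "G_front_middle": "frontal",
    "G_front_sup": "frontal",
    "G_Ins_lg_and_S_cent_ins": "insula",
    "G_insular_short": "insula",
    "G_occipital_middle": "occipital",
    "G_occipital_sup": "occipital",
    "G_oc-temp_lat-fusifor": "temporal",
    "G_oc-temp_med-Lingual": "occipital",
    "G_oc-temp_med-Parahip": "temporal",
    "G_orbital": "frontal",
    "G_pariet_inf-Angular": "parietal",
    "G_pariet_inf-Supramar": "parietal",
    "G_parietal_sup": "parietal",
    "G_postcentral": "parietal",
    "G_precentral": "frontal",
    "G_precuneus": "parietal",
    "G_rectus": "frontal",
    "G_subcallosal": "cingulate",
    "G_temp_sup-G_T_transv": "temporal",
    "G_temp_sup-Lateral": "temporal",
    "G_temp_sup-Plan_polar": "temporal",
    "G_temp_sup-Plan_tempo": "temporal",
    "G_temporal_inf": "temporal",
    "G_temporal_middle": "temporal",
    "Lat_Fis-ant-Horizont": "frontal",
    "Lat_Fis-ant-Vertical": "frontal",
    "Lat_Fis-post": "temporal",
    "Pole_occipital": "occipital",
    "Pole_temporal": "temporal",
    "S_calcarine": "occipital",
    "S_central": "frontal",
    "S_cingul-Marginalis": "cingulate",
    "S_circular_insula_ant": "insula",
    "S_circular_insula_inf": "insula",
    "S_circular_insula_sup": "insula",
    "S_collat_transv_ant": "temporal",
    "S_collat_transv_post": "occipital",
    "S_front_inf": "frontal",
    "S_front_middle": "frontal",
    "S_front_sup": "frontal",
    "S_interm_prim-Jensen": "parietal",
    "S_intrapariet_and_P_trans": "parietal",
    "S_oc_middle_and_Lunatus": "occipital",
    "S_oc_sup_and_transversal": "occipital",
    "S_occipital_ant": "occipital",
    "S_oc-temp_lat": "temporal",
    "S_oc-temp_med_and_Lingual": "temporal",
    "S_orbital_lateral": "frontal",
    "S_orbital_med-olfact": "frontal",
    "S_orbital-H_Shaped": "frontal",
    "S_parieto_occipital": "parietal",
    "S_pericallosal": "cingulate",
    "S_postcentral": "parietal",
    "S_precentral-inf-part": "frontal",
    "S_precentral-sup-part": "frontal",
    "S_suborbital": "frontal",
    "S_subparietal": "parietal",
    "S_temporal_inf": "temporal",
    "S_temporal_sup": "temporal",
    "S_temporal_transverse": "temporal",
}

_VOLUME_LOBES = {
    "hippocampus": "temporal",
    "amygdala": "temporal",
    "thalamus": "subcortical",
    "caudate": "subcortical",
    "putamen": "subcortical",
    "pallidum": "subcortical",
    "accumbens": "subcortical",
    "ventral_dc": "subcortical",
    "lateral_ventricle": "subcortical",
    "inferior_lateral_ventricle": "temporal",
}

LOBE_OF: dict[str, str] = {**_DK_LOBES, **_DESTRIEUX_LOBES, **_VOLUME_LOBES}


def lobe_of(region: str) -> str | None:
    """Lobe of a parcellation/segmentation label (None for global/other)."""
    return LOBE_OF.get(region)


# ---------------------------------------------------------------------------
# Dataset-level match indicators
# ---------------------------------------------------------------------------

NOT_APPLICABLE = float("nan")


def _matches(detection: RegionScore, targets: set[tuple[str, str]], level: str) -> bool:
    if detection.hemisphere is None:
        return False
    if level == "hemispheric":
        return any(h == detection.hemisphere for h, _ in targets)
    if level == "lobar":
        dl = lobe_of(detection.region)
        return any(
            h == detection.hemisphere and dl is not None and lobe_of(r) == dl
            for h, r in targets
        )
    if level == "sublobar":
        return any(h == detection.hemisphere and r == detection.region for h, r in targets)
    raise ValueError(f"unknown level {level!r}; expected one of {MATCH_LEVELS}")


def _gt_targets(gt: GroundTruth, source: str) -> set[tuple[str, str]] | None:
    """Target (hemisphere, region) set for a GT source; None when unavailable."""
    if source == "expert":
        return set(gt.expert_regions) if gt.expert_regions else None
    if source == "surgery":
        if not gt.surgery_evaluable:
            return None
        hemisphere, _, labels = gt.resection
        return {(hemisphere, label) for label in labels}
    if source == "eeg":
        if gt.eeg_lateralization not in ("left", "right"):
            return None
        return {(gt.eeg_lateralization, "")}
    raise ValueError(f"unknown ground-truth source {source!r}")


_SOURCE_LEVEL = {"expert": "sublobar", "surgery": "sublobar", "eeg": "hemispheric"}


def dataset_sensitivity(
    detections: Sequence[RegionScore], gt: GroundTruth, source: str, level: str | None = None
) -> float:
    """1 if any detection is consistent with the GT source, 0 otherwise;
    NaN (not applicable) when the source is unavailable for the dataset."""
    targets = _gt_targets(gt, source)
    if targets is None:
        return NOT_APPLICABLE
    level = level or _SOURCE_LEVEL[source]
    return float(any(_matches(d, targets, level) for d in detections))


def dataset_specificity(
    detections: Sequence[RegionScore], gt: GroundTruth, source: str, level: str | None = None
) -> float:
    """As :func:`dataset_sensitivity` but restricted to the top-3 detections."""
    targets = _gt_targets(gt, source)
    if targets is None:
        return NOT_APPLICABLE
    level = level or _SOURCE_LEVEL[source]
    return float(any(_matches(d, targets, level) for d in top_k(detections, 3)))


def expert_eeg_agreement(gt: GroundTruth) -> float:
    """1 when the expert-MRI lateralization contains the EEG side."""
    if not gt.expert_regions or gt.eeg_lateralization not in ("left", "right"):
        return NOT_APPLICABLE
    hemispheres = {h for h, _ in gt.expert_regions}
    return float(gt.eeg_lateralization in hemispheres)


MATCH_COLUMNS = (
    "sens_expert",
    "sens_surgery",
    "sens_eeg",
    "spec_expert",
    "spec_surgery",
    "spec_eeg",
    "agreement",
)


def match_table(
    detections_by_dataset: Mapping[str, Sequence[RegionScore]],
    ground_truths: Sequence[GroundTruth],
    level: str | None = None,
) -> pd.DataFrame:
    """Per-dataset sensitive/specific indicators vs. each GT source.

    Rows are datasets; indicator cells are 1.0, 0.0 or NaN (source not
    available / not applicable). Datasets without detections data (failed
    quality control) keep all-NaN morphometry columns but may still carry
    the expert-vs-EEG agreement indicator.
    """
    rows = []
    for gt in ground_truths:
        det = detections_by_dataset.get(gt.dataset_id)
        row: dict[str, object] = {
            "dataset_id": gt.dataset_id,
            "patient_id": gt.patient_id,
            "subtype": gt.subtype,
        }
        for source in ("expert", "surgery", "eeg"):
            if det is None:
                row[f"sens_{source}"] = NOT_APPLICABLE
                row[f"spec_{source}"] = NOT_APPLICABLE
            else:
                row[f"sens_{source}"] = dataset_sensitivity(det, gt, source, level)
                row[f"spec_{source}"] = dataset_specificity(det, gt, source, level)
        row["agreement"] = expert_eeg_agreement(gt)
        rows.append(row)
    return pd.DataFrame(rows, columns=["dataset_id", "patient_id", "subtype", *MATCH_COLUMNS])


def aggregate(table: pd.DataFrame, column: str) -> float:
    """Fraction of consistent datasets among evaluable ones for one column."""
    values = pd.to_numeric(table[column], errors="coerce").dropna()
    if values.empty:
        raise ValueError(f"no evaluable dataset for {column!r}")
    return float(values.mean())


def aggregate_counts(table: pd.DataFrame, column: str) -> tuple[int, int]:
    values = pd.to_numeric(table[column], errors="coerce").dropna()
    return int(values.sum()), int(len(values))


def load_reference_match_table() -> pd.DataFrame:
    """Bundled reference match-indicator table (47 TLE MRI datasets)."""
    ref = importlib.resources.files("morphonorm.data").joinpath("tle_match_table.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "patient_id": str})


def surgery_overlap_by_consistency(table: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Resection overlap of surgery datasets split by whether the patient's
    expert-MRI and EEG readings agree.

    A patient counts as *consistent* (agreement 1) or *equivocal*
    (agreement 0) from any of their datasets carrying the indicator;
    patients without an agreement determination are reported separately.
    Overlap uses the top-3 (specific) surgery indicator.
    """
    agreement_of: dict[str, float] = {}
    for _, row in table.iterrows():
        a = pd.to_numeric(pd.Series([row["agreement"]]), errors="coerce").iloc[0]
        if pd.notna(a) and row["patient_id"] not in agreement_of:
            agreement_of[str(row["patient_id"])] = float(a)
    out = {"consistent": [0, 0], "equivocal": [0, 0], "undetermined": [0, 0]}
    for _, row in table.iterrows():
        overlap = pd.to_numeric(pd.Series([row["spec_surgery"]]), errors="coerce").iloc[0]
        if pd.isna(overlap):
            continue
        status = agreement_of.get(str(row["patient_id"]))
        bucket = "undetermined" if status is None else ("consistent" if status == 1.0 else "equivocal")
        out[bucket][0] += int(overlap)
        out[bucket][1] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Regional 2x2 accuracy
# ---------------------------------------------------------------------------


@dataclass
class RegionalAccuracy:
    region: str
    hemisphere: str | None
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def dor(self) -> float:
        return diagnostic_odds_ratio(self.tp, self.fp, self.fn, self.tn)[2]

    @property
    def ppv(self) -> float:
        return predictive_values(self.tp, self.fp, self.fn, self.tn)[0]

    @property
    def npv(self) -> float:
        return predictive_values(self.tp, self.fp, self.fn, self.tn)[1]


def diagnostic_odds_ratio(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    """(LR+, LR-, DOR) of a 2x2 detection table.

    DOR = LR+/LR- = (TP*TN)/(FP*FN); a +1/2 continuity correction is
    applied to every cell when any cell is zero, keeping log(DOR) finite.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fp + fn + tn == 0:
        return (float("nan"),) * 3
    a, b, c, d = (float(x) for x in (tp, fp, fn, tn))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    sens = a / (a + c)
    spec = d / (b + d)
    lr_pos = sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    return lr_pos, lr_neg, (a * d) / (b * c)


def predictive_values(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float]:
    """(PPV, NPV); NaN where the defining column is empty."""
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return float(ppv), float(npv)


def regional_accuracy(
    region_scores_by_dataset: Mapping[str, Sequence[RegionScore]],
    ground_truths: Sequence[GroundTruth],
    source: str = "expert",
    level: str = "sublobar",
) -> list[RegionalAccuracy]:
    """Per-region TP/FP/FN/TN across datasets, vs. one GT source."""
    gts = {gt.dataset_id: gt for gt in ground_truths}
    counts: dict[tuple[str, str | None], list[int]] = {}
    for dataset_id, scores in region_scores_by_dataset.items():
        gt = gts.get(dataset_id)
        if gt is None:
            continue
        targets = _gt_targets(gt, source)
        if targets is None:
            continue
        for score in scores:
            key = (score.region, score.hemisphere)
            cell = counts.setdefault(key, [0, 0, 0, 0])
            truth = _matches(score, targets, level)
            detected = score.detected
            if detected and truth:
                cell[0] += 1
            elif detected and not truth:
                cell[1] += 1
            elif not detected and truth:
                cell[2] += 1
            else:
                cell[3] += 1
    return [
        RegionalAccuracy(region=r, hemisphere=h, tp=c[0], fp=c[1], fn=c[2], tn=c[3])
        for (r, h), c in sorted(counts.items(), key=lambda kv: (kv[0][0], kv[0][1] or ""))
    ]


def write_accuracy(
    table: pd.DataFrame, regional: Sequence[RegionalAccuracy], out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "match_table.tsv", sep="\t", index=False)
    rows = [
        {
            "region": r.region,
            "hemisphere": r.hemisphere or "",
            "tp": r.tp,
            "fp": r.fp,
            "fn": r.fn,
            "tn": r.tn,
            "dor": r.dor,
            "ppv": r.ppv,
            "npv": r.npv,
        }
        for r in regional
    ]
    pd.DataFrame(rows).to_csv(out_dir / "regional_accuracy.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------


def _default_statistic(groups: Sequence[np.ndarray]) -> float:
    if len(groups) == 2:
        return float(np.mean(groups[0]) - np.mean(groups[1]))
    grand = np.mean(np.concatenate(groups))
    return float(sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups))


def randomization_test(
    groups: Sequence[Sequence[float]],
    statistic: Callable[[Sequence[np.ndarray]], float] | None = None,
    n_resamples: int = N_RESAMPLES,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Label-permutation p-value, two-sided by |statistic| symmetrization.

    p = (1 + #{|T*| >= |T|}) / (N + 1), which can never be zero. Degenerate
    data (all observations identical) returns p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0
    stat = statistic or _default_statistic
    observed = abs(stat(arrays))
    sizes = [len(a) for a in arrays]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        resampled = []
        start = 0
        for size in sizes:
            resampled.append(perm[start : start + size])
            start += size
        if abs(stat(resampled)) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_resamples + 1)


def exact_test_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    return float(sps.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def binomial_rate_test(count: int, n: int, p0: float) -> float:
    """Exact binomial upper-tail p of observing >= ``count`` successes in
    ``n`` trials when the reference rate is ``p0``."""
    if not 0 <= count <= n:
        raise ValueError("count must be in [0, n]")
    return float(sps.binom.sf(count - 1, n, p0))


ALPHA_SIGNIFICANT = 0.01
ALPHA_TREND = 0.05


def _band(p: float) -> str:
    if p < ALPHA_SIGNIFICANT:
        return "significant"
    if p < ALPHA_TREND:
        return "trend"
    return "not significant"


@dataclass
class SequentialTestResult:
    kruskal_p: float
    kruskal_band: str
    pairwise: dict[tuple[str, str], tuple[float, str]]


def sequential_group_test(data_by_group: Mapping[str, Sequence[float]]) -> SequentialTestResult:
    """Kruskal-Wallis across groups; pairwise MWW only when the first level
    is at least marginally significant (p < 0.05).

    Decisions use alpha = 0.01; 0.01 <= p < 0.05 is labeled a trend.
    Groups with fewer than two observations are excluded with a warning.
    """
    usable = {}
    for name, values in data_by_group.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 2:
            logger.warning("group %s has < 2 observations; excluded", name)
            continue
        usable[name] = values
    if len(usable) < 2:
        raise ValueError("need at least two usable groups")
    names = sorted(usable)
    pooled = np.concatenate([usable[n] for n in names])
    if np.all(pooled == pooled[0]):
        kw_p = 1.0
    else:
        kw_p = float(sps.kruskal(*[usable[n] for n in names]).pvalue)
    pairwise: dict[tuple[str, str], tuple[float, str]] = {}
    if kw_p < ALPHA_TREND:
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                p = float(sps.mannwhitneyu(usable[a], usable[b], alternative="two-sided").pvalue)
                pairwise[(a, b)] = (p, _band(p))
    return SequentialTestResult(kruskal_p=kw_p, kruskal_band=_band(kw_p), pairwise=pairwise)
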