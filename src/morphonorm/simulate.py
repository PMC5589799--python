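"""Synthetic morphometry cohorts for the full analysis pipeline.

Real inputs to this analysis are MRI-derived morphometric tables; this
module generates statistically matched stand-ins: a normative control
cohort with polynomial age trends, region-specific population spread,
scanner/sequence offsets, repeated scans with measurement error, optional
gross artifact contamination, and temporal-lobe-epilepsy patient cohorts
with subtype-specific injected effects plus matching ground truth.

Generative model per measured feature f of subject s at age a:

    x = [ base_f(a) + sigma_f * u_{s,f} + offset_{scanner,f}
          + effect + sigma_f * mfrac * eps ] * c_{scanner,f} * (etiv/ref)^n_f

* ``base_f(a)`` is a per-feature polynomial (order 0-2) around a realistic
  parameter-specific baseline;
* ``u_{s,f}`` is a persistent standard-normal subject effect, correlated
  0.9 between hemispheres of the same structure so asymmetry indices have
  realistically small spread;
* ``mfrac`` (default 0.4) sets the scan-rescan measurement error as a
  fraction of the between-subject SD; repeated scans share ``u`` and draw
  new ``eps``;
* additive scanner offsets (SD 0.1 sigma) model hardware differences;
  grey-white contrast instead gets a multiplicative per-scanner factor
  ``c`` (all other features have c = 1), mirroring its sequence
  dependence;
* the head-size factor uses the same isometric exponents the
  normalization step assumes, so eTIV normalization can remove it
  exactly; eTIV is sex-dependent log-normal;
* injected subtype effects are expressed in units of the feature's null
  width sigma_f * sqrt(1 + mfrac^2);
* with probability ``artifact_rate`` a value is displaced by a gross
  6-12 sigma outlier (a segmentation failure stand-in).

Defaults (300 control subjects of whom 40 are rescanned within three
years, ages 7-79; patients aged 18-76; four TLE subtypes with unilateral
mesiotemporal atrophy for MTLE-HS and lateral temporal cortical changes
for LTLE) mirror the study scale this package is designed around.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .normalization import DEFAULT_EXPONENTS
from .schema import (
    GLOBAL,
    LEFT,
    RIGHT,
    SURFACE_REGIONS,
    VOLUME,
    FeatureKey,
    GroundTruth,
    assemble_schema,
)

SUBTYPES = ("MTLE-HS-left", "MTLE-HS-right", "LTLE-left", "LTLE-right")

AGE_PIVOT = 43.0  # years; trend polynomials are centered here
AGE_DECADE = 10.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic test-bed (defaults are the
    conditions every acceptance-level simulation uses)."""

    seed: int = 0
    population_seed: int = 20170907  # fixes the synthetic "population biology"
    n_controls: int = 300
    n_repeat_pairs: int = 40
    age_range: tuple[float, float] = (7.0, 79.0)
    patient_age_range: tuple[float, float] = (18.0, 76.0)
    scanners: tuple[tuple[str, float], ...] = (
        ("scanner_A_mprage", 0.40),
        ("scanner_B_mprage", 0.35),
        ("scanner_C_spgr", 0.25),
    )
    scanner_offset_sd: float = 0.10  # additive, in units of sigma_b
    contrast_scanner_sd: float = 0.05  # multiplicative log-SD for contrast
    measurement_frac: float = 0.4  # sigma_m / sigma_b
    lr_correlation: float = 0.9
    artifact_rate: float = 0.01
    artifact_magnitude: tuple[float, float] = (6.0, 12.0)
    reference_etiv: float = 1475.0
    n_patients: int = 10  # per subtype
    effect_scale: float = 1.0
    discordance_rate: float = 0.1  # EEG non-lateralizing fraction
    surgery_fraction: float = 0.4
    favorable_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_rate <= 0.2:
            raise ValueError("artifact_rate must be in [0, 0.2]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("age_range", "patient_age_range", "artifact_magnitude"):
            if key in data:
                data[key] = tuple(data[key])
        if "scanners" in data:
            data["scanners"] = tuple((str(n), float(w)) for n, w in data["scanners"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Subtype effect templates (left-sided; right is mirrored)
# ---------------------------------------------------------------------------

_MTLE_EFFECTS = [
    ("hippocampus", VOLUME, -4.0),
    ("amygdala", VOLUME, -1.5),
    ("pallidum", VOLUME, -1.0),
    ("putamen", VOLUME, -0.8),
    ("superiortemporal", "thickness", -2.0),
    ("middletemporal", "thickness", -2.0),
    ("entorhinal", "thickness", -2.0),
    ("parahippocampal", "thickness", -2.0),
    ("fusiform", "thickness", -2.0),
    ("G_temp_sup-Lateral", "thickness", -2.0),
    ("G_oc-temp_med-Parahip", "thickness", -2.0),
    ("Pole_temporal", "thickness", -2.0),
    ("G_temp_sup-Plan_polar", "grayvol", -1.5),
]

_LTLE_EFFECTS = [
    ("superiortemporal", "thickness", -4.0),
    ("superiortemporal", "grayvol", -3.5),
    ("superiortemporal", "surfarea", -2.5),
    ("middletemporal", "thickness", -4.0),
    ("middletemporal", "grayvol", -3.5),
    ("middletemporal", "surfarea", -2.5),
    ("G_temp_sup-Lateral", "thickness", -4.0),
    ("G_temp_sup-Lateral", "grayvol", -3.5),
    ("G_temp_sup-Lateral", "surfarea", -2.5),
    ("G_temporal_middle", "thickness", -4.0),
    ("G_temporal_middle", "grayvol", -3.5),
    ("G_temporal_middle", "surfarea", -2.5),
    ("inferiortemporal", "thickness", -2.0),
    ("S_temporal_sup", "thickness", -2.0),
]

_MTLE_RESECTION = (
    "hippocampus",
    "amygdala",
    "entorhinal",
    "parahippocampal",
    "G_oc-temp_med-Parahip",
    "Pole_temporal",
)
_LTLE_RESECTION = (
    "superiortemporal",
    "middletemporal",
    "inferiortemporal",
    "transversetemporal",
    "G_temp_sup-Lateral",
    "G_temporal_middle",
    "G_temporal_inf",
    "S_temporal_sup",
)


@dataclass(frozen=True)
class SubtypeTemplate:
    name: str
    hemisphere: str
    effects: tuple[tuple[str, str, str, float], ...]  # (region, parameter, side, size)
    expert_regions: frozenset[tuple[str, str]]
    resection_labels: tuple[str, ...]


def _template(name: str) -> SubtypeTemplate:
    base, hemisphere = name.rsplit("-", 1)
    effects = _MTLE_EFFECTS if base == "MTLE-HS" else _LTLE_EFFECTS
    resection = _MTLE_RESECTION if base == "MTLE-HS" else _LTLE_RESECTION
    expert = (
        {"hippocampus", "amygdala"} if base == "MTLE-HS" else {"superiortemporal", "middletemporal"}
    )
    return SubtypeTemplate(
        name=name,
        hemisphere=hemisphere,
        effects=tuple((r, p, hemisphere, s) for r, p, s in effects),
        expert_regions=frozenset((hemisphere, r) for r in expert),
        resection_labels=resection,
    )


SUBTYPE_TEMPLATES: dict[str, SubtypeTemplate] = {name: _template(name) for name in SUBTYPES}


# ---------------------------------------------------------------------------
# Population (fixed by population_seed, independent of cohort sampling)
# ---------------------------------------------------------------------------

_BASELINES_VOLUME = {  # ml, bilateral structures (per hemisphere)
    "hippocampus": 4.1,
    "amygdala": 1.6,
    "thalamus": 7.5,
    "caudate": 3.6,
    "putamen": 5.2,
    "pallidum": 1.8,
    "accumbens": 0.6,
    "ventral_dc": 4.0,
    "lateral_ventricle": 8.0,
    "inferior_lateral_ventricle": 0.5,
    "cerebellum_cortex": 53.0,
    "cerebellum_white_matter": 14.0,
    "cerebral_white_matter": 230.0,
    "cerebral_cortex": 240.0,
}
_BASELINES_GLOBAL = {  # ml
    "third_ventricle": 1.0,
    "fourth_ventricle": 1.7,
    "brainstem": 21.0,
    "csf_segmentation": 1.1,
    "optic_chiasm": 0.2,
    "cc_posterior": 0.95,
    "cc_mid_posterior": 0.45,
    "cc_central": 0.5,
    "cc_mid_anterior": 0.45,
    "cc_anterior": 0.9,
    "total_csf": 380.0,
    "total_gray_matter": 620.0,
    "total_white_matter": 480.0,
    "brain_volume": 1100.0,
    "intracranial_volume": 1475.0,
    "supratentorial_volume": 1000.0,
    "subcortical_gray_volume": 58.0,
    "ventricle_choroid_volume": 20.0,
}
_VENTRICULAR = {
    "lateral_ventricle",
    "inferior_lateral_ventricle",
    "third_ventricle",
    "fourth_ventricle",
    "total_csf",
    "csf_segmentation",
    "ventricle_choroid_volume",
}

#: between-subject coefficient of variation per parameter
_CV = {
    VOLUME: 0.07,
    "grayvol": 0.08,
    "surfarea": 0.08,
    "thickness": 0.04,
    "thicknessstd": 0.08,
    "meancurv": 0.08,
    "gausscurv": 0.10,
    "curvind": 0.12,
    "foldind": 0.10,
    "pctmean": 0.05,
}


class SyntheticPopulation:
    """Deterministic per-feature generative parameters.

    All structural choices (baselines, spreads, trend shapes, scanner
    offsets, subtype templates) are drawn once from ``population_seed`` and
    are therefore identical across cohorts sampled with different ``seed``
    values -- patients and controls come from the same population.
    """

    def __init__(self, config: GeneratorConfig):
        self.config = config
        schema = assemble_schema()
        self.measured_keys = schema.measured_keys
        self.ids = [k.id for k in self.measured_keys]
        self.index = {fid: i for i, fid in enumerate(self.ids)}
        F = len(self.ids)

        # feature -> (region, parameter) group and side code
        groups: dict[tuple[str, str], int] = {}
        self.group_idx = np.zeros(F, dtype=int)
        self.side_code = np.zeros(F, dtype=int)  # 0 left, 1 right, 2 global
        for i, key in enumerate(self.measured_keys):
            g = (key.region, key.parameter)
            self.group_idx[i] = groups.setdefault(g, len(groups))
            self.side_code[i] = {LEFT: 0, RIGHT: 1, GLOBAL: 2}[key.side]
        self.n_groups = len(groups)

        rng = np.random.default_rng(config.population_seed)
        g_base = np.zeros(self.n_groups)
        g_s1 = np.zeros(self.n_groups)
        g_s2 = np.zeros(self.n_groups)
        region_factor = {r: float(np.exp(rng.normal(0.0, 0.35))) for r in SURFACE_REGIONS}
        thickness_of = {r: float(np.clip(rng.normal(2.5, 0.2), 2.0, 3.1)) for r in SURFACE_REGIONS}
        for (region, parameter), gi in groups.items():
            if parameter == VOLUME:
                base = _BASELINES_VOLUME.get(region, _BASELINES_GLOBAL.get(region))
            else:
                u = region_factor[region]
                if parameter == "surfarea":
                    base = 1800.0 * u
                elif parameter == "grayvol":
                    base = 1800.0 * u * thickness_of[region] / 1000.0
                elif parameter == "thickness":
                    base = thickness_of[region]
                elif parameter == "thicknessstd":
                    base = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
                elif parameter == "meancurv":
                    base = float(np.clip(rng.normal(0.125, 0.02), 0.07, 0.2))
                elif parameter == "gausscurv":
                    base = float(np.clip(rng.normal(0.025, 0.006), 0.01, 0.05))
                elif parameter == "curvind":
                    base = 2.5 * u
                elif parameter == "foldind":
                    base = 15.0 * u
                else:  # pctmean
                    base = float(np.clip(rng.normal(20.0, 1.5), 15.0, 25.0))
            g_base[gi] = base
            # age-trend shape in units of sigma_b per decade around AGE_PIVOT
            order = rng.choice([0, 1, 2], p=[0.15, 0.55, 0.30])
            growing = region in _VENTRICULAR
            if order >= 1:
                g_s1[gi] = rng.normal(+0.5 if growing else -0.30, 0.12)
            if order >= 2:
                g_s2[gi] = rng.normal(+0.08 if growing else -0.08, 0.04)

        self.baseline = g_base[self.group_idx]
        cv = np.array([_CV[k.parameter] for k in self.measured_keys])
        self.sigma_b = cv * np.abs(self.baseline)
        self.s1 = g_s1[self.group_idx]
        self.s2 = g_s2[self.group_idx]
        self.exponent = np.array(
            [DEFAULT_EXPONENTS.get(k.parameter, 0.0) for k in self.measured_keys]
        )
        self.is_contrast = np.array([k.parameter == "pctmean" for k in self.measured_keys])

        scanner_names = [name for name, _ in config.scanners]
        self.scanner_names = scanner_names
        self.scanner_weights = np.array([w for _, w in config.scanners], dtype=float)
        self.scanner_weights /= self.scanner_weights.sum()
        self.offsets = rng.normal(
            0.0, config.scanner_offset_sd, size=(len(scanner_names), F)
        ) * self.sigma_b[None, :]
        self.offsets[:, self.is_contrast] = 0.0
        g_contrast = np.exp(
            rng.normal(0.0, config.contrast_scanner_sd, size=(len(scanner_names), self.n_groups))
        )
        self.contrast_factor = np.where(
            self.is_contrast[None, :], g_contrast[:, self.group_idx], 1.0
        )

    # -- helpers -------------------------------------------------------------

    @property
    def null_width(self) -> np.ndarray:
        """sigma_b * sqrt(1 + measurement_frac^2): the spread a single new
        scan's residual has around the age trend (at reference head size)."""
        return self.sigma_b * np.sqrt(1.0 + self.config.measurement_frac**2)

    def trend(self, ages) -> np.ndarray:
        """Trend matrix (n_ages x n_features) at reference head size."""
        x = (np.atleast_1d(np.asarray(ages, dtype=float)) - AGE_PIVOT) / AGE_DECADE
        return (
            self.baseline[None, :]
            + self.sigma_b[None, :] * (self.s1[None, :] * x[:, None] + self.s2[None, :] * x[:, None] ** 2)
        )

    def subject_effects(self, n_subjects: int, rng: np.random.Generator) -> np.ndarray:
        """Persistent per-subject effects (n_subjects x F) with left/right
        correlation ``lr_correlation`` within each (region, parameter)."""
        rho = self.config.lr_correlation
        shared = rng.standard_normal((n_subjects, self.n_groups))
        indep = rng.standard_normal((n_subjects, len(self.ids)))
        u = np.sqrt(rho) * shared[:, self.group_idx] + np.sqrt(1.0 - rho) * indep
        is_global = self.side_code == 2
        u[:, is_global] = shared[:, self.group_idx[is_global]]
        return u

    def effect_vector(self, template: SubtypeTemplate, scale: float) -> np.ndarray:
        """Additive injected effect per feature, in measurement units."""
        effect = np.zeros(len(self.ids))
        width = self.null_width
        for region, parameter, side, size in template.effects:
            fid = FeatureKey(region, parameter, side).id
            if fid not in self.index:
                raise KeyError(f"effect target {fid} not in catalog")
            effect[self.index[fid]] += scale * size * width[self.index[fid]]
        return effect


def _scan_values(
    pop: SyntheticPopulation,
    ages: np.ndarray,
    subject_u: np.ndarray,
    scanner_idx: np.ndarray,
    etiv: np.ndarray,
    rng: np.random.Generator,
    effect: np.ndarray | None = None,
) -> np.ndarray:
    cfg = pop.config
    base = pop.trend(ages)
    values = base + pop.sigma_b[None, :] * subject_u + pop.offsets[scanner_idx]
    if effect is not None:
        values = values + effect[None, :]
    values = values + cfg.measurement_frac * pop.sigma_b[None, :] * rng.standard_normal(values.shape)
    values = values * pop.contrast_factor[scanner_idx]
    head = (etiv[:, None] / cfg.reference_etiv) ** pop.exponent[None, :]
    values = values * head
    if cfg.artifact_rate > 0:
        mask = rng.random(values.shape) < cfg.artifact_rate
        lo, hi = cfg.artifact_magnitude
        shift = rng.uniform(lo, hi, size=values.shape) * np.where(rng.random(values.shape) < 0.5, -1.0, 1.0)
        values = values + mask * shift * pop.sigma_b[None, :] * head
        # segmentation failures produce wrong, but still physical, values
        values = np.maximum(values, 0.02 * np.abs(pop.baseline)[None, :])
    return values


def _sample_subjects(
    pop: SyntheticPopulation, n: int, age_range: tuple[float, float], rng: np.random.Generator
):
    ages = rng.uniform(*age_range, size=n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    etiv_mean = np.where(sex == "male", np.log(1550.0), np.log(1400.0))
    etiv = np.exp(rng.normal(etiv_mean, 0.07))
    scanner_idx = rng.choice(len(pop.scanner_names), size=n, p=pop.scanner_weights)
    return ages, sex, etiv, scanner_idx


def _frame(pop, subject_ids, session_ids, ages, sex, scanner_idx, etiv, values) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "session_id": session_ids,
            "age": ages,
            "sex": sex,
            "scanner_sequence": [pop.scanner_names[i] for i in scanner_idx],
            "etiv": etiv,
        }
    )
    return pd.concat([meta, pd.DataFrame(values, columns=pop.ids)], axis=1)


def generate_controls(config: GeneratorConfig) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Normative cohort table plus repeat-pair session links.

    The first ``n_repeat_pairs`` subjects receive a second scan 0.3-2.5
    years after the first (same subject effects, scanner and eTIV; fresh
    measurement noise). Reproducible bit-for-bit under a fixed config.
    """
    pop = SyntheticPopulation(config)
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_controls
    ages, sex, etiv, scanner_idx = _sample_subjects(pop, n, config.age_range, rng)
    u = pop.subject_effects(n, rng)

    n_rep = min(config.n_repeat_pairs, n)
    gaps = rng.uniform(0.3, 2.5, size=n_rep)

    all_ages = np.concatenate([ages, ages[:n_rep] + gaps])
    subj_rows = np.concatenate([np.arange(n), np.arange(n_rep)])
    values = _scan_values(
        pop, all_ages, u[subj_rows], scanner_idx[subj_rows], etiv[subj_rows], rng
    )
    subject_ids = [f"HC{i:04d}" for i in subj_rows]
    session = np.concatenate([np.ones(n, dtype=int), np.full(n_rep, 2, dtype=int)])
    session_ids = [f"HC{i:04d}_s{s}" for i, s in zip(subj_rows, session)]
    frame = _frame(
        pop, subject_ids, session_ids, all_ages, sex[subj_rows], scanner_idx[subj_rows],
        etiv[subj_rows], values,
    )
    pairs = [(f"HC{i:04d}_s1", f"HC{i:04d}_s2") for i in range(n_rep)]
    return frame, pairs


def generate_patients(
    config: GeneratorConfig,
    subtype: str,
    n: int | None = None,
    n_repeats: int = 0,
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Patient cohort of one TLE subtype plus ground-truth annotations.

    Injected effects follow the subtype template scaled by
    ``config.effect_scale`` (0 gives null patients statistically identical
    to controls). EEG lateralization equals the injected hemisphere except
    for a ``discordance_rate`` fraction reported as diffuse; the first
    ``surgery_fraction`` of patients carry a resection covering the
    injected site, with ``favorable_fraction`` of them Engel class I.
    The first ``n_repeats`` patients receive a second scan.
    """
    if subtype not in SUBTYPE_TEMPLATES:
        raise KeyError(f"unknown subtype {subtype!r}; expected one of {SUBTYPES}")
    template = SUBTYPE_TEMPLATES[subtype]
    pop = SyntheticPopulation(config)
    rng = np.random.default_rng([config.seed, 2, SUBTYPES.index(subtype)])
    n = config.n_patients if n is None else n
    ages, sex, etiv, scanner_idx = _sample_subjects(pop, n, config.patient_age_range, rng)
    u = pop.subject_effects(n, rng)
    effect = pop.effect_vector(template, config.effect_scale)

    n_rep = min(n_repeats, n)
    gaps = rng.uniform(0.3, 2.5, size=n_rep)
    all_ages = np.concatenate([ages, ages[:n_rep] + gaps])
    subj_rows = np.concatenate([np.arange(n), np.arange(n_rep)])
    values = _scan_values(
        pop, all_ages, u[subj_rows], scanner_idx[subj_rows], etiv[subj_rows], rng, effect=effect
    )

    tag = subtype.replace("-", "")
    subject_ids = [f"{tag}{i:03d}" for i in subj_rows]
    session = np.concatenate([np.ones(n, dtype=int), np.full(n_rep, 2, dtype=int)])
    session_ids = [f"{tag}{i:03d}_s{s}" for i, s in zip(subj_rows, session)]
    frame = _frame(
        pop, subject_ids, session_ids, all_ages, sex[subj_rows], scanner_idx[subj_rows],
        etiv[subj_rows], values,
    )

    diffuse = rng.random(n) < config.discordance_rate
    n_surgery = int(round(config.surgery_fraction * n))
    favorable = rng.random(n_surgery) < config.favorable_fraction
    gts = []
    for row, i in enumerate(subj_rows):
        resection = None
        engel = None
        followup = None
        if i < n_surgery:
            resection = (template.hemisphere, "temporal", template.resection_labels)
            engel = "I" if favorable[i] else "III"
            followup = 24.0
        gts.append(
            GroundTruth(
                dataset_id=session_ids[row],
                patient_id=f"{tag}{i:03d}",
                subtype=subtype,
                expert_regions=template.expert_regions if config.effect_scale > 0 else frozenset(),
                eeg_lateralization="diffuse" if diffuse[i] else template.hemisphere,
                resection=resection,
                engel_class=engel,
                followup_months=followup,
            )
        )
    return frame, gts


def generate_study(config: GeneratorConfig, n_repeats: int = 0):
    """All four subtype cohorts concatenated, with their ground truths."""
    frames, gts = [], []
    for subtype in SUBTYPES:
        frame, gt = generate_patients(config, subtype, n_repeats=n_repeats)
        frames.append(frame)
        gts.extend(gt)
    return pd.concat(frames, ignore_index=True), gts
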