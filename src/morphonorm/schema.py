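"""Fixed feature catalog and tabular IO for brain-morphometry cohorts.

The analysis operates on a fixed catalog of 2,976 (region, parameter, side)
features per scan:

* 60 volume features: 14 bilateral segmented structures evaluated left,
  right and as an asymmetry index (42 features) plus 18 midline structures
  and whole-brain partial volumes (``side == "global"``);
* 2,916 surface features: 34 Desikan-Killiany and 74 Destrieux cortical
  parcellations per hemisphere, each with 9 surface-based morphometric
  parameters, evaluated left, right and as an asymmetry index
  ((34 + 74) x 3 x 9).

The catalog ordering is deterministic and versioned by this module; two
calls to :func:`assemble_schema` always return identical orderings.

The exact composition of the 60-entry volume block is a documented
convention of this package (segmentation tools expose many more labels than
60); see ``BILATERAL_VOLUME_REGIONS`` and ``GLOBAL_VOLUME_REGIONS``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Catalog constants
# ---------------------------------------------------------------------------

LEFT = "left"
RIGHT = "right"
ASYMMETRY = "asymmetry"
GLOBAL = "global"
SIDES = (LEFT, RIGHT, ASYMMETRY, GLOBAL)
HEMISPHERES = (LEFT, RIGHT)

VOLUME = "volume"

#: The nine surface-based morphometric parameters per cortical parcellation:
#: grey-matter volume, surface area, mean and SD of cortical thickness, mean
#: curvature, Gaussian curvature, curvature index, folding index and mean
#: grey-white percent contrast.
SURFACE_PARAMETERS = (
    "grayvol",
    "surfarea",
    "thickness",
    "thicknessstd",
    "meancurv",
    "gausscurv",
    "curvind",
    "foldind",
    "pctmean",
)

#: Desikan-Killiany cortical atlas, 34 parcellations per hemisphere.
DK_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Destrieux cortical atlas (a2009s), 74 parcellations per hemisphere.
DESTRIEUX_REGIONS = (
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
)

#: Bilateral segmented structures carried as left/right/asymmetry volumes.
BILATERAL_VOLUME_REGIONS = (
    "hippocampus",
    "amygdala",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
    "ventral_dc",
    "lateral_ventricle",
    "inferior_lateral_ventricle",
    "cerebellum_cortex",
    "cerebellum_white_matter",
    "cerebral_white_matter",
    "cerebral_cortex",
)

#: Midline structures and whole-brain partial volumes (one entry each).
GLOBAL_VOLUME_REGIONS = (
    "third_ventricle",
    "fourth_ventricle",
    "brainstem",
    "csf_segmentation",
    "optic_chiasm",
    "cc_posterior",
    "cc_mid_posterior",
    "cc_central",
    "cc_mid_anterior",
    "cc_anterior",
    "total_csf",
    "total_gray_matter",
    "total_white_matter",
    "brain_volume",
    "intracranial_volume",
    "supratentorial_volume",
    "subcortical_gray_volume",
    "ventricle_choroid_volume",
)

SURFACE_ATLASES: dict[str, tuple[str, ...]] = {
    "DK": DK_REGIONS,
    "Destrieux": DESTRIEUX_REGIONS,
}

SURFACE_REGIONS: tuple[str, ...] = DK_REGIONS + DESTRIEUX_REGIONS

ATLAS_OF: dict[str, str] = {r: "DK" for r in DK_REGIONS}
ATLAS_OF.update({r: "Destrieux" for r in DESTRIEUX_REGIONS})

N_FEATURES = 2976
N_SURFACE_FEATURES = (len(DK_REGIONS) + len(DESTRIEUX_REGIONS)) * 3 * len(SURFACE_PARAMETERS)
N_VOLUME_FEATURES = len(BILATERAL_VOLUME_REGIONS) * 3 + len(GLOBAL_VOLUME_REGIONS)


class SchemaError(ValueError):
    """Raised for malformed tables or values outside the feature catalog."""


# ---------------------------------------------------------------------------
# Feature keys and schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class FeatureKey:
    """One (region, parameter, side) entry of the feature catalog."""

    region: str
    parameter: str
    side: str

    @property
    def id(self) -> str:
        return f"{self.region}|{self.parameter}|{self.side}"

    @classmethod
    def from_id(cls, key_id: str) -> "FeatureKey":
        parts = key_id.split("|")
        if len(parts) != 3:
            raise SchemaError(f"malformed feature id {key_id!r}")
        return cls(*parts)

    @property
    def is_surface(self) -> bool:
        return self.parameter != VOLUME

    @property
    def atlas(self) -> str | None:
        return ATLAS_OF.get(self.region)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, versioned catalog of all 2,976 features."""

    entries: tuple[FeatureKey, ...]
    version: str = "1"
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {k.id: i for i, k in enumerate(self.entries)}
        if len(index) != len(self.entries):
            raise SchemaError("duplicate FeatureKey in schema")
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: FeatureKey | str) -> bool:
        key_id = key if isinstance(key, str) else key.id
        return key_id in self._index

    def ids(self) -> list[str]:
        return [k.id for k in self.entries]

    def position(self, key: FeatureKey | str) -> int:
        key_id = key if isinstance(key, str) else key.id
        return self._index[key_id]

    @property
    def surface_keys(self) -> tuple[FeatureKey, ...]:
        return tuple(k for k in self.entries if k.is_surface)

    @property
    def volume_keys(self) -> tuple[FeatureKey, ...]:
        return tuple(k for k in self.entries if not k.is_surface)

    @property
    def measured_keys(self) -> tuple[FeatureKey, ...]:
        """Keys present at ingest (asymmetry entries are computed later)."""
        return tuple(k for k in self.entries if k.side != ASYMMETRY)

    @property
    def asymmetry_keys(self) -> tuple[FeatureKey, ...]:
        return tuple(k for k in self.entries if k.side == ASYMMETRY)

    def contrast_keys(self) -> tuple[FeatureKey, ...]:
        """Grey-white contrast features (normalized per scanner group, not eTIV)."""
        return tuple(k for k in self.entries if k.parameter == "pctmean")


def _build_entries() -> tuple[FeatureKey, ...]:
    entries: list[FeatureKey] = []
    for region in BILATERAL_VOLUME_REGIONS:
        for side in (LEFT, RIGHT, ASYMMETRY):
            entries.append(FeatureKey(region, VOLUME, side))
    for region in GLOBAL_VOLUME_REGIONS:
        entries.append(FeatureKey(region, VOLUME, GLOBAL))
    for atlas in ("DK", "Destrieux"):
        for region in SURFACE_ATLASES[atlas]:
            for side in (LEFT, RIGHT, ASYMMETRY):
                for parameter in SURFACE_PARAMETERS:
                    entries.append(FeatureKey(region, parameter, side))
    return tuple(entries)


_SCHEMA: FeatureSchema | None = None


def assemble_schema() -> FeatureSchema:
    """Return the fixed feature catalog (memoized; always the same object)."""
    global _SCHEMA
    if _SCHEMA is None:
        _SCHEMA = FeatureSchema(entries=_build_entries())
    return _SCHEMA


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

SEXES = ("female", "male")

#: Metadata columns of a cohort table, in canonical order.
METADATA_COLUMNS = ("subject_id", "session_id", "age", "sex", "scanner_sequence", "etiv")


@dataclass
class MorphometricRecord:
    """One scan's raw feature values plus demographics and scanner metadata.

    ``values`` maps feature ids (``region|parameter|side``) to raw,
    un-normalized measurements; asymmetry entries are absent at ingest and
    computed by the normalization step. Metadata may be ``None`` when read
    from bare stats files and filled in later; values are validated when
    present.
    """

    subject_id: str | None = None
    session_id: str | None = None
    age: float | None = None
    sex: str | None = None
    scanner_sequence: str | None = None
    etiv: float | None = None
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise SchemaError(f"age must be positive, got {self.age}")
        if self.etiv is not None and not self.etiv > 0:
            raise SchemaError(f"etiv must be positive, got {self.etiv}")
        if self.sex is not None and self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        schema = assemble_schema()
        for key_id, value in self.values.items():
            key = FeatureKey.from_id(key_id)
            if key.side != ASYMMETRY and key.parameter in ("volume", "grayvol", "surfarea", "thickness", "thicknessstd"):
                if value < 0:
                    raise SchemaError(f"negative value {value} for {key_id}")
            if key_id not in schema:
                raise SchemaError(f"feature {key_id!r} not in schema")


def records_to_frame(records: Sequence[MorphometricRecord]) -> pd.DataFrame:
    """Stack records into a cohort table (one row per scan)."""
    schema = assemble_schema()
    measured = [k.id for k in schema.measured_keys]
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "session_id": rec.session_id,
            "age": rec.age,
            "sex": rec.sex,
            "scanner_sequence": rec.scanner_sequence,
            "etiv": rec.etiv,
        }
        row.update(rec.values)
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = [c for c in METADATA_COLUMNS if c in frame.columns]
    ordered += [c for c in measured if c in frame.columns]
    return frame[ordered]


def frame_to_records(frame: pd.DataFrame) -> list[MorphometricRecord]:
    feature_cols = [c for c in frame.columns if "|" in c]
    records = []
    for _, row in frame.iterrows():
        values = {c: float(row[c]) for c in feature_cols if pd.notna(row[c])}
        records.append(
            MorphometricRecord(
                subject_id=str(row["subject_id"]),
                session_id=str(row["session_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                scanner_sequence=str(row["scanner_sequence"]),
                etiv=float(row["etiv"]),
                values=values,
            )
        )
    return records


def write_cohort_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort table {path} lacks metadata columns {missing}")
    return frame


# ---------------------------------------------------------------------------
# Per-scan stats-file readers (generic TSV is the canonical interchange)
# ---------------------------------------------------------------------------

DIALECTS = ("generic_tsv", "freesurfer_aseg", "freesurfer_aparc")

#: Map from FreeSurfer aseg StructName to (region, side) of this catalog.
FS_ASEG_NAMES: dict[str, tuple[str, str]] = {}
for _region, _fsname in (
    ("hippocampus", "Hippocampus"),
    ("amygdala", "Amygdala"),
    ("thalamus", "Thalamus-Proper"),
    ("caudate", "Caudate"),
    ("putamen", "Putamen"),
    ("pallidum", "Pallidum"),
    ("accumbens", "Accumbens-area"),
    ("ventral_dc", "VentralDC"),
    ("lateral_ventricle", "Lateral-Ventricle"),
    ("inferior_lateral_ventricle", "Inf-Lat-Vent"),
    ("cerebellum_cortex", "Cerebellum-Cortex"),
    ("cerebellum_white_matter", "Cerebellum-White-Matter"),
    ("cerebral_white_matter", "Cerebral-White-Matter"),
    ("cerebral_cortex", "Cerebral-Cortex"),
):
    FS_ASEG_NAMES[f"Left-{_fsname}"] = (_region, LEFT)
    FS_ASEG_NAMES[f"Right-{_fsname}"] = (_region, RIGHT)
FS_ASEG_NAMES.update(
    {
        "3rd-Ventricle": ("third_ventricle", GLOBAL),
        "4th-Ventricle": ("fourth_ventricle", GLOBAL),
        "Brain-Stem": ("brainstem", GLOBAL),
        "CSF": ("csf_segmentation", GLOBAL),
        "Optic-Chiasm": ("optic_chiasm", GLOBAL),
        "CC_Posterior": ("cc_posterior", GLOBAL),
        "CC_Mid_Posterior": ("cc_mid_posterior", GLOBAL),
        "CC_Central": ("cc_central", GLOBAL),
        "CC_Mid_Anterior": ("cc_mid_anterior", GLOBAL),
        "CC_Anterior": ("cc_anterior", GLOBAL),
    }
)

#: aparc.stats columns -> surface parameter names of this catalog.
FS_APARC_COLUMNS = {
    "SurfArea": "surfarea",
    "GrayVol": "grayvol",
    "ThickAvg": "thickness",
    "ThickStd": "thicknessstd",
    "MeanCurv": "meancurv",
    "GausCurv": "gausscurv",
    "FoldInd": "foldind",
    "CurvInd": "curvind",
}


def _parse_generic_tsv(path: Path) -> MorphometricRecord:
    meta: dict[str, object] = {}
    values: dict[str, float] = {}
    schema = assemble_schema()
    seen: set[str] = set()
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*[:=]\s*(.*)", line)
                if m and m.group(1) in METADATA_COLUMNS:
                    meta[m.group(1)] = m.group(2).strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:4] != ["region", "parameter", "side", "value"]:
                    raise SchemaError(
                        f"{path}:{lineno}: malformed header {header!r}; "
                        "expected columns region, parameter, side, value"
                    )
                continue
            if len(fields) != len(header):
                raise SchemaError(f"{path}:{lineno}: expected {len(header)} fields")
            region, parameter, side, raw = fields[:4]
            key = FeatureKey(region, parameter, side)
            if key.id not in schema._index:
                logger.warning("%s:%d: unknown feature %s skipped", path, lineno, key.id)
                continue
            if key.id in seen:
                raise SchemaError(f"{path}:{lineno}: duplicate row for {key.id}")
            seen.add(key.id)
            values[key.id] = float(raw)
    if header is None:
        raise SchemaError(f"{path}: empty file, no header found")
    return MorphometricRecord(
        subject_id=meta.get("subject_id"),
        session_id=meta.get("session_id"),
        age=float(meta["age"]) if "age" in meta else None,
        sex=meta.get("sex"),
        scanner_sequence=meta.get("scanner_sequence"),
        etiv=float(meta["etiv"]) if "etiv" in meta else None,
        values=values,
    )


def _parse_freesurfer_aseg(path: Path) -> MorphometricRecord:
    """Parse an ``aseg.stats``-style whitespace table with '#' headers.

    Volumes are converted from mm^3 to ml (the catalog's canonical unit).
    """
    values: dict[str, float] = {}
    etiv = None
    columns: list[str] | None = None
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*Measure\s+EstimatedTotalIntraCranialVol\b.*?,\s*([\d.eE+-]+)\s*,\s*mm\^?3", line)
                if m:
                    etiv = float(m.group(1)) / 1000.0
                m = re.match(r"#\s*ColHeaders\s+(.*)", line)
                if m:
                    columns = m.group(1).split()
                continue
            if columns is None:
                raise SchemaError(f"{path}:{lineno}: table row before '# ColHeaders' header")
            fields = line.split()
            if len(fields) != len(columns):
                raise SchemaError(f"{path}:{lineno}: expected {len(columns)} columns")
            row = dict(zip(columns, fields))
            name = row.get("StructName")
            if name is None or "Volume_mm3" not in row:
                raise SchemaError(f"{path}:{lineno}: missing StructName/Volume_mm3 column")
            if name not in FS_ASEG_NAMES:
                logger.warning("%s:%d: unknown segmentation %r skipped", path, lineno, name)
                continue
            if name in seen:
                raise SchemaError(f"{path}:{lineno}: duplicate segmentation row {name!r}")
            seen.add(name)
            region, side = FS_ASEG_NAMES[name]
            values[FeatureKey(region, VOLUME, side).id] = float(row["Volume_mm3"]) / 1000.0
    return MorphometricRecord(etiv=etiv, values=values)


def _parse_freesurfer_aparc(path: Path) -> MorphometricRecord:
    values: dict[str, float] = {}
    hemi = None
    columns: list[str] | None = None
    seen: set[str] = set()
    known = set(SURFACE_REGIONS)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*hemi\s+(\w+)", line)
                if m:
                    hemi = {"lh": LEFT, "rh": RIGHT}.get(m.group(1))
                    if hemi is None:
                        raise SchemaError(f"{path}:{lineno}: unknown hemisphere {m.group(1)!r}")
                m = re.match(r"#\s*ColHeaders\s+(.*)", line)
                if m:
                    columns = m.group(1).split()
                continue
            if columns is None or hemi is None:
                raise SchemaError(f"{path}:{lineno}: table row before '# hemi'/'# ColHeaders' headers")
            fields = line.split()
            if len(fields) != len(columns):
                raise SchemaError(f"{path}:{lineno}: expected {len(columns)} columns")
            row = dict(zip(columns, fields))
            name = row.get("StructName")
            if name not in known:
                logger.warning("%s:%d: unknown parcellation %r skipped", path, lineno, name)
                continue
            if name in seen:
                raise SchemaError(f"{path}:{lineno}: duplicate parcellation row {name!r}")
            seen.add(name)
            for col, parameter in FS_APARC_COLUMNS.items():
                if col in row:
                    value = float(row[col])
                    if parameter == "grayvol":
                        value /= 1000.0  # mm^3 -> ml
                    values[FeatureKey(name, parameter, hemi).id] = value
    return MorphometricRecord(values=values)


def read_stats_table(path: str | Path, dialect: str = "generic_tsv") -> MorphometricRecord:
    """Read one scan's morphometry table into a :class:`MorphometricRecord`.

    ``dialect`` selects between the canonical generic TSV (columns region,
    parameter, side, value, metadata in ``# key: value`` comments) and
    FreeSurfer ``aseg.stats`` / ``aparc.stats`` convenience readers. Rows
    whose label is not in the catalog are logged and skipped; duplicated
    rows raise :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in DIALECTS:
        raise SchemaError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "generic_tsv":
        return _parse_generic_tsv(path)
    if dialect == "freesurfer_aseg":
        return _parse_freesurfer_aseg(path)
    return _parse_freesurfer_aparc(path)


def merge_records(*records: MorphometricRecord) -> MorphometricRecord:
    """Merge partial records of the same scan (e.g. aseg + two aparc files)."""
    merged = MorphometricRecord()
    for rec in records:
        for attr in ("subject_id", "session_id", "age", "sex", "scanner_sequence", "etiv"):
            value = getattr(rec, attr)
            if value is not None:
                setattr(merged, attr, value)
        overlap = set(merged.values) & set(rec.values)
        if overlap:
            raise SchemaError(f"records overlap on features {sorted(overlap)[:3]}...")
        merged.values.update(rec.values)
    return merged


def write_record(record: MorphometricRecord, path: str | Path) -> None:
    """Write a record as generic TSV (round-trips with ``read_stats_table``)."""
    with open(path, "w") as fh:
        for attr in METADATA_COLUMNS:
            value = getattr(record, attr)
            if value is not None:
                fh.write(f"# {attr}: {value}\n")
        fh.write("region\tparameter\tside\tvalue\n")
        schema = assemble_schema()
        for key in schema.entries:
            if key.id in record.values:
                fh.write(f"{key.region}\t{key.parameter}\t{key.side}\t{record.values[key.id]!r}\n")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

EEG_LATERALIZATIONS = ("left", "right", "diffuse", "none")
ENGEL_CLASSES = ("I", "II", "III", "IV")
FAVORABLE_ENGEL = ("I", "II")
MIN_FOLLOWUP_MONTHS = 6.0


@dataclass
class GroundTruth:
    """Expert/surgery/EEG annotations for one MRI dataset.

    ``expert_regions`` holds (hemisphere, region-label) pairs with visually
    detectable abnormalities; an empty set encodes a non-lesional expert
    reading. ``resection`` is ``(hemisphere, lobe, sublobar labels)``.
    """

    dataset_id: str
    expert_regions: frozenset[tuple[str, str]] = frozenset()
    eeg_lateralization: str = "none"
    resection: tuple[str, str, tuple[str, ...]] | None = None
    engel_class: str | None = None
    followup_months: float | None = None
    subtype: str | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.eeg_lateralization not in EEG_LATERALIZATIONS:
            raise SchemaError(
                f"unknown EEG lateralization {self.eeg_lateralization!r}; "
                f"expected one of {EEG_LATERALIZATIONS}"
            )
        if self.engel_class is not None and self.engel_class not in ENGEL_CLASSES:
            raise SchemaError(f"unknown Engel class {self.engel_class!r}")
        self.expert_regions = frozenset(self.expert_regions)

    @property
    def surgery_evaluable(self) -> bool:
        """Surgery comparisons require favorable outcome and >= 6 months follow-up."""
        return (
            self.resection is not None
            and self.engel_class in FAVORABLE_ENGEL
            and self.followup_months is not None
            and self.followup_months >= MIN_FOLLOWUP_MONTHS
        )


def write_ground_truth(gts: Sequence[GroundTruth], path: str | Path) -> None:
    rows = []
    for gt in gts:
        res = gt.resection
        rows.append(
            {
                "dataset_id": gt.dataset_id,
                "patient_id": gt.patient_id or "",
                "subtype": gt.subtype or "",
                "expert_regions": ";".join(
                    f"{h}:{r}" for h, r in sorted(gt.expert_regions)
                ),
                "eeg_lateralization": gt.eeg_lateralization,
                "resection_hemisphere": res[0] if res else "",
                "resection_lobe": res[1] if res else "",
                "resection_labels": ";".join(res[2]) if res else "",
                "engel_class": gt.engel_class or "",
                "followup_months": "" if gt.followup_months is None else gt.followup_months,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "dataset_id",
            "patient_id",
            "subtype",
            "expert_regions",
            "eeg_lateralization",
            "resection_hemisphere",
            "resection_lobe",
            "resection_labels",
            "engel_class",
            "followup_months",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        return []
    gts = []
    for _, row in frame.iterrows():
        expert = frozenset(
            tuple(item.split(":", 1)) for item in row["expert_regions"].split(";") if item
        )
        resection = None
        if row.get("resection_hemisphere", ""):
            resection = (
                row["resection_hemisphere"],
                row["resection_lobe"],
                tuple(x for x in row["resection_labels"].split(";") if x),
            )
        gts.append(
            GroundTruth(
                dataset_id=row["dataset_id"],
                patient_id=row.get("patient_id") or None,
                subtype=row.get("subtype") or None,
                expert_regions=expert,
                eeg_lateralization=row["eeg_lateralization"] or "none",
                resection=resection,
                engel_class=row["engel_class"] or None,
                followup_months=float(row["followup_months"]) if row["followup_months"] else None,
            )
        )
    return gts
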