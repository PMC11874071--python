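"""Reading and validation of the pipeline's on-disk inputs.

Three kinds of input are handled:

* 4D resting-state BOLD volumes (NIfTI-1), one per subject;
* an integer-label parcellation volume (NIfTI-1) plus a delimited region
  table (the 90-region AAL configuration ships with the package);
* a phenotype table (CSV/TSV) with demographics, diagnostic group, and
  behavioral scale scores, with configurable column names (ABIDE-style
  defaults).

All tabular outputs elsewhere in the package are TSV with a stable column
order; this module provides the matching writers for the synthetic round
trips.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, LengthError, SchemaError

logger = logging.getLogger(__name__)

#: Behavioral scales carried through the pipeline (ABIDE phenotype column names).
DEFAULT_BEHAVIOR_COLUMNS = {
    "ADI_R_RRB": "ADI_RRB_TOTAL_C",
    "ADI_R_ONSET": "ADI_R_ONSET_TOTAL_D",
    "ADOS2_COMM": "ADOS_COMM",
    "ADOS2_STEREO": "ADOS_STEREO_BEHAV",
    "SRS_COGNITION": "SRS_COGNITION",
    "SRS_COMMUNICATION": "SRS_COMMUNICATION",
    "VABS_EXPRESSIVE": "VINELAND_EXPRESSIVE_V_SCALED",
    "VABS_COMM_STANDARD": "VINELAND_COMMUNICATION_STANDARD",
    "VABS_PERSONAL_DLS": "VINELAND_PERSONAL_V_SCALED",
    "VABS_COMMUNITY_DLS": "VINELAND_COMMUNITY_V_SCALED",
    "VABS_INTERPERSONAL": "VINELAND_INTERPERSONAL_V_SCALED",
    "VABS_SUM": "VINELAND_SUM_SCORES",
}

DEFAULT_COLUMN_MAP = {
    "subject_id": "SUB_ID",
    "group": "DX_GROUP",
    "age": "AGE_AT_SCAN",
    "sex": "SEX",
    "fiq": "FIQ",
    "behavior": DEFAULT_BEHAVIOR_COLUMNS,
}

#: ABIDE codings: DX_GROUP 1 = autism, 2 = control; SEX 1 = male, 2 = female.
GROUP_CODES = {"1": "case", "2": "control", "case": "case", "control": "control",
               "autism": "case", "asd": "case", "td": "control"}
SEX_CODES = {"1": "male", "2": "female", "male": "male", "female": "female",
             "m": "male", "f": "female"}


@dataclass
class BoldVolume:
    """One subject's 4D BOLD image plus the mask of analyzable voxels."""

    data: np.ndarray          # (x, y, z, t) float
    voxel_mask: np.ndarray    # (x, y, z) bool
    subject_id: str

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise FormatError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise LengthError("BOLD volume needs at least 2 timepoints")
        if self.voxel_mask.shape != self.data.shape[:3]:
            raise FormatError("mask shape does not match spatial shape of data")
        masked = self.data[self.voxel_mask]
        if masked.size and not np.all(np.isfinite(masked)):
            raise FormatError("masked voxels contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class Parcellation:
    """Integer-label region volume with its region lookup table."""

    labels: np.ndarray        # (x, y, z) int, 0 = background
    region_table: pd.DataFrame  # columns: region_id, name, hemisphere

    def __post_init__(self) -> None:
        required = {"region_id", "name", "hemisphere"}
        if not required.issubset(self.region_table.columns):
            raise SchemaError(f"region table needs columns {sorted(required)}")
        ids = self.region_table["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ConsistencyError("duplicate region ids in region table")
        present = np.unique(self.labels)
        present = present[present != 0]
        unknown = set(present.tolist()) - set(ids.tolist())
        if unknown:
            raise ConsistencyError(
                f"labels present in volume but absent from region table: {sorted(unknown)}")
        if present.size == 0:
            logger.warning("parcellation volume contains no nonzero labels")

    @property
    def region_ids(self) -> list[int]:
        return [int(r) for r in self.region_table["region_id"]]


@dataclass
class SubjectRecord:
    """One participant: demographics, diagnostic group, behavioral scores."""

    subject_id: str
    group: str                 # 'case' | 'control'
    age: float                 # years
    sex: str                   # 'male' | 'female'
    fiq: float | None = None
    behavioral_scores: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise SchemaError(f"group must be case/control, got {self.group!r}")
        if self.sex not in ("male", "female"):
            raise SchemaError(f"sex must be male/female, got {self.sex!r}")
        if not (math.isfinite(self.age) and self.age > 0):
            raise SchemaError(f"age must be finite and positive, got {self.age}")


def default_mask(data: np.ndarray) -> np.ndarray:
    """Analyzable voxels: finite everywhere with nonzero temporal variance."""
    finite = np.all(np.isfinite(data), axis=3)
    var = np.zeros(data.shape[:3])
    var[finite] = data[finite].var(axis=-1)
    return finite & (var > 0)


def read_bold(path: str | Path, mask_path: str | Path | None = None,
              subject_id: str | None = None) -> BoldVolume:
    """Load a 4D NIfTI BOLD image.

    Without an explicit mask, voxels with zero temporal variance (or any
    non-finite sample) are excluded — the gray-matter mask, when available
    upstream, should be passed explicitly.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D NIfTI, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.shape[3] < 2:
        raise LengthError(f"{path}: fewer than 2 timepoints")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
        mask_source = "explicit mask file"
    else:
        mask = default_mask(data)
        mask_source = "nonzero-variance default"
    logger.info("read_bold %s: shape=%s mask=%s (%d voxels)",
                path, data.shape, mask_source, int(mask.sum()))
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return BoldVolume(data=data, voxel_mask=mask, subject_id=sid)


def write_bold(vol: BoldVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data, affine=np.eye(4)), str(path))


def read_region_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"region_id", "name", "hemisphere"}
    if not required.issubset(table.columns):
        raise SchemaError(f"region table {path} needs columns {sorted(required)}")
    table["region_id"] = table["region_id"].astype(int)
    return table


def load_aal90_table() -> pd.DataFrame:
    """The packaged 90-region AAL table (odd ids = left, even = right)."""
    with resources.as_file(resources.files("braintraj.data") / "aal90_regions.tsv") as p:
        return read_region_table(p)


def read_parcellation(path: str | Path, region_table_path: str | Path | None = None) -> Parcellation:
    """Load an integer-label parcellation and cross-validate against its region table.

    With no table path, the packaged AAL-90 table is used.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D label NIfTI, got {img.ndim}D")
    raw = np.asarray(img.get_fdata())
    labels = np.rint(raw).astype(np.int64)
    if not np.allclose(raw, labels, atol=1e-6):
        raise FormatError(f"{path}: label volume is not integer-valued")
    table = load_aal90_table() if region_table_path is None else read_region_table(region_table_path)
    return Parcellation(labels=labels, region_table=table)


def write_parcellation(parc: Parcellation, path: str | Path,
                       region_table_path: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int16), affine=np.eye(4)), str(path))
    if region_table_path is not None:
        parc.region_table.to_csv(region_table_path, sep="\t", index=False)


def _parse_float(cell) -> float | None:
    try:
        v = float(cell)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def read_phenotypes(path: str | Path, column_map: dict | None = None) -> list[SubjectRecord]:
    """Parse a phenotype table into SubjectRecords.

    ``column_map`` names the mandatory columns (``subject_id``, ``group``,
    ``age``, ``sex``) plus optional ``fiq`` and a ``behavior`` sub-map of
    scale-name -> column. Unparseable behavioral cells become missing values;
    rows with a non-numeric age are rejected with a logged warning. Row order
    is preserved.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for key in ("subject_id", "group", "age", "sex"):
        if cmap[key] not in table.columns:
            raise SchemaError(f"phenotype table missing mandatory column {cmap[key]!r} ({key})")
    behavior_cols = {k: v for k, v in cmap.get("behavior", {}).items() if v in table.columns}
    records: list[SubjectRecord] = []
    for _, row in table.iterrows():
        sid = str(row[cmap["subject_id"]])
        age = _parse_float(row[cmap["age"]])
        if age is None or age <= 0:
            logger.warning("phenotypes: rejecting subject %s (unparseable age %r)",
                           sid, row[cmap["age"]])
            continue
        group = GROUP_CODES.get(str(row[cmap["group"]]).strip().lower())
        sex = SEX_CODES.get(str(row[cmap["sex"]]).strip().lower())
        if group is None or sex is None:
            logger.warning("phenotypes: rejecting subject %s (bad group/sex coding)", sid)
            continue
        fiq = _parse_float(row[cmap["fiq"]]) if cmap.get("fiq") in table.columns else None
        scores = {scale: _parse_float(row[col]) for scale, col in behavior_cols.items()}
        records.append(SubjectRecord(subject_id=sid, group=group, age=age,
                                     sex=sex, fiq=fiq, behavioral_scores=scores))
    return records


def write_phenotypes(records: list[SubjectRecord], path: str | Path,
                     column_map: dict | None = None) -> None:
    """Write records in the same ABIDE-style layout ``read_phenotypes`` parses."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    group_out = {"case": 1, "control": 2}
    sex_out = {"male": 1, "female": 2}
    scales = sorted({s for r in records for s in r.behavioral_scores})
    rows = []
    for r in records:
        row = {
            cmap["subject_id"]: r.subject_id,
            cmap["group"]: group_out[r.group],
            cmap["age"]: r.age,
            cmap["sex"]: sex_out[r.sex],
            cmap["fiq"]: "" if r.fiq is None else r.fiq,
        }
        for s in scales:
            v = r.behavioral_scores.get(s)
            row[cmap["behavior"].get(s, s)] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
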