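"""Volumetric data model and I/O.

Every stage of the pipeline operates on :class:`VolumeGrid` objects — a 3D
scalar lattice plus a 4x4 voxel-to-world affine (mm).  All volumes belonging
to one patient (dose map, atlas labels, lesion mask) must live on the same
grid: alignment means equal shapes and element-wise equal affines (within
``ALIGN_TOL``).  Misalignment is always an error, never silently resampled —
registration is assumed to have happened upstream.

Atlas labels are interpreted through a :class:`LabelScheme`, which maps
integer label ids to (structure, laterality, subregion) with structure one of
``SVZ`` (subventricular zone), ``HPC`` (hippocampus) or ``OTHER``.  Label 0
is reserved for background; a configurable id set is reserved for
lesion/synthetic tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

ALIGN_TOL = 1e-6

STRUCTURES = ("SVZ", "HPC", "OTHER")
LATERALITIES = ("left", "right", "none")


class GridError(ValueError):
    """Invalid volume grid (shape, affine or value constraints violated)."""


class AlignmentError(GridError):
    """Two grids expected to share a space do not."""


class LabelSchemeError(ValueError):
    """Invalid label scheme definition."""


@dataclass
class VolumeGrid:
    """A 3D scalar volume with a voxel-index → world-mm affine.

    Parameters
    ----------
    values:
        3D array.  Dose maps are in Gy, label volumes hold non-negative
        integer ids, masks hold {0, 1}.
    affine:
        4x4 matrix mapping homogeneous voxel indices (0-based) to world
        coordinates in mm.  Only the affine is trusted for geometry; no
        assumption is made about RAS vs LPS orientation.
    unit:
        Free-form tag ("Gy", "label", "binary", ...) carried for
        bookkeeping; not used in comparisons.
    """

    values: np.ndarray
    affine: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise GridError(
                f"volume must be 3D, got {self.values.ndim}D shape {self.values.shape}"
            )
        if self.affine.shape != (4, 4):
            raise GridError(f"affine must be 4x4, got {self.affine.shape}")
        if not np.allclose(self.affine[3], [0.0, 0.0, 0.0, 1.0], atol=ALIGN_TOL):
            raise GridError("last affine row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GridError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3, |det| of the 3x3 affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxels_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to (N, 3) world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VolumeGrid":
        """New grid on the same lattice with different values."""
        return VolumeGrid(values, self.affine.copy(), self.unit if unit is None else unit)

    def validate_labels(self) -> None:
        """Check the label-volume contract: non-negative integers only."""
        vals = self.values
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise GridError("label volume contains non-integer values")
        if vals.min() < 0:
            raise GridError("label volume contains negative ids")


def check_aligned(a: VolumeGrid, b: VolumeGrid, tol: float = ALIGN_TOL) -> bool:
    """True iff the two grids share shape and affine (within ``tol``)."""
    return a.shape == b.shape and bool(np.allclose(a.affine, b.affine, atol=tol))


def require_aligned(*grids: VolumeGrid) -> None:
    """Raise :class:`AlignmentError` unless all grids share one space."""
    first = grids[0]
    for g in grids[1:]:
        if not check_aligned(first, g):
            raise AlignmentError(
                f"grids are not aligned: shapes {first.shape} vs {g.shape}, "
                f"max affine difference "
                f"{np.max(np.abs(first.affine - g.affine)):.3g} mm"
            )


def read_volume(path, unit: str = "") -> VolumeGrid:
    """Read a NIfTI-1 volume (.nii / .nii.gz) into a :class:`VolumeGrid`.

    Raises
    ------
    GridError
        If the file is unreadable, not 3D, or carries a singular affine.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise GridError(f"cannot read NIfTI volume {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GridError(f"{path!s}: expected a 3D image, got {data.ndim}D")
    return VolumeGrid(np.asarray(data), np.asarray(img.affine), unit=unit)


def write_volume(grid: VolumeGrid, path, dtype=None) -> None:
    """Write a grid as NIfTI-1.

    Dose maps default to float32, integer-valued grids to uint16, per the
    on-disk convention used throughout the pipeline.
    """
    if dtype is None:
        dtype = np.uint16 if np.issubdtype(grid.values.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(grid.values.astype(dtype), grid.affine)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write volume to {path!s}: {exc}") from exc


# ---------------------------------------------------------------------------
# Label schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelInfo:
    structure: str  # SVZ | HPC | OTHER
    laterality: str  # left | right | none
    subregion: str


@dataclass
class LabelScheme:
    """Mapping of integer label ids to anatomical meaning.

    ``0`` is reserved for background and may never be assigned; ids in
    ``lesion_ids`` mark lesion/synthetic tissue and likewise carry no
    structure.  Every SVZ/HPC id must have a left/right laterality so that
    unilateral vs bilateral lesion contact is well defined.
    """

    entries: dict[int, LabelInfo]
    lesion_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.lesion_ids = frozenset(int(i) for i in self.lesion_ids)
        if 0 in self.entries or 0 in self.lesion_ids:
            raise LabelSchemeError("label 0 is reserved for background")
        for lid, info in self.entries.items():
            if lid < 0:
                raise LabelSchemeError(f"negative label id {lid}")
            if lid in self.lesion_ids:
                raise LabelSchemeError(f"label {lid} is both structural and lesion")
            if info.structure not in STRUCTURES:
                raise LabelSchemeError(f"label {lid}: unknown structure {info.structure!r}")
            if info.laterality not in LATERALITIES:
                raise LabelSchemeError(f"label {lid}: unknown laterality {info.laterality!r}")
            if info.structure in ("SVZ", "HPC") and info.laterality == "none":
                raise LabelSchemeError(
                    f"label {lid}: {info.structure} labels require a left/right laterality"
                )

    def ids_for(self, structure: str, laterality: str | None = None) -> list[int]:
        """All ids of a structure, optionally restricted to one side."""
        return sorted(
            lid
            for lid, info in self.entries.items()
            if info.structure == structure
            and (laterality is None or info.laterality == laterality)
        )

    def known_ids(self) -> frozenset[int]:
        return frozenset(self.entries) | self.lesion_ids | {0}

    def check_covers(self, labels: VolumeGrid) -> None:
        """Raise if the label volume contains ids the scheme does not know."""
        labels.validate_labels()
        present = frozenset(int(v) for v in np.unique(labels.values))
        unknown = present - self.known_ids()
        if unknown:
            raise LabelSchemeError(f"label volume contains unknown ids {sorted(unknown)}")

    # -- config-file round trip --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lesion_ids": sorted(self.lesion_ids),
            "labels": {
                int(lid): {
                    "structure": info.structure,
                    "laterality": info.laterality,
                    "subregion": info.subregion,
                }
                for lid, info in sorted(self.entries.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelScheme":
        entries = {
            int(lid): LabelInfo(v["structure"], v["laterality"], v["subregion"])
            for lid, v in d.get("labels", {}).items()
        }
        return cls(entries, frozenset(d.get("lesion_ids", ())))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "LabelScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

#: Documented cohort-table header.  One row per patient; categorical columns
#: use the spelled-out levels below, 'unknown' marks missingness.
COHORT_COLUMNS = [
    "patient_id",
    "age",                    # years
    "sex",                    # female | male
    "who_status",             # 0 | 1 | 2 | 3 | unknown
    "histology",              # LUAD | LUSC | unknown
    "n_bm",                   # 1 | 2-4 | >4
    "extracranial_mets",      # yes | no
    "chemotherapy",           # yes | no | unknown
    "other_systemic_therapy", # yes | no | unknown
    "resection_extent",       # none | partial | complete
    "gtv_volume_cm3",
    "ptv_volume_cm3",
    "svz_volume_cm3",
    "sgz_volume_cm3",
    "svz_mean_dose_gy",       # single-fraction equivalent Gy
    "hpc_mean_dose_gy",       # single-fraction equivalent Gy
    "svz_contact",            # yes | no
    "hpc_contact",            # yes | no
    "centrality_cm",          # PTV CoG to AC distance; NaN unless single BM
    "os_months",
    "event",                  # 1 = death observed, 0 = censored
]

CATEGORICAL_LEVELS = {
    "sex": ["female", "male"],
    "who_status": ["0", "1", "2", "3", "unknown"],
    "histology": ["LUAD", "LUSC", "unknown"],
    "n_bm": ["1", "2-4", ">4"],
    "extracranial_mets": ["no", "yes"],
    "chemotherapy": ["no", "yes", "unknown"],
    "other_systemic_therapy": ["no", "yes", "unknown"],
    "resection_extent": ["none", "partial", "complete"],
    "svz_contact": ["no", "yes"],
    "hpc_contact": ["no", "yes"],
}


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the documented contract.

    Returns the table with categorical columns cast to string dtype; raises
    ``ValueError`` on missing columns, non-positive survival times/volumes,
    negative doses or out-of-vocabulary category levels.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")
    table = table.copy()
    for col, levels in CATEGORICAL_LEVELS.items():
        table[col] = table[col].astype(str)
        bad = set(table[col]) - set(levels)
        if bad:
            raise ValueError(f"column {col!r} has invalid levels {sorted(bad)}")
    if (table["os_months"] <= 0).any():
        raise ValueError("os_months must be positive")
    for col in ("gtv_volume_cm3", "ptv_volume_cm3", "svz_volume_cm3", "sgz_volume_cm3"):
        if (table[col] <= 0).any():
            raise ValueError(f"{col} must be positive")
    for col in ("svz_mean_dose_gy", "hpc_mean_dose_gy"):
        if (table[col] < 0).any():
            raise ValueError(f"{col} must be non-negative")
    if not set(table["event"].unique()) <= {0, 1}:
        raise ValueError("event flag must be 0/1")
    return table


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    return validate_cohort(pd.read_csv(path))


def write_cohort(table: pd.DataFrame, path) -> None:
    """Validate and write a cohort CSV (stable column order)."""
    validate_cohort(table)[COHORT_COLUMNS].to_csv(path, index=False)
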