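"""Per-patient dosimetry features for the neurogenic niches.

Given a co-registered (dose map, atlas label volume, lesion mask) triple,
this module derives the quantities the survival analysis consumes:

* lesion-niche **contact**: a niche (SVZ or HPC) is in contact with the
  lesion when at least one of its labelled voxels falls inside the lesion
  mask; sidedness gives none / unilateral / bilateral status;
* **mean dose per subregion**, computed over the voxels of each atlas
  subregion that lie *outside* the lesion mask — subregions swallowed
  entirely by the lesion are recorded as excluded and contribute nothing;
* cumulative **dose-volume histograms** (fraction of a structure receiving
  at least each dose level);
* the **centrality** of a target: Euclidean distance (cm) from the PTV
  centre of gravity to the anterior commissure, the anatomical centre of
  the template brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import LabelScheme, VolumeGrid, require_aligned

DEFAULT_DVH_BIN_GY = 0.1
DEFAULT_AC_POINT_MM = (0.0, 0.0, 0.0)  # anterior commissure in template world mm


# ---------------------------------------------------------------------------
# Contact classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactStatus:
    """Lesion contact of one niche: overlap voxel counts per side."""

    structure: str  # SVZ | HPC
    overlap_left: int
    overlap_right: int
    min_overlap: int = 1  # voxels required to call a side "in contact"

    @property
    def left(self) -> bool:
        return self.overlap_left >= self.min_overlap

    @property
    def right(self) -> bool:
        return self.overlap_right >= self.min_overlap

    @property
    def status(self) -> str:
        if self.left and self.right:
            return "bilateral"
        if self.left or self.right:
            return "unilateral"
        return "none"

    @property
    def any_contact(self) -> bool:
        return self.status != "none"


def classify_contact(
    labels: VolumeGrid,
    lesion_mask: VolumeGrid,
    scheme: LabelScheme,
    structure: str,
    min_overlap: int = 1,
) -> ContactStatus:
    """Classify lesion contact with one niche (pure geometry, dose-free).

    Overlap per side counts voxels whose atlas label belongs to
    ``(structure, side)`` and that lie inside the lesion mask.  By default a
    single overlapping voxel constitutes contact; the raw counts are kept so
    stricter thresholds remain testable.
    """
    if structure not in ("SVZ", "HPC"):
        raise ValueError(f"structure must be SVZ or HPC, got {structure!r}")
    require_aligned(labels, lesion_mask)
    scheme.check_covers(labels)
    inside = np.asarray(lesion_mask.values) > 0
    lab = np.asarray(labels.values)
    overlaps = {}
    for side in ("left", "right"):
        ids = scheme.ids_for(structure, side)
        overlaps[side] = int((np.isin(lab, ids) & inside).sum()) if ids else 0
    return ContactStatus(structure, overlaps["left"], overlaps["right"], min_overlap)


# ---------------------------------------------------------------------------
# Region mean doses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubregionDose:
    structure: str
    laterality: str
    subregion: str
    label_id: int
    mean_dose_gy: float
    voxel_count: int
    volume_cm3: float


@dataclass
class NicheDoseSummary:
    """Dose summary over the SVZ and HPC of one patient.

    ``pooled_mean_gy[structure]`` is the voxel-count-weighted mean over all
    included (non-lesion) subregion voxels; it is NaN when the lesion
    swallowed the structure entirely.  ``dvh[structure]`` holds
    ``(bin_edges_gy, fraction_at_least)`` over the same included voxels.
    """

    subregions: list[SubregionDose]
    pooled_mean_gy: dict[str, float]
    pooled_volume_cm3: dict[str, float]
    dvh: dict[str, tuple[np.ndarray, np.ndarray]]
    excluded_labels: list[int] = field(default_factory=list)

    def subregion_means(self, structure: str) -> dict[str, float]:
        """{'left:subregion': mean, ...} for one structure."""
        return {
            f"{s.laterality}:{s.subregion}": s.mean_dose_gy
            for s in self.subregions
            if s.structure == structure
        }


def mean_dose_by_region(
    dose: VolumeGrid,
    labels: VolumeGrid,
    lesion_mask: VolumeGrid,
    scheme: LabelScheme,
    dvh_bin_gy: float = DEFAULT_DVH_BIN_GY,
    pooling: str = "voxel",
) -> NicheDoseSummary:
    """Mean dose per SVZ/HPC subregion, excluding lesion-affected voxels.

    Only voxels carrying a niche label *and* lying outside the lesion mask
    contribute.  Subregions left with zero voxels are listed in
    ``excluded_labels`` rather than silently dropped, so patient-level QC can
    report them.

    ``pooling`` selects how the per-structure mean is formed: ``"voxel"``
    (default) weights by voxel count; ``"subregion"`` averages the subregion
    means with equal weight.
    """
    if pooling not in ("voxel", "subregion"):
        raise ValueError(f"pooling must be 'voxel' or 'subregion', got {pooling!r}")
    require_aligned(dose, labels, lesion_mask)
    scheme.check_covers(labels)
    dose_vals = np.asarray(dose.values, dtype=float)
    lab = np.asarray(labels.values)
    outside_lesion = np.asarray(lesion_mask.values) <= 0
    vox_cm3 = dose.voxel_volume_cm3

    subregions: list[SubregionDose] = []
    excluded: list[int] = []
    pooled_mean: dict[str, float] = {}
    pooled_vol: dict[str, float] = {}
    dvhs: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    for structure in ("SVZ", "HPC"):
        struct_doses = []
        for lid in scheme.ids_for(structure):
            info = scheme.entries[lid]
            sel = (lab == lid) & outside_lesion
            n_vox = int(sel.sum())
            if n_vox == 0:
                excluded.append(lid)
                continue
            voxel_doses = dose_vals[sel]
            subregions.append(
                SubregionDose(
                    structure=structure,
                    laterality=info.laterality,
                    subregion=info.subregion,
                    label_id=lid,
                    mean_dose_gy=float(voxel_doses.mean()),
                    voxel_count=n_vox,
                    volume_cm3=n_vox * vox_cm3,
                )
            )
            struct_doses.append(voxel_doses)
        if struct_doses:
            all_doses = np.concatenate(struct_doses)
            if pooling == "voxel":
                pooled_mean[structure] = float(all_doses.mean())
            else:
                pooled_mean[structure] = float(
                    np.mean([s.mean_dose_gy for s in subregions if s.structure == structure])
                )
            pooled_vol[structure] = all_doses.size * vox_cm3
            dvhs[structure] = _cumulative_dvh(all_doses, dvh_bin_gy)
        else:
            # whole structure lesion-affected: undefined, never reported as 0
            pooled_mean[structure] = float("nan")
            pooled_vol[structure] = 0.0

    return NicheDoseSummary(subregions, pooled_mean, pooled_vol, dvhs, excluded)


def _cumulative_dvh(doses: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    dmax = float(doses.max()) if doses.size else 0.0
    n_edges = int(np.floor(dmax / bin_width)) + 2  # one edge strictly above max
    edges = np.arange(n_edges) * bin_width
    sorted_doses = np.sort(doses)
    # fraction of voxels with dose >= edge
    frac = 1.0 - np.searchsorted(sorted_doses, edges, side="left") / doses.size
    return edges, frac


def dvh(dose: VolumeGrid, mask: VolumeGrid, bin_width: float = DEFAULT_DVH_BIN_GY):
    """Cumulative dose-volume histogram over a binary mask.

    Returns ``(edges, fraction)`` with ``fraction[i]`` the fraction of masked
    voxels receiving at least ``edges[i]`` Gy.  Edges run 0, w, 2w, ... up to
    one step beyond the maximum dose, so the curve starts at 1 and ends at 0.
    """
    require_aligned(dose, mask)
    sel = np.asarray(mask.values) > 0
    if not sel.any():
        raise ValueError("mask is empty")
    return _cumulative_dvh(np.asarray(dose.values, dtype=float)[sel], bin_width)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def centroid_world(mask: VolumeGrid) -> np.ndarray:
    """Unweighted centre of gravity of a mask in world coordinates (mm)."""
    idx = np.argwhere(np.asarray(mask.values) > 0)
    if idx.size == 0:
        raise ValueError("mask is empty")
    return mask.voxels_to_world(idx).mean(axis=0)


def centrality(ptv_mask: VolumeGrid, ac_point_mm=DEFAULT_AC_POINT_MM) -> float:
    """Distance (cm) from the PTV centre of gravity to the AC point.

    The anterior commissure serves as the common central reference of the
    template space; by convention it sits at the world origin, but the point
    is configurable.
    """
    cog = centroid_world(ptv_mask)
    return float(np.linalg.norm(cog - np.asarray(ac_point_mm, dtype=float))) / 10.0
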