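"""Synthetic phantom imaging and cohort generation.

Patient-level imaging and survival data of the kind this pipeline analyses
cannot be shared, so every stage is exercised on synthetic stand-ins with
the statistical structure the analysis assumes:

* a **brain phantom**: an ellipsoidal brain on a 3 mm lattice in a
  template-like space (anterior commissure at the world origin) carrying
  mirror-symmetric bilateral SVZ ribbons (thin sheets lining the lateral
  ventricles, split into anterior/middle/posterior subregions) and
  hippocampal blobs (head/tail subregions), sized to match typical niche
  volumes (~10.8 cm^3 SVZ, ~1.6 cm^3 SGZ in total);
* **lesions and plans**: spherical GTVs dilated by a fixed margin to PTVs,
  with a conformal dose — prescription plus a bounded boost core inside the
  PTV and an isotropic Gaussian shoulder outside — constructed to satisfy
  stereotactic plan constraints (>= 98 % PTV coverage at prescription,
  point maximum <= 130 % of prescription);
* a **cohort table** whose covariate marginals follow a published
  brain-metastasis series (median age 67, balanced sex, ~51 % single
  metastasis, ~25 % SVZ and ~4 % HPC lesion contact, prescription mix
  dominated by 1x21 / 1x24 Gy with a hypofractionated minority) and whose
  survival times follow a Weibull proportional-hazards model with
  configurable log-hazard ratios, including per-Gy effects of the mean SVZ
  and HPC dose.

Two cohort routes exist.  :func:`generate_cohort_table` samples dosimetry
features directly from configured distributions (fast; used for large
parameter-recovery simulations).  :func:`generate_cohort` runs the full
imaging pipeline per patient — phantom, lesion placement, physical dose,
single-fraction-equivalent conversion, feature extraction — and then the
same survival model, so every pipeline stage is exercised end to end.

Randomness follows one master seed; the imaging route derives a deterministic
per-patient substream from it, so individual patients can be regenerated
without re-running the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import fractionation, niche_dosimetry
from .volume_io import COHORT_COLUMNS, LabelInfo, LabelScheme, VolumeGrid

# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

LESION_LABEL_ID = 99
BRAIN_LABEL_ID = 1


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic brain phantom (all lengths in mm)."""

    shape: tuple[int, int, int] = (49, 59, 49)
    voxel_mm: float = 3.0
    brain_semiaxes: tuple[float, float, float] = (66.0, 82.0, 60.0)
    # SVZ: one-voxel-thick parasagittal sheets at x = +/- svz_x
    svz_x: float = 15.0
    svz_y_range: tuple[float, float] = (-33.0, 24.0)
    svz_z_range: tuple[float, float] = (0.0, 27.0)
    svz_n_subregions: int = 3  # anterior / middle / posterior along y
    # HPC: ellipsoidal blobs
    hpc_center: tuple[float, float, float] = (27.0, -24.0, -12.0)  # right; left mirrored
    hpc_semiaxes: tuple[float, float, float] = (5.5, 9.0, 4.5)
    hpc_n_subregions: int = 2  # head / tail along y
    ac_point_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def affine(self) -> np.ndarray:
        """3 mm isotropic affine placing the grid centre at the world origin."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_mm
        for ax in range(3):
            aff[ax, 3] = -self.voxel_mm * (self.shape[ax] - 1) / 2.0
        return aff


@dataclass
class Phantom:
    """Generated phantom: label volume, scheme, brain mask and geometry."""

    spec: PhantomSpec
    labels: VolumeGrid
    scheme: LabelScheme
    brain_mask: VolumeGrid
    _maps: dict = field(default_factory=dict, repr=False)

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        aff = self.labels.affine
        ii = np.arange(self.spec.shape[0]) * aff[0, 0] + aff[0, 3]
        jj = np.arange(self.spec.shape[1]) * aff[1, 1] + aff[1, 3]
        kk = np.arange(self.spec.shape[2]) * aff[2, 2] + aff[2, 3]
        return np.meshgrid(ii, jj, kk, indexing="ij")

    def placement_maps(self) -> dict:
        """Cached distance maps (mm) used by the lesion placer."""
        if not self._maps:
            vox = self.spec.voxel_mm
            brain = self.brain_mask.values > 0
            lab = self.labels.values
            svz = np.isin(lab, self.scheme.ids_for("SVZ"))
            hpc = np.isin(lab, self.scheme.ids_for("HPC"))
            self._maps = {
                "depth": ndimage.distance_transform_edt(brain, sampling=vox),
                "d_svz": ndimage.distance_transform_edt(~svz, sampling=vox),
                "d_hpc": ndimage.distance_transform_edt(~hpc, sampling=vox),
            }
        return self._maps


def _default_label_scheme(spec: PhantomSpec) -> LabelScheme:
    entries: dict[int, LabelInfo] = {BRAIN_LABEL_ID: LabelInfo("OTHER", "none", "brain")}
    svz_names = ["posterior", "middle", "anterior"][: spec.svz_n_subregions]
    hpc_names = ["tail", "head"][: spec.hpc_n_subregions]
    lid = 10
    for side in ("left", "right"):
        for name in svz_names:
            lid += 1
            entries[lid] = LabelInfo("SVZ", side, name)
    lid = 20
    for side in ("left", "right"):
        for name in hpc_names:
            lid += 1
            entries[lid] = LabelInfo("HPC", side, name)
    return LabelScheme(entries, lesion_ids=frozenset({LESION_LABEL_ID}))


def generate_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> Phantom:
    """Build the deterministic brain phantom with bilateral niche labels.

    The label volume satisfies the phantom contract: SVZ and HPC labels are
    disjoint, lie inside the brain mask and are left/right mirror symmetric.
    The generator is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages.
    """
    spec = spec or PhantomSpec()
    aff = spec.affine()
    shape = spec.shape
    coords = np.meshgrid(
        np.arange(shape[0]) * spec.voxel_mm + aff[0, 3],
        np.arange(shape[1]) * spec.voxel_mm + aff[1, 3],
        np.arange(shape[2]) * spec.voxel_mm + aff[2, 3],
        indexing="ij",
    )
    X, Y, Z = coords
    a, b, c = spec.brain_semiaxes
    brain = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.uint16)
    labels[brain] = BRAIN_LABEL_ID
    scheme = _default_label_scheme(spec)

    half = spec.voxel_mm / 2.0
    y0, y1 = spec.svz_y_range
    z0, z1 = spec.svz_z_range
    # subregion boundaries along y, equal thirds of the ribbon extent
    svz_edges = np.linspace(y0 - half, y1 + half, spec.svz_n_subregions + 1)
    for side, sign in (("left", -1.0), ("right", 1.0)):
        sheet = (
            (np.abs(X - sign * spec.svz_x) < half)
            & (Y >= y0 - half)
            & (Y <= y1 + half)
            & (Z >= z0 - half)
            & (Z <= z1 + half)
            & brain
        )
        ids = scheme.ids_for("SVZ", side)  # sorted posterior->anterior by construction
        for k, lid in enumerate(ids):
            labels[sheet & (Y >= svz_edges[k]) & (Y < svz_edges[k + 1])] = lid

    hx, hy, hz = spec.hpc_center
    ha, hb, hc = spec.hpc_semiaxes
    for side, sign in (("left", -1.0), ("right", 1.0)):
        blob = ((X - sign * hx) / ha) ** 2 + ((Y - hy) / hb) ** 2 + ((Z - hz) / hc) ** 2 <= 1.0
        blob &= brain
        ids = scheme.ids_for("HPC", side)
        for k, lid in enumerate(ids):  # tail (posterior) then head (anterior)
            lo = hy - hb if k == 0 else hy
            hi = hy if k == 0 and len(ids) > 1 else hy + hb
            labels[blob & (Y >= lo - half) & (Y <= hi + half) & (labels < 20)] = lid

    for structure in ("SVZ", "HPC"):
        for side in ("left", "right"):
            if not np.isin(labels, scheme.ids_for(structure, side)).any():
                raise ValueError(
                    f"{side} {structure} does not fit inside the brain; "
                    "check the phantom spec geometry"
                )

    label_grid = VolumeGrid(labels, aff, unit="label")
    brain_grid = VolumeGrid(brain.astype(np.uint8), aff, unit="binary")
    return Phantom(spec, label_grid, scheme, brain_grid)


# ---------------------------------------------------------------------------
# Lesion placement and dose
# ---------------------------------------------------------------------------

@dataclass
class LesionPlan:
    gtv_mask: VolumeGrid
    ptv_mask: VolumeGrid
    dose: VolumeGrid  # total physical dose, Gy
    center_mm: np.ndarray
    gtv_radius_mm: float
    prescription_gy: float


PLACEMENT_POLICIES = ("random", "svz_contact", "hpc_contact", "avoid_niches")

# Inside-PTV boost profile: dose rises from 100 % at the PTV surface to at
# most (1 + BOOST) * prescription at the core; noise is clipped so the plan
# constraints (coverage >= 98 %, max <= 130 %) hold by construction.
PTV_BOOST = 0.25
PTV_NOISE_SD = 0.004
PTV_NOISE_MAX = 0.02
_VOXEL_DIAG_SAFETY = 1.1  # placement slack, in units of the voxel diagonal


def _gtv_radius_mm(volume_cm3: float) -> float:
    return (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _candidate_centers(phantom: Phantom, policy: str, r_mm: float) -> np.ndarray:
    """Voxel indices where a GTV of radius r can be centred under ``policy``."""
    maps = phantom.placement_maps()
    vox_diag = phantom.spec.voxel_mm * np.sqrt(3.0) * _VOXEL_DIAG_SAFETY
    fits = maps["depth"] >= r_mm  # whole GTV inside the brain
    clear_svz = maps["d_svz"] > r_mm + vox_diag
    clear_hpc = maps["d_hpc"] > r_mm + vox_diag
    if policy == "random":
        sel = fits
    elif policy == "avoid_niches":
        sel = fits & clear_svz & clear_hpc
    elif policy == "svz_contact":
        # nearest SVZ voxel centre strictly inside the sphere => >= 1 overlap voxel
        sel = fits & (maps["d_svz"] < max(r_mm - 0.5, 0.0)) & clear_hpc
    elif policy == "hpc_contact":
        sel = fits & (maps["d_hpc"] < max(r_mm - 0.5, 0.0)) & clear_svz
    else:
        raise ValueError(f"unknown placement policy {policy!r}")
    return np.argwhere(sel)


def place_lesion_and_dose(
    phantom: Phantom,
    gtv_volume_cm3: float,
    policy: str = "random",
    prescription_gy: float = 21.0,
    falloff_mm: float = 5.0,
    seed: int | np.random.Generator = 0,
    ptv_margin_mm: float = 2.0,
) -> LesionPlan:
    """Place a spherical GTV and synthesise a conformal physical dose map.

    The GTV is a sphere of the requested volume centred on a voxel drawn
    uniformly from the set compatible with ``policy`` (touching the SVZ,
    touching the HPC, clear of both niches, or unconstrained).  The PTV is
    the GTV dilated by ``ptv_margin_mm``.  The dose equals the prescription
    at the PTV surface, rises to a bounded boost core inside, and falls off
    as an isotropic Gaussian of scale ``falloff_mm`` outside, so that every
    emitted plan meets the coverage and point-maximum constraints checked by
    :func:`validate_plan`.
    """
    if gtv_volume_cm3 <= 0:
        raise ValueError("GTV volume must be positive")
    if prescription_gy <= 0 or falloff_mm <= 0:
        raise ValueError("prescription and falloff must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = _gtv_radius_mm(gtv_volume_cm3)
    candidates = _candidate_centers(phantom, policy, r)
    if len(candidates) == 0:
        raise ValueError(
            f"no admissible centre for a {gtv_volume_cm3:.2f} cm^3 GTV "
            f"under policy {policy!r}"
        )
    ijk = candidates[rng.integers(len(candidates))]
    center = phantom.labels.voxels_to_world(ijk)[0]

    X, Y, Z = phantom.world_coords()
    dist = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    gtv = dist <= r
    gtv[tuple(ijk)] = True  # sub-voxel lesions still occupy their centre voxel
    ptv = dist <= r + ptv_margin_mm
    ptv |= gtv

    # distance from the PTV surface, inward (depth) and outward
    vox = phantom.spec.voxel_mm
    depth_in = ndimage.distance_transform_edt(ptv, sampling=vox)
    dist_out = ndimage.distance_transform_edt(~ptv, sampling=vox)
    core = depth_in / depth_in.max() if depth_in.max() > 0 else np.zeros_like(depth_in)
    noise = np.clip(rng.normal(0.0, PTV_NOISE_SD, size=ptv.shape), 0.0, PTV_NOISE_MAX)
    dose = np.where(
        ptv,
        prescription_gy * (1.0 + PTV_BOOST * core) * (1.0 + noise),
        prescription_gy * np.exp(-(dist_out**2) / (2.0 * falloff_mm**2)),
    )

    aff = phantom.labels.affine
    return LesionPlan(
        gtv_mask=VolumeGrid(gtv.astype(np.uint8), aff, unit="binary"),
        ptv_mask=VolumeGrid(ptv.astype(np.uint8), aff, unit="binary"),
        dose=VolumeGrid(dose, aff, unit="Gy"),
        center_mm=center,
        gtv_radius_mm=r,
        prescription_gy=prescription_gy,
    )


@dataclass(frozen=True)
class PlanCheck:
    coverage: float    # fraction of PTV voxels at >= prescription
    max_ratio: float   # max PTV dose / prescription
    passed: bool


def validate_plan(dose: VolumeGrid, ptv_mask: VolumeGrid, prescription_gy: float) -> PlanCheck:
    """Check a plan against the stereotactic constraints.

    Passing means at least 98 % of PTV voxels receive the full prescription
    and no PTV voxel exceeds 130 % of it.
    """
    from .volume_io import require_aligned

    require_aligned(dose, ptv_mask)
    sel = np.asarray(ptv_mask.values) > 0
    if not sel.any():
        raise ValueError("PTV mask is empty")
    ptv_dose = np.asarray(dose.values, dtype=float)[sel]
    coverage = float((ptv_dose >= prescription_gy * (1.0 - 1e-9)).mean())
    max_ratio = float(ptv_dose.max() / prescription_gy)
    return PlanCheck(coverage, max_ratio, coverage >= 0.98 and max_ratio <= 1.30)


# ---------------------------------------------------------------------------
# Cohort simulation config
# ---------------------------------------------------------------------------

#: Default per-covariate log hazard ratios of the survival model.  Keys use
#: the design-matrix column naming of survival_models.build_design_matrix.
#: The niche-dose effects default to per-Gy hazard ratios of 1.306 (SVZ) and
#: 1.222 (HPC), the magnitudes the analysis is designed to detect.
DEFAULT_LOG_HRS: dict[str, float] = {
    "age": 0.015,
    "sex[male]": 0.10,
    "who_status[1]": 0.35,
    "who_status[2]": 0.80,
    "who_status[3]": 1.20,
    "histology[LUSC]": 0.21,
    "n_bm[2-4]": 0.25,
    "n_bm[>4]": 0.50,
    "extracranial_mets[yes]": 0.30,
    "chemotherapy[yes]": -0.15,
    "other_systemic_therapy[yes]": -0.25,
    "resection_extent[partial]": -0.10,
    "resection_extent[complete]": -0.30,
    "gtv_volume_cm3": 0.012,
    "svz_volume_cm3": 0.0,
    "sgz_volume_cm3": 0.0,
    "svz_mean_dose_gy": float(np.log(1.306)),
    "hpc_mean_dose_gy": float(np.log(1.222)),
}

#: Reference values at which continuous covariates are centred inside the
#: linear predictor (cohort medians), so the Weibull baseline describes a
#: reference patient.  Centring does not change hazard ratios.
DEFAULT_CENTERING: dict[str, float] = {
    "age": 67.0,
    "gtv_volume_cm3": 6.4,
    "svz_volume_cm3": 10.8,
    "sgz_volume_cm3": 1.6,
    "svz_mean_dose_gy": 0.0,
    "hpc_mean_dose_gy": 0.0,
}


def _table1_marginals() -> dict:
    """Cohort covariate marginals (fractions from the reference series)."""
    return {
        "p_male": 0.50,
        "who_probs": {"0": 0.217, "1": 0.623, "2": 0.080, "3": 0.029},
        "who_missing": 0.051,
        "histology_probs": {"LUAD": 0.739, "LUSC": 0.152},
        "histology_missing": 0.109,
        "n_bm_probs": {"1": 0.514, "2-4": 0.370, ">4": 0.116},
        "extracranial_p": 0.326,
        "chemo_p": 0.587 / (0.587 + 0.391),
        "chemo_missing": 0.022,
        "other_sys_p": 0.486 / (0.486 + 0.478),
        "other_sys_missing": 0.036,
        "resection_probs": {"none": 0.797, "partial": 0.051, "complete": 0.152},
        "svz_contact_p": 0.246,
        "hpc_contact_p": 0.036,
        # (n fractions, dose per fraction Gy, frequency)
        "schemes": (
            (1, 15.0, 0.022),
            (1, 16.0, 0.014),
            (1, 18.0, 0.130),
            (1, 20.0, 0.022),
            (1, 21.0, 0.319),
            (1, 24.0, 0.319),
            (3, 8.0, 0.167),
            (5, 6.0, 0.007),
        ),
    }


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic cohort generator.

    Covariate marginals default to a published brain-metastasis series
    (median age 67, IQR-matched log-normal volumes, ~25 % SVZ and ~4 % HPC
    lesion contact); the survival model is Weibull proportional hazards with
    ``log_hrs`` applied to the same design coding the Cox fits use, and
    administrative censoring drawn uniformly over the follow-up window
    implied by staggered accrual.
    """

    n_patients: int = 138
    seed: int = 0
    marginals: dict = field(default_factory=_table1_marginals)
    # continuous covariate distributions
    age_mean: float = 67.0
    age_sd: float = 10.4          # IQR 60-74 -> sd = 14 / 1.349
    age_range: tuple[float, float] = (18.0, 95.0)
    gtv_log_median: float = float(np.log(6.4))
    gtv_log_sd: float = 1.19      # IQR 2.59-12.89 on the log scale
    gtv_range_cm3: tuple[float, float] = (0.2, 25.0)
    svz_vol_log_median: float = float(np.log(10.8))
    svz_vol_log_sd: float = 0.265
    sgz_vol_log_median: float = float(np.log(1.6))
    sgz_vol_log_sd: float = 0.129
    centrality_mean_cm: float = 6.7
    centrality_sd_cm: float = 1.8
    # tabular dose model (log scale; see docs/methods.md).  The intercepts
    # sit below the target cohort medians (1.50 / 1.22 Gy) because the
    # burden and contact terms shift the population median upward.
    svz_dose_log_median: float = float(np.log(1.50)) - 0.34
    hpc_dose_log_median: float = float(np.log(1.22)) - 0.17
    dose_gtv_slope: float = 0.35      # per sd of log GTV
    dose_nbm_slope: float = 0.28      # per ordinal step of metastasis count
    dose_contact_shift: float = 0.9   # contact lesions sit on the niche
    dose_log_sd: float = 0.55
    # plan geometry
    ptv_margin_mm: float = 2.0
    falloff_mm: float = 5.0
    alpha_beta: float = 2.0
    # survival model
    weibull_shape: float = 1.1
    weibull_scale_months: float = 39.0
    log_hrs: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HRS))
    centering: dict = field(default_factory=lambda: dict(DEFAULT_CENTERING))
    censor_low_months: float = 26.0
    censor_high_months: float = 90.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.weibull_shape <= 0 or self.weibull_scale_months <= 0:
            raise ValueError("Weibull parameters must be positive")
        if not 0 < self.censor_low_months <= self.censor_high_months:
            raise ValueError("censoring window must be positive and ordered")
        m = self.marginals
        probs = [m["p_male"], m["extracranial_p"], m["svz_contact_p"], m["hpc_contact_p"],
                 m["chemo_p"], m["other_sys_p"], m["who_missing"], m["histology_missing"],
                 m["chemo_missing"], m["other_sys_missing"]]
        probs += list(m["who_probs"].values()) + list(m["histology_probs"].values())
        probs += list(m["n_bm_probs"].values()) + list(m["resection_probs"].values())
        probs += [p for _, _, p in m["schemes"]]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all marginal probabilities must lie in [0, 1]")

    def with_effects(self, **log_hrs: float) -> "CohortSimConfig":
        """Copy of the config with some log hazard ratios replaced."""
        new = dict(self.log_hrs)
        new.update(log_hrs)
        return replace(self, log_hrs=new)


def recovery_config(
    niche: str,
    n_patients: int = 2000,
    true_hr_per_gy: float | None = None,
    **kwargs,
) -> CohortSimConfig:
    """Config for a single-niche parameter-recovery experiment.

    The nested Cox models under study include one niche's mean dose but not
    the other's, while the two doses are correlated through shared
    tumour-burden geometry.  A recovery experiment is therefore only
    well-posed when the generating truth matches the fitted model: this
    config keeps the studied niche's per-Gy effect (``true_hr_per_gy``,
    default the standard effect size) and switches the *other* niche's
    direct dose effect off.  With both effects active the fitted single-dose
    models are confounded by the omitted correlated exposure — a real
    phenomenon, but a property of the models, not of the estimator.
    """
    if niche not in ("svz", "hpc"):
        raise ValueError("niche must be 'svz' or 'hpc'")
    own = f"{niche}_mean_dose_gy"
    other = f"{'hpc' if niche == 'svz' else 'svz'}_mean_dose_gy"
    config = CohortSimConfig(n_patients=n_patients, **kwargs)
    effects = {other: 0.0}
    if true_hr_per_gy is not None:
        effects[own] = float(np.log(true_hr_per_gy))
    return config.with_effects(**effects)


# ---------------------------------------------------------------------------
# Survival simulation
# ---------------------------------------------------------------------------

def _linear_predictor(table: pd.DataFrame, config: CohortSimConfig) -> np.ndarray:
    """Sum of beta * covariate over the design coding of the Cox fits.

    Rows with an 'unknown' categorical level contribute 0 for that covariate
    (they are dropped from complete-case fits anyway); continuous covariates
    are centred at the configured reference values.
    """
    lp = np.zeros(len(table), dtype=float)
    for key, beta in config.log_hrs.items():
        if beta == 0.0:
            continue
        if "[" in key:
            col, level = key[:-1].split("[")
            lp += beta * (table[col].astype(str) == level).to_numpy(dtype=float)
        else:
            center = config.centering.get(key, 0.0)
            lp += beta * (table[key].to_numpy(dtype=float) - center)
    return lp


def simulate_survival(
    table: pd.DataFrame,
    config: CohortSimConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw survival outcomes for a covariate table under the Weibull PH model.

    Event times satisfy ``S(t | x) = exp(-(t/scale)^shape * exp(x'beta))``,
    so proportional hazards holds by construction and each configured
    ``exp(beta)`` is the true hazard ratio the Cox fits should recover.
    Administrative censoring is uniform over the configured follow-up
    window.  Returns a copy of the table with ``os_months`` and ``event``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lp = _linear_predictor(table, config)
    u = rng.uniform(size=len(table))
    t_event = config.weibull_scale_months * (-np.log(u) * np.exp(-lp)) ** (
        1.0 / config.weibull_shape
    )
    t_censor = rng.uniform(config.censor_low_months, config.censor_high_months, len(table))
    out = table.copy()
    out["os_months"] = np.maximum(np.minimum(t_event, t_censor), 1e-3)
    out["event"] = (t_event <= t_censor).astype(int)
    return out


# ---------------------------------------------------------------------------
# Covariate sampling (shared by both cohort routes)
# ---------------------------------------------------------------------------

def _sample_categorical(rng, probs: dict[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[lv] for lv in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _sample_covariates(rng: np.random.Generator, config: CohortSimConfig) -> pd.DataFrame:
    """Draw the clinical covariates (no dosimetry, no missingness yet)."""
    n = config.n_patients
    m = config.marginals
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    table = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": np.where(rng.uniform(size=n) < m["p_male"], "male", "female"),
            "who_status": _sample_categorical(rng, m["who_probs"], n),
            "histology": _sample_categorical(rng, m["histology_probs"], n),
            "n_bm": _sample_categorical(rng, m["n_bm_probs"], n),
            "extracranial_mets": np.where(
                rng.uniform(size=n) < m["extracranial_p"], "yes", "no"
            ),
            "chemotherapy": np.where(rng.uniform(size=n) < m["chemo_p"], "yes", "no"),
            "other_systemic_therapy": np.where(
                rng.uniform(size=n) < m["other_sys_p"], "yes", "no"
            ),
            "resection_extent": _sample_categorical(rng, m["resection_probs"], n),
            "gtv_volume_cm3": np.clip(
                np.exp(rng.normal(config.gtv_log_median, config.gtv_log_sd, n)),
                *config.gtv_range_cm3,
            ),
        }
    )
    return table


def _apply_missingness(table: pd.DataFrame, rng, config: CohortSimConfig) -> pd.DataFrame:
    """Mask a configured fraction of some covariates to 'unknown' (MCAR)."""
    m = config.marginals
    out = table.copy()
    for col, p in (
        ("who_status", m["who_missing"]),
        ("histology", m["histology_missing"]),
        ("chemotherapy", m["chemo_missing"]),
        ("other_systemic_therapy", m["other_sys_missing"]),
    ):
        mask = rng.uniform(size=len(out)) < p
        out.loc[mask, col] = "unknown"
    return out


def _sample_schemes(rng, config: CohortSimConfig, n: int) -> list[tuple[int, float]]:
    schemes = config.marginals["schemes"]
    p = np.array([s[2] for s in schemes], dtype=float)
    p = p / p.sum()
    picks = rng.choice(len(schemes), size=n, p=p)
    return [(schemes[i][0], schemes[i][1]) for i in picks]


def _ptv_volume_from_gtv(gtv_cm3: np.ndarray, n_lesions: np.ndarray, margin_mm: float) -> np.ndarray:
    """Total PTV volume for equal-size spherical lesions dilated by the margin."""
    per_lesion = gtv_cm3 / n_lesions
    r = _gtv_radius_mm(1.0) * per_lesion ** (1.0 / 3.0)
    return n_lesions * per_lesion * ((r + margin_mm) / r) ** 3


_N_BM_ORDINAL = {"1": 1.0, "2-4": 2.0, ">4": 3.0}


def generate_cohort_table(config: CohortSimConfig, seed: int | None = None) -> pd.DataFrame:
    """Fast cohort route: sample dosimetry features from configured marginals.

    Clinical covariates, contact flags, niche volumes and mean niche doses
    are drawn directly from the configured distributions (log-normal doses
    rising with tumour burden and jumping for contact lesions), then
    survival is simulated from the Weibull PH model.  Suitable for large
    parameter-recovery studies where the voxel pipeline would be wasteful.
    """
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(master)
    n = config.n_patients
    m = config.marginals

    table = _sample_covariates(rng, config)
    table["svz_contact"] = np.where(rng.uniform(size=n) < m["svz_contact_p"], "yes", "no")
    table["hpc_contact"] = np.where(rng.uniform(size=n) < m["hpc_contact_p"], "yes", "no")
    table["svz_volume_cm3"] = np.exp(
        rng.normal(config.svz_vol_log_median, config.svz_vol_log_sd, n)
    )
    table["sgz_volume_cm3"] = np.exp(
        rng.normal(config.sgz_vol_log_median, config.sgz_vol_log_sd, n)
    )

    n_lesions = np.ones(n)
    multi = table["n_bm"] == "2-4"
    many = table["n_bm"] == ">4"
    n_lesions[multi] = rng.integers(2, 5, int(multi.sum()))
    n_lesions[many] = rng.integers(5, 9, int(many.sum()))
    table["ptv_volume_cm3"] = _ptv_volume_from_gtv(
        table["gtv_volume_cm3"].to_numpy(), n_lesions, config.ptv_margin_mm
    )

    z_gtv = (np.log(table["gtv_volume_cm3"]) - config.gtv_log_median) / config.gtv_log_sd
    nbm_ord = table["n_bm"].map(_N_BM_ORDINAL).to_numpy()
    shared = rng.normal(size=n)  # common plan-geometry factor for both niches
    for dose_col, log_med, contact_col in (
        ("svz_mean_dose_gy", config.svz_dose_log_median, "svz_contact"),
        ("hpc_mean_dose_gy", config.hpc_dose_log_median, "hpc_contact"),
    ):
        eps = 0.6 * shared + 0.8 * rng.normal(size=n)
        log_dose = (
            log_med
            + config.dose_gtv_slope * z_gtv
            + config.dose_nbm_slope * (nbm_ord - 1.0)
            + config.dose_contact_shift * (table[contact_col] == "yes")
            + config.dose_log_sd * eps
        )
        table[dose_col] = np.exp(log_dose)

    single = table["n_bm"] == "1"
    centr = np.full(n, np.nan)
    centr[single] = np.clip(
        rng.normal(config.centrality_mean_cm, config.centrality_sd_cm, int(single.sum())),
        0.5,
        12.0,
    )
    table["centrality_cm"] = centr

    table = simulate_survival(table, config, rng)
    table = _apply_missingness(table, rng, config)
    return table[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Full imaging cohort
# ---------------------------------------------------------------------------

@dataclass
class PatientBundle:
    """Per-patient imaging artifacts from the end-to-end route."""

    patient_id: str
    plans: list[LesionPlan]
    lesion_mask: VolumeGrid
    ptv_mask: VolumeGrid
    dose_physical: VolumeGrid
    dose_sfed: VolumeGrid
    scheme_n: int
    scheme_d: float
    summary: niche_dosimetry.NicheDoseSummary


def _patient_imaging(
    phantom: Phantom,
    rng: np.random.Generator,
    config: CohortSimConfig,
    patient_id: str,
    gtv_total_cm3: float,
    n_lesions: int,
    scheme: tuple[int, float],
    want_svz_contact: bool,
    want_hpc_contact: bool,
) -> PatientBundle:
    """Place lesions, synthesise the plan and convert to SFED for one patient."""
    n_frac, d_frac = scheme
    prescription = n_frac * d_frac
    weights = rng.dirichlet(np.full(n_lesions, 2.0)) if n_lesions > 1 else np.ones(1)
    volumes = np.maximum(gtv_total_cm3 * weights, 0.05)

    # contact lesions first, remaining lesions kept clear of both niches so
    # the drawn contact flags are realised exactly
    policies: list[str] = []
    if want_svz_contact:
        policies.append("svz_contact")
    if want_hpc_contact and (n_lesions > len(policies) or not want_svz_contact):
        policies.append("hpc_contact")
    while len(policies) < n_lesions:
        policies.append("avoid_niches")
    policies = policies[:n_lesions]

    plans = [
        place_lesion_and_dose(
            phantom,
            float(v),
            policy,
            prescription_gy=prescription,
            falloff_mm=config.falloff_mm,
            seed=rng,
            ptv_margin_mm=config.ptv_margin_mm,
        )
        for v, policy in zip(volumes, policies)
    ]
    aff = phantom.labels.affine
    lesion = np.zeros(phantom.spec.shape, dtype=np.uint8)
    ptv = np.zeros_like(lesion)
    dose = np.zeros(phantom.spec.shape, dtype=float)
    for plan in plans:
        lesion |= plan.gtv_mask.values.astype(np.uint8)
        ptv |= plan.ptv_mask.values.astype(np.uint8)
        dose = np.maximum(dose, plan.dose.values)

    dose_grid = VolumeGrid(dose, aff, unit="Gy")
    sfed = fractionation.sfed_map(dose_grid, n_frac, config.alpha_beta)
    lesion_grid = VolumeGrid(lesion, aff, unit="binary")
    summary = niche_dosimetry.mean_dose_by_region(
        sfed, phantom.labels, lesion_grid, phantom.scheme
    )
    return PatientBundle(
        patient_id=patient_id,
        plans=plans,
        lesion_mask=lesion_grid,
        ptv_mask=VolumeGrid(ptv, aff, unit="binary"),
        dose_physical=dose_grid,
        dose_sfed=sfed,
        scheme_n=n_frac,
        scheme_d=d_frac,
        summary=summary,
    )


def generate_cohort(
    config: CohortSimConfig,
    seed: int | None = None,
    phantom: Phantom | None = None,
    return_bundles: bool = False,
):
    """End-to-end imaging cohort: phantom -> plans -> SFED -> features -> survival.

    Every patient gets lesions placed on the shared phantom according to the
    drawn contact flags, a conformal physical dose map, the voxelwise
    single-fraction-equivalent conversion, and dosimetry features extracted
    with the same operations the analysis of real data would use.  Survival
    is then simulated from the extracted features under the configured
    Weibull PH model.  Per-patient randomness comes from substreams spawned
    off the master seed, so any one patient can be regenerated in isolation.

    Returns the cohort table, or ``(table, bundles)`` when
    ``return_bundles`` is true.
    """
    master = config.seed if seed is None else seed
    phantom = phantom or generate_phantom()
    root = np.random.SeedSequence(master)
    cohort_ss, survival_ss = root.spawn(2)
    rng = np.random.default_rng(cohort_ss)
    n = config.n_patients
    m = config.marginals

    table = _sample_covariates(rng, config)
    schemes = _sample_schemes(rng, config, n)
    want_svz = rng.uniform(size=n) < m["svz_contact_p"]
    want_hpc = rng.uniform(size=n) < m["hpc_contact_p"]
    n_lesions = np.ones(n, dtype=int)
    multi = (table["n_bm"] == "2-4").to_numpy()
    many = (table["n_bm"] == ">4").to_numpy()
    n_lesions[multi] = rng.integers(2, 5, int(multi.sum()))
    n_lesions[many] = rng.integers(5, 9, int(many.sum()))
    # a single lesion cannot touch both niches in this geometry; SVZ wins
    both_single = want_svz & want_hpc & (n_lesions == 1)
    want_hpc[both_single] = False

    patient_seeds = cohort_ss.spawn(n)
    bundles: list[PatientBundle] = []
    rows = []
    vox_cm3 = phantom.labels.voxel_volume_cm3
    for i in range(n):
        prng = np.random.default_rng(patient_seeds[i])
        bundle = _patient_imaging(
            phantom,
            prng,
            config,
            table.at[i, "patient_id"],
            float(table.at[i, "gtv_volume_cm3"]),
            int(n_lesions[i]),
            schemes[i],
            bool(want_svz[i]),
            bool(want_hpc[i]),
        )
        svz_contact = niche_dosimetry.classify_contact(
            phantom.labels, bundle.lesion_mask, phantom.scheme, "SVZ"
        )
        hpc_contact = niche_dosimetry.classify_contact(
            phantom.labels, bundle.lesion_mask, phantom.scheme, "HPC"
        )
        row = {
            "svz_mean_dose_gy": bundle.summary.pooled_mean_gy["SVZ"],
            "hpc_mean_dose_gy": bundle.summary.pooled_mean_gy["HPC"],
            "svz_volume_cm3": bundle.summary.pooled_volume_cm3["SVZ"],
            "sgz_volume_cm3": bundle.summary.pooled_volume_cm3["HPC"],
            "svz_contact": "yes" if svz_contact.any_contact else "no",
            "hpc_contact": "yes" if hpc_contact.any_contact else "no",
            "ptv_volume_cm3": float(bundle.ptv_mask.values.sum()) * vox_cm3,
            "centrality_cm": (
                niche_dosimetry.centrality(bundle.ptv_mask, phantom.spec.ac_point_mm)
                if n_lesions[i] == 1
                else np.nan
            ),
        }
        rows.append(row)
        if return_bundles:
            bundles.append(bundle)

    features = pd.DataFrame(rows)
    table = pd.concat([table, features], axis=1)
    # fully swallowed niches have undefined dose; keep rows but mark dose NaN
    srng = np.random.default_rng(survival_ss)
    table = simulate_survival(table.fillna({"svz_mean_dose_gy": 0.0, "hpc_mean_dose_gy": 0.0}), config, srng)
    table = _apply_missingness(table, srng, config)
    table = table[COHORT_COLUMNS]
    return (table, bundles) if return_bundles else table
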