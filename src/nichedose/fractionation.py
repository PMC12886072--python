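"""Linear-quadratic fractionation corrections: BED and SFED.

Multi-fraction stereotactic regimens are made comparable to single-fraction
radiosurgery through the biologically effective dose (BED) of the
linear-quadratic model,

    BED = n * d * (1 + d / (alpha/beta)),

with ``n`` the fraction count, ``d`` the dose per fraction (Gy) and
``alpha/beta`` the tissue sensitivity ratio (Gy; 2 Gy is a common value for
late-responding brain tissue).  The single-fraction equivalent dose (SFED) is
the single-fraction dose with the same BED, i.e. the positive root of
``d^2 + d*(a/b) - BED*(a/b) = 0``:

    SFED = (a/b)/2 * (sqrt(1 + 4*BED/(a/b)) - 1),

which for alpha/beta = 2 reduces to sqrt(1 + 2*BED) - 1.  For example, both
3 x 8 Gy and 5 x 6 Gy have BED 120 Gy and convert to 14.52 Gy in one
fraction.

Voxelwise variants apply the same algebra to a whole 3D dose map: the total
dose map is divided by ``n`` to obtain the per-fraction map, which drives a
voxelwise correction factor ``1 + d_voxel/(a/b)``; multiplying the original
map by that factor yields the BED map, and the closed-form inversion above
maps it to the SFED map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume_io import VolumeGrid

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_BETA = 2.0  # Gy, late-responding brain tissue


@dataclass(frozen=True)
class FractionationScheme:
    """A uniform fractionation regimen: ``n`` fractions of ``d`` Gy each."""

    n: int
    d: float
    alpha_beta: float = DEFAULT_ALPHA_BETA

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"fraction count must be a positive integer, got {self.n}")
        if self.d < 0:
            raise ValueError(f"dose per fraction must be non-negative, got {self.d}")
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha/beta must be positive, got {self.alpha_beta}")

    @property
    def total_dose(self) -> float:
        """Total physical dose n*d in Gy."""
        return self.n * self.d


def bed_scalar(scheme: FractionationScheme) -> float:
    """BED of a regimen: ``n * d * (1 + d/(alpha/beta))`` in Gy."""
    return scheme.n * scheme.d * (1.0 + scheme.d / scheme.alpha_beta)


def sfed_from_bed(bed, alpha_beta: float = DEFAULT_ALPHA_BETA):
    """Invert BED to the single-fraction dose (positive quadratic root).

    Accepts scalars or arrays; raises on negative BED (no physical solution).
    """
    bed = np.asarray(bed, dtype=float)
    if np.any(bed < 0):
        raise ValueError("BED must be non-negative")
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be positive")
    out = 0.5 * alpha_beta * (np.sqrt(1.0 + 4.0 * bed / alpha_beta) - 1.0)
    return float(out) if out.ndim == 0 else out


def sfed_scheme(scheme: FractionationScheme) -> float:
    """Single-fraction equivalent dose of a regimen in Gy.

    Equals ``scheme.d`` when ``n == 1``; strictly below the physical total
    ``n*d`` for any true multi-fraction course with d > 0.
    """
    return float(sfed_from_bed(bed_scalar(scheme), scheme.alpha_beta))


def _clamped_dose(dose: VolumeGrid) -> np.ndarray:
    """Dose values with negatives (upstream interpolation artifacts) set to 0."""
    vals = np.asarray(dose.values, dtype=float)
    neg = vals < 0
    if neg.any():
        logger.warning(
            "clamped %d negative dose voxels (min %.4g Gy) to 0", neg.sum(), vals.min()
        )
        vals = np.where(neg, 0.0, vals)
    return vals


def bed_map(dose: VolumeGrid, n: int, alpha_beta: float = DEFAULT_ALPHA_BETA) -> VolumeGrid:
    """Voxelwise BED map of a total (multi-fraction) dose map.

    Each voxel's total dose D becomes ``D * (1 + (D/n)/(alpha/beta))``,
    assuming the dose was delivered uniformly over ``n`` fractions.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"fraction count must be a positive integer, got {n}")
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be positive")
    total = _clamped_dose(dose)
    correction = 1.0 + (total / n) / alpha_beta
    return dose.with_values(total * correction, unit="Gy(BED)")


def sfed_map(dose: VolumeGrid, n: int, alpha_beta: float = DEFAULT_ALPHA_BETA) -> VolumeGrid:
    """Voxelwise single-fraction equivalent of a total dose map.

    Composition of :func:`bed_map` with the closed-form BED inversion; an
    ``n == 1`` map is returned unchanged up to floating point, and voxel
    ordering is preserved (the transform is strictly increasing).
    """
    bed = bed_map(dose, n, alpha_beta)
    return dose.with_values(sfed_from_bed(bed.values, alpha_beta), unit="Gy")
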