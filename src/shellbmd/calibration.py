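"""Two-energy phantom calibration and pixel-wise decomposition.

The calibration phantom carries cylindrical hydroxyapatite (HA) inserts
of known density.  Mean HU inside each insert is measured on the 50 and
200 keV virtual-monoenergetic volumes over identical voxel sets, an
ordinary least-squares line ``HU = slope * density + intercept`` is
fitted independently per energy, and each image pixel's HU pair is then
solved for the bone volume fraction ``f`` in a two-equation least
squares sense:

    hu_E ≈ intercept_E + f * slope_E * rho_ref       (E = 50, 200)

with closed form (unit weights)

    f = sum_E (hu_E - intercept_E) * slope_E * rho_ref
        / sum_E (slope_E * rho_ref)^2

and ``BMD = clamp(f) * rho_ref``.  ``rho_ref`` is the density of the
pure-mineral basis endpoint; it cancels in BMD and is fixed by
convention to the densest phantom insert so that f spans [0, 1] over
the calibrated range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

from .volumes import SpectralVolume, require_same_grid

__all__ = [
    "CalibrationSample",
    "CalibrationModel",
    "DecompositionResult",
    "measure_insert_vois",
    "fit_calibration",
    "decompose_pixel",
    "SingularFitError",
    "MeasurementError",
]


class SingularFitError(ValueError):
    """Calibration samples do not span distinct densities."""


class MeasurementError(ValueError):
    """A VOI could not be measured (e.g. empty after shrinking)."""


@dataclass(frozen=True)
class CalibrationSample:
    """Mean HU of one phantom insert at both energies."""

    density: float          # known insert density, mgHA/cm^3
    mean_hu_50: float
    mean_hu_200: float
    voxel_count: int

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("insert density must be >= 0")
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-energy HU-vs-density lines plus the mineral basis endpoint.

    ``bilinear`` optionally holds (a, b, c) of the alternative single
    joint fit ``bmd = a*hu50 + b*hu200 + c``; both modes coincide on
    noise-free phantom data.
    """

    slope_50: float         # HU per mgHA/cm^3 at 50 keV
    intercept_50: float     # HU
    slope_200: float
    intercept_200: float
    rho_ref: float          # mgHA/cm^3
    fit_r2_pair: tuple[float, float] = (float("nan"), float("nan"))
    bilinear: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.rho_ref <= 0:
            raise ValueError("rho_ref must be > 0")

    def basis_endpoints(self) -> dict[str, tuple[float, float]]:
        """HU pair of the soft-tissue (f=0) and pure-mineral (f=1) endpoints."""
        return {
            "soft_tissue": (self.intercept_50, self.intercept_200),
            "mineral": (
                self.intercept_50 + self.slope_50 * self.rho_ref,
                self.intercept_200 + self.slope_200 * self.rho_ref,
            ),
        }


@dataclass(frozen=True)
class DecompositionResult:
    """Pixel decomposition output: volume fraction, BMD and HU misfit."""

    fraction: float         # clamped bone volume fraction
    bmd: float              # mgHA/cm^3, = fraction * rho_ref
    residual: float         # root-sum-square HU misfit at the solution


def measure_insert_vois(
    volume_50: SpectralVolume,
    volume_200: SpectralVolume,
    spec,
    voi_shrink: float = 0.7,
) -> list[CalibrationSample]:
    """Measure mean HU in shrunken cylindrical VOIs inside each insert.

    The VOI radius is ``voi_shrink`` times the insert radius (and the
    cylinder height is shrunk by the same factor when finite), which
    keeps the VOI away from partial-volume rims.  The identical voxel
    set is averaged in both volumes.
    """
    require_same_grid(volume_50, volume_200)
    if not (0 < voi_shrink <= 1):
        raise ValueError("voi_shrink must lie in (0, 1]")
    nx, ny, nz = volume_50.shape
    sx, sy, sz = volume_50.spacing_mm
    ox, oy, oz = volume_50.origin_mm
    xs = ox + (np.arange(nx) + 0.5) * sx
    ys = oy + (np.arange(ny) + 0.5) * sy
    zs = oz + (np.arange(nz) + 0.5) * sz
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    samples = []
    for density, center in zip(spec.insert_densities, spec.insert_centers):
        cx, cy, cz = center
        r = voi_shrink * spec.insert_radius_mm
        in_plane = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
        height = getattr(spec, "insert_height_mm", None)
        if height is None:
            z_ok = np.ones(nz, dtype=bool)
        else:
            z_ok = np.abs(zs - cz) <= voi_shrink * height / 2.0
        mask = in_plane[:, :, None] & z_ok[None, None, :]
        count = int(mask.sum())
        if count == 0:
            raise MeasurementError(
                f"VOI for insert at {center} is empty after shrink {voi_shrink}"
            )
        samples.append(
            CalibrationSample(
                density=float(density),
                mean_hu_50=float(volume_50.voxels[mask].mean()),
                mean_hu_200=float(volume_200.voxels[mask].mean()),
                voxel_count=count,
            )
        )
    return samples


def fit_calibration(
    samples: list[CalibrationSample],
    rho_ref: float | None = None,
    fit_bilinear: bool = True,
) -> CalibrationModel:
    """OLS line HU = slope*density + intercept, independently per energy.

    ``rho_ref`` defaults to the largest sample density.  With exactly
    two samples the lines interpolate them; r^2 is reported per energy.
    """
    if len(samples) < 2:
        raise SingularFitError("need at least 2 calibration samples")
    d = np.array([s.density for s in samples], dtype=float)
    if np.ptp(d) == 0:
        raise SingularFitError("all calibration densities identical; fit is singular")
    if rho_ref is None:
        rho_ref = float(d.max())

    r2 = []
    lines = []
    for hu in (
        np.array([s.mean_hu_50 for s in samples]),
        np.array([s.mean_hu_200 for s in samples]),
    ):
        res = _sstats.linregress(d, hu)
        lines.append((res.slope, res.intercept))
        # linregress rvalue is nan-free here since ptp(d) > 0; a perfectly
        # flat response gives rvalue 0
        r2.append(float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0)

    bilinear = None
    if fit_bilinear:
        A = np.column_stack(
            [
                [s.mean_hu_50 for s in samples],
                [s.mean_hu_200 for s in samples],
                np.ones(len(samples)),
            ]
        )
        coef, *_ = np.linalg.lstsq(A, d, rcond=None)
        bilinear = (float(coef[0]), float(coef[1]), float(coef[2]))

    return CalibrationModel(
        slope_50=float(lines[0][0]),
        intercept_50=float(lines[0][1]),
        slope_200=float(lines[1][0]),
        intercept_200=float(lines[1][1]),
        rho_ref=float(rho_ref),
        fit_r2_pair=(r2[0], r2[1]),
        bilinear=bilinear,
    )


def _solve_fraction(hu_50, hu_200, model: CalibrationModel):
    """Closed-form least-squares bone volume fraction (unclamped)."""
    a50 = model.slope_50 * model.rho_ref
    a200 = model.slope_200 * model.rho_ref
    num = (np.asarray(hu_50, dtype=float) - model.intercept_50) * a50 + (
        np.asarray(hu_200, dtype=float) - model.intercept_200
    ) * a200
    den = a50**2 + a200**2
    return num / den


def decompose_pixel(
    hu_50,
    hu_200,
    model: CalibrationModel,
    clamp: str = "floor-zero",
    mode: str = "per_energy",
):
    """Decompose an HU pair into bone volume fraction and BMD.

    Scalar inputs return a :class:`DecompositionResult`; array inputs
    return ``(fraction, bmd, residual)`` arrays.  ``clamp`` is
    ``"floor-zero"`` (negative fractions mapped to 0, the default; ROI
    population minima of 0 motivate a hard floor) or ``"none"``.
    ``mode="bilinear"`` uses the joint fit stored on the model.
    """
    if clamp not in ("floor-zero", "none"):
        raise ValueError(f"unknown clamp policy {clamp!r}")
    if mode == "per_energy":
        f = _solve_fraction(hu_50, hu_200, model)
    elif mode == "bilinear":
        if model.bilinear is None:
            raise ValueError("model carries no bilinear fit")
        a, b, c = model.bilinear
        bmd_raw = a * np.asarray(hu_50, dtype=float) + b * np.asarray(hu_200, dtype=float) + c
        f = bmd_raw / model.rho_ref
    else:
        raise ValueError(f"unknown decomposition mode {mode!r}")

    if clamp == "floor-zero":
        f_cl = np.maximum(f, 0.0)
    else:
        f_cl = f
    bmd = f_cl * model.rho_ref
    r50 = model.intercept_50 + f_cl * model.slope_50 * model.rho_ref - np.asarray(hu_50, dtype=float)
    r200 = (
        model.intercept_200 + f_cl * model.slope_200 * model.rho_ref - np.asarray(hu_200, dtype=float)
    )
    residual = np.sqrt(r50**2 + r200**2)

    if np.isscalar(hu_50) or (np.ndim(hu_50) == 0 and np.ndim(hu_200) == 0):
        return DecompositionResult(
            fraction=float(f_cl), bmd=float(bmd), residual=float(residual)
        )
    return f_cl, bmd, residual
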