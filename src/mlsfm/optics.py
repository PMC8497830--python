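"""Closed-form optical model for a zoom-body light-sheet macroscope.

The detection side is a macro zoom body (zoom 0.63-6.3x) behind a low-power,
high-NA objective, projecting onto an sCMOS camera; the illumination side is a
cylindrical-lens telescope producing a Gaussian sheet whose waist is swept
axially by a tunable lens.  Everything here is algebra on those parameters:
relative brightness laws, the magnification chain, sample-space pixel size,
diffraction-limited resolution, and Gaussian-beam sheet geometry.

Units: lengths in micrometres (um) unless the name says otherwise; focal
lengths in millimetres (mm); NA, magnification, zoom dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ObjectiveSpec",
    "DetectionPath",
    "SheetModel",
    "relative_brightness_lsfm",
    "relative_brightness_widefield",
    "total_magnification",
    "effective_pixel_size",
    "rayleigh_resolution",
    "telescope_expansion",
    "rayleigh_range",
    "sheet_half_thickness",
    "sheet_fwhm",
    "aperture_to_waist",
    "load_na_mag_table",
]

#: Intensity FWHM of a Gaussian beam of 1/e^2 radius w is sqrt(2 ln 2) * w.
GAUSSIAN_BEAM_FWHM_FACTOR = math.sqrt(2.0 * math.log(2.0))


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class ObjectiveSpec:
    """A detection or illumination objective.

    ``numerical_aperture`` must be below ``immersion_index`` (NA = n sin θ).
    """

    name: str
    numerical_aperture: float
    magnification: float
    working_distance_mm: float | None = None
    immersion_index: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            numerical_aperture=self.numerical_aperture,
            magnification=self.magnification,
        )
        if self.immersion_index < 1.0:
            raise ValueError("immersion_index must be >= 1")
        if not self.numerical_aperture < self.immersion_index:
            raise ValueError(
                "numerical_aperture must be < immersion_index "
                f"({self.numerical_aperture} >= {self.immersion_index})"
            )


@dataclass(frozen=True)
class DetectionPath:
    """Objective + zoom body + camera: the full detection chain."""

    objective: ObjectiveSpec
    zoom: float = 1.0
    camera_pixel_pitch_um: float = 6.5
    sensor_shape_px: tuple[int, int] = (2048, 2048)
    emission_wavelength_um: float = 0.52
    zoom_range: tuple[float, float] = (0.63, 6.3)

    def __post_init__(self) -> None:
        _require_positive(
            zoom=self.zoom,
            camera_pixel_pitch_um=self.camera_pixel_pitch_um,
            emission_wavelength_um=self.emission_wavelength_um,
        )
        lo, hi = self.zoom_range
        if not (lo <= self.zoom <= hi):
            raise ValueError(f"zoom {self.zoom} outside configured range [{lo}, {hi}]")
        if any(int(s) <= 0 for s in self.sensor_shape_px):
            raise ValueError("sensor_shape_px must be positive")

    @property
    def total_magnification(self) -> float:
        return total_magnification(self.zoom, self.objective.magnification)

    @property
    def pixel_size_um(self) -> float:
        return effective_pixel_size(self.camera_pixel_pitch_um, self.total_magnification)

    @property
    def fov_um(self) -> tuple[float, float]:
        """(rows, cols) field of view in sample space."""
        p = self.pixel_size_um
        return (self.sensor_shape_px[0] * p, self.sensor_shape_px[1] * p)

    @property
    def relative_brightness(self) -> float:
        return relative_brightness_lsfm(
            self.objective.numerical_aperture, self.total_magnification
        )

    def lateral_resolution_um(self) -> float:
        return rayleigh_resolution(
            self.emission_wavelength_um, self.objective.numerical_aperture
        )


@dataclass(frozen=True)
class SheetModel:
    """Gaussian light sheet: waist radius w0 (1/e^2 intensity) and wavelength.

    ``aperture_fraction`` models the motorised iris trimming the beam before
    the illumination objective; closing the iris widens the waist inversely.
    """

    waist_radius_w0_um: float = 1.7
    excitation_wavelength_um: float = 0.488
    medium_index: float = 1.33
    aperture_fraction: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            waist_radius_w0_um=self.waist_radius_w0_um,
            excitation_wavelength_um=self.excitation_wavelength_um,
            medium_index=self.medium_index,
            aperture_fraction=self.aperture_fraction,
        )
        if self.aperture_fraction > 1.0:
            raise ValueError("aperture_fraction must be <= 1")


def relative_brightness_lsfm(na: float, mag: float) -> float:
    """Relative image brightness NA^2 / Mag^2 for light-sheet detection.

    The sheet thickness fixes the illuminated slab, so only the collection
    power (NA^2) and image-area dilution (1/Mag^2) remain.
    """
    _require_positive(na=na, mag=mag)
    return na**2 / mag**2


def relative_brightness_widefield(na: float, mag: float) -> float:
    """Relative brightness NA^4 / Mag^2 for epifluorescence.

    Illumination condensing contributes a second NA^2 factor because the same
    objective both excites and collects.
    """
    _require_positive(na=na, mag=mag)
    return na**4 / mag**2


def total_magnification(zoom: float, objective_mag: float) -> float:
    """Zoom body x objective, e.g. 6.3 x 2 = 12.6."""
    _require_positive(zoom=zoom, objective_mag=objective_mag)
    return zoom * objective_mag


def effective_pixel_size(
    camera_pitch_um: float, total_mag: float, expansion_factor: float = 1.0
) -> float:
    """Sample-space pixel size: pitch / (magnification x tissue expansion)."""
    _require_positive(
        camera_pitch_um=camera_pitch_um,
        total_mag=total_mag,
        expansion_factor=expansion_factor,
    )
    return camera_pitch_um / (total_mag * expansion_factor)


def rayleigh_resolution(emission_wavelength_um: float, na: float) -> float:
    """Rayleigh lateral resolution 0.61 lambda / NA."""
    _require_positive(emission_wavelength_um=emission_wavelength_um, na=na)
    return 0.61 * emission_wavelength_um / na


def telescope_expansion(f_in_mm: float, f_out_mm: float) -> float:
    """Beam expansion ratio f_out / f_in of a two-lens telescope."""
    _require_positive(f_in_mm=f_in_mm, f_out_mm=f_out_mm)
    return f_out_mm / f_in_mm


def rayleigh_range(sheet: SheetModel) -> float:
    """z_R = pi w0^2 n / lambda: distance over which the waist grows sqrt(2)."""
    return (
        math.pi
        * sheet.waist_radius_w0_um**2
        * sheet.medium_index
        / sheet.excitation_wavelength_um
    )


def sheet_half_thickness(sheet: SheetModel, z_offset_um):
    """Gaussian beam half-thickness w(z) = w0 sqrt(1 + (z/z_R)^2).

    ``z_offset_um`` is distance along the propagation axis from the waist;
    scalar or array.  Even in z and non-decreasing in |z|.
    """
    z = np.asarray(z_offset_um, dtype=float)
    zr = rayleigh_range(sheet)
    w = sheet.waist_radius_w0_um * np.sqrt(1.0 + (z / zr) ** 2)
    return float(w) if np.isscalar(z_offset_um) else w


def sheet_fwhm(sheet: SheetModel, z_offset_um):
    """Intensity FWHM across the sheet, sqrt(2 ln 2) * w(z) ~ 1.177 w(z)."""
    return GAUSSIAN_BEAM_FWHM_FACTOR * sheet_half_thickness(sheet, z_offset_um)


def aperture_to_waist(sheet: SheetModel, na_illum_max: float) -> float:
    """Waist from the iris setting: w0 = lambda / (pi * a * NA_max).

    Halving the open aperture fraction ``a`` doubles the waist (and thickens
    the sheet), which is how the electric diaphragm trades sheet length for
    thinness across zoom settings.
    """
    _require_positive(na_illum_max=na_illum_max)
    if sheet.aperture_fraction <= 0:
        raise ValueError("aperture_fraction must be > 0")
    return sheet.excitation_wavelength_um / (
        math.pi * sheet.aperture_fraction * na_illum_max
    )


def load_na_mag_table() -> pd.DataFrame:
    """Bundled (magnification, NA) table of representative commercial objectives.

    NA rises monotonically but sublinearly (concave) with magnification, so
    NA/Mag falls with magnification: light-sheet brightness NA^2/Mag^2 is
    strictly decreasing over the table while the widefield NA^4/Mag^2 law
    peaks at an interior magnification.
    """
    with resources.files("mlsfm.data").joinpath("objectives_na_mag.csv").open() as fh:
        return pd.read_csv(fh)
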