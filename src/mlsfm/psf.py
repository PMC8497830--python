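"""Bead detection and Gaussian FWHM fitting for PSF characterization.

Sub-resolution fluorescent beads are detected as isolated local maxima,
cropped, projected onto each axis, and fitted with a 1D Gaussian plus a
baseline; the per-axis FWHM (2 sqrt(2 ln 2) sigma) is aggregated across
beads by the median.  This mirrors the usual bead-based resolution
measurement where the reported triple (lateral x, lateral y, axial z) may be
limited by pixel size and z-step rather than by optics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .acquisition import TileStack
from .triage import MAD_TO_SD

__all__ = ["PSFEstimate", "detect_beads", "fit_fwhm", "characterize"]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


@dataclass
class PSFEstimate:
    """Median per-axis FWHM (um) over the analysed beads."""

    center_um: tuple[float, float, float]
    fwhm_z_um: float
    fwhm_y_um: float
    fwhm_x_um: float
    fit_r2: tuple[float, float, float]
    n_beads: int

    def __post_init__(self) -> None:
        for f in (self.fwhm_z_um, self.fwhm_y_um, self.fwhm_x_um):
            if f <= 0:
                raise ValueError("FWHM must be > 0")
        for r in self.fit_r2:
            if not (0.0 <= r <= 1.0 + 1e-9):
                raise ValueError("r2 must be in [0, 1]")


def _background_stats(vol: np.ndarray) -> tuple[float, float]:
    med = float(np.median(vol))
    sd = MAD_TO_SD * float(np.median(np.abs(vol - med)))
    return med, sd


def detect_beads(
    stack: TileStack | np.ndarray,
    min_separation_px: int = 8,
    threshold_k: float = 10.0,
) -> np.ndarray:
    """Centres (z, y, x in px, centroid-refined) of isolated beads.

    Local maxima above background median + k * MAD-sd are kept; any pair of
    candidates closer than ``min_separation_px`` is rejected *entirely* (both
    members), because overlapping bead images bias the fit.  An empty array
    is a valid result.
    """
    vol = (stack.voxels if isinstance(stack, TileStack) else np.asarray(stack)).astype(float)
    if vol.size == 0:
        raise ValueError("empty stack")
    med, sd = _background_stats(vol)
    thr = med + threshold_k * max(sd, 1e-12)
    peaks = peak_local_max(vol, min_distance=1, threshold_abs=thr, exclude_border=1)
    if len(peaks) == 0:
        return np.empty((0, vol.ndim))
    # drop every member of any too-close pair
    keep = np.ones(len(peaks), dtype=bool)
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            if np.linalg.norm(peaks[i] - peaks[j]) < min_separation_px:
                keep[i] = keep[j] = False
    peaks = peaks[keep]
    # centroid refinement on a small background-subtracted crop
    centers = []
    r = 3
    for p in peaks:
        sl = tuple(
            slice(max(0, c - r), min(s, c + r + 1)) for c, s in zip(p, vol.shape)
        )
        crop = vol[sl] - med
        crop = np.clip(crop, 0, None)
        total = crop.sum()
        if total <= 0:
            centers.append(p.astype(float))
            continue
        grids = np.meshgrid(
            *[np.arange(s.start, s.stop) for s in sl], indexing="ij"
        )
        centers.append(np.array([float((g * crop).sum() / total) for g in grids]))
    return np.array(centers)


def _gaussian(x, amplitude, center, sigma, baseline):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2) + baseline


def fit_fwhm(profile: np.ndarray, spacing: float = 1.0) -> tuple[float, float]:
    """Least-squares Gaussian fit of a 1D profile -> (FWHM, r^2).

    The model is amplitude * exp(-(x-c)^2 / 2 sigma^2) + baseline; the FWHM
    is 2 sqrt(2 ln 2) sigma * spacing.  A flat or non-convergent profile
    raises with the residual context.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 samples")
    x = np.arange(y.size, dtype=float)
    baseline0 = float(y.min())
    amp0 = float(y.max() - baseline0)
    if amp0 <= 0:
        raise ValueError("flat profile: no peak to fit")
    c0 = float(np.argmax(y))
    above = y - baseline0 > amp0 / 2
    sigma0 = max(np.count_nonzero(above) / FWHM_FACTOR, 0.5)
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=[amp0, c0, sigma0, baseline0],
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise ValueError(f"Gaussian fit did not converge: {exc}") from exc
    amplitude, center, sigma, baseline = popt
    residual = y - _gaussian(x, *popt)
    ss_res = float(np.sum(residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if amplitude <= 0 or not np.isfinite(sigma):
        raise ValueError(
            f"degenerate fit (amplitude={amplitude:.3g}); residual SS={ss_res:.3g}"
        )
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return abs(sigma) * FWHM_FACTOR * spacing, max(0.0, min(1.0, r2))


def characterize(
    stack: TileStack | np.ndarray,
    voxel_size_um: tuple[float, float, float],
    min_separation_px: int = 8,
    threshold_k: float = 10.0,
    crop_radius_px: tuple[int, int, int] = (8, 8, 8),
) -> PSFEstimate:
    """Detect beads, fit per-axis FWHM on axis projections, aggregate.

    Each bead crop is max-projected onto z, y and x, fitted independently,
    and the median FWHM (and median r^2) across beads is reported.
    ``voxel_size_um`` is (z, y, x) sampling.
    """
    vol = (stack.voxels if isinstance(stack, TileStack) else np.asarray(stack)).astype(float)
    centers = detect_beads(vol, min_separation_px, threshold_k)
    if len(centers) == 0:
        raise ValueError("no beads detected")
    per_axis: list[list[float]] = [[], [], []]
    r2s: list[list[float]] = [[], [], []]
    for c in centers:
        sl = tuple(
            slice(max(0, int(round(ci)) - r), min(s, int(round(ci)) + r + 1))
            for ci, r, s in zip(c, crop_radius_px, vol.shape)
        )
        crop = vol[sl]
        for ax in range(3):
            others = tuple(i for i in range(3) if i != ax)
            profile = crop.max(axis=others)
            try:
                fwhm, r2 = fit_fwhm(profile, spacing=voxel_size_um[ax])
            except ValueError:
                continue
            per_axis[ax].append(fwhm)
            r2s[ax].append(r2)
    if any(len(v) == 0 for v in per_axis):
        raise ValueError("no bead produced a usable fit on every axis")
    med = [float(np.median(v)) for v in per_axis]
    center_um = tuple(
        float(np.median(centers[:, ax]) * voxel_size_um[ax]) for ax in range(3)
    )
    return PSFEstimate(
        center_um=center_um,
        fwhm_z_um=med[0],
        fwhm_y_um=med[1],
        fwhm_x_um=med[2],
        fit_r2=tuple(float(np.median(r)) for r in r2s),
        n_beads=len(centers),
    )
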