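"""Electrophysiological boundary localization along an electrode track.

Near the boundary of a GABAergic shell nucleus (e.g. the thalamic reticular
nucleus), the fraction of narrow-spiking units rises from ~0 to ~1 as the
electrode crosses in.  Fitting a logistic curve to the per-unit
narrow/wide labels against signed distance gives the half-probability point
d0 — the physiology-based estimate of the boundary location — and a
transition width (slope).  The fit is a Bernoulli maximum-likelihood
logistic regression on the raw labels (bin-free); the confidence interval
for d0 comes from the profile likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .phantom import SpikeTrackData

__all__ = [
    "SigmoidFit",
    "narrow_fraction_profile",
    "fit_sigmoid",
    "fit_sigmoid_per_track",
]


@dataclass
class SigmoidFit:
    """P(narrow | d) = 1 / (1 + exp(-(d - d0)/slope))."""

    d0_um: float
    slope_um: float
    loglik: float
    ci_d0_um: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if self.slope_um <= 0:
            raise ValueError("slope must be > 0")

    def predict(self, distance_um) -> np.ndarray:
        return expit((np.asarray(distance_um, float) - self.d0_um) / self.slope_um)


def narrow_fraction_profile(
    data: SpikeTrackData, bin_width_um: float
) -> pd.DataFrame:
    """Binned narrow-spiking fraction along the track.

    Returns (distance_um = bin centre, fraction, n); empty bins are omitted.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    d = np.asarray(data.distance_um, float)
    if d.size == 0:
        raise ValueError("empty spike-track data")
    lo = np.floor(d.min() / bin_width_um) * bin_width_um
    hi = np.ceil(d.max() / bin_width_um) * bin_width_um
    edges = np.arange(lo, hi + bin_width_um, bin_width_um)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width_um])
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append(
            {
                "distance_um": 0.5 * (edges[b] + edges[b + 1]),
                "fraction": float(np.mean(data.is_narrow[sel])),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def _nll(params: np.ndarray, d: np.ndarray, y: np.ndarray) -> float:
    d0, log_s = params
    z = (d - d0) / np.exp(log_s)
    # log P(y) = y * log expit(z) + (1-y) * log expit(-z), numerically stable
    return float(-np.sum(np.where(y, log_expit(z), log_expit(-z))))


def fit_sigmoid(
    data: SpikeTrackData,
    ci_level: float = 0.95,
    min_slope_um: float = 1e-3,
    compute_ci: bool = True,
) -> SigmoidFit:
    """Bernoulli MLE of the logistic transition (d0, slope).

    Requires both classes to be present (otherwise d0 is non-identifiable).
    With perfectly separated data the likelihood pushes the slope toward
    zero; the optimum is taken at ``min_slope_um`` with d0 inside the gap,
    which keeps the estimate stable.  The d0 confidence interval is the
    profile-likelihood interval at ``ci_level``.
    """
    d = np.asarray(data.distance_um, float)
    y = np.asarray(data.is_narrow, bool)
    if y.all() or not y.any():
        raise ValueError("need both narrow and wide units to fit a transition")

    span = float(d.max() - d.min()) or 1.0
    starts = [
        (float(np.quantile(d, q)), np.log(span / 10.0)) for q in (0.25, 0.5, 0.75)
    ]
    best = None
    for x0 in starts:
        res = minimize(
            _nll,
            x0=np.array(x0),
            args=(d, y),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    d0 = float(best.x[0])
    slope = max(float(np.exp(best.x[1])), min_slope_um)
    nll0 = float(best.fun)

    ci = (d0, d0)
    if compute_ci:
        # profile likelihood CI for d0: scan d0, re-maximize over slope
        from scipy.stats import chi2

        crit = 0.5 * chi2.ppf(ci_level, df=1)

        def profile(d0_fixed: float) -> float:
            r = minimize(
                lambda ls: _nll(np.array([d0_fixed, ls[0]]), d, y),
                x0=np.array([np.log(slope)]),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-8},
            )
            return float(r.fun)

        grid = np.linspace(
            d0 - 4.0 * slope - 0.05 * span, d0 + 4.0 * slope + 0.05 * span, 81
        )
        inside = [g for g in grid if profile(g) - nll0 <= crit]
        ci = (min(inside), max(inside)) if inside else (d0, d0)

    return SigmoidFit(
        d0_um=d0,
        slope_um=slope,
        loglik=-nll0,
        ci_d0_um=(float(ci[0]), float(ci[1])),
        n=len(d),
    )


def fit_sigmoid_per_track(data: SpikeTrackData, **kwargs) -> dict[int, SigmoidFit]:
    """Independent fits per track id (requires ``track_id`` labels)."""
    if data.track_id is None:
        raise ValueError("data has no track_id labels")
    out = {}
    for tid in np.unique(data.track_id):
        sel = data.track_id == tid
        sub = SpikeTrackData(
            distance_um=data.distance_um[sel], is_narrow=data.is_narrow[sel]
        )
        out[int(tid)] = fit_sigmoid(sub, **kwargs)
    return out
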