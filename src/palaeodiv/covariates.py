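"""Analysis-ready environmental covariate curves.

Builds the time-continuous covariates C_i(t) used by the multivariate
birth-death model: the delta-18-O to deep-sea temperature transform, merging
of curves from different sources/eras, smoothing-spline subsampling to a
regular (default 0.5 Myr) grid, interpolation, and the self-diversity
covariate derived from a range-through diversity curve.

Covariates are kept in raw units (degrees C, metres, per-mil, index values,
km^3); correlation coefficients downstream are therefore per covariate unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "EnvCurve",
    "EPSTEIN_COEFFS",
    "d18o_to_temperature",
    "merge_curves",
    "spline_subsample",
    "curve_value_at",
    "diversity_covariate_from_ltt",
]

#: Coefficients (a, b, c) of the classic palaeotemperature quadratic
#: T = a + b * d18O + c * d18O**2 (carbonate-water fractionation).
EPSTEIN_COEFFS = (16.5, -4.3, 0.14)


@dataclass(frozen=True)
class EnvCurve:
    """A named covariate sampled at strictly increasing ages (Ma)."""

    name: str
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.ndim != 1 or ages.shape != values.shape:
            raise ValueError("ages and values must be 1-D arrays of equal length")
        if ages.size == 0:
            raise ValueError("empty curve")
        if ages.size > 1 and not np.all(np.diff(ages) > 0):
            raise ValueError("ages must be strictly increasing")
        if not (np.isfinite(ages).all() and np.isfinite(values).all()):
            raise ValueError("curve contains non-finite entries")

    def __len__(self) -> int:
        return int(self.ages.size)

    def at(self, t) -> np.ndarray | float:
        return curve_value_at(self, t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": self.ages, self.name: self.values})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def d18o_to_temperature(delta18o):
    """Deep-sea temperature (degrees C) from benthic delta-18-O (per mil).

    Uses the canonical quadratic palaeotemperature equation
    ``T = 16.5 - 4.3 * d + 0.14 * d**2``; no ice-volume or seawater
    correction is applied (interpolated long-term curves smooth such biases).
    """
    a, b, c = EPSTEIN_COEFFS
    d = np.asarray(delta18o, dtype=float)
    out = a + b * d + c * d * d
    return float(out) if out.ndim == 0 else out


def merge_curves(young: EnvCurve, old: EnvCurve, switch_age: float) -> EnvCurve:
    """Splice two curves at ``switch_age``: ``young`` strictly below it,
    ``old`` at and above it (e.g. a Cenozoic and a Mesozoic isotope record).
    """
    if old.ages.min() - switch_age > 1.0:
        raise ValueError(
            f"coverage gap: old curve starts at {old.ages.min()} Ma, "
            f"more than 1 Myr past switch age {switch_age}"
        )
    if switch_age - young.ages.max() > 1.0:
        raise ValueError(
            f"coverage gap: young curve ends at {young.ages.max()} Ma, "
            f"more than 1 Myr short of switch age {switch_age}"
        )
    keep_y = young.ages < switch_age
    keep_o = old.ages >= switch_age
    ages = np.concatenate([young.ages[keep_y], old.ages[keep_o]])
    values = np.concatenate([young.values[keep_y], old.values[keep_o]])
    order = np.argsort(ages)
    return EnvCurve(name=young.name, ages=ages[order], values=values[order])


def _natural_spline_penalty(x: np.ndarray) -> np.ndarray:
    """Penalty matrix K of the natural cubic smoothing spline (Reinsch form),
    K = Q R^{-1} Q^T with the usual banded Q ((n, n-2)) and R ((n-2, n-2))."""
    n = x.size
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        Q[i, i] = 1.0 / h[i]
        Q[i + 1, i] = -1.0 / h[i] - 1.0 / h[i + 1]
        Q[i + 2, i] = 1.0 / h[i + 1]
        R[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            R[i, i + 1] = R[i + 1, i] = h[i + 1] / 6.0
    return Q @ np.linalg.solve(R, Q.T)


def spline_subsample(curve: EnvCurve, step: float = 0.5, df: float = 200.0) -> EnvCurve:
    """Smooth a curve with a penalized natural cubic spline tuned to a target
    equivalent degrees of freedom, then resample on a regular ``step`` grid.

    The smoothing parameter is solved so that the trace of the smoother
    matrix equals ``df`` (as in R's ``smooth.spline(df=...)``); when
    ``df >= n`` the fit degenerates to an interpolating cubic spline.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    x, y = curve.ages, curve.values
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points for spline smoothing")
    lo, hi = float(x[0]), float(x[-1])
    grid = lo + step * np.arange(int(np.floor((hi - lo) / step)) + 1)
    if df >= n:
        fitted = y
    else:
        K = _natural_spline_penalty(x)
        evals, evecs = np.linalg.eigh(K)
        evals = np.clip(evals, 0.0, None)

        def edf(log_lam: float) -> float:
            return float(np.sum(1.0 / (1.0 + 10.0**log_lam * evals)))

        lo_l, hi_l = -14.0, 14.0
        for _ in range(200):
            mid = 0.5 * (lo_l + hi_l)
            if edf(mid) > df:
                lo_l = mid  # more smoothing needed
            else:
                hi_l = mid
        lam = 10.0 ** (0.5 * (lo_l + hi_l))
        shrink = 1.0 / (1.0 + lam * evals)
        fitted = evecs @ (shrink * (evecs.T @ y))
    spl = CubicSpline(x, fitted, bc_type="natural")
    return EnvCurve(name=curve.name, ages=grid, values=spl(grid))


def curve_value_at(curve: EnvCurve, t) -> np.ndarray | float:
    """Linear interpolation of the curve at age(s) ``t``; values beyond the
    curve's range clamp to the end values."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    out = np.interp(np.asarray(t, dtype=float), curve.ages, curve.values)
    return float(out) if out.ndim == 0 else out


def diversity_covariate_from_ltt(ltt) -> EnvCurve:
    """Self-diversity covariate: the clade's own range-through richness as a
    function of time, for diversity-dependence tests (dropped when the
    analysis removes diversity dependence)."""
    return EnvCurve(
        name="self-diversity",
        ages=np.asarray(ltt.times, dtype=float),
        values=np.asarray(ltt.richness, dtype=float),
    )
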