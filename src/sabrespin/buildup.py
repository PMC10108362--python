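"""Mono-exponential build-up fitting.

Hyperpolarization build-up is summarized by p(t) = p_max (1 - exp(-t/T_hyp)).
The fit is unweighted nonlinear least squares; standard errors come from the
local quadratic approximation of the objective at the optimum (the usual
Jacobian-based covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dynamics import BuildUpCurve

__all__ = ["FitResult", "fit_monoexp"]


@dataclass(frozen=True)
class FitResult:
    """Mono-exponential fit parameters and uncertainties."""

    p_max: float
    t_hyp: float
    p_max_err: float
    t_hyp_err: float
    residual_norm: float
    offset: float = 0.0
    offset_err: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t_hyp > 0):
            raise ValueError("fitted T_hyp must be positive")
        if self.p_max_err < 0 or self.t_hyp_err < 0:
            raise ValueError("standard errors must be non-negative")

    def as_dict(self) -> dict:
        return {
            "p_max": self.p_max,
            "t_hyp_s": self.t_hyp,
            "p_max_stderr": self.p_max_err,
            "t_hyp_stderr": self.t_hyp_err,
            "residual_norm": self.residual_norm,
            "offset": self.offset,
            "offset_stderr": self.offset_err,
        }


def _monoexp(t, p_max, T):
    return p_max * (1.0 - np.exp(-t / T))


def _monoexp_offset(t, p_max, T, c):
    return c + p_max * (1.0 - np.exp(-t / T))


def fit_monoexp(curve: BuildUpCurve, with_offset: bool = False) -> FitResult:
    """Fit p(t) = p_max (1 - exp(-t/T_hyp)) to a build-up curve.

    Initialization: p_max from the last sample, T_hyp from the first time the
    curve reaches (1 - 1/e) of it; T_hyp is bounded to (0, 10 t_max].

    Raises
    ------
    ValueError
        For fewer than 3 distinct time points, non-finite values, or an
        all-zero (degenerate) curve.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.values, dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct time points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in build-up curve")
    if np.allclose(y, 0.0):
        raise ValueError("degenerate all-zero build-up curve")

    t_max = float(t.max())
    sign = np.sign(y[np.argmax(np.abs(y))]) or 1.0
    p0_max = y[-1] if y[-1] != 0 else sign * np.max(np.abs(y))
    target = (1.0 - np.exp(-1.0)) * p0_max
    crossed = np.nonzero(sign * y >= sign * target)[0]
    T0 = float(t[crossed[0]]) if crossed.size and t[crossed[0]] > 0 else t_max / 3.0
    T0 = min(max(T0, 1e-6 * t_max if t_max > 0 else 1e-6), 10.0 * t_max)

    if with_offset:
        fn, p0 = _monoexp_offset, [p0_max, T0, 0.0]
        lo = [-np.inf, 1e-12, -np.inf]
        hi = [np.inf, 10.0 * t_max, np.inf]
    else:
        fn, p0 = _monoexp, [p0_max, T0]
        lo = [-np.inf, 1e-12]
        hi = [np.inf, 10.0 * t_max]
    popt, pcov = curve_fit(
        fn, t, y, p0=p0, bounds=(lo, hi), maxfev=20000,
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    resid = y - fn(t, *popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if with_offset:
        return FitResult(
            p_max=float(popt[0]),
            t_hyp=float(popt[1]),
            p_max_err=float(perr[0]),
            t_hyp_err=float(perr[1]),
            residual_norm=float(np.linalg.norm(resid)),
            offset=float(popt[2]),
            offset_err=float(perr[2]),
        )
    return FitResult(
        p_max=float(popt[0]),
        t_hyp=float(popt[1]),
        p_max_err=float(perr[0]),
        t_hyp_err=float(perr[1]),
        residual_norm=float(np.linalg.norm(resid)),
    )
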