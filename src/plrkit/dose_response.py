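"""Constrained variable-slope sigmoidal intensity-response (EC50) fitting.

The pupil's intensity-response curve is modeled with the conventional
variable-slope (four-parameter logistic) sigmoid in log10 illuminance:

    rpa(I) = bottom + (top - bottom) / (1 + 10**((logEC50 - log10 I) * h))

with ``top`` fixed to 1.0 (fully open pupil in darkness) and ``bottom``
either constrained to [0, 0.10] (near-complete constriction) or free in
[0, 1] for genotypes that never constrict that far. The Hill slope ``h``
is negative for constriction. EC50 statistics are computed on the log
scale, since EC50s are log-normally distributed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError

#: Upper bound of the constrained bottom asymptote.
CONSTRAINED_BOTTOM_MAX = 0.10


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted variable-slope sigmoid dose-response parameters.

    ``log_ec50`` is log10 of the half-maximal illuminance in lux;
    ``hill_slope`` is per log10(lux) and negative for constriction.
    """

    top: float
    bottom: float
    log_ec50: float
    hill_slope: float
    constrained_top: bool = True
    constrained_bottom: bool = True
    rss: float = float("nan")

    def __post_init__(self):
        if self.bottom > self.top + 1e-12:
            raise ValidationError("bottom must not exceed top")
        if self.constrained_top and abs(self.top - 1.0) > 1e-9:
            raise ValidationError("constrained top must equal 1.0")
        if self.constrained_bottom and not (
            -1e-12 <= self.bottom <= CONSTRAINED_BOTTOM_MAX + 1e-12
        ):
            raise ValidationError("constrained bottom must lie in [0, 0.10]")

    def __call__(self, intensity) -> np.ndarray | float:
        return predict_rpa(self, intensity)


def sigmoid(log_intensity, top, bottom, log_ec50, hill_slope):
    """Variable-slope sigmoid evaluated at log10 illuminance."""
    log_intensity = np.asarray(log_intensity, dtype=float)
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (
            1.0 + 10.0 ** ((log_ec50 - log_intensity) * hill_slope)
        )


def fit_intensity_response(
    intensities: Sequence[float],
    rpa: Sequence[float],
    constrain_bottom: bool = True,
    auto_fallback: bool = True,
) -> SigmoidFit:
    """Fit the constrained variable-slope sigmoid to (intensity, RPA) points.

    Parameters
    ----------
    intensities : array-like of lux
        Stimulus illuminances; zero-lux points are excluded (log undefined).
    rpa : array-like
        Relative pupil areas in (0, 1.5).
    constrain_bottom : bool
        Bound the bottom asymptote to [0, 0.10]; otherwise free in [0, 1].
    auto_fallback : bool
        If the constrained bottom pins at 0.10 while no observed RPA reaches
        0.10, refit with the bottom unconstrained (for genotypes that never
        show near-complete constriction).

    The top asymptote is always fixed at 1.0. Fitting is bounded nonlinear
    least squares with multi-start over Hill slope and logEC50 grids.
    """
    intensities = np.asarray(intensities, dtype=float)
    rpa = np.asarray(rpa, dtype=float)
    if intensities.shape != rpa.shape:
        raise ValidationError("intensities and rpa must have equal length")
    if np.any(intensities < 0):
        raise ValidationError("intensities must be >= 0 lux")
    keep = intensities > 0
    intensities, rpa = intensities[keep], rpa[keep]
    if np.unique(intensities).size < 4:
        raise ValidationError("need >= 4 distinct positive intensities to fit")
    if np.any((rpa <= 0) | (rpa >= 1.5)):
        raise ValidationError("rpa values must lie in (0, 1.5)")

    log_i = np.log10(intensities)
    bottom_hi = CONSTRAINED_BOTTOM_MAX if constrain_bottom else 1.0
    lo = np.array([0.0, log_i.min() - 3.0, -10.0])
    hi = np.array([bottom_hi, log_i.max() + 3.0, 10.0])

    def residuals(p):
        bottom, log_ec50, hill = p
        return sigmoid(log_i, 1.0, bottom, log_ec50, hill) - rpa

    b0 = min(max(rpa.min(), 0.0), bottom_hi)
    starts = [
        (b0, le, h)
        for le in np.linspace(log_i.min(), log_i.max(), 5)
        for h in (-0.5, -1.0, -2.0)
    ]
    best, diagnostics = None, []
    for start in starts:
        try:
            sol = least_squares(residuals, np.clip(start, lo, hi), bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append(str(exc))
            continue
        if not sol.success:
            diagnostics.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(
            "sigmoid fit failed to converge from any start", details=diagnostics
        )
    bottom, log_ec50, hill = best.x
    rss = float(2 * best.cost)

    if (
        constrain_bottom
        and auto_fallback
        and bottom >= CONSTRAINED_BOTTOM_MAX - 1e-6
        and rpa.min() > CONSTRAINED_BOTTOM_MAX
    ):
        return fit_intensity_response(
            intensities, rpa, constrain_bottom=False, auto_fallback=False
        )
    return SigmoidFit(
        top=1.0,
        bottom=float(bottom),
        log_ec50=float(log_ec50),
        hill_slope=float(hill),
        constrained_top=True,
        constrained_bottom=constrain_bottom,
        rss=rss,
    )


def ec50_lux(fit: SigmoidFit) -> float:
    """Half-maximal illuminance in lux: 10**log_ec50."""
    return float(10.0 ** fit.log_ec50)


class EC50Summary(NamedTuple):
    """Log-scale EC50 summary over a group of fits."""

    log_mean: float
    log_sd: float
    n: int

    @property
    def geometric_mean(self) -> float:
        return float(10.0 ** self.log_mean)


def group_ec50_summary(fits: Sequence[SigmoidFit]) -> EC50Summary:
    """Mean and SD of log10 EC50 across fits (EC50s are log-normal)."""
    if len(fits) == 0:
        raise ValidationError("cannot summarize an empty collection of fits")
    logs = np.array([f.log_ec50 for f in fits], dtype=float)
    sd = float(logs.std(ddof=1)) if logs.size > 1 else 0.0
    return EC50Summary(log_mean=float(logs.mean()), log_sd=sd, n=logs.size)


def predict_rpa(fit: SigmoidFit, intensity) -> np.ndarray | float:
    """Evaluate the fitted curve at an illuminance (lux).

    Zero lux returns ``top`` (fully open pupil in darkness); outputs are
    clamped to (0, top]. Scalar in, scalar out.
    """
    scalar = np.isscalar(intensity)
    arr = np.atleast_1d(np.asarray(intensity, dtype=float))
    if np.any(arr < 0):
        raise ValidationError("intensity must be >= 0 lux")
    out = np.full(arr.shape, fit.top, dtype=float)
    pos = arr > 0
    if np.any(pos):
        out[pos] = sigmoid(
            np.log10(arr[pos]), fit.top, fit.bottom, fit.log_ec50, fit.hill_slope
        )
    tiny = np.finfo(float).tiny
    out = np.clip(out, tiny, fit.top)
    return float(out[0]) if scalar else out
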