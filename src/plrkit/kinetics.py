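"""One- and two-phase exponential kinetics of pupil constriction and decay.

Constriction after light onset follows a one-phase association,

    Y(t) = plateau + (y0 - plateau) * exp(-k * (t - t_offset)),   t >= t_offset

with Y = y0 before the offset (the offset absorbs the short latency
between light onset and the first detectable constriction). Half-life is
ln 2 / k. The "two-phase" model is a general bi-exponential with signed
spans, which permits the non-monotone constrict-then-redilate time course
seen when cone input adapts within the 30-s transient recording.

The sustained-phase decay rate changes with illuminance; a sigmoid in
log10 lux with its top and bottom pinned to the measured rates at 1 and
100 lux interpolates between them (:class:`DecayRateCurve`). Sustained
rates are expressed per minute, transient rates per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateFitError, FitError, ValidationError
from .pupil_io import RelativeTrace

LN2 = math.log(2.0)

#: Relative RSS improvement a two-phase fit must show over the one-phase
#: fit before the extra phase is accepted.
TWO_PHASE_RSS_IMPROVEMENT = 0.01


@dataclass(frozen=True)
class KineticFit:
    """Parameters of a one- or two-phase exponential fit.

    One-phase: ``y0``, ``plateau``, ``k`` (with optional ``t_offset``).
    Two-phase: ``Y(t) = plateau + span1*exp(-k*t) + span2*exp(-k2*t)``
    with spans unconstrained in sign; ``y0 = plateau + span1 + span2``.
    """

    y0: float
    plateau: float
    k: float
    t_offset: float = 0.0
    kind: str = "one_phase"
    k2: float | None = None
    span1: float | None = None
    span2: float | None = None
    rss: float = float("nan")
    k_at_bound: bool = False
    reduced_to_one_phase: bool = False

    def __post_init__(self):
        if self.k <= 0:
            raise ValidationError("rate constant k must be > 0")
        if self.kind not in ("one_phase", "two_phase"):
            raise ValidationError(f"unknown fit kind {self.kind!r}")
        if self.kind == "two_phase":
            if self.k2 is None or self.k2 <= 0:
                raise ValidationError("two-phase fit requires k2 > 0")
            if abs(self.k2 - self.k) < 1e-12:
                raise ValidationError("two-phase rates must differ")

    @property
    def half_life(self) -> float:
        """Half-life of the (first) phase, ln 2 / k."""
        return half_life(self.k)

    @property
    def span_fraction(self) -> float | None:
        """Fraction of the total span carried by the first phase."""
        if self.kind != "two_phase":
            return None
        total = abs(self.span1) + abs(self.span2)
        return abs(self.span1) / total if total > 0 else float("nan")

    def predict(self, times) -> np.ndarray:
        """Evaluate the fitted curve at arbitrary times (s)."""
        t = np.asarray(times, dtype=float)
        if self.kind == "one_phase":
            tau = np.maximum(t - self.t_offset, 0.0)
            return self.plateau + (self.y0 - self.plateau) * np.exp(-self.k * tau)
        tau = np.maximum(t - self.t_offset, 0.0)
        return (
            self.plateau
            + self.span1 * np.exp(-self.k * tau)
            + self.span2 * np.exp(-self.k2 * tau)
        )


def half_life(k: float) -> float:
    """ln 2 / k, in the time unit of 1/k."""
    if k <= 0:
        raise ValidationError("rate constant must be > 0")
    return LN2 / k


def _trace_arrays(rel, t_min: float = 0.0):
    if isinstance(rel, RelativeTrace):
        times, values = rel.times, rel.rpa
    else:
        times, values = rel
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
    mask = times >= t_min
    return times[mask], values[mask]


def fit_one_phase(rel, t_offset: float = 0.0) -> KineticFit:
    """Fit a one-phase association/decay to the post-onset trace.

    ``rel`` is a :class:`RelativeTrace` or a ``(times, values)`` pair.
    Samples before ``t_offset`` enter the loss at the constant value y0,
    so the fit is invariant to adding pre-offset samples at y0.
    """
    times, values = _trace_arrays(rel)
    if times.size < 4:
        raise ValidationError("need >= 4 post-onset samples for a one-phase fit")
    if np.ptp(values) < 1e-12:
        raise DegenerateFitError("constant trace cannot identify a rate constant")

    tau = np.maximum(times - t_offset, 0.0)
    k_lo, k_hi = 1e-6, 1e3
    lo = np.array([-10.0, -10.0, k_lo])
    hi = np.array([10.0, 10.0, k_hi])

    def residuals(p):
        y0, plateau, k = p
        return plateau + (y0 - plateau) * np.exp(-k * tau) - values

    span = times.max() - max(times.min(), t_offset)
    k_guess = 3.0 / span if span > 0 else 1.0
    starts = [
        (values[0], values[-1], k)
        for k in (k_guess, 0.01, 0.1, 1.0, 5.0)
    ]
    best, diagnostics = None, []
    for start in starts:
        sol = least_squares(residuals, np.clip(start, lo, hi), bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if not sol.success:
            diagnostics.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("one-phase fit failed to converge", details=diagnostics)
    y0, plateau, k = best.x
    return KineticFit(
        y0=float(y0),
        plateau=float(plateau),
        k=float(k),
        t_offset=t_offset,
        kind="one_phase",
        rss=float(2 * best.cost),
        k_at_bound=bool(k <= k_lo * 1.01 or k >= k_hi * 0.99),
    )


def fit_two_phase(rel, t_offset: float = 0.0) -> KineticFit:
    """Fit a bi-exponential with signed spans to the post-onset trace.

    If the best two-phase fit does not improve the residual sum of squares
    over the one-phase fit by at least ``TWO_PHASE_RSS_IMPROVEMENT``
    (relative), the one-phase fit is returned with
    ``reduced_to_one_phase=True``.
    """
    times, values = _trace_arrays(rel)
    if times.size < 6:
        raise ValidationError("need >= 6 post-onset samples for a two-phase fit")
    one = fit_one_phase(rel, t_offset=t_offset)

    tau = np.maximum(times - t_offset, 0.0)
    k_lo, k_hi = 1e-6, 1e3
    lo = np.array([-10.0, -10.0, k_lo, -10.0, k_lo])
    hi = np.array([10.0, 10.0, k_hi, 10.0, k_hi])

    def residuals(p):
        plateau, a1, k1, a2, k2 = p
        return (
            plateau + a1 * np.exp(-k1 * tau) + a2 * np.exp(-k2 * tau) - values
        )

    span0 = values[0] - values[-1]
    k_grid = (0.05, 0.2, 1.0, 3.0)
    starts = []
    for k1 in k_grid:
        for k2 in k_grid:
            if k2 >= k1:
                continue
            starts.append((values[-1], span0, k1, 0.0, k2))
            starts.append((values[-1], span0, k1, -0.5 * span0, k2))
    best, diagnostics = None, []
    for start in starts:
        sol = least_squares(residuals, np.clip(start, lo, hi), bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if not sol.success:
            diagnostics.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("two-phase fit failed to converge", details=diagnostics)
    rss2 = float(2 * best.cost)
    if rss2 >= one.rss * (1.0 - TWO_PHASE_RSS_IMPROVEMENT):
        return KineticFit(
            y0=one.y0,
            plateau=one.plateau,
            k=one.k,
            t_offset=t_offset,
            kind="one_phase",
            rss=one.rss,
            k_at_bound=one.k_at_bound,
            reduced_to_one_phase=True,
        )
    plateau, a1, k1, a2, k2 = best.x
    if k1 < k2:  # report the faster phase first
        a1, k1, a2, k2 = a2, k2, a1, k1
    if abs(k1 - k2) < 1e-12:
        k2 *= 1.0 + 1e-9
    return KineticFit(
        y0=float(plateau + a1 + a2),
        plateau=float(plateau),
        k=float(k1),
        t_offset=t_offset,
        kind="two_phase",
        k2=float(k2),
        span1=float(a1),
        span2=float(a2),
        rss=rss2,
    )


@dataclass(frozen=True)
class DecayRateCurve:
    """Sustained-phase decay rate as a sigmoid function of log10 illuminance.

    The top and bottom plateaus are pinned to the measured rates at 1 and
    100 lux; evaluation outside the fitted 1-100 lux range clamps to the
    respective plateau rather than extrapolating. Rates are per minute.
    """

    top_rate: float
    bottom_rate: float
    log_midpoint: float
    slope: float

    def __post_init__(self):
        if self.top_rate <= 0 or self.bottom_rate <= 0:
            raise ValidationError("decay rates must be > 0")

    def __call__(self, intensity) -> np.ndarray | float:
        scalar = np.isscalar(intensity)
        arr = np.atleast_1d(np.asarray(intensity, dtype=float))
        if np.any(arr <= 0):
            raise ValidationError("intensity must be > 0 lux")
        out = np.empty(arr.shape, dtype=float)
        below, above = arr <= 1.0, arr >= 100.0
        mid = ~(below | above)
        out[below] = self.top_rate
        out[above] = self.bottom_rate
        if np.any(mid):
            log_i = np.log10(arr[mid])
            out[mid] = self.bottom_rate + (self.top_rate - self.bottom_rate) / (
                1.0 + 10.0 ** ((log_i - self.log_midpoint) * self.slope)
            )
        lo = min(self.top_rate, self.bottom_rate)
        hi = max(self.top_rate, self.bottom_rate)
        out = np.clip(out, lo, hi)
        return float(out[0]) if scalar else out


def fit_decay_rate_vs_intensity(rates: Mapping[float, float]) -> DecayRateCurve:
    """Fit the decay-rate-vs-intensity sigmoid to rates at 1, 10 and 100 lux.

    ``rates`` maps illuminance (lux) to decay rate (1/min) and must contain
    the keys 1, 10 and 100. The plateaus are pinned to the 1- and 100-lux
    rates; the midpoint and slope are fitted so the curve passes near the
    10-lux rate.
    """
    try:
        r1, r10, r100 = (float(rates[k]) for k in (1, 10, 100))
    except KeyError as exc:
        raise ValidationError("rates must be given at 1, 10 and 100 lux") from exc
    if min(r1, r10, r100) <= 0:
        raise ValidationError("decay rates must be > 0")
    if abs(r1 - r100) < 1e-15:
        return DecayRateCurve(r1, r100, log_midpoint=1.0, slope=1.0)

    def residual(p):
        mid, slope = p
        value = r100 + (r1 - r100) / (1.0 + 10.0 ** ((1.0 - mid) * slope))
        return [value - r10]

    sol = least_squares(
        residual, x0=[1.0, 1.0], bounds=([-1.0, 0.01], [3.0, 10.0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not sol.success:
        raise FitError("decay-rate sigmoid fit failed", details=sol.message)
    return DecayRateCurve(
        top_rate=r1,
        bottom_rate=r100,
        log_midpoint=float(sol.x[0]),
        slope=float(sol.x[1]),
    )
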