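"""Negative-feedback simulation of pupillary light response decay.

Pupil constriction reduces the light reaching the retina (retinal lux =
RPA x environmental lux), which in turn reduces the drive to constrict —
a negative feedback loop. This module bounds the contribution of that
loop to PLR decay with a discrete-time "packet" model:

* each second of light is a packet whose constriction depth is read from
  the open-loop intensity-response curve at the current *retinal*
  illuminance;
* a packet's effect is distributed over the following seconds by a
  temporal weighting ``omega`` measured in a 1-s light pulse-chase
  experiment (constriction peaks ~6 s after the pulse);
* the system has **zero temporal summation**: at any moment the pupil
  adopts the single deepest weighted packet (a max, never a sum). This
  deliberately maximizes feedback's leverage, so the simulated decay is
  an upper bound on what feedback alone can produce.

The recursion, per second t over a default 956-s horizon:

    C(t)     = max_{s < t} depth_s * omega(t - s)       (0 beyond lag L)
    lux_t    = (1 - C(t)) * env_lux
    depth_t  = 1 - drc(lux_t)
    rpa_t    = 1 - max_{s <= t} depth_s * omega(t - s)

The module is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dose_response import SigmoidFit, fit_intensity_response, ec50_lux, predict_rpa
from .errors import ValidationError
from .pupil_io import RelativeTrace

#: Default temporal-weighting support (lags 0..30 s inclusive).
DEFAULT_MAX_LAG_S = 30

#: Default simulation horizon in seconds.
DEFAULT_HORIZON_S = 956

#: The nine illuminances of the default intensity sweep (lux).
DEFAULT_SWEEP_LUX = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1e3, 1e4)

#: Extended sweep reaching 100,000 lux.
EXTENDED_SWEEP_LUX = DEFAULT_SWEEP_LUX + (1e5,)


@dataclass(frozen=True)
class TemporalWeighting:
    """Normalized pulse-chase constriction profile omega(lag).

    Weights are in [0, 1] with max exactly 1 at ``peak_lag``; lags are
    integer seconds 0..L.
    """

    lags: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=int)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "weights", weights)
        if lags.shape != weights.shape or lags.ndim != 1:
            raise ValidationError("lags and weights must be equal-length 1-d arrays")
        if not np.array_equal(lags, np.arange(lags.size)):
            raise ValidationError("lags must be consecutive integers starting at 0")
        if np.any(weights < 0) or np.any(weights > 1):
            raise ValidationError("weights must lie in [0, 1]")
        if abs(weights.max() - 1.0) > 1e-12:
            raise ValidationError("maximum weight must equal 1 exactly")

    @property
    def max_lag(self) -> int:
        return int(self.lags[-1])

    @property
    def peak_lag(self) -> int:
        """Lag (s) of maximal constriction after a 1-s pulse."""
        return int(np.argmax(self.weights))


def omega_from_pulse_chase(rel: RelativeTrace) -> TemporalWeighting:
    """Derive the temporal weighting from a 1-s pulse-chase trace.

    The trace's post-pulse samples at integer lags 0..L are converted to
    constriction depth 1 - rpa (negative values clipped to 0) and
    normalized to the maximum depth achieved.
    """
    times, rpa = rel.times, rel.rpa
    mask = times >= 0
    lags = np.round(times[mask]).astype(int)
    depth = np.clip(1.0 - rpa[mask], 0.0, None)
    n_lags = int(lags.max()) + 1
    if not np.array_equal(np.unique(lags), np.arange(n_lags)):
        raise ValidationError("pulse-chase samples must cover integer lags 0..L")
    peak = depth.max()
    if peak <= 0:
        raise ValidationError("no constriction in pulse-chase trace")
    return TemporalWeighting(lags=np.arange(n_lags), weights=depth / peak)


@dataclass(frozen=True)
class FeedbackSimResult:
    """Per-second output of the negative-feedback recursion."""

    env_lux: float
    horizon: int
    times: np.ndarray  # 1..horizon, s
    rpa_t: np.ndarray
    retinal_lux_t: np.ndarray
    openloop_plateau: float
    depths: np.ndarray = field(repr=False)
    omega: TemporalWeighting = field(repr=False, default=None)

    @property
    def decay_magnitude(self) -> float:
        """Re-dilation from the deepest constriction to the horizon end."""
        return float(self.rpa_t[-1] - self.rpa_t.min())

    @property
    def min_rpa(self) -> float:
        return float(self.rpa_t.min())

    @property
    def end_rpa(self) -> float:
        return float(self.rpa_t[-1])

    def rpa_matrix(self) -> np.ndarray:
        """Debug view: the horizon x horizon store of weighted packet RPAs.

        Row s holds the RPA time course contributed by the packet sensed at
        second s+1 (columns are time), i.e. 1 - depth_s * omega(lag); cells
        outside a packet's support are 1 (no constriction).
        """
        h = self.horizon
        w = self.omega.weights
        mat = np.ones((h, h), dtype=float)
        for s in range(h):
            span = min(w.size, h - s)
            mat[s, s : s + span] = 1.0 - self.depths[s] * w[:span]
        return mat

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "rpa": self.rpa_t,
                "retinal_lux": self.retinal_lux_t,
            }
        )


def _as_drc_callable(drc) -> Callable[[float], float]:
    if isinstance(drc, SigmoidFit):
        return lambda lux: predict_rpa(drc, lux)
    if callable(drc):
        return drc
    raise ValidationError("drc must be a SigmoidFit or a callable lux -> rpa")


def simulate_feedback(
    drc,
    omega: TemporalWeighting,
    env_lux: float,
    horizon: int = DEFAULT_HORIZON_S,
) -> FeedbackSimResult:
    """Run the zero-summation negative-feedback recursion.

    Parameters
    ----------
    drc : SigmoidFit or callable
        Open-loop dose-response curve mapping lux to RPA in (0, 1].
    omega : TemporalWeighting
        Pulse-chase temporal weighting of each 1-s light packet.
    env_lux : float
        Environmental illuminance (>= 0 lux).
    horizon : int
        Number of 1-s steps to simulate (>= 1).
    """
    if env_lux < 0:
        raise ValidationError("environmental intensity must be >= 0 lux")
    if horizon < 1:
        raise ValidationError("horizon must be >= 1 s")
    alpha = _as_drc_callable(drc)
    w = omega.weights
    L = omega.max_lag

    def checked_alpha(lux: float) -> float:
        value = float(alpha(lux))
        if not (0.0 < value <= 1.0):
            raise ValidationError(
                f"dose-response output {value} at {lux} lux is outside (0, 1]"
            )
        return value

    depths = np.empty(horizon)
    lux_t = np.empty(horizon)
    rpa_t = np.empty(horizon)
    for t in range(horizon):
        lo = max(0, t - L)
        if t == 0:
            feedback_c = 0.0
        else:
            seg = depths[lo:t]
            feedback_c = float(np.max(seg * w[t - lo : 0 : -1])) if seg.size else 0.0
        lux_t[t] = (1.0 - feedback_c) * env_lux
        depths[t] = 1.0 - checked_alpha(lux_t[t])
        seg = depths[lo : t + 1]
        rpa_t[t] = 1.0 - float(np.max(seg * w[t - lo :: -1]))
    return FeedbackSimResult(
        env_lux=float(env_lux),
        horizon=int(horizon),
        times=np.arange(1, horizon + 1, dtype=float),
        rpa_t=rpa_t,
        retinal_lux_t=lux_t,
        openloop_plateau=checked_alpha(float(env_lux)),
        depths=depths,
        omega=omega,
    )


@dataclass(frozen=True)
class SweepResult:
    """Per-intensity feedback-decay summaries and model EC50s."""

    summary: pd.DataFrame
    results: tuple
    ec50_min_lux: float
    ec50_end_lux: float


def feedback_intensity_sweep(
    drc,
    omega: TemporalWeighting,
    intensities: Sequence[float] = DEFAULT_SWEEP_LUX,
    horizon: int = DEFAULT_HORIZON_S,
) -> SweepResult:
    """Simulate feedback at each illuminance and fit model EC50s.

    Returns per-intensity decay magnitude plus two EC50s fitted (via the
    dose-response module) to the early-minimum RPA (transient-like) and
    to the horizon-end RPA (sustained-like); feedback can only raise the
    latter.
    """
    intensities = [float(i) for i in intensities]
    if any(i < 0 for i in intensities):
        raise ValidationError("intensities must be >= 0 lux")
    results = tuple(
        simulate_feedback(drc, omega, lux, horizon=horizon) for lux in intensities
    )
    summary = pd.DataFrame(
        {
            "intensity_lux": intensities,
            "min_rpa": [r.min_rpa for r in results],
            "end_rpa": [r.end_rpa for r in results],
            "decay_magnitude": [r.decay_magnitude for r in results],
            "openloop_plateau": [r.openloop_plateau for r in results],
        }
    )
    positive = summary[summary["intensity_lux"] > 0]
    fit_min = fit_intensity_response(
        positive["intensity_lux"], positive["min_rpa"].clip(lower=1e-9)
    )
    fit_end = fit_intensity_response(
        positive["intensity_lux"], positive["end_rpa"].clip(lower=1e-9)
    )
    return SweepResult(
        summary=summary,
        results=results,
        ec50_min_lux=ec50_lux(fit_min),
        ec50_end_lux=ec50_lux(fit_end),
    )
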