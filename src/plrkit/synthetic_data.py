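"""Synthetic pupillometry data with the structure the analyses assume.

No raw animal traces accompany the study this toolkit models, so every
pipeline stage is exercised against generated data instead. A
:class:`GenotypeSpec` encodes, per mouse line:

* a transient phase — one-phase association from a fully open pupil to an
  intensity-dependent plateau (variable-slope sigmoid in log lux), with an
  optional onset delay and an optional within-transient fade (cone-driven
  constriction that re-dilates within 30 s);
* a sustained phase — one-phase decay from the 30-s pupil size toward an
  intensity-dependent sustained plateau at an intensity-dependent rate
  (per minute), optionally modulated sinusoidally ("pulsatile" dynamics of
  glutamate-deficient lines);
* additive Gaussian measurement noise on relative pupil area and a dark
  baseline pupil area in mm^2.

Wild-type defaults anchor to the headline physiology: transient EC50
0.53 lux, transient constriction half-life 1.1 s, sustained EC50 7.9 lux,
sustained decay half-lives of 2-5 min across 1-100 lux, and a pulse-chase
constriction profile peaking 6 s after a 1-s pulse. Mutant lines without
printed parameters are encoded qualitatively (see docs/methods.md).

All randomness flows from a single user seed through per-mouse
counter-derived streams, so identical seeds give bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import SigmoidFit
from .errors import ValidationError
from .kinetics import DecayRateCurve
from .pupil_io import PupilTrace, RelativeTrace, relative_trace, transient_endpoint

LN2 = math.log(2.0)

#: Start of the sustained decay phase (s after light onset).
SUSTAINED_ONSET_S = 30.0

#: Relative pupil area floor applied after adding noise.
RPA_FLOOR = 0.02

#: Default additive noise SD on relative pupil area.
DEFAULT_NOISE_SD = 0.03

#: Pulse-chase constriction peaks this many seconds after a 1-s pulse.
PULSE_CHASE_PEAK_S = 6.0


@dataclass(frozen=True)
class TransientParams:
    """Transient-phase (0-30 s) parameters of a genotype."""

    ec50: float  # lux
    k: float  # constriction rate, 1/s
    hill: float = -1.0
    bottom: float = 0.05  # plateau floor at saturating light (rpa)
    onset_delay: float = 0.0  # s between light onset and constriction
    fade_rate: float = 0.0  # 1/s; > 0 => constriction decays within 30 s

    def __post_init__(self):
        if self.ec50 <= 0 or self.k <= 0:
            raise ValidationError("transient ec50 and k must be > 0")
        if not 0.0 <= self.bottom <= 1.0:
            raise ValidationError("transient bottom must lie in [0, 1]")
        if self.onset_delay < 0 or self.fade_rate < 0:
            raise ValidationError("onset_delay and fade_rate must be >= 0")

    def plateau(self, intensity) -> np.ndarray | float:
        return _sigmoid_rpa(intensity, self.bottom, self.ec50, self.hill)


@dataclass(frozen=True)
class SustainedParams:
    """Sustained-phase (30 s - 60 min) parameters of a genotype."""

    ec50: float  # lux
    rate_at_1lux: float  # decay rate, 1/min
    rate_at_100lux: float  # 1/min
    hill: float = -1.0
    bottom: float = 0.05
    log_midpoint: float = 1.0
    slope: float = 1.0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValidationError("sustained ec50 must be > 0")
        if self.rate_at_1lux <= 0 or self.rate_at_100lux <= 0:
            raise ValidationError("sustained decay rates must be > 0")
        if not 0.0 <= self.bottom <= 1.0:
            raise ValidationError("sustained bottom must lie in [0, 1]")

    def plateau(self, intensity) -> np.ndarray | float:
        return _sigmoid_rpa(intensity, self.bottom, self.ec50, self.hill)

    def decay_rate_curve(self) -> DecayRateCurve:
        return DecayRateCurve(
            top_rate=self.rate_at_1lux,
            bottom_rate=self.rate_at_100lux,
            log_midpoint=self.log_midpoint,
            slope=self.slope,
        )


@dataclass(frozen=True)
class GenotypeSpec:
    """Full generative description of one mouse line."""

    name: str
    transient: TransientParams
    sustained: SustainedParams
    noise_sd: float = DEFAULT_NOISE_SD
    baseline_area: float = 4.0  # mm^2, dark-adapted
    pulsatile_period: float = 0.0  # s; > 0 enables sinusoidal modulation
    pulsatile_depth: float = 0.0  # fraction of constriction depth modulated

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.baseline_area <= 0:
            raise ValidationError("baseline_area must be > 0")

    def transient_curve(self) -> SigmoidFit:
        """The transient intensity-response sigmoid as a SigmoidFit."""
        return SigmoidFit(
            top=1.0,
            bottom=self.transient.bottom,
            log_ec50=math.log10(self.transient.ec50),
            hill_slope=self.transient.hill,
            constrained_top=True,
            constrained_bottom=self.transient.bottom <= 0.10,
            rss=0.0,
        )

    def sustained_curve(self) -> SigmoidFit:
        return SigmoidFit(
            top=1.0,
            bottom=self.sustained.bottom,
            log_ec50=math.log10(self.sustained.ec50),
            hill_slope=self.sustained.hill,
            constrained_top=True,
            constrained_bottom=self.sustained.bottom <= 0.10,
            rss=0.0,
        )


def _sigmoid_rpa(intensity, bottom, ec50, hill):
    """Variable-slope sigmoid (top = 1) evaluated at illuminance in lux."""
    arr = np.asarray(intensity, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.ones(arr.shape, dtype=float)
    pos = arr > 0
    with np.errstate(over="ignore"):
        x = (math.log10(ec50) - np.log10(arr[pos])) * hill
        out[pos] = bottom + (1.0 - bottom) / (1.0 + 10.0 ** x)
    return float(out[0]) if scalar else out


def model_rpa(spec: GenotypeSpec, intensity: float, times) -> np.ndarray:
    """Noiseless relative pupil area of a genotype at given times (s).

    Implements the two-phase shape: delayed one-phase association to the
    transient plateau, then from 30 s a one-phase decay toward the
    sustained plateau at the spec's intensity-dependent rate. A positive
    ``fade_rate`` multiplies the transient constriction depth by
    exp(-fade_rate * t), producing the constrict-then-redilate profile of
    cone-only lines. Pre-onset times (t < 0) return 1.
    """
    t = np.asarray(times, dtype=float)
    if intensity < 0:
        raise ValidationError("intensity must be >= 0 lux")
    if intensity == 0:
        return np.ones(t.shape, dtype=float)
    tr = spec.transient
    p_t = float(tr.plateau(intensity))
    tau = np.clip(t - tr.onset_delay, 0.0, None)

    def transient_depth(tau_arr):
        depth = (1.0 - p_t) * (1.0 - np.exp(-tr.k * tau_arr))
        if tr.fade_rate > 0:
            depth = depth * np.exp(-tr.fade_rate * tau_arr)
        return depth

    rpa = 1.0 - transient_depth(tau)

    late = t > SUSTAINED_ONSET_S
    if np.any(late):
        su = spec.sustained
        p_s = float(su.plateau(intensity))
        rate_s = float(su.decay_rate_curve()(intensity)) / 60.0
        tau30 = np.clip(SUSTAINED_ONSET_S - tr.onset_delay, 0.0, None)
        y30 = 1.0 - float(transient_depth(np.asarray(tau30)))
        decay = p_s + (y30 - p_s) * np.exp(-rate_s * (t[late] - SUSTAINED_ONSET_S))
        if spec.pulsatile_period > 0 and spec.pulsatile_depth > 0:
            phase = 2.0 * math.pi * (t[late] - SUSTAINED_ONSET_S) / spec.pulsatile_period
            modulation = 1.0 - 0.5 * spec.pulsatile_depth * (1.0 + np.sin(phase))
            decay = 1.0 - (1.0 - decay) * modulation
        rpa[late] = decay
    rpa[t < 0] = 1.0
    return rpa


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(int(seed))


def _add_noise(rpa: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd > 0:
        noise = np.clip(rng.normal(0.0, sd, size=rpa.shape), -4.0 * sd, 4.0 * sd)
        rpa = rpa + noise
    return np.clip(rpa, RPA_FLOOR, None)


def generate_trace(
    spec: GenotypeSpec,
    intensity: float,
    duration: float,
    dt: float,
    seed,
    mouse_id: str = "m0",
    noise_sd: float | None = None,
    n_baseline: int = 3,
) -> PupilTrace:
    """Generate one raw pupil-area trace (with dark-baseline samples).

    Post-onset samples run from 0 to ``duration`` inclusive in steps of
    ``dt``; ``n_baseline`` (>= 3) dark samples precede onset. ``seed`` may
    be an int, a SeedSequence or a Generator. Identical seeds give
    identical traces.
    """
    if duration <= 0 or dt <= 0:
        raise ValidationError("duration and dt must be > 0")
    n_baseline = max(int(n_baseline), 3)
    rng = _rng_from(seed)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    pre = -dt * np.arange(n_baseline, 0, -1)
    post = np.arange(0.0, duration + dt / 2.0, dt)
    times = np.concatenate([pre, post])
    rpa = model_rpa(spec, intensity, times)
    rpa = _add_noise(rpa, sd, rng)
    return PupilTrace(
        mouse_id=mouse_id,
        genotype=spec.name,
        intensity=float(intensity),
        times=times,
        areas=rpa * spec.baseline_area,
    )


def generate_pulse_chase(
    spec: GenotypeSpec,
    seed,
    max_lag: int = 30,
    peak_depth: float = 0.4,
    noise_sd: float | None = None,
) -> RelativeTrace:
    """Relative-pupil trace following a 1-s light pulse in darkness.

    Constriction depth follows a gamma-like profile
    d(lag) = peak_depth * ((lag/6) * exp(1 - lag/6))**2, zero at lag 0 and
    maximal exactly at the 6-s time point, sampled at integer lags
    0..max_lag. Three dark-baseline samples precede the pulse.
    """
    rng = _rng_from(seed)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    lags = np.arange(0, max_lag + 1, dtype=float)
    shape = (lags / PULSE_CHASE_PEAK_S) * np.exp(1.0 - lags / PULSE_CHASE_PEAK_S)
    depth = peak_depth * shape**2
    times = np.concatenate([[-3.0, -2.0, -1.0], lags])
    rpa = np.concatenate([np.ones(3), 1.0 - depth])
    rpa = _add_noise(rpa, sd, rng)
    return RelativeTrace(
        mouse_id="pulse",
        genotype=spec.name,
        intensity=float("nan"),
        times=times,
        rpa=rpa,
    )


@dataclass(frozen=True)
class Cohort:
    """Endpoint table plus the transient traces it was extracted from."""

    endpoints: pd.DataFrame
    transient_traces: tuple = field(repr=False, default=())


def generate_cohort(
    specs: Sequence[GenotypeSpec] | Mapping[str, GenotypeSpec],
    intensities: Sequence[float],
    n_per_genotype: int,
    base_seed: int,
    noise_sd: float | None = None,
    transient_dt: float = 0.5,
    keep_traces: bool = True,
) -> Cohort:
    """Per-mouse transient and sustained endpoints across intensities.

    For every mouse x intensity the transient endpoint comes from a 30-s
    protocol trace pushed through baseline normalization and the min(5 s,
    30 s) endpoint rule, and the sustained endpoint is the relative pupil
    area after 60 min of continuous light. Reproducible from ``base_seed``
    via per-mouse counter-derived streams.
    """
    if n_per_genotype < 1:
        raise ValidationError("n_per_genotype must be >= 1")
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    rows, traces = [], []
    for g_idx, spec in enumerate(specs):
        for m_idx in range(n_per_genotype):
            mouse_id = f"{spec.name}_{m_idx:02d}"
            for i_idx, lux in enumerate(intensities):
                ss = np.random.SeedSequence(
                    entropy=int(base_seed), spawn_key=(g_idx, m_idx, i_idx)
                )
                rng_transient, rng_sustained = (
                    np.random.default_rng(child) for child in ss.spawn(2)
                )
                trace = generate_trace(
                    spec,
                    lux,
                    duration=30.0,
                    dt=transient_dt,
                    seed=rng_transient,
                    mouse_id=mouse_id,
                    noise_sd=noise_sd,
                )
                rel = relative_trace(trace)
                endpoint_t = transient_endpoint(rel)
                sd = spec.noise_sd if noise_sd is None else noise_sd
                rpa_60min = model_rpa(spec, lux, np.array([3600.0]))
                endpoint_s = float(_add_noise(rpa_60min, sd, rng_sustained)[0])
                rows.append(
                    {
                        "mouse_id": mouse_id,
                        "genotype": spec.name,
                        "intensity_lux": float(lux),
                        "transient_rpa": endpoint_t,
                        "sustained_rpa": endpoint_s,
                    }
                )
                if keep_traces:
                    traces.append(trace)
    return Cohort(endpoints=pd.DataFrame(rows), transient_traces=tuple(traces))


def default_genotype_library() -> dict[str, GenotypeSpec]:
    """Generative parameters for the nine standard mouse lines.

    Wild-type values anchor to the printed physiology (transient EC50
    0.53 lux and half-life 1.1 s; sustained EC50 7.9 lux with decay
    half-lives 2-5 min over 1-100 lux; glutamate-KO transient half-life
    4.8 s). The remaining lines are qualitative encodings of the reported
    phenotypes; see docs/methods.md for the reasoning behind each number.
    """
    wt_transient = TransientParams(ec50=0.53, k=LN2 / 1.1)
    wt_sustained = SustainedParams(
        ec50=7.9, rate_at_1lux=LN2 / 2.0, rate_at_100lux=LN2 / 5.0
    )
    no_sustained = SustainedParams(
        # plateau ~1 everywhere: constriction fully decays within minutes
        ec50=1e6, rate_at_1lux=LN2 / 4.0, rate_at_100lux=LN2 / 4.0
    )
    lib = {
        "wildtype": GenotypeSpec(
            name="wildtype", transient=wt_transient, sustained=wt_sustained
        ),
        # Rods gone: ~2 log-unit transient sensitivity loss; sustained
        # sensitivity matches melanopsin-only lines.
        "rod_ko": GenotypeSpec(
            name="rod_ko",
            transient=TransientParams(ec50=53.0, k=LN2 / 1.1),
            sustained=SustainedParams(
                ec50=53.0, rate_at_1lux=LN2 / 2.0, rate_at_100lux=LN2 / 5.0
            ),
        ),
        # Cones dispensable for both phases.
        "cone_ko": GenotypeSpec(
            name="cone_ko", transient=wt_transient, sustained=wt_sustained
        ),
        # Normal transient, virtually no sustained constriction.
        "melanopsin_ko": GenotypeSpec(
            name="melanopsin_ko", transient=wt_transient, sustained=no_sustained
        ),
        # Rods alone recapitulate the transient; sustained is the residual
        # rod-driven component seen without melanopsin.
        "rod_only": GenotypeSpec(
            name="rod_only",
            transient=wt_transient,
            sustained=SustainedParams(
                ec50=10.0,
                bottom=0.55,
                rate_at_1lux=LN2 / 2.0,
                rate_at_100lux=LN2 / 5.0,
            ),
        ),
        # Minimal, insensitive transient that re-dilates within 30 s; no
        # sustained response.
        "cone_only": GenotypeSpec(
            name="cone_only",
            transient=TransientParams(ec50=500.0, k=1.0, fade_rate=0.12),
            sustained=no_sustained,
        ),
        # Sluggish, delayed transient; no light adaptation, so transient
        # and sustained sensitivities are identical.
        "melanopsin_only": GenotypeSpec(
            name="melanopsin_only",
            transient=TransientParams(ec50=53.0, k=LN2 / 5.0, onset_delay=3.0),
            sustained=SustainedParams(
                ec50=53.0, rate_at_1lux=LN2 / 2.0, rate_at_100lux=LN2 / 5.0
            ),
        ),
        # Slow, shallow transient; sustained improves over transient and
        # is pulsatile (slow neuropeptide vesicle delivery).
        "iprgc_glutamate_ko": GenotypeSpec(
            name="iprgc_glutamate_ko",
            transient=TransientParams(ec50=100.0, k=LN2 / 4.8, bottom=0.5),
            sustained=SustainedParams(
                ec50=30.0,
                bottom=0.25,
                rate_at_1lux=LN2 / 2.0,
                rate_at_100lux=LN2 / 5.0,
            ),
            pulsatile_period=120.0,
            pulsatile_depth=0.3,
        ),
        # Normal transient; attenuated, decaying sustained response.
        "iprgc_pacap_ko": GenotypeSpec(
            name="iprgc_pacap_ko",
            transient=wt_transient,
            sustained=SustainedParams(
                ec50=50.0,
                bottom=0.4,
                rate_at_1lux=LN2 / 5.0,
                rate_at_100lux=LN2 / 5.0,
            ),
        ),
    }
    return lib
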