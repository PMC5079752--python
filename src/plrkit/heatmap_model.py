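"""Time x intensity pupil matrices and necessity/sufficiency contribution maps.

A genotype's pupil behavior over stimulus duration and illuminance is
summarized as a matrix of modeled relative pupil areas built from fitted
parameters: a one-phase association toward the transient plateau for the
first 30 s, then a one-phase relaxation from the transient plateau toward
the sustained plateau with an intensity-dependent rate.

From wild-type, knockout and "-only" genotype matrices the module derives:

* **necessity** of a component: constriction lost when it is knocked out,
  N = clamp(rpa_ko - rpa_wt, 0, 1);
* **sufficiency**: constriction achieved when only that component is
  functional, S = clamp(1 - rpa_only, 0, 1);
* **contribution**: cellwise max(N, S) — for the neurotransmitter panel
  only necessity is used, so contribution == necessity there.

Up to three contribution maps combine into an RGB composite (black = no
contribution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .dose_response import SigmoidFit, predict_rpa
from .errors import ValidationError
from .kinetics import DecayRateCurve

#: End of the transient phase / start of the sustained phase (s).
PHASE_BOUNDARY_S = 30.0

COMPONENTS = ("rod", "cone", "melanopsin", "glutamate", "PACAP")


def default_intensity_grid() -> np.ndarray:
    """log10 lux from 0.001 to 100,000 lux in 0.25 log-unit steps."""
    return np.arange(-3.0, 5.0 + 1e-9, 0.25)


def default_transient_time_grid() -> np.ndarray:
    """0-30 s in 1-s steps."""
    return np.arange(0.0, PHASE_BOUNDARY_S + 1e-9, 1.0)


def default_sustained_time_grid() -> np.ndarray:
    """30 s to 60 min in 5-s steps."""
    return np.arange(PHASE_BOUNDARY_S, 3600.0 + 1e-9, 5.0)


def _check_grid(grid, name):
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValidationError(f"{name} must be a strictly increasing 1-d grid")
    return grid


@dataclass(frozen=True)
class PupilMatrix:
    """Modeled relative pupil area on a (intensity x time) grid.

    ``intensity_grid`` holds log10 lux (rows); ``time_grid`` seconds
    (columns); values lie in (0, 1].
    """

    genotype: str
    phase: str  # "transient" | "sustained"
    intensity_grid: np.ndarray
    time_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        ig = _check_grid(self.intensity_grid, "intensity_grid")
        tg = _check_grid(self.time_grid, "time_grid")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "intensity_grid", ig)
        object.__setattr__(self, "time_grid", tg)
        object.__setattr__(self, "values", values)
        if self.phase not in ("transient", "sustained"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        if values.shape != (ig.size, tg.size):
            raise ValidationError("values shape must be (n_intensity, n_time)")
        if np.any(values <= 0) or np.any(values > 1 + 1e-12):
            raise ValidationError("matrix cells must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.intensity_grid, name="log10_lux"),
            columns=pd.Index(self.time_grid, name="time_s"),
        )


@dataclass(frozen=True)
class ContributionMap:
    """Necessity, sufficiency or contribution values in [0, 1] per cell."""

    component: str
    kind: str  # "necessity" | "sufficiency" | "contribution"
    phase: str
    intensity_grid: np.ndarray
    time_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        ig = _check_grid(self.intensity_grid, "intensity_grid")
        tg = _check_grid(self.time_grid, "time_grid")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "intensity_grid", ig)
        object.__setattr__(self, "time_grid", tg)
        object.__setattr__(self, "values", values)
        if self.component not in COMPONENTS:
            raise ValidationError(f"unknown component {self.component!r}")
        if self.kind not in ("necessity", "sufficiency", "contribution"):
            raise ValidationError(f"unknown map kind {self.kind!r}")
        if values.shape != (ig.size, tg.size):
            raise ValidationError("values shape must be (n_intensity, n_time)")
        if np.any(values < 0) or np.any(values > 1):
            raise ValidationError("map cells must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.intensity_grid, name="log10_lux"),
            columns=pd.Index(self.time_grid, name="time_s"),
        )


def _plateau_values(curve, intensity_grid: np.ndarray) -> np.ndarray:
    lux = 10.0 ** np.asarray(intensity_grid, dtype=float)
    if isinstance(curve, SigmoidFit):
        return np.asarray(predict_rpa(curve, lux), dtype=float)
    if callable(curve):
        return np.asarray([float(curve(x)) for x in lux], dtype=float)
    raise ValidationError("plateau curve must be a SigmoidFit or callable lux -> rpa")


def _same_grids(a, b):
    return np.array_equal(a.intensity_grid, b.intensity_grid) and np.array_equal(
        a.time_grid, b.time_grid
    )


def build_transient_matrix(
    plateau_curve,
    k_rapid: float,
    genotype: str = "",
    time_grid: np.ndarray | None = None,
    intensity_grid: np.ndarray | None = None,
) -> PupilMatrix:
    """One-phase association from a fully open pupil to the transient plateau.

    cell(t, I) = plateau(I) + (1 - plateau(I)) * exp(-k_rapid * t); the
    starting value is 1 at every intensity and ``k_rapid`` (1/s) is shared
    across intensities (extracted from the wild-type rapid-constriction
    kinetics at 100 lux).
    """
    if k_rapid <= 0:
        raise ValidationError("k_rapid must be > 0")
    tg = default_transient_time_grid() if time_grid is None else np.asarray(time_grid, float)
    ig = default_intensity_grid() if intensity_grid is None else np.asarray(intensity_grid, float)
    plateau = _plateau_values(plateau_curve, ig)[:, None]
    t = np.asarray(tg, dtype=float)[None, :]
    values = plateau + (1.0 - plateau) * np.exp(-k_rapid * t)
    return PupilMatrix(
        genotype=genotype, phase="transient", intensity_grid=ig, time_grid=tg,
        values=values,
    )


def build_sustained_matrix(
    transient_plateau_curve,
    sustained_plateau_curve,
    k_sustained: DecayRateCurve,
    genotype: str = "",
    time_grid: np.ndarray | None = None,
    intensity_grid: np.ndarray | None = None,
) -> PupilMatrix:
    """One-phase relaxation from the transient to the sustained plateau.

    cell(t, I) = pS(I) + (pT(I) - pS(I)) * exp(-k(I) * (t - 30 s)), where
    the start value pT(I) is the transient plateau at each intensity and
    ``k_sustained`` maps intensity to a decay rate in 1/min.
    """
    tg = default_sustained_time_grid() if time_grid is None else np.asarray(time_grid, float)
    ig = default_intensity_grid() if intensity_grid is None else np.asarray(intensity_grid, float)
    if tg[0] < PHASE_BOUNDARY_S - 1e-9:
        raise ValidationError("sustained time grid must start at >= 30 s")
    p_t = _plateau_values(transient_plateau_curve, ig)[:, None]
    p_s = _plateau_values(sustained_plateau_curve, ig)[:, None]
    rate_per_s = np.asarray(k_sustained(10.0 ** ig), dtype=float)[:, None] / 60.0
    t = np.asarray(tg, dtype=float)[None, :]
    # convex-combination form so the t = 30 s column equals the transient
    # plateau exactly
    w = np.exp(-rate_per_s * (t - PHASE_BOUNDARY_S))
    values = p_t * w + p_s * (1.0 - w)
    return PupilMatrix(
        genotype=genotype, phase="sustained", intensity_grid=ig, time_grid=tg,
        values=values,
    )


def average_matrices(matrices: Sequence[PupilMatrix]) -> PupilMatrix:
    """Cellwise mean of replicate mutant-line matrices (identical grids)."""
    if len(matrices) == 0:
        raise ValidationError("cannot average zero matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if not _same_grids(first, m) or m.phase != first.phase:
            raise ValidationError("matrices must share grids and phase to average")
    mean = np.mean([m.values for m in matrices], axis=0)
    label = "mean(" + ",".join(m.genotype for m in matrices) + ")"
    return replace(first, genotype=label, values=mean)


def necessity_map(wt: PupilMatrix, ko: PupilMatrix, component: str) -> ContributionMap:
    """Constriction lost on knockout: clamp(rpa_ko - rpa_wt, 0, 1).

    Larger where the component is more required; automatically normalized
    by the wild-type constriction available at that cell.
    """
    if not _same_grids(wt, ko) or wt.phase != ko.phase:
        raise ValidationError("wild-type and knockout matrices must share grids")
    values = np.clip(ko.values - wt.values, 0.0, 1.0)
    return ContributionMap(
        component=component, kind="necessity", phase=wt.phase,
        intensity_grid=wt.intensity_grid, time_grid=wt.time_grid, values=values,
    )


def sufficiency_map(only_line: PupilMatrix, component: str) -> ContributionMap:
    """Constriction achieved by the isolated component: clamp(1 - rpa, 0, 1)."""
    values = np.clip(1.0 - only_line.values, 0.0, 1.0)
    return ContributionMap(
        component=component, kind="sufficiency", phase=only_line.phase,
        intensity_grid=only_line.intensity_grid, time_grid=only_line.time_grid,
        values=values,
    )


def contribution_map(
    necessity: ContributionMap, sufficiency: ContributionMap | None = None
) -> ContributionMap:
    """Cellwise max of necessity and sufficiency.

    With ``sufficiency=None`` (the neurotransmitter panel, where no "-only"
    line exists) the contribution equals the necessity map.
    """
    if necessity.kind != "necessity":
        raise ValidationError("first argument must be a necessity map")
    if sufficiency is None:
        return replace(necessity, kind="contribution")
    if sufficiency.kind != "sufficiency":
        raise ValidationError("second argument must be a sufficiency map")
    if necessity.component != sufficiency.component:
        raise ValidationError("necessity and sufficiency maps must share a component")
    if not _same_grids(necessity, sufficiency):
        raise ValidationError("maps must share grids")
    return replace(
        necessity,
        kind="contribution",
        values=np.maximum(necessity.values, sufficiency.values),
    )


def apply_cone_decay_adjustment(
    matrix: PupilMatrix, cone_only_decay_rate: float
) -> PupilMatrix:
    """Relax each intensity row toward 1 after its constriction minimum.

    Models the rapid adaptation of cone-driven constriction: past the most
    constricted time point of each row, the remaining constriction depth
    decays at the cone-only transient decay rate (1/s, measured at 100 lux
    and applied at all intensities). The rate -> 0 limit leaves the matrix
    unchanged and the adjustment never deepens constriction.
    """
    if cone_only_decay_rate < 0:
        raise ValidationError("decay rate must be >= 0")
    t = matrix.time_grid
    t_min = t[np.argmin(matrix.values, axis=1)][:, None]
    fade = np.exp(-cone_only_decay_rate * np.clip(t[None, :] - t_min, 0.0, None))
    # cells at/before the minimum keep their exact original value
    values = np.where(
        fade < 1.0, 1.0 - (1.0 - matrix.values) * fade, matrix.values
    )
    return replace(matrix, values=values)


def compose_rgb(
    red: ContributionMap | None = None,
    green: ContributionMap | None = None,
    blue: ContributionMap | None = None,
) -> np.ndarray:
    """Combine up to three contribution maps into an 8-bit RGB image array.

    Channel value = round(255 * contribution); unassigned channels are 0,
    so black means no contribution. Returns a (n_intensity, n_time, 3)
    uint8 array.
    """
    maps = {"red": red, "green": green, "blue": blue}
    assigned = {ch: m for ch, m in maps.items() if m is not None}
    if not assigned:
        raise ValidationError("at least one channel must be assigned")
    ids = [id(m) for m in assigned.values()]
    if len(set(ids)) != len(ids):
        raise ValidationError("each map may be assigned to only one channel")
    first = next(iter(assigned.values()))
    for m in assigned.values():
        if not _same_grids(first, m):
            raise ValidationError("maps must share grids to compose an image")
    shape = first.values.shape
    img = np.zeros(shape + (3,), dtype=np.uint8)
    for idx, ch in enumerate(("red", "green", "blue")):
        m = maps[ch]
        if m is not None:
            img[:, :, idx] = np.rint(255.0 * m.values).astype(np.uint8)
    return img


def save_rgb_png(rgb: np.ndarray, path) -> None:
    """Write an RGB composite to a PNG file (dim intensities at the bottom)."""
    Image.fromarray(rgb[::-1, :, :], mode="RGB").save(path, format="PNG")
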