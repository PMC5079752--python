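"""Reading pupil-area tables and converting traces to relative pupil area.

The toolkit consumes long-format CSV tables of manually measured pupil
areas (one row per video frame) and works internally with two containers:

* :class:`PupilTrace` — raw areas for one mouse at one stimulus intensity,
  with times in seconds relative to light onset (negative = dark baseline);
* :class:`RelativeTrace` — the same trace divided by its dark-baseline
  area, so 1.0 means a fully open pupil.

The transient endpoint of a trace follows the convention of taking the
*minimum* relative pupil size at either 5 s or 30 s after light onset,
whichever is smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Standard column names of the trace CSV format.
TRACE_COLUMNS = ("mouse_id", "genotype", "intensity_lux", "time_s", "pupil_area")

#: Nearest-sample tolerance (s) when locating the 5 s / 30 s endpoints.
ENDPOINT_TOLERANCE_S = 0.5


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class PupilTrace:
    """Raw pupil-area time series for one mouse at one light intensity.

    ``times`` are seconds relative to light onset and must be strictly
    increasing with at least one dark-baseline sample (time < 0); areas are
    strictly positive (pixels or mm^2 — the unit cancels on normalization).
    """

    mouse_id: str
    genotype: str
    intensity: float
    times: np.ndarray
    areas: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        areas = _as_float_array(self.areas, "areas")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "areas", areas)
        if times.shape != areas.shape:
            raise ValidationError("times and areas must have equal length")
        if times.size == 0:
            raise ValidationError("trace is empty")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.any(times < 0):
            raise ValidationError("trace has no dark-baseline sample (time < 0)")
        if np.any(areas <= 0):
            raise ValidationError("pupil areas must be > 0")
        if self.intensity < 0:
            raise ValidationError("intensity must be >= 0 lux")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class RelativeTrace:
    """Baseline-normalized pupil time series (relative pupil area, RPA)."""

    mouse_id: str
    genotype: str
    intensity: float
    times: np.ndarray
    rpa: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        rpa = _as_float_array(self.rpa, "rpa")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rpa", rpa)
        if times.shape != rpa.shape:
            raise ValidationError("times and rpa must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(rpa <= 0):
            raise ValidationError("relative pupil area must be > 0")

    def __len__(self) -> int:
        return self.times.size

    def post_onset(self) -> "RelativeTrace":
        """Return the sub-trace at times >= 0 (light on)."""
        mask = self.times >= 0
        return replace(self, times=self.times[mask], rpa=self.rpa[mask])


def read_trace_table(
    path,
    schema: Mapping[str, str] | None = None,
) -> list[PupilTrace]:
    """Read a long-format pupil-area CSV into one trace per (mouse, intensity).

    Parameters
    ----------
    path : str or file-like
        CSV with columns ``mouse_id, genotype, intensity_lux, time_s,
        pupil_area`` (or renamed via ``schema``).
    schema : mapping, optional
        Maps standard column names to the names used in the file, e.g.
        ``{"pupil_area": "area_px"}``.

    Returns
    -------
    list of PupilTrace, sorted by (mouse_id, intensity), times sorted
    within each trace.
    """
    table = pd.read_csv(path)
    colmap = {std: (schema or {}).get(std, std) for std in TRACE_COLUMNS}
    missing = [col for col in colmap.values() if col not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = table[[colmap[c] for c in TRACE_COLUMNS]].copy()
    df.columns = list(TRACE_COLUMNS)
    for col in ("intensity_lux", "time_s", "pupil_area"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not numeric: {exc}") from exc
    bad = df.index[df["pupil_area"] <= 0]
    if len(bad):
        raise ValidationError(
            f"non-positive pupil_area at input row(s) {list(bad[:5])}"
        )

    traces = []
    for (mouse, intensity), group in df.groupby(
        ["mouse_id", "intensity_lux"], sort=True
    ):
        group = group.sort_values("time_s")
        genotypes = group["genotype"].unique()
        if len(genotypes) != 1:
            raise ValidationError(
                f"mouse {mouse!r} has conflicting genotype labels: {genotypes}"
            )
        traces.append(
            PupilTrace(
                mouse_id=str(mouse),
                genotype=str(genotypes[0]),
                intensity=float(intensity),
                times=group["time_s"].to_numpy(),
                areas=group["pupil_area"].to_numpy(),
            )
        )
    return traces


def write_relative_table(traces: Sequence[RelativeTrace], path) -> None:
    """Write relative traces to a long-format CSV (columns: mouse_id,
    genotype, intensity_lux, time_s, rpa)."""
    frames = [
        pd.DataFrame(
            {
                "mouse_id": t.mouse_id,
                "genotype": t.genotype,
                "intensity_lux": t.intensity,
                "time_s": t.times,
                "rpa": t.rpa,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_relative_table(path) -> list[RelativeTrace]:
    """Read a relative-trace CSV written by :func:`write_relative_table`."""
    df = pd.read_csv(path)
    needed = {"mouse_id", "genotype", "intensity_lux", "time_s", "rpa"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")
    out = []
    for (mouse, intensity), group in df.groupby(["mouse_id", "intensity_lux"]):
        group = group.sort_values("time_s")
        out.append(
            RelativeTrace(
                mouse_id=str(mouse),
                genotype=str(group["genotype"].iloc[0]),
                intensity=float(intensity),
                times=group["time_s"].to_numpy(dtype=float),
                rpa=group["rpa"].to_numpy(dtype=float),
            )
        )
    return out


def relative_trace(trace: PupilTrace) -> RelativeTrace:
    """Normalize a raw trace by its mean dark-baseline area.

    The baseline is the mean area over all pre-onset samples (time < 0),
    which reduces to the single-frame rule when only one dark frame exists.
    """
    baseline_mask = trace.times < 0
    if not np.any(baseline_mask):
        raise ValidationError("no baseline sample (time < 0) to normalize by")
    baseline = float(trace.areas[baseline_mask].mean())
    return RelativeTrace(
        mouse_id=trace.mouse_id,
        genotype=trace.genotype,
        intensity=trace.intensity,
        times=trace.times,
        rpa=trace.areas / baseline,
    )


def _nearest_sample(rel: RelativeTrace, t: float, tol: float) -> float | None:
    idx = int(np.argmin(np.abs(rel.times - t)))
    if abs(rel.times[idx] - t) <= tol:
        return float(rel.rpa[idx])
    return None


def transient_endpoint(
    rel: RelativeTrace, tol: float = ENDPOINT_TOLERANCE_S
) -> float:
    """Transient-phase endpoint: min RPA at 5 s or 30 s after light onset.

    Samples are matched to the nominal 5 s / 30 s time points by nearest
    sample within ``tol`` seconds (video frame times are irregular). If only
    one of the two time points is available its value is returned; if
    neither is, a :class:`ValidationError` is raised.
    """
    values = [v for t in (5.0, 30.0) if (v := _nearest_sample(rel, t, tol)) is not None]
    if not values:
        raise ValidationError(
            "no sample within tolerance of either the 5 s or the 30 s time point"
        )
    return min(values)
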