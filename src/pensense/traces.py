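"""Switching-time (Cq) extraction from fluorescence time traces.

The statistic mirrors the qPCR-style workflow used for this class of
isothermal switch experiments: each trace is affinely normalized to
[0, 1]; forward differences between points 10 minutes apart are computed
(start points within the final 10 minutes are excluded); the earliest
start time of the maximal difference is the Cq.  Flat traces -- no
distinctive switch-driven fluorescence increase -- are assigned
1/Cq = 0.  The original workflow called flat traces manually; here the
call is automated: a trace is flat when its raw dynamic range is below a
fraction of the instrument full scale, or when the maximal normalized
10-min difference is below ``flat_threshold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .circuit import TraceSet

__all__ = ["FluorescenceTrace", "CqResult", "normalize", "extract_cq", "batch_cq"]

#: default analysis window (minutes) for the steepest-rise search
DEFAULT_WINDOW = 10.0
#: default flatness threshold on the maximal normalized window difference
DEFAULT_FLAT_THRESHOLD = 0.05
#: fraction of the instrument full scale below which a raw range is flat
FLAT_RANGE_FRACTION = 0.05


@dataclass(frozen=True)
class FluorescenceTrace:
    """One reporter fluorescence time trace on a uniform minute-scale grid."""

    time: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.time.ndim != 1 or self.time.shape != self.values.shape:
            raise ValueError(f"trace {self.label!r}: time and values must be 1-D and equal length")
        if self.time.size < 2:
            raise ValueError(f"trace {self.label!r}: at least two samples required")
        dt = np.diff(self.time)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError(f"trace {self.label!r}: time grid must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class CqResult:
    """Switching time of one trace.

    ``cq`` is NaN and ``inv_cq`` 0 for flat traces; otherwise
    ``inv_cq = 1/cq`` (infinite for the degenerate Cq = 0 of, e.g., a
    pure linear ramp starting at t = 0).  ``max_diff`` is the maximal
    10-min forward difference on the normalized trace.
    """

    cq: float
    inv_cq: float
    flat: bool
    max_diff: float
    label: str = ""


def normalize(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Affine rescaling of the values to [0, 1] (min to 0, max to 1).

    A trace with zero dynamic range cannot be rescaled; it is returned
    with all-zero values (the downstream flatness rule catches it), never
    dividing by zero.
    """
    vmin = float(np.min(trace.values))
    vmax = float(np.max(trace.values))
    rng = vmax - vmin
    if rng == 0.0:
        return replace(trace, values=np.zeros_like(trace.values))
    return replace(trace, values=(trace.values - vmin) / rng)


def extract_cq(
    trace: FluorescenceTrace,
    window: float = DEFAULT_WINDOW,
    flat_threshold: float = DEFAULT_FLAT_THRESHOLD,
    min_range: float | None = None,
) -> CqResult:
    """Cq of one raw trace via the maximal 10-minute forward difference.

    Parameters
    ----------
    window : float
        Difference window in minutes; must be a multiple of the sampling
        interval.  Start points in the final ``window`` minutes are
        excluded.
    flat_threshold : float
        The trace is flat when the maximal normalized window difference
        falls below this value.
    min_range : float, optional
        Absolute raw dynamic range below which the trace is flat
        regardless of its shape (typically a fraction of the instrument
        full scale); guards against normalization amplifying pure noise.

    Ties in the maximal difference are broken toward the earliest start
    point.
    """
    dt = trace.dt
    steps = window / dt
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
        raise ValueError(f"window {window} must be a positive multiple of the sampling interval {dt}")
    steps = int(round(steps))
    if trace.values.size < 2 * steps:
        raise ValueError(
            f"trace {trace.label!r}: {trace.values.size} samples is too short "
            f"for a {window}-min window"
        )

    raw_range = float(np.ptp(trace.values))
    norm = normalize(trace)
    diffs = norm.values[steps:] - norm.values[:-steps]
    max_diff = float(np.max(diffs))
    # earliest start point among ties (to float tolerance, so that exact
    # ties, e.g. on a linear ramp, are not broken by rounding noise)
    imax = int(np.nonzero(diffs >= max_diff - 1e-12)[0][0])

    flat = raw_range == 0.0 or max_diff < flat_threshold
    if min_range is not None and raw_range < min_range:
        flat = True
    if flat:
        return CqResult(cq=math.nan, inv_cq=0.0, flat=True, max_diff=max_diff, label=trace.label)
    cq = float(norm.time[imax])
    inv_cq = 1.0 / cq if cq > 0 else math.inf
    return CqResult(cq=cq, inv_cq=inv_cq, flat=False, max_diff=max_diff, label=trace.label)


def batch_cq(
    traces: TraceSet,
    window: float = DEFAULT_WINDOW,
    flat_threshold: float = DEFAULT_FLAT_THRESHOLD,
    min_range: float | None = None,
) -> list[CqResult]:
    """Normalize and extract Cq for every trace of a TraceSet.

    When ``min_range`` is not given and the TraceSet carries an
    instrument full scale, traces moving less than
    ``FLAT_RANGE_FRACTION`` of that scale are called flat.
    """
    if min_range is None and traces.full_scale is not None:
        min_range = FLAT_RANGE_FRACTION * traces.full_scale
    results = []
    for row, cond in zip(traces.traces, traces.conditions):
        tr = FluorescenceTrace(time=traces.time, values=row, label=cond.label)
        try:
            results.append(
                extract_cq(tr, window=window, flat_threshold=flat_threshold, min_range=min_range)
            )
        except ValueError as err:
            raise ValueError(f"condition {cond.label!r}: {err}") from err
    return results
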