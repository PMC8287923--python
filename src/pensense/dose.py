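"""Dose-response curves (1/Cq versus ligand concentration) and Hill fits.

The response of a sensing circuit is summarized as the mean replicate
1/Cq at each ligand concentration.  The error bar follows the
maximum-single-point rule used for the original triplicate experiments:
the largest absolute single-replicate deviation from its concentration
mean, over the whole replicate set, applied uniformly to every point.

Hill characterization fits the four-parameter model

    increasing:  r(c) = baseline + amplitude * c^n / (K^n + c^n)
    decreasing:  r(c) = baseline + amplitude * K^n / (K^n + c^n)

by unweighted least squares in linear concentration space (so c = 0
points are retained), with multi-start initialization because
ultrasensitive fits (n ~ 10) have narrow basins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import spearmanr

from .traces import CqResult

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "assemble",
    "hill_response",
    "generate_hill_curve",
    "fit_hill",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Mean 1/Cq (per minute) against ligand concentration (uM)."""

    ligand: str
    concentrations: np.ndarray
    inv_cq_mean: np.ndarray
    inv_cq_err: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        for name in ("concentrations", "inv_cq_mean", "inv_cq_err"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.concentrations.size == self.inv_cq_mean.size == self.inv_cq_err.size):
            raise ValueError("concentration and response arrays must have equal length")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters: apparent Kd in uM, dimensionless n."""

    baseline: float
    amplitude: float
    kd_app: float
    n_hill: float
    direction: str
    residual_norm: float


def _inv_cq_value(rep: "CqResult | float") -> float:
    if isinstance(rep, CqResult):
        return rep.inv_cq
    return float(rep)


def assemble(
    ligand: str,
    groups: Mapping[float, Sequence["CqResult | float"]],
) -> DoseResponseCurve:
    """Build a dose-response curve from replicate Cq results per concentration.

    ``groups`` maps ligand concentration (uM) to that condition's
    replicates, given either as `CqResult` (flat replicates contribute
    1/Cq = 0) or as bare 1/Cq values.  Requires at least four distinct
    concentrations.  ``n_replicates`` reports the smallest replicate
    count encountered (conditions may be incomplete).
    """
    if len(groups) < 4:
        raise ValueError("at least 4 distinct concentrations required")
    concs = np.array(sorted(groups), dtype=float)
    means = np.empty_like(concs)
    max_dev = 0.0
    n_min = math.inf
    for i, c in enumerate(concs):
        reps = [_inv_cq_value(r) for r in groups[c]]
        if not reps:
            raise ValueError(f"concentration {c}: no replicates")
        n_min = min(n_min, len(reps))
        means[i] = float(np.mean(reps))
        max_dev = max(max_dev, float(np.max(np.abs(np.asarray(reps) - means[i]))))
    errs = np.full_like(concs, max_dev)
    return DoseResponseCurve(
        ligand=ligand,
        concentrations=concs,
        inv_cq_mean=means,
        inv_cq_err=errs,
        n_replicates=int(n_min),
    )


def hill_response(
    conc: "np.ndarray | float",
    baseline: float,
    amplitude: float,
    kd: float,
    n: float,
    direction: str = "increasing",
) -> np.ndarray:
    """Evaluate the four-parameter Hill model."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        occ = c**n / (kd**n + c**n)
    if direction == "increasing":
        return baseline + amplitude * occ
    if direction == "decreasing":
        return baseline + amplitude * (1.0 - occ)
    raise ValueError(f"unknown direction {direction!r}")


def generate_hill_curve(
    ligand: str,
    kd: float,
    n: float,
    direction: str,
    baseline: float = 0.0,
    amplitude: float = 0.01,
    concentrations: "np.ndarray | None" = None,
    n_points: int = 10,
    span_decades: float = 3.0,
) -> DoseResponseCurve:
    """Noise-free dose-response generated from the Hill model itself.

    Default grid: ``n_points`` log-spaced concentrations centered on the
    apparent Kd, spanning ``span_decades`` decades.  Used for estimator
    round-trip checks and calibration.
    """
    if concentrations is None:
        half = span_decades / 2.0
        concentrations = np.logspace(math.log10(kd) - half, math.log10(kd) + half, n_points)
    concentrations = np.asarray(concentrations, dtype=float)
    resp = hill_response(concentrations, baseline, amplitude, kd, n, direction)
    return DoseResponseCurve(
        ligand=ligand,
        concentrations=concentrations,
        inv_cq_mean=resp,
        inv_cq_err=np.zeros_like(resp),
        n_replicates=1,
    )


def _infer_direction(curve: DoseResponseCurve) -> str:
    rho = spearmanr(curve.concentrations, curve.inv_cq_mean).statistic
    if not np.isfinite(rho) or rho == 0:
        raise ValueError(f"curve {curve.ligand!r}: direction is ambiguous; supply it explicitly")
    return "increasing" if rho > 0 else "decreasing"


def fit_hill(curve: DoseResponseCurve, direction: str = "auto") -> HillFit:
    """Least-squares Hill fit of a dose-response curve.

    Multi-start over Hill coefficients {1, 2, 8} and Kd around the
    geometric mean of the (positive) concentration range; the best
    converged start wins.  Noise-free input generated from the model is
    recovered essentially exactly.
    """
    y = curve.inv_cq_mean
    if float(np.ptp(y)) == 0.0:
        raise ValueError(f"curve {curve.ligand!r}: no response to fit")
    if direction == "auto":
        direction = _infer_direction(curve)

    c = curve.concentrations
    pos = c[c > 0]
    if pos.size < 2:
        raise ValueError(f"curve {curve.ligand!r}: need at least two positive concentrations")
    gm = math.exp(float(np.mean(np.log(pos))))
    span = float(np.ptp(y))
    base0 = float(np.min(y))

    def residuals(p: np.ndarray) -> np.ndarray:
        baseline, amplitude, kd, n = p
        return hill_response(c, baseline, amplitude, kd, n, direction) - y

    best = None
    lower = [-np.inf, 1e-12, 1e-9, 1e-2]
    upper = [np.inf, np.inf, np.inf, 100.0]
    for n0 in (1.0, 2.0, 8.0):
        for k0 in (gm / 3.0, gm, 3.0 * gm):
            p0 = np.array([base0, span, k0, n0])
            try:
                sol = least_squares(
                    residuals, p0, bounds=(lower, upper),
                    method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"curve {curve.ligand!r}: Hill fit did not converge")

    baseline, amplitude, kd, n = (float(v) for v in best.x)
    return HillFit(
        baseline=baseline,
        amplitude=amplitude,
        kd_app=kd,
        n_hill=n,
        direction=direction,
        residual_norm=float(np.linalg.norm(residuals(best.x))),
    )
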