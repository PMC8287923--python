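"""Two-input classifier maps: response surfaces on a ligand concentration grid.

A circuit carrying two sensing templates (one per transcription factor)
maps a 2-D concentration space to switching speed 1/Cq.  The four
direct/inverted template combinations realize the four sign patterns of
an approximate weighted log-sum readout

    1/Cq  ~  w0 + w_x * log(c_x) + w_y * log(c_y)

fitted by least squares over the non-flat grid cells (1/Cq = 0 is a
censoring value, not a response level, and is excluded from the fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitSpec, simulate
from .traces import batch_cq

__all__ = ["GridResult", "LogSumFit", "simulate_grid", "fit_logsum", "expected_weight_sign"]


@dataclass(frozen=True)
class GridResult:
    """1/Cq matrix over a 2-D ligand concentration grid.

    ``inv_cq`` has shape (len(y_concs), len(x_concs)); flat cells are 0.
    ``logic`` records the template architecture per axis
    (``"direct"`` for psT, ``"inverted"`` for pskT).
    """

    ligand_x: str
    ligand_y: str
    x_concs: np.ndarray
    y_concs: np.ndarray
    inv_cq: np.ndarray
    logic: tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_concs", np.asarray(self.x_concs, dtype=float))
        object.__setattr__(self, "y_concs", np.asarray(self.y_concs, dtype=float))
        object.__setattr__(self, "inv_cq", np.asarray(self.inv_cq, dtype=float))
        if self.inv_cq.shape != (self.y_concs.size, self.x_concs.size):
            raise ValueError("inv_cq must have shape (len(y_concs), len(x_concs))")
        if np.any(self.inv_cq < 0):
            raise ValueError("inv_cq entries must be >= 0")


@dataclass(frozen=True)
class LogSumFit:
    """Weighted log-sum plane fitted to the non-flat cells of a grid."""

    w0: float
    w_x: float
    w_y: float
    residual_norm: float
    n_cells: int


def _axis_logic(spec: CircuitSpec, ligand: str) -> str:
    """Template architecture sensing a ligand: psT = direct, pskT = inverted."""
    roles = set()
    for t in spec.templates:
        if t.operator is not None and spec.tf(t.operator).ligand_name == ligand:
            roles.add(t.role)
    if not roles:
        raise ValueError(f"no sensing template is coupled to ligand {ligand!r}")
    if roles == {"psT"}:
        return "direct"
    if roles == {"pskT"}:
        return "inverted"
    raise ValueError(f"ligand {ligand!r} is sensed by both psT and pskT templates")


def expected_weight_sign(spec: CircuitSpec, ligand: str) -> int:
    """Expected sign of d(1/Cq)/d(ligand) from architecture and TF mode.

    An inducer frees a psT (faster switching, +) or a pskT (antisignal
    production, -); a corepressor blocks them, flipping both signs.
    """
    arch = _axis_logic(spec, ligand)
    tf = next(
        spec.tf(t.operator) for t in spec.templates
        if t.operator is not None and spec.tf(t.operator).ligand_name == ligand
    )
    sign = 1 if arch == "direct" else -1
    return sign if tf.mode == "inducer" else -sign


def simulate_grid(
    spec: CircuitSpec,
    ligand_x: str,
    x_concs: np.ndarray,
    ligand_y: str,
    y_concs: np.ndarray,
    duration: float = 600.0,
) -> GridResult:
    """Simulate the circuit on every grid cell and extract 1/Cq.

    Deterministic (noise-free traces).  Simulation failures are
    re-raised annotated with the grid coordinates.
    """
    x_concs = np.asarray(x_concs, dtype=float)
    y_concs = np.asarray(y_concs, dtype=float)
    logic = (_axis_logic(spec, ligand_x), _axis_logic(spec, ligand_y))
    inv = np.zeros((y_concs.size, x_concs.size))
    for j, cy in enumerate(y_concs):
        for i, cx in enumerate(x_concs):
            cond = spec.with_ligands(**{ligand_x: float(cx), ligand_y: float(cy)})
            try:
                ts = simulate(cond, duration=duration)
                res = batch_cq(ts)[0]
            except Exception as err:
                raise RuntimeError(
                    f"grid cell ({ligand_x}={cx:g}, {ligand_y}={cy:g}): {err}"
                ) from err
            inv[j, i] = 0.0 if res.flat else res.inv_cq
    return GridResult(
        ligand_x=ligand_x, ligand_y=ligand_y,
        x_concs=x_concs, y_concs=y_concs, inv_cq=inv, logic=logic,
    )


def fit_logsum(grid: GridResult) -> LogSumFit:
    """Least-squares plane fit of 1/Cq against the log ligand inputs.

    Requires strictly positive grid concentrations; flat cells are
    excluded.  Raises if every cell is flat.
    """
    if np.any(grid.x_concs <= 0) or np.any(grid.y_concs <= 0):
        raise ValueError("log-sum fit requires strictly positive concentrations")
    lx, ly = np.meshgrid(np.log(grid.x_concs), np.log(grid.y_concs))
    mask = grid.inv_cq > 0
    if not np.any(mask):
        raise ValueError("all grid cells are flat; nothing to fit")
    A = np.column_stack([np.ones(mask.sum()), lx[mask], ly[mask]])
    b = grid.inv_cq[mask]
    coef, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
    resid = float(np.linalg.norm(A @ coef - b))
    return LogSumFit(
        w0=float(coef[0]), w_x=float(coef[1]), w_y=float(coef[2]),
        residual_norm=resid, n_cells=int(mask.sum()),
    )
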