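import numpy as np
import pytest

from pensense.circuit import CircuitSpec, TemplateSpec, simulate
from pensense.dose import assemble
from pensense.io import bundled_config
from pensense.traces import batch_cq


@pytest.fixture
def bare_switch() -> CircuitSpec:
    """The aT/pT/rT bistable amplification switch with no input module."""
    return CircuitSpec(
        templates=[
            TemplateSpec("aT", "aT", 50.0),
            TemplateSpec("pT", "pT", 7.0),
            TemplateSpec("rT", "rT", 10.0),
        ]
    )


@pytest.fixture
def fig_config():
    """Loader for the bundled per-figure circuit fixtures."""
    return bundled_config


@pytest.fixture
def simulated_dose_curve():
    """Simulate a noise-free single-replicate dose-response for one circuit."""

    def _run(config_name: str, ligand: str, concentrations, duration: float = 600.0):
        spec = bundled_config(config_name)
        groups = {}
        for c in concentrations:
            ts = simulate(spec.with_ligands(**{ligand: float(c)}), duration=duration)
            groups[float(c)] = [batch_cq(ts)[0]]
        return assemble(ligand, groups)

    return _run


def brute_force_cq(time, values, window=10.0, flat_threshold=0.05):
    """Independent all-pairs oracle for the Cq statistic.

    Scans every pair of samples exactly ``window`` apart on the
    normalized trace, keeping the earliest start point of the maximal
    difference.  Returns (cq, inv_cq, flat).
    """
    time = [float(t) for t in time]
    values = [float(v) for v in values]
    vmin, vmax = min(values), max(values)
    if vmax == vmin:
        return (None, 0.0, True)
    norm = [(v - vmin) / (vmax - vmin) for v in values]
    best = None
    best_i = None
    for i in range(len(time)):
        for j in range(i + 1, len(time)):
            gap = time[j] - time[i]
            if gap > window + 1e-9:  # times increase; no later j can match
                break
            if abs(gap - window) < 1e-9:
                d = norm[j] - norm[i]
                if best is None or d > best + 1e-12:
                    best, best_i = d, i
    assert best is not None, "trace shorter than the window"
    if best < flat_threshold:
        return (None, 0.0, True)
    cq = time[best_i]
    return (cq, (1.0 / cq if cq > 0 else np.inf), False)
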