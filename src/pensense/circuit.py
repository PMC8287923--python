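"""Kinetic model of PEN-toolbox bistable-switch circuits with
transcription-factor input-translating modules.

The model follows the module architecture of the experimental system: an
autocatalytic template (aT) exponentially amplifies a short DNA signal
strand, a pseudotemplate (pT) deactivates it through a fast but saturable
sink (creating a concentration threshold and hence bistability), and a
hairpin reporter template (rT) is irreversibly opened by the signal, which
is the fluorescence observable.  Input-translating templates (sT, psT,
pskT) act as constitutive sources of signal or antisignal strands; on psT
and pskT the nicking site is sterically occluded by a bound transcription
factor, so their source flux is proportional to the TF-free template
fraction, recomputed at quasi-equilibrium from the instantaneous ligand
concentration.  An optional enzyme layer produces the TF ligand in situ
from two substrates with two-substrate Michaelis-Menten kinetics.

Units are fixed globally: time in minutes, DNA species in nM, ligands and
enzymes in uM.  Fluxes on templates use a saturable Michaelis-type form
``k * T * s / (Km + s)`` so that the pseudotemplate sink is faster than
amplification at trace signal levels but has limited capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TemplateSpec",
    "TFSpec",
    "EnzymeSpec",
    "RateParameters",
    "CircuitSpec",
    "Condition",
    "TraceSet",
    "ReactionNetwork",
    "active_tf_fraction",
    "template_occupancy",
    "build_network",
    "simulate",
    "simulate_many",
    "enzyme_rate",
    "add_noise",
    "switch_threshold",
    "synthetic_switch_trace",
]

TEMPLATE_ROLES = ("aT", "pT", "rT", "sT", "psT", "pskT")
#: roles whose nicking site can be occluded by a bound transcription factor
SENSING_ROLES = ("psT", "pskT")
#: enzyme concentration (uM) above which the circuit is flagged non-specific
DISRUPTION_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# declarative circuit description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateSpec:
    """One DNA template of the circuit.

    Parameters
    ----------
    name : str
        Unique identifier (e.g. ``"psT_LacI"``).
    role : str
        One of ``aT`` (autocatalytic), ``pT`` (pseudotemplate sink),
        ``rT`` (reporter), ``sT`` (unconditional source), ``psT``
        (protein-sensing source, signal output) or ``pskT``
        (protein-sensing killer, antisignal output).
    concentration : float
        Total template concentration in nM.
    output_polarity : str
        ``"signal"`` or ``"antisignal"``; derived from the role when not
        given (only pskT produces antisignal).
    operator : str or None
        Name of the transcription factor whose operator the template
        carries; required for psT/pskT, forbidden otherwise.
    """

    name: str
    role: str
    concentration: float
    output_polarity: str | None = None
    operator: str | None = None

    def __post_init__(self) -> None:
        if self.role not in TEMPLATE_ROLES:
            raise ValueError(f"template {self.name!r}: unknown role {self.role!r}")
        if self.concentration < 0:
            raise ValueError(f"template {self.name!r}: concentration must be >= 0")
        default_polarity = "antisignal" if self.role == "pskT" else "signal"
        if self.output_polarity is None:
            object.__setattr__(self, "output_polarity", default_polarity)
        elif self.output_polarity != default_polarity:
            raise ValueError(
                f"template {self.name!r}: role {self.role} implies "
                f"{default_polarity} output, got {self.output_polarity!r}"
            )
        if self.role in SENSING_ROLES and self.operator is None:
            raise ValueError(f"template {self.name!r}: {self.role} requires an operator TF")
        if self.role not in SENSING_ROLES and self.operator is not None:
            raise ValueError(f"template {self.name!r}: role {self.role} takes no operator")


@dataclass(frozen=True)
class TFSpec:
    """An allosteric DNA-binding transcription factor.

    ``mode="inducer"`` means the ligand releases the TF from its operator
    (LacI/IPTG): saturating ligand weakens operator binding by
    ``induction_fold``.  ``mode="corepressor"`` means the TF binds its
    operator only in the presence of ligand (TrpR/L-tryptophan).

    Units: ``dimer_concentration`` and ``operator_kd`` in nM;
    ``ligand_kd`` in uM.
    """

    name: str
    dimer_concentration: float
    operator_kd: float
    ligand_name: str
    ligand_kd: float
    mode: str
    ligand_hill: float = 1.0
    induction_fold: float = 1.0e4

    def __post_init__(self) -> None:
        if self.mode not in ("inducer", "corepressor"):
            raise ValueError(f"TF {self.name!r}: mode must be inducer or corepressor")
        if self.dimer_concentration < 0:
            raise ValueError(f"TF {self.name!r}: dimer_concentration must be >= 0")
        if self.operator_kd <= 0 or self.ligand_kd <= 0:
            raise ValueError(f"TF {self.name!r}: binding constants must be > 0")
        if self.ligand_hill < 1:
            raise ValueError(f"TF {self.name!r}: ligand_hill must be >= 1")
        if self.mode == "inducer" and self.induction_fold <= 1:
            raise ValueError(f"TF {self.name!r}: inducer requires induction_fold > 1")


@dataclass(frozen=True)
class EnzymeSpec:
    """A ligand-producing enzyme (tryptophan-synthase-like).

    Converts two substrates (canonically indole, uM, and L-serine, mM) to
    the named product ligand with two-substrate Michaelis-Menten kinetics.
    ``concentration`` in uM, ``kcat`` per minute, ``km_indole`` in uM,
    ``km_serine`` in mM.
    """

    name: str
    concentration: float
    kcat: float
    km_indole: float
    km_serine: float
    product: str
    substrate_indole: str = "indole"
    substrate_serine: str = "serine"
    disruption_threshold: float = DISRUPTION_THRESHOLD

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"enzyme {self.name!r}: concentration must be >= 0")
        if self.kcat <= 0 or self.km_indole <= 0 or self.km_serine <= 0:
            raise ValueError(f"enzyme {self.name!r}: kcat and Km values must be > 0")


@dataclass(frozen=True)
class RateParameters:
    """Effective kinetic constants of the PEN machinery.

    No rate constants are published for this system; the defaults are a
    single frozen calibration chosen so that (i) an unrepressed 5 nM psT
    circuit fires at Cq of roughly 60-120 min, (ii) the 7 nM pT sink
    capacity matches the source flux of ~7-8 pM of source template
    ("minimally saturating"), and (iii) the aT/pT pair is bistable in the
    initial signal concentration.

    All first-order constants are per minute; ``km_*`` in nM; ``k_hyb``
    per nM per minute.  ``k_amp``/``km_amp`` act on aT, ``k_deact`` /
    ``km_deact`` on pT, ``k_report``/``km_report`` on rT, ``k_source`` on
    free sT/psT/pskT, ``k_degr`` is the exonuclease degradation of free
    signal strands and ``k_hyb`` the signal-antisignal annihilation rate.
    """

    k_amp: float = 0.04
    km_amp: float = 20.0
    k_deact: float = 1.4e-5
    km_deact: float = 2.7e-4
    k_report: float = 0.1
    km_report: float = 50.0
    k_source: float = 0.004
    k_degr: float = 0.01
    k_hyb: float = 5.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"rate parameter {name} must be > 0")
        # the pT reaction must be faster than the aT one at trace signal
        # concentrations (it is the saturable sink that creates the threshold)
        if self.k_deact / self.km_deact <= self.k_amp / self.km_amp:
            raise ValueError(
                "deactivation flux must exceed amplification flux at trace "
                "concentrations: require k_deact/km_deact > k_amp/km_amp"
            )


@dataclass(frozen=True)
class CircuitSpec:
    """Full declarative description of one circuit assembly."""

    templates: tuple[TemplateSpec, ...]
    tfs: tuple[TFSpec, ...] = ()
    enzymes: tuple[EnzymeSpec, ...] = ()
    ligand_inputs: Mapping[str, float] = field(default_factory=dict)
    initial_signal: float = 0.0
    rates: RateParameters = field(default_factory=RateParameters)
    name: str = "circuit"
    temperature_note: str = "37C"

    def __post_init__(self) -> None:
        object.__setattr__(self, "templates", tuple(self.templates))
        object.__setattr__(self, "tfs", tuple(self.tfs))
        object.__setattr__(self, "enzymes", tuple(self.enzymes))
        object.__setattr__(self, "ligand_inputs", dict(self.ligand_inputs))
        names = [t.name for t in self.templates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate template names")
        roles = [t.role for t in self.templates]
        if roles.count("aT") != 1:
            raise ValueError("exactly one aT required")
        if roles.count("pT") > 1:
            raise ValueError("at most one pT allowed")
        if roles.count("rT") != 1:
            raise ValueError("exactly one rT required")
        tf_names = {tf.name for tf in self.tfs}
        if len(tf_names) != len(self.tfs):
            raise ValueError("duplicate TF names")
        for t in self.templates:
            if t.operator is not None and t.operator not in tf_names:
                raise ValueError(f"template {t.name!r} references undeclared TF {t.operator!r}")
        declared = set(self.ligand_inputs)
        for tf in self.tfs:
            if tf.ligand_name not in declared:
                raise ValueError(f"TF {tf.name!r} ligand {tf.ligand_name!r} not declared")
        for e in self.enzymes:
            for lig in (e.product, e.substrate_indole, e.substrate_serine):
                if lig not in declared:
                    raise ValueError(f"enzyme {e.name!r} ligand {lig!r} not declared")
        if self.initial_signal < 0:
            raise ValueError("initial_signal must be >= 0")
        for lig, conc in self.ligand_inputs.items():
            if conc < 0:
                raise ValueError(f"ligand {lig!r}: concentration must be >= 0")

    # convenience accessors -------------------------------------------------
    def template(self, role: str) -> TemplateSpec:
        for t in self.templates:
            if t.role == role:
                return t
        raise KeyError(role)

    def tf(self, name: str) -> TFSpec:
        for tf in self.tfs:
            if tf.name == name:
                return tf
        raise KeyError(name)

    def with_ligands(self, **ligands: float) -> "CircuitSpec":
        """Copy of the spec with some ligand input concentrations replaced."""
        unknown = set(ligands) - set(self.ligand_inputs)
        if unknown:
            raise KeyError(f"undeclared ligands: {sorted(unknown)}")
        merged = {**self.ligand_inputs, **ligands}
        return replace(self, ligand_inputs=merged)


# ---------------------------------------------------------------------------
# trace container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """Provenance of one trace: ligand inputs, replicate id and noise seed."""

    label: str
    ligands: Mapping[str, float] = field(default_factory=dict)
    replicate: int = 0
    seed: int | None = None


@dataclass
class TraceSet:
    """Minute-sampled reporter fluorescence for a set of conditions.

    ``traces`` has shape (n_conditions, n_time); ``full_scale`` is the
    instrument full scale (total rT for simulated data), used downstream
    to call flat traces.
    """

    time: np.ndarray
    traces: np.ndarray
    conditions: list[Condition]
    full_scale: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[0] != len(self.conditions):
            raise ValueError("one condition required per trace row")
        if self.traces.shape[1] != self.time.size:
            raise ValueError("trace length must match time grid")
        dt = np.diff(self.time)
        if self.time.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time grid must be uniform and strictly increasing")

    def __len__(self) -> int:
        return self.traces.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else float("nan")

    def concat(self, other: "TraceSet") -> "TraceSet":
        if not np.array_equal(self.time, other.time):
            raise ValueError("time grids differ")
        scale = self.full_scale if self.full_scale is not None else other.full_scale
        if self.full_scale is not None and other.full_scale is not None:
            scale = max(self.full_scale, other.full_scale)
        return TraceSet(
            time=self.time,
            traces=np.vstack([self.traces, other.traces]),
            conditions=self.conditions + other.conditions,
            full_scale=scale,
            warnings=self.warnings + other.warnings,
        )


# ---------------------------------------------------------------------------
# transcription-factor layer
# ---------------------------------------------------------------------------

def active_tf_fraction(tf: TFSpec, ligand_conc: float) -> float:
    """Fraction of operator-competent TF at a given ligand concentration.

    For a corepressor the ligand gates the active TF pool directly:
    ``L^h / (K^h + L^h)`` (zero without ligand).  For an inducer the TF is
    fully competent without ligand; ligand binding lowers competence down
    to a residual ``1/induction_fold`` at saturation, which downstream is
    applied as an effective-affinity scaling (operator Kd divided by this
    fraction).
    """
    if ligand_conc < 0:
        raise ValueError("ligand concentration must be >= 0")
    L = float(ligand_conc)
    K = tf.ligand_kd
    h = tf.ligand_hill
    occ = L**h / (K**h + L**h) if L > 0 else 0.0
    if tf.mode == "corepressor":
        return occ
    floor = 1.0 / tf.induction_fold
    return floor + (1.0 - floor) * (1.0 - occ)


def template_occupancy(tf_total: float, template_total: float, kd_eff: float) -> float:
    """TF-bound template (nM) from the exact two-species binding quadratic.

    Solves ``free_tf * free_template = kd_eff * bound`` with mass
    conservation, using the numerically stable root form.
    """
    if tf_total < 0 or template_total < 0:
        raise ValueError("concentrations must be >= 0")
    if kd_eff <= 0:
        raise ValueError("kd_eff must be > 0")
    if tf_total == 0 or template_total == 0:
        return 0.0
    b = tf_total + template_total + kd_eff
    disc = b * b - 4.0 * tf_total * template_total
    return 2.0 * tf_total * template_total / (b + math.sqrt(max(disc, 0.0)))


def _occluded_fraction(tf: TFSpec, template_total: float, ligand_conc: float) -> float:
    """Fraction of a sensing template occluded by its TF at quasi-equilibrium."""
    if template_total <= 0:
        return 0.0
    frac = active_tf_fraction(tf, ligand_conc)
    if tf.mode == "corepressor":
        active = tf.dimer_concentration * frac
        kd_eff = tf.operator_kd
    else:
        active = tf.dimer_concentration
        if frac <= 0:
            return 0.0
        kd_eff = tf.operator_kd / frac
    bound = template_occupancy(active, template_total, kd_eff)
    return bound / template_total


# ---------------------------------------------------------------------------
# enzyme layer
# ---------------------------------------------------------------------------

def enzyme_rate(enzyme: EnzymeSpec, indole: float, serine: float) -> float:
    """Two-substrate Michaelis-Menten product flux in uM/min.

    ``indole`` in uM, ``serine`` in mM.  Saturating both substrates gives
    the limiting rate ``kcat * E``.
    """
    if indole < 0 or serine < 0:
        raise ValueError("substrate concentrations must be >= 0")
    return (
        enzyme.kcat
        * enzyme.concentration
        * (indole / (enzyme.km_indole + indole))
        * (serine / (enzyme.km_serine + serine))
    )


# ---------------------------------------------------------------------------
# reaction network assembly and integration
# ---------------------------------------------------------------------------

class ReactionNetwork:
    """Right-hand-side function over the circuit state vector.

    State layout: ``[signal, antisignal, deactivated, rT_unreported,
    rT_reported, <ligand pools in declaration order>]``.  DNA species in
    nM; ligand pools in uM except the serine pool, which is carried in mM
    to match its Km convention.
    """

    def __init__(self, spec: CircuitSpec):
        self.spec = spec
        self.rates = spec.rates
        self.species = {"signal": 0, "antisignal": 1, "deactivated": 2,
                        "rt_dark": 3, "rt_lit": 4}
        self.ligand_names = list(spec.ligand_inputs)
        for i, lig in enumerate(self.ligand_names):
            self.species[lig] = 5 + i
        self.n_species = 5 + len(self.ligand_names)
        self.observable_index = self.species["rt_lit"]

        self.aT = spec.template("aT").concentration
        self.pT = sum(t.concentration for t in spec.templates if t.role == "pT")
        self.rT = spec.template("rT").concentration
        self._signal_sources = [
            t for t in spec.templates
            if t.role in ("sT", "psT", "pskT") and t.output_polarity == "signal"
        ]
        self._anti_sources = [
            t for t in spec.templates
            if t.role in ("sT", "psT", "pskT") and t.output_polarity == "antisignal"
        ]
        self._tf_by_name = {tf.name: tf for tf in spec.tfs}
        self.warnings: list[str] = []
        for e in spec.enzymes:
            if e.concentration > e.disruption_threshold:
                self.warnings.append(
                    f"enzyme {e.name}: concentration {e.concentration} uM exceeds "
                    f"{e.disruption_threshold} uM (non-specific disruption regime)"
                )

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_species)
        y0[self.species["signal"]] = self.spec.initial_signal
        y0[self.species["rt_dark"]] = self.rT
        for lig, conc in self.spec.ligand_inputs.items():
            y0[self.species[lig]] = conc
        return y0

    def _source_flux(self, templates: Sequence[TemplateSpec], y: np.ndarray) -> float:
        flux = 0.0
        for t in templates:
            free = t.concentration
            if t.operator is not None:
                tf = self._tf_by_name[t.operator]
                lig = max(float(y[self.species[tf.ligand_name]]), 0.0)
                free *= 1.0 - _occluded_fraction(tf, t.concentration, lig)
            flux += self.rates.k_source * free
        return flux

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        r = self.rates
        s = max(float(y[0]), 0.0)
        a = max(float(y[1]), 0.0)
        rt_dark = max(float(y[3]), 0.0)

        amp = r.k_amp * self.aT * s / (r.km_amp + s)
        deact = r.k_deact * self.pT * s / (r.km_deact + s)
        report = r.k_report * rt_dark * s / (r.km_report + s)
        hyb = r.k_hyb * s * a

        dy = np.zeros_like(y)
        dy[0] = (self._source_flux(self._signal_sources, y) + amp
                 - deact - report - r.k_degr * s - hyb)
        dy[1] = self._source_flux(self._anti_sources, y) - r.k_degr * a - hyb
        dy[2] = deact - r.k_degr * max(float(y[2]), 0.0)
        dy[3] = -report
        dy[4] = report

        for e in self.spec.enzymes:
            ind = max(float(y[self.species[e.substrate_indole]]), 0.0)
            ser = max(float(y[self.species[e.substrate_serine]]), 0.0)
            v = enzyme_rate(e, ind, ser)  # uM/min
            dy[self.species[e.product]] += v
            dy[self.species[e.substrate_indole]] -= v
            dy[self.species[e.substrate_serine]] -= v * 1e-3  # serine pool in mM
        return dy


def build_network(spec: CircuitSpec) -> ReactionNetwork:
    """Assemble the mass-action/quasi-equilibrium rate-function object."""
    return ReactionNetwork(spec)


def integrate(
    spec: CircuitSpec,
    duration: float,
    dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, ReactionNetwork]:
    """Integrate the full state on a uniform output grid.

    Returns ``(time, states, network)`` with ``states`` of shape
    (n_species, n_time).  Mainly for diagnostics and tests; `simulate`
    wraps this and keeps only the reporter observable.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    net = build_network(spec)
    t_eval = np.arange(0.0, duration + dt / 2, dt)
    sol = solve_ivp(
        net.rhs,
        (0.0, float(t_eval[-1])),
        net.initial_state(),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for circuit {spec.name!r} "
            f"(ligands {dict(spec.ligand_inputs)}): {sol.message}"
        )
    return sol.t, sol.y, net


def _condition_label(spec: CircuitSpec, replicate: int) -> str:
    ligs = "_".join(f"{k}={v:g}" for k, v in spec.ligand_inputs.items())
    base = spec.name if not ligs else f"{spec.name}_{ligs}"
    return f"{base}_r{replicate}" if replicate else base


def simulate(
    spec: CircuitSpec,
    duration: float = 600.0,
    seed: int | None = None,
    dt: float = 1.0,
    label: str | None = None,
) -> TraceSet:
    """Noise-free reporter trace for one circuit condition.

    The trace is the reported-rT concentration on a 1-min grid; it is
    non-decreasing because the unquenching reaction is irreversible.
    Measurement noise is added separately by `add_noise` (the seed is
    recorded in the condition metadata for that purpose).
    """
    t, y, net = integrate(spec, duration, dt=dt)
    trace = y[net.observable_index]
    cond = Condition(
        label=label or _condition_label(spec, 0),
        ligands=dict(spec.ligand_inputs),
        replicate=0,
        seed=seed,
    )
    return TraceSet(
        time=t,
        traces=trace[np.newaxis, :],
        conditions=[cond],
        full_scale=net.rT,
        warnings=list(net.warnings),
    )


def simulate_many(
    spec: CircuitSpec,
    ligand_sets: Sequence[Mapping[str, float]],
    duration: float = 600.0,
    dt: float = 1.0,
) -> TraceSet:
    """Simulate one trace per ligand-input mapping and stack them."""
    out: TraceSet | None = None
    for ligands in ligand_sets:
        ts = simulate(spec.with_ligands(**ligands), duration=duration, dt=dt)
        out = ts if out is None else out.concat(ts)
    if out is None:
        raise ValueError("no conditions given")
    return out


# ---------------------------------------------------------------------------
# measurement noise and synthetic traces
# ---------------------------------------------------------------------------

def add_noise(
    traces: TraceSet,
    sigma_rel: float = 0.02,
    drift: float = 0.0,
    seed: int | None = None,
) -> TraceSet:
    """Multiplicative Gaussian noise plus linear baseline drift.

    ``sigma_rel`` is the relative noise amplitude per point; ``drift`` in
    a.u./min.  Reproducible for a given seed; the noise-free traces are
    recovered at ``sigma_rel = drift = 0``.
    """
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = traces.traces.copy()
    if sigma_rel > 0:
        eps = rng.standard_normal(noisy.shape)
        noisy = noisy * (1.0 + sigma_rel * eps)
    if drift != 0.0:
        noisy = noisy + drift * traces.time[np.newaxis, :]
    conds = [replace(c, seed=seed) for c in traces.conditions]
    return TraceSet(
        time=traces.time.copy(),
        traces=noisy,
        conditions=conds,
        full_scale=traces.full_scale,
        warnings=list(traces.warnings),
    )


def synthetic_switch_trace(
    switch_time: float,
    duration: float = 600.0,
    dt: float = 1.0,
    amplitude: float = 10.0,
    steepness: float = 5.0,
    window: float = 10.0,
) -> np.ndarray:
    """Idealized sigmoidal switch-activation trace with a prescribed Cq.

    A logistic centered at ``switch_time + window/2`` so that the start of
    the steepest ``window``-minute rise (the Cq statistic) falls at
    ``switch_time``.  Used for estimator calibration independently of the
    mechanistic simulator.
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    center = switch_time + window / 2.0
    return amplitude / (1.0 + np.exp(-(t - center) / steepness))


# ---------------------------------------------------------------------------
# bistability diagnostics
# ---------------------------------------------------------------------------

def _fires(spec: CircuitSpec, s0: float, duration: float) -> bool:
    t, y, net = integrate(replace(spec, initial_signal=s0), duration)
    return y[net.observable_index, -1] > 0.5 * net.rT


def switch_threshold(
    spec: CircuitSpec,
    lo: float = 1e-6,
    hi: float = 10.0,
    duration: float = 600.0,
    xtol_rel: float = 0.02,
) -> float:
    """Bistability threshold in initial signal concentration (nM).

    Bisection (in log concentration) on the long-time switch outcome.
    Raises if the outcome is not bracketed, i.e. the circuit is not
    bistable over ``[lo, hi]``.
    """
    if _fires(spec, lo, duration):
        raise ValueError(f"circuit fires already at initial signal {lo} nM")
    if not _fires(spec, hi, duration):
        raise ValueError(f"circuit does not fire at initial signal {hi} nM")
    f = lambda x: 1.0 if _fires(spec, 10.0**x, duration) else -1.0
    a, b = math.log10(lo), math.log10(hi)
    while b - a > math.log10(1.0 + xtol_rel):
        m = 0.5 * (a + b)
        if f(m) > 0:
            b = m
        else:
            a = m
    return 10.0 ** (0.5 * (a + b))
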