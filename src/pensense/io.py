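"""Configuration parsing, trace/Cq CSV round-trips, run manifests and the
end-to-end pipeline.

Circuit configs are single-document YAML files mirroring `CircuitSpec`
(strict parsing: unknown keys are rejected, errors name the offending
field).  Units follow the global convention: templates/TFs in nM, ligands
in uM -- except a ligand named ``serine``, carried in mM to match the
enzyme Km convention.  Trace tables are CSV with a ``time_min`` column
and one column per condition, plus a JSON sidecar holding conditions,
seeds and the instrument full scale, so a TraceSet survives a disk
round-trip intact.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import (
    CircuitSpec,
    Condition,
    EnzymeSpec,
    RateParameters,
    TFSpec,
    TemplateSpec,
    TraceSet,
    add_noise,
    simulate,
)
from .dose import HillFit, assemble, fit_hill
from .maps import GridResult, LogSumFit, fit_logsum, simulate_grid
from .traces import CqResult, batch_cq

__all__ = [
    "load_config",
    "loads_config",
    "save_config",
    "spec_to_dict",
    "bundled_config",
    "bundled_config_names",
    "write_traces",
    "read_traces",
    "write_cq_table",
    "read_cq_table",
    "RunManifest",
    "run_dose_pipeline",
    "run_grid_pipeline",
]

log = logging.getLogger("pensense")

_TEMPLATE_KEYS = {"name", "role", "concentration", "output_polarity", "operator"}
_TF_KEYS = {
    "name", "dimer_concentration", "operator_kd", "ligand", "ligand_kd",
    "ligand_hill", "mode", "induction_fold",
}
_ENZYME_KEYS = {
    "name", "concentration", "kcat", "km_indole", "km_serine", "product",
    "substrate_indole", "substrate_serine", "disruption_threshold",
}
_TOP_KEYS = {
    "name", "templates", "tfs", "enzymes", "ligands", "initial_signal",
    "rates", "temperature_note",
}
_RATE_KEYS = set(RateParameters.__dataclass_fields__)


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")


_STRING_FIELDS = {
    "name", "role", "operator", "output_polarity", "ligand", "mode",
    "product", "substrate_indole", "substrate_serine",
}


def _coerce_numbers(item: Mapping[str, Any], where: str) -> dict[str, Any]:
    # YAML 1.1 reads "1.0e4" (no signed exponent) as a string; be lenient
    out: dict[str, Any] = {}
    for key, val in item.items():
        if key in _STRING_FIELDS or not isinstance(val, str):
            out[key] = val
        else:
            try:
                out[key] = float(val)
            except ValueError:
                raise ValueError(f"{where}: field {key!r} must be numeric, got {val!r}") from None
    return out


def _build_spec(doc: Mapping[str, Any], where: str) -> CircuitSpec:
    if not isinstance(doc, Mapping):
        raise ValueError(f"{where}: config must be a mapping")
    _check_keys(doc, _TOP_KEYS, where)
    if "templates" not in doc:
        raise ValueError(f"{where}: 'templates' section required")

    templates = []
    for i, item in enumerate(doc["templates"]):
        ctx = f"{where}: templates[{i}]"
        _check_keys(item, _TEMPLATE_KEYS, ctx)
        item = _coerce_numbers(item, ctx)
        try:
            templates.append(TemplateSpec(**item))
        except (TypeError, ValueError) as err:
            raise ValueError(f"{ctx}: {err}") from err

    tfs = []
    for i, item in enumerate(doc.get("tfs") or []):
        ctx = f"{where}: tfs[{i}]"
        _check_keys(item, _TF_KEYS, ctx)
        item = _coerce_numbers(item, ctx)
        if "ligand" in item:
            item["ligand_name"] = item.pop("ligand")
        try:
            tfs.append(TFSpec(**item))
        except (TypeError, ValueError) as err:
            raise ValueError(f"{ctx}: {err}") from err

    enzymes = []
    for i, item in enumerate(doc.get("enzymes") or []):
        ctx = f"{where}: enzymes[{i}]"
        _check_keys(item, _ENZYME_KEYS, ctx)
        item = _coerce_numbers(item, ctx)
        try:
            enzymes.append(EnzymeSpec(**item))
        except (TypeError, ValueError) as err:
            raise ValueError(f"{ctx}: {err}") from err

    rates_doc = doc.get("rates") or {}
    _check_keys(rates_doc, _RATE_KEYS, f"{where}: rates")
    rates = RateParameters(**{k: float(v) for k, v in rates_doc.items()})

    try:
        return CircuitSpec(
            templates=tuple(templates),
            tfs=tuple(tfs),
            enzymes=tuple(enzymes),
            ligand_inputs={str(k): float(v) for k, v in (doc.get("ligands") or {}).items()},
            initial_signal=float(doc.get("initial_signal", 0.0)),
            rates=rates,
            name=str(doc.get("name", "circuit")),
            temperature_note=str(doc.get("temperature_note", "37C")),
        )
    except ValueError as err:
        raise ValueError(f"{where}: {err}") from err


def loads_config(text: str, where: str = "<config>") -> CircuitSpec:
    return _build_spec(yaml.safe_load(text), where)


def load_config(path: "str | Path") -> CircuitSpec:
    """Load and fully validate a circuit config file."""
    path = Path(path)
    return loads_config(path.read_text(), where=str(path))


def spec_to_dict(spec: CircuitSpec) -> dict[str, Any]:
    """Serializable mapping mirroring the config schema (round-trips)."""
    doc: dict[str, Any] = {"name": spec.name}
    doc["templates"] = []
    for t in spec.templates:
        item = {"name": t.name, "role": t.role, "concentration": t.concentration}
        if t.operator is not None:
            item["operator"] = t.operator
        doc["templates"].append(item)
    if spec.tfs:
        doc["tfs"] = []
        for tf in spec.tfs:
            item = {
                "name": tf.name,
                "dimer_concentration": tf.dimer_concentration,
                "operator_kd": tf.operator_kd,
                "ligand": tf.ligand_name,
                "ligand_kd": tf.ligand_kd,
                "ligand_hill": tf.ligand_hill,
                "mode": tf.mode,
            }
            if tf.mode == "inducer":
                item["induction_fold"] = tf.induction_fold
            doc["tfs"].append(item)
    if spec.enzymes:
        doc["enzymes"] = [dataclasses.asdict(e) for e in spec.enzymes]
    if spec.ligand_inputs:
        doc["ligands"] = dict(spec.ligand_inputs)
    if spec.initial_signal:
        doc["initial_signal"] = spec.initial_signal
    defaults = RateParameters()
    overrides = {
        k: getattr(spec.rates, k)
        for k in _RATE_KEYS
        if getattr(spec.rates, k) != getattr(defaults, k)
    }
    if overrides:
        doc["rates"] = overrides
    if spec.temperature_note != "37C":
        doc["temperature_note"] = spec.temperature_note
    return doc


def save_config(spec: CircuitSpec, path: "str | Path") -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def bundled_config_names() -> list[str]:
    """Names of the shipped circuit fixtures (without extension)."""
    pkg = resources.files("pensense.configs")
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def bundled_config(name: str) -> CircuitSpec:
    """Load one of the shipped circuit fixtures (e.g. ``"fig1f"``)."""
    res = resources.files("pensense.configs") / f"{name}.yaml"
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no bundled config {name!r}; available: {bundled_config_names()}"
        ) from None
    return loads_config(text, where=f"pensense.configs/{name}.yaml")


# ---------------------------------------------------------------------------
# trace / Cq tables
# ---------------------------------------------------------------------------

def write_traces(ts: TraceSet, path: "str | Path") -> Path:
    """Write a TraceSet as CSV plus a JSON metadata sidecar.

    Returns the sidecar path.  Column order matches the condition order;
    labels must therefore be unique.
    """
    path = Path(path)
    labels = [c.label for c in ts.conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique to serialize a TraceSet")
    df = pd.DataFrame({"time_min": ts.time})
    for lab, row in zip(labels, ts.traces):
        df[lab] = row
    # 17 significant digits: float64 survives the text round-trip exactly
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(".meta.json")
    meta = {
        "conditions": [dataclasses.asdict(c) for c in ts.conditions],
        "full_scale": ts.full_scale,
        "warnings": ts.warnings,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_traces(path: "str | Path") -> TraceSet:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_min" not in df.columns:
        raise ValueError(f"{path}: missing 'time_min' column")
    labels = [c for c in df.columns if c != "time_min"]
    sidecar = path.with_suffix(".meta.json")
    full_scale = None
    warnings: list[str] = []
    conditions = [Condition(label=lab) for lab in labels]
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        full_scale = meta.get("full_scale")
        warnings = list(meta.get("warnings", []))
        conditions = [Condition(**c) for c in meta.get("conditions", [])]
        if [c.label for c in conditions] != labels:
            raise ValueError(f"{path}: sidecar conditions do not match CSV columns")
    return TraceSet(
        time=df["time_min"].to_numpy(),
        traces=df[labels].to_numpy().T,
        conditions=conditions,
        full_scale=full_scale,
        warnings=warnings,
    )


def write_cq_table(
    results: Sequence[CqResult],
    path: "str | Path",
    extra: "Mapping[str, Sequence[Any]] | None" = None,
) -> None:
    """CSV with columns label, cq_min, inv_cq, flat (+ optional extras)."""
    df = pd.DataFrame(
        {
            "label": [r.label for r in results],
            "cq_min": [r.cq for r in results],
            "inv_cq": [r.inv_cq for r in results],
            "flat": [r.flat for r in results],
        }
    )
    for col, vals in (extra or {}).items():
        df[col] = list(vals)
    df.to_csv(path, index=False)


def read_cq_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# manifests and pipelines
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    config_path: str
    config_sha256: str
    seed: "int | None"
    stage_params: dict[str, Any]
    package_version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _config_hash(spec: CircuitSpec) -> str:
    blob = json.dumps(spec_to_dict(spec), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _fit_to_dict(fit: HillFit) -> dict[str, Any]:
    return dataclasses.asdict(fit)


def run_dose_pipeline(
    spec: CircuitSpec,
    ligand: str,
    concentrations: Sequence[float],
    out_dir: "str | Path",
    seed: int = 0,
    n_replicates: int = 3,
    sigma_rel: float = 0.02,
    duration: float = 600.0,
    direction: str = "auto",
    config_path: str = "<in-memory>",
) -> "HillFit | None":
    """simulate -> Cq -> dose-response -> Hill fit, with files on disk.

    Writes ``traces.csv`` (+ sidecar), ``cq.csv``, ``fit.json`` and
    ``manifest.json`` into ``out_dir``.  Replicate noise seeds are spawned
    deterministically from ``seed``, so re-running reproduces byte-identical
    outputs.  Returns the Hill fit (None when the curve is degenerate and
    the circuit showed no response, e.g. an uncoupled ligand).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ligand not in spec.ligand_inputs:
        raise KeyError(f"ligand {ligand!r} is not declared in circuit {spec.name!r}")

    concentrations = [float(c) for c in sorted(concentrations)]
    seeds = np.random.SeedSequence(seed).generate_state(len(concentrations) * n_replicates)
    all_ts: TraceSet | None = None
    rows: list[tuple[float, int]] = []
    k = 0
    for c in concentrations:
        cond_spec = spec.with_ligands(**{ligand: c})
        base = simulate(cond_spec, duration=duration)
        log.info("simulated %s %s=%g uM", spec.name, ligand, c)
        for rep in range(n_replicates):
            rep_seed = int(seeds[k] % (2**31))
            k += 1
            noisy = add_noise(base, sigma_rel=sigma_rel, seed=rep_seed)
            noisy.conditions = [
                dataclasses.replace(
                    noisy.conditions[0],
                    label=f"{ligand}={c:g}_r{rep}",
                    replicate=rep,
                    seed=rep_seed,
                )
            ]
            all_ts = noisy if all_ts is None else all_ts.concat(noisy)
            rows.append((c, rep))
    assert all_ts is not None

    write_traces(all_ts, out_dir / "traces.csv")
    results = batch_cq(all_ts)
    write_cq_table(
        results,
        out_dir / "cq.csv",
        extra={
            "ligand": [ligand] * len(rows),
            "concentration": [c for c, _ in rows],
            "replicate": [r for _, r in rows],
        },
    )

    groups: dict[float, list[CqResult]] = {}
    for (c, _), res in zip(rows, results):
        groups.setdefault(c, []).append(res)
    curve = assemble(ligand, groups)

    manifest = RunManifest(
        config_path=str(config_path),
        config_sha256=_config_hash(spec),
        seed=seed,
        stage_params={
            "ligand": ligand,
            "concentrations": concentrations,
            "n_replicates": n_replicates,
            "sigma_rel": sigma_rel,
            "duration": duration,
            "direction": direction,
            "flat_rule": "range<5% full scale or max 10-min diff<0.05",
        },
        timestamp="1970-01-01T00:00:00+00:00",  # fixed for byte-identical reruns
    )
    manifest.write(out_dir / "manifest.json")

    try:
        fit = fit_hill(curve, direction=direction)
    except ValueError as err:
        if "no response" in str(err) or "ambiguous" in str(err):
            (out_dir / "fit.json").write_text(
                json.dumps({"error": str(err), "ligand": ligand}, indent=2)
            )
            log.warning("dose pipeline %s: %s", spec.name, err)
            return None
        raise
    doc = _fit_to_dict(fit)
    doc["curve"] = {
        "ligand": ligand,
        "concentrations": list(curve.concentrations),
        "inv_cq_mean": list(curve.inv_cq_mean),
        "inv_cq_err": list(curve.inv_cq_err),
        "n_replicates": curve.n_replicates,
    }
    (out_dir / "fit.json").write_text(json.dumps(doc, indent=2))
    return fit


def run_grid_pipeline(
    spec: CircuitSpec,
    ligand_x: str,
    x_concs: Sequence[float],
    ligand_y: str,
    y_concs: Sequence[float],
    out_dir: "str | Path",
    seed: int = 0,
    duration: float = 600.0,
    config_path: str = "<in-memory>",
) -> tuple[GridResult, LogSumFit]:
    """simulate_grid -> weighted log-sum fit, with grid.csv + weights.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = simulate_grid(
        spec, ligand_x, np.asarray(x_concs), ligand_y, np.asarray(y_concs),
        duration=duration,
    )
    df = pd.DataFrame(
        grid.inv_cq,
        index=pd.Index(grid.y_concs, name=f"{ligand_y}_uM"),
        columns=[f"{c:g}" for c in grid.x_concs],
    )
    df.to_csv(out_dir / "grid.csv")
    weights = fit_logsum(grid)
    doc = dataclasses.asdict(weights)
    doc["logic"] = list(grid.logic)
    doc["ligand_x"] = ligand_x
    doc["ligand_y"] = ligand_y
    (out_dir / "weights.json").write_text(json.dumps(doc, indent=2))
    manifest = RunManifest(
        config_path=str(config_path),
        config_sha256=_config_hash(spec),
        seed=seed,
        stage_params={
            "ligand_x": ligand_x, "x_concs": [float(c) for c in x_concs],
            "ligand_y": ligand_y, "y_concs": [float(c) for c in y_concs],
            "duration": duration,
        },
        timestamp="1970-01-01T00:00:00+00:00",
    )
    manifest.write(out_dir / "manifest.json")
    return grid, weights
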