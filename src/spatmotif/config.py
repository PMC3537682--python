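"""Run configuration parsing/serialization and tabular/JSON writers.

A run config is a flat INI-style text with blocks [domain], [signal],
[model], [solver], [output]. Unknown keys are rejected against a schema built
from the motif registry; parse -> serialize -> parse is the identity on the
resolved configuration.
"""

from __future__ import annotations

import configparser
import io
import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import ConfigurationError
from .motifs import MOTIF_REGISTRY, MotifModel, build_motif
from .signals import FORMS, SignalProfile
from .simulate import SimulationResult, SolverSettings

SCHEMA_VERSION = "1"

_DOMAIN_KEYS = {"n_points", "length"}
_SIGNAL_KEYS = {"form", "a", "b", "amp", "theta0", "alpha", "theta1", "theta2", "table"}
_SOLVER_KEYS = {
    "rel_tol", "abs_tol", "t_max", "steady_tol", "stiff", "detect_steady",
    "transient_fraction", "grid_check", "n_samples",
}
_OUTPUT_KEYS = {"out_dir", "write_trajectory"}
_MODEL_META_KEYS = {"motif"}


@dataclass
class RunConfig:
    """Parsed and validated run configuration."""

    domain: Dict[str, float]
    signal: Dict[str, object]
    model: Dict[str, object]
    solver: Dict[str, object] = field(default_factory=dict)
    output: Dict[str, object] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def build_signal_profile(self) -> SignalProfile:
        s = dict(self.signal)
        form = s.pop("form")
        kwargs = {}
        for key, attr in (("a", "a"), ("b", "b"), ("amp", "A"), ("theta0", "theta0"),
                          ("alpha", "alpha"), ("theta1", "theta1"), ("theta2", "theta2")):
            if key in s:
                kwargs[attr] = float(s[key])
        return SignalProfile(form=form, **kwargs)

    def build_model(self) -> MotifModel:
        m = dict(self.model)
        motif_id = m.pop("motif")
        params = {k[len("param_"):]: float(v) for k, v in m.items() if k.startswith("param_")}
        totals = {k[len("total_"):]: float(v) for k, v in m.items() if k.startswith("total_")}
        diff = {k[len("diff_"):]: float(v) for k, v in m.items() if k.startswith("diff_")}
        return build_motif(motif_id, params, diff, totals)

    def build_settings(self) -> SolverSettings:
        s = dict(self.solver)
        kwargs = {}
        for key in ("rel_tol", "abs_tol", "t_max", "steady_tol", "transient_fraction"):
            if key in s:
                kwargs[key] = float(s[key])
        for key in ("stiff", "detect_steady", "grid_check"):
            if key in s:
                kwargs[key] = _parse_bool(s[key])
        if "n_samples" in s:
            t_max = kwargs.get("t_max", SolverSettings().t_max)
            kwargs["sample_times"] = np.linspace(0.0, t_max, int(s["n_samples"]))
        return SolverSettings(**kwargs)


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "on"):
        return True
    if s in ("false", "0", "no", "off"):
        return False
    raise ConfigurationError(f"cannot parse boolean value {v!r}")


def _validate_keys(block: str, keys, allowed, dynamic_prefixes=()):
    for k in keys:
        if k in allowed:
            continue
        if any(k.startswith(p) for p in dynamic_prefixes):
            continue
        raise ConfigurationError(f"unknown key {block}.{k!r}")


def parse_config(text: str) -> RunConfig:
    """Parse an INI-style run config, rejecting unknown blocks and keys."""
    cp = configparser.ConfigParser()
    cp.optionxform = str  # preserve case (K_M1 etc.)
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigurationError(f"malformed config: {exc}") from exc

    known_blocks = {"meta", "domain", "signal", "model", "solver", "output"}
    for sec in cp.sections():
        if sec not in known_blocks:
            raise ConfigurationError(f"unknown config block [{sec}]")
    for required in ("domain", "signal", "model"):
        if required not in cp:
            raise ConfigurationError(f"missing config block [{required}]")

    domain = {k: float(v) for k, v in cp["domain"].items()}
    _validate_keys("domain", domain, _DOMAIN_KEYS)

    signal = dict(cp["signal"].items())
    _validate_keys("signal", signal, _SIGNAL_KEYS)
    if "form" not in signal:
        raise ConfigurationError("signal.form is required")
    if signal["form"] not in FORMS:
        raise ConfigurationError(f"unknown signal form {signal['form']!r}")

    model = dict(cp["model"].items())
    if "motif" not in model:
        raise ConfigurationError("model.motif is required")
    motif_id = model["motif"]
    if motif_id not in MOTIF_REGISTRY:
        raise ConfigurationError(f"unknown motif {motif_id!r}")
    spec = MOTIF_REGISTRY[motif_id]
    if motif_id != "cyclic":
        for k in model:
            if k.startswith("param_") and k[len("param_"):] not in spec.required_params:
                raise ConfigurationError(
                    f"unknown parameter {k[len('param_'):]!r} for motif {motif_id}"
                )
    _validate_keys("model", model, _MODEL_META_KEYS,
                   dynamic_prefixes=("param_", "total_", "diff_"))

    solver = dict(cp["solver"].items()) if "solver" in cp else {}
    _validate_keys("solver", solver, _SOLVER_KEYS)
    output = dict(cp["output"].items()) if "output" in cp else {}
    _validate_keys("output", output, _OUTPUT_KEYS)

    version = cp["meta"].get("schema_version", SCHEMA_VERSION) if "meta" in cp else SCHEMA_VERSION
    return RunConfig(domain=domain, signal=signal, model=model,
                     solver=solver, output=output, schema_version=version)


def serialize_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to INI text (round-trip stable)."""
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp["meta"] = {"schema_version": cfg.schema_version}
    cp["domain"] = {k: _fmt(v) for k, v in cfg.domain.items()}
    cp["signal"] = {k: _fmt(v) for k, v in cfg.signal.items()}
    cp["model"] = {k: _fmt(v) for k, v in cfg.model.items()}
    if cfg.solver:
        cp["solver"] = {k: _fmt(v) for k, v in cfg.solver.items()}
    if cfg.output:
        cp["output"] = {k: _fmt(v) for k, v in cfg.output.items()}
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def _fmt(v) -> str:
    if isinstance(v, float):
        return format(v, ".12g")
    return str(v)


def write_profiles(result: SimulationResult, path) -> None:
    """Final per-node profiles: theta then species columns, 12 significant digits."""
    cols = ["theta"] + list(result.model.species)
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for i in range(result.domain.n_points):
            row = [result.domain.theta[i]] + [result.state[j, i]
                                              for j in range(result.model.n_species)]
            fh.write(",".join(format(v, ".12g") for v in row) + "\n")


def write_trajectory(result: SimulationResult, path) -> None:
    """Long-format trajectory CSV: time, theta, species, value."""
    with open(path, "w") as fh:
        fh.write("time,theta,species,value\n")
        for it, t in enumerate(result.times):
            for j, sp in enumerate(result.model.species):
                for i in range(result.domain.n_points):
                    fh.write(
                        f"{format(t, '.12g')},{format(result.domain.theta[i], '.12g')},"
                        f"{sp},{format(result.trajectory[it, j, i], '.12g')}\n"
                    )


def write_report(report: dict, path) -> None:
    """JSON report writer (sorted keys for reproducibility)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def meta_dict(result: SimulationResult, cfg: Optional[RunConfig] = None) -> dict:
    """Run metadata echo: residual, drift, grid audit, versions."""
    from . import __version__

    meta = {
        "spatmotif_version": __version__,
        "converged": bool(result.converged),
        "residual": float(result.residual),
        "conservation_drift": {k: float(v) for k, v in result.conservation_drift.items()},
        "grid_check": None if result.grid_check is None else float(result.grid_check),
        "unresolved": bool(result.unresolved),
    }
    if cfg is not None:
        meta["config"] = {
            "schema_version": cfg.schema_version,
            "domain": cfg.domain, "signal": cfg.signal, "model": cfg.model,
            "solver": cfg.solver, "output": cfg.output,
        }
    return meta
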