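"""Run configuration: one YAML file holding every scalar model parameter.

The configuration round-trips losslessly (load -> save -> load gives an
identical document) and unknown keys are rejected so that typos fail loudly
instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .birth_death import BirthDeathParams, derive_lambda
from .model import CRMModelSpec, IndelParams
from .profiles import BindingProfile, read_jaspar_pfm
from .substitution import RateMatrix, build_gtr

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


_MODEL_KEYS = {
    "profiles", "pseudocount", "delta", "lambda", "mu", "alpha", "beta",
    "epsilon", "c_indel", "c_branch", "strand_factor", "factor_frequencies",
    "background",
}
_RUN_KEYS = {"seed", "hirschberg_cell_budget", "log_level"}
_TOP_KEYS = {"model", "run"}


@dataclass
class RunConfig:
    spec: CRMModelSpec
    background: RateMatrix
    delta: float | None
    pseudocount: float = 0.1
    c_indel: float = 1.0
    c_branch: float = 1.0
    seed: int = 0
    hirschberg_cell_budget: float = 5e7
    log_level: str = "INFO"
    profile_sources: list = field(default_factory=list)


def _check_keys(mapping, allowed, context):
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")


def load_config(path, base_dir=None) -> RunConfig:
    path = Path(path)
    base = Path(base_dir) if base_dir else path.parent
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(doc, _TOP_KEYS, "top-level")
    model = doc.get("model", {})
    run = doc.get("run", {})
    _check_keys(model, _MODEL_KEYS, "model")
    _check_keys(run, _RUN_KEYS, "run")

    pseudocount = float(model.get("pseudocount", 0.1))
    profiles = []
    sources = []
    for item in model.get("profiles", []):
        if isinstance(item, str):
            item = {"path": item}
        if "path" in item:
            p = read_jaspar_pfm(base / item["path"], pseudocount,
                                factor_name=item.get("name"))
            sources.append(str(item["path"]))
        elif "counts" in item:
            counts = np.asarray(item["counts"], dtype=float).T
            probs = counts + pseudocount
            probs /= probs.sum(axis=1, keepdims=True)
            p = BindingProfile(item.get("name", f"tf{len(profiles)}"), probs)
            sources.append("inline")
        elif "probabilities" in item:
            probs = np.asarray(item["probabilities"], dtype=float).T
            p = BindingProfile(item.get("name", f"tf{len(profiles)}"), probs)
            sources.append("inline")
        else:
            raise ConfigError(
                "profile entries need 'path', 'counts' or 'probabilities'"
            )
        profiles.append(p)

    mu = float(model.get("mu", 0.08))
    delta = model.get("delta")
    if "lambda" in model and delta is not None:
        raise ConfigError("give either 'lambda' or 'delta', not both")
    if "lambda" in model:
        lam = float(model["lambda"])
    else:
        lam = derive_lambda(float(delta), mu) if delta is not None else 0.0

    bg_cfg = model.get("background", {})
    _check_keys(bg_cfg, {"exchangeabilities", "equilibrium"}, "background")
    background = build_gtr(
        bg_cfg.get("exchangeabilities", [1.0] * 6),
        bg_cfg.get("equilibrium", [0.25] * 4),
    )

    spec = CRMModelSpec(
        profiles=profiles,
        bd_params=BirthDeathParams(lam, mu),
        factor_frequencies=model.get("factor_frequencies"),
        strand_factor=float(model.get("strand_factor", 0.5)),
        epsilon=float(model.get("epsilon", 0.00001)),
        indel_params=IndelParams(
            float(model.get("alpha", 0.02)), float(model.get("beta", 0.5))
        ),
    )
    return RunConfig(
        spec=spec,
        background=background,
        delta=float(delta) if delta is not None else None,
        pseudocount=pseudocount,
        c_indel=float(model.get("c_indel", 1.0)),
        c_branch=float(model.get("c_branch", 1.0)),
        seed=int(run.get("seed", 0)),
        hirschberg_cell_budget=float(run.get("hirschberg_cell_budget", 5e7)),
        log_level=str(run.get("log_level", "INFO")),
        profile_sources=sources,
    )


def save_config(config: RunConfig, path):
    spec = config.spec
    model = {
        "profiles": [
            {
                "name": p.factor_name,
                "probabilities": p.columns.T.tolist(),
            }
            for p in spec.profiles
        ],
        "pseudocount": config.pseudocount,
        "mu": spec.bd_params.death_rate,
        "alpha": spec.indel_params.alpha,
        "beta": spec.indel_params.beta,
        "epsilon": spec.epsilon,
        "c_indel": config.c_indel,
        "c_branch": config.c_branch,
        "strand_factor": spec.strand_factor,
        "factor_frequencies": spec.factor_frequencies,
        "background": {
            "exchangeabilities": _gtr_exchangeabilities(config.background),
            "equilibrium": config.background.equilibrium.tolist(),
        },
    }
    if config.delta is not None:
        model["delta"] = config.delta
    else:
        model["lambda"] = spec.bd_params.birth_rate
    doc = {
        "model": model,
        "run": {
            "seed": config.seed,
            "hirschberg_cell_budget": config.hirschberg_cell_budget,
            "log_level": config.log_level,
        },
    }
    Path(path).write_text(yaml.safe_dump(_plain(doc), sort_keys=False))


def _plain(obj):
    """Recursively coerce numpy scalars/arrays to built-in types for YAML."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        # 12-decimal rounding makes save->load->save a fixed point
        return float(round(float(obj), 12))
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    return obj


def _gtr_exchangeabilities(q: RateMatrix) -> list:
    eq = q.equilibrium
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    ex = [q.rates[i, j] / eq[j] for i, j in pairs]
    ref = ex[-1] if ex[-1] > 0 else max(ex)
    return [e / ref for e in ex]
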