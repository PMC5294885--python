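"""Run configuration: YAML/JSON schema shared by the CLI and the library.

A config has three blocks::

    model:
      motif: misa            # misa | ets_dimer | ets_monomer | self_regulating
      preset: baseline       # optional named preset (baseline | slow), motif-specific
      parameters: {g0: 2, g1: 14, k: 1, h_a: 1e-2, f_a: 1, h_r: 1e-4, f_r: 1e-2}
      n_max: 30
      dimer_ordered: true    # h n (n-1) vs h n (n-1) / 2
      sequester: true        # DNA binding removes copies from the free pool
    analysis:
      tau: 5.0
      n_macrostates: 4
      n_eigenvalues: 10
      tpt: {source: 1, target: 3}   # 1-based macrostate labels
      error_K: 500
    simulation:
      seed: 1
      t_end: 10000.0
      n_runs: 16

Unknown keys raise a :class:`ConfigError` naming the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .models import (
    RateParameters,
    ReactionNetwork,
    build_motif,
    ets_dimer_preset,
    ets_monomer_preset,
    misa_preset,
    self_regulating_preset,
)

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_config"]


class ConfigError(ValueError):
    """A configuration field is missing, unknown, or invalid."""


_PRESETS = {
    ("misa", "baseline"): lambda: misa_preset(),
    ("misa", "slow"): lambda: misa_preset(slow=True),
    ("ets_dimer", "baseline"): lambda: ets_dimer_preset(),
    ("ets_monomer", "baseline"): lambda: ets_monomer_preset(),
    ("self_regulating", "baseline"): lambda: self_regulating_preset(),
}

_DEFAULT_NMAX = {"misa": 30, "ets_dimer": 30, "ets_monomer": 50, "self_regulating": 20}


@dataclass
class RunConfig:
    network: ReactionNetwork
    n_max: int
    tau: float = 5.0
    n_macrostates: int = 4
    n_eigenvalues: int = 10
    tpt_source: int = 1
    tpt_target: int = 2
    error_K: int = 500
    seed: int | None = None
    t_end: float = 1000.0
    n_runs: int = 8
    raw: dict = field(default_factory=dict)


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where!r} block")


def parse_config(cfg: dict) -> RunConfig:
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(cfg, {"model", "analysis", "simulation", "output"}, "root")
    model = cfg.get("model")
    if not model or "motif" not in model:
        raise ConfigError("config requires model.motif")
    _check_keys(model, {"motif", "preset", "parameters", "n_max",
                        "dimer_ordered", "sequester"}, "model")
    motif = model["motif"]
    preset = model.get("preset", "baseline")
    try:
        params = _PRESETS[(motif, preset)]()
    except KeyError:
        if "parameters" not in model:
            raise ConfigError(
                f"no preset {preset!r} for motif {motif!r} and no "
                "model.parameters given"
            ) from None
        params = None
    overrides = model.get("parameters") or {}
    if params is None:
        try:
            params = RateParameters(**overrides)
        except TypeError as err:
            raise ConfigError(f"bad model.parameters: {err}") from None
    elif overrides:
        params = params.with_updates(**{k: float(v) for k, v in overrides.items()})
    try:
        network = build_motif(
            motif, params,
            dimer_ordered=bool(model.get("dimer_ordered", True)),
            sequester=bool(model.get("sequester", True)),
        )
    except (ValueError, KeyError) as err:
        raise ConfigError(str(err)) from None

    analysis = cfg.get("analysis") or {}
    _check_keys(analysis, {"tau", "n_macrostates", "n_eigenvalues", "tpt",
                           "error_K"}, "analysis")
    sim = cfg.get("simulation") or {}
    _check_keys(sim, {"seed", "t_end", "n_runs"}, "simulation")
    tpt = analysis.get("tpt") or {}
    _check_keys(tpt, {"source", "target"}, "analysis.tpt")

    rc = RunConfig(
        network=network,
        n_max=int(model.get("n_max", _DEFAULT_NMAX.get(motif, 30))),
        tau=float(analysis.get("tau", 5.0)),
        n_macrostates=int(analysis.get("n_macrostates", 4)),
        n_eigenvalues=int(analysis.get("n_eigenvalues", 10)),
        tpt_source=int(tpt.get("source", 1)),
        tpt_target=int(tpt.get("target", 2)),
        error_K=int(analysis.get("error_K", 500)),
        seed=None if sim.get("seed") is None else int(sim["seed"]),
        t_end=float(sim.get("t_end", 1000.0)),
        n_runs=int(sim.get("n_runs", 8)),
        raw=cfg,
    )
    C = rc.n_macrostates
    for name, v in (("tpt.source", rc.tpt_source), ("tpt.target", rc.tpt_target)):
        if not 1 <= v <= C:
            raise ConfigError(f"analysis.{name}={v} outside 1..C={C}")
    if rc.n_eigenvalues < rc.n_macrostates:
        rc.n_eigenvalues = rc.n_macrostates + 4
    return rc


def load_config(path) -> RunConfig:
    cfg = yaml.safe_load(Path(path).read_text())
    return parse_config(cfg)
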