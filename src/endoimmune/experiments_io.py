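"""Config-driven experiment pipelines and file I/O.

Three computational experiments are provided, mirroring the package's
study protocol:

* ``retrograde_sweep`` — cyclic-influx studies across retrograde-fraction
  levels ``rho_0``, with per-cycle immune/attachment metrics;
* ``dysfunction_heatmap`` — end-of-cycle attachment and macrophage
  activation over a (detection ``beta_1``, clearance ``omega``) grid,
  with the analytic low/high-attachment partition overlay;
* ``transition_map`` — surrogate-model bifurcation products: region map,
  equilibrium branch with folds, and quasi-static hysteresis traces.

All outputs are plain CSV/JSON and carry a manifest (config echo, package
version, seed, runtime).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bifurcation import codim2_region_map, continue_branch, hysteresis_sweep
from .classify import DEFAULT_EPSILON, DEFAULT_TAU, classify_attachment
from .equilibria import find_equilibria, partition_boundary
from .fixtures import DEFAULTS, fixtures, get_fixture
from .model_core import ParameterSet
from .simulate import SolverSettings, run_study

__all__ = [
    "ExperimentConfig",
    "load_config",
    "write_outputs",
    "retrograde_sweep",
    "dysfunction_heatmap",
    "transition_map",
    "run_experiment",
    "fixtures",
]

log = logging.getLogger("endoimmune")

EXPERIMENTS = (
    "baseline",
    "retrograde_sweep",
    "dysfunction_heatmap",
    "transition_map",
    "hysteresis",
)

_GRID_KEYS = {"min", "max", "n", "scale"}
_CONFIG_KEYS = {
    "experiment", "params", "overrides", "rho0_levels", "beta1_grid",
    "omega_grid", "n_cycles", "epsilon", "tau", "seed", "solver",
    "vary", "range", "n_steps", "out_dir",
}
_SOLVER_KEYS = {"rel_tol", "abs_tol", "max_step", "dense_output_dt", "stiff"}


@dataclass
class ExperimentConfig:
    experiment: str = "baseline"
    params: str | dict = "default"        # fixture name or full mapping
    overrides: dict = field(default_factory=dict)
    rho0_levels: list[float] = field(default_factory=lambda: [0.005, 0.05, 0.1])
    beta1_grid: dict = field(default_factory=lambda: {"min": 1e-8, "max": 1e-4, "n": 30, "scale": "log"})
    omega_grid: dict = field(default_factory=lambda: {"min": 1e-8, "max": 1e-4, "n": 30, "scale": "log"})
    n_cycles: int = 10
    epsilon: float = DEFAULT_EPSILON
    tau: float = DEFAULT_TAU
    seed: int = 0
    solver: dict = field(default_factory=dict)
    vary: str = "omega"
    range: list[float] = field(default_factory=lambda: [2e-6, 3e-5])
    n_steps: int = 25
    out_dir: str = "results"

    def parameter_set(self) -> ParameterSet:
        if isinstance(self.params, str):
            base = get_fixture(self.params).to_dict()
        else:
            base = {**DEFAULTS, **self.params}
        base.update(self.overrides)
        return ParameterSet.from_dict(base)

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(**self.solver)

    def grid(self, which: str) -> np.ndarray:
        spec = self.beta1_grid if which == "beta_1" else self.omega_grid
        if spec.get("scale", "log") == "log":
            return np.geomspace(spec["min"], spec["max"], int(spec["n"]))
        return np.linspace(spec["min"], spec["max"], int(spec["n"]))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _validate(raw: dict) -> list[str]:
    problems = []
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    for k in unknown:
        problems.append(f"unknown config key: {k!r}")
    exp = raw.get("experiment", "baseline")
    if exp not in EXPERIMENTS:
        problems.append(f"unknown experiment {exp!r}; expected one of {EXPERIMENTS}")
    for gk in ("beta1_grid", "omega_grid"):
        if gk in raw:
            g = raw[gk]
            if not isinstance(g, dict):
                problems.append(f"{gk} must be a mapping with keys {_GRID_KEYS}")
            else:
                bad = sorted(set(g) - _GRID_KEYS)
                if bad:
                    problems.append(f"{gk}: unknown keys {bad}")
                for need in ("min", "max", "n"):
                    if need not in g:
                        problems.append(f"{gk}: missing key {need!r}")
    if "solver" in raw and isinstance(raw["solver"], dict):
        bad = sorted(set(raw["solver"]) - _SOLVER_KEYS)
        if bad:
            problems.append(f"solver: unknown keys {bad}")
    if "rho0_levels" in raw:
        try:
            if not all(0.0 <= float(r) <= 1.0 for r in raw["rho0_levels"]):
                problems.append("rho0_levels must lie in [0, 1]")
        except (TypeError, ValueError):
            problems.append("rho0_levels must be a list of numbers")
    if "params" in raw and isinstance(raw["params"], str) \
            and raw["params"] not in ("default", *fixtures()):
        problems.append(f"unknown fixture name {raw['params']!r}")
    return problems


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML (or JSON) experiment config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    problems = _validate(raw)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    cfg = ExperimentConfig(**raw)
    cfg.parameter_set()  # fail fast on bad parameter values
    return cfg


def write_outputs(cfg: ExperimentConfig, out_dir, tables: dict[str, pd.DataFrame],
                  payloads: dict[str, str], runtime_s: float) -> dict:
    """Write experiment tables/JSON payloads plus a manifest; returns the
    manifest mapping."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p.name)
    for name, text in payloads.items():
        p = out / f"{name}.json"
        p.write_text(text)
        written.append(p.name)
    manifest = {
        "config": cfg.to_dict(),
        "package_version": __version__,
        "seed": cfg.seed,
        "runtime_s": round(runtime_s, 3),
        "files": sorted(written),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def baseline(cfg: ExperimentConfig):
    """Single two-stage study at the configured parameters."""
    params = cfg.parameter_set()
    settings = cfg.solver_settings()
    traj = run_study(params, cfg.n_cycles, settings)
    report = classify_attachment(traj, cfg.epsilon, cfg.tau)
    tables = {
        "trajectory": traj.to_frame(),
        "per_cycle": report.per_cycle_frame(),
    }
    payloads = {"attachment_report": report.to_json()}
    return tables, payloads


def retrograde_sweep(cfg: ExperimentConfig):
    """Cyclic studies across rho_0 levels; per-cycle metric table."""
    params = cfg.parameter_set()
    settings = cfg.solver_settings()
    rows, summary = [], []
    for r in cfg.rho0_levels:
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"rho_0 level {r} outside [0, 1]")
        p = params.replace(rho_0=float(r))
        try:
            traj = run_study(p, cfg.n_cycles, settings)
            rep = classify_attachment(traj, cfg.epsilon, cfg.tau)
        except Exception as exc:  # per-level failures recorded, sweep continues
            log.warning("rho_0=%g failed: %s", r, exc)
            summary.append({"rho_0": r, "label": "", "error": str(exc)})
            continue
        for cm in rep.per_cycle:
            row = {"rho_0": r, **dataclasses.asdict(cm)}
            rows.append(row)
        summary.append({
            "rho_0": r, "label": rep.label, "peak_EA": rep.peak_EA,
            "end_EA": rep.end_EA,
            "mean_M1_frac": float(np.mean([c.mean_M1_frac for c in rep.per_cycle])),
            "mean_M2_frac": float(np.mean([c.mean_M2_frac for c in rep.per_cycle])),
            "mean_KA": float(np.mean([c.mean_KA for c in rep.per_cycle])),
            "error": "",
        })
    tables = {
        "per_cycle": pd.DataFrame(rows),
        "summary": pd.DataFrame(summary),
    }
    return tables, {}


def dysfunction_heatmap(cfg: ExperimentConfig):
    """End-of-cycle attachment and macrophage activation over a
    (beta_1, omega) grid, per rho_0 level, plus the analytic partition."""
    params = cfg.parameter_set()
    settings = cfg.solver_settings()
    b1g, wg = cfg.grid("beta_1"), cfg.grid("omega")
    rows = []
    for r in cfg.rho0_levels:
        for b1 in b1g:
            for w in wg:
                p = params.replace(rho_0=float(r), beta_1=float(b1), omega=float(w))
                rec = {"rho_0": r, "beta_1": b1, "omega": w}
                try:
                    traj = run_study(p, cfg.n_cycles, settings)
                    rep = classify_attachment(traj, cfg.epsilon, cfg.tau)
                    cm = rep.per_cycle[-1]
                    rec.update(end_EA=rep.end_EA, peak_EA=rep.peak_EA,
                               label=rep.label,
                               end_M1_frac=cm.end_M1_frac,
                               end_M2_frac=cm.end_M2_frac,
                               valid=True, error="")
                except Exception as exc:
                    log.warning("cell (%g, %g, %g) failed: %s", r, b1, w, exc)
                    rec.update(end_EA=np.nan, peak_EA=np.nan, label="",
                               end_M1_frac=np.nan, end_M2_frac=np.nan,
                               valid=False, error=str(exc))
                rows.append(rec)
    boundary, margins = partition_boundary(params, b1g, wg, seed=cfg.seed)
    tables = {
        "heatmap": pd.DataFrame(rows),
        "partition_boundary": pd.DataFrame(boundary, columns=["beta_1", "omega"]),
        "stability_margin": pd.DataFrame(
            [{"beta_1": b1, "omega": w, "margin": margins[i, j]}
             for i, b1 in enumerate(b1g) for j, w in enumerate(wg)]
        ),
    }
    return tables, {}


def transition_map(cfg: ExperimentConfig):
    """Bifurcation products: region map over the configured grids, the
    equilibrium branch in ``cfg.vary`` with folds, and hysteresis traces."""
    params = cfg.parameter_set()
    b1g, wg = cfg.grid("beta_1"), cfg.grid("omega")
    rmap = codim2_region_map(params, b1g, wg, cfg.rho0_levels, seed=cfg.seed)

    lo, hi = sorted(float(v) for v in cfg.range)
    p_top = params.replace(**{cfg.vary: hi})
    eqs = find_equilibria(p_top, n_starts=30, seed=cfg.seed)
    tables, payloads = {}, {"region_map": rmap.to_json()}
    if eqs:
        br = continue_branch(p_top, cfg.vary, (lo, hi), eqs[0])
        tables["branch"] = br.to_frame()
        payloads["folds"] = json.dumps(
            {"vary": cfg.vary, "folds": br.folds,
             "oscillatory_segments": br.oscillatory_segments}, indent=2)
    fwd, bwd = hysteresis_sweep(params, cfg.vary, (lo, hi), cfg.n_steps)
    htab = []
    for tr in (fwd, bwd):
        for v, xs, ok in zip(tr.param_values, tr.end_states, tr.converged):
            htab.append({"direction": tr.direction, cfg.vary: v,
                         "end_EA": xs[7], "converged": bool(ok)})
    tables["hysteresis"] = pd.DataFrame(htab)
    return tables, payloads


def hysteresis(cfg: ExperimentConfig):
    params = cfg.parameter_set()
    fwd, bwd = hysteresis_sweep(params, cfg.vary,
                                tuple(sorted(map(float, cfg.range))), cfg.n_steps)
    rows = []
    for tr in (fwd, bwd):
        for v, xs, ok in zip(tr.param_values, tr.end_states, tr.converged):
            rows.append({"direction": tr.direction, cfg.vary: v,
                         "end_EA": xs[7], "converged": bool(ok)})
    return {"hysteresis": pd.DataFrame(rows)}, {}


_RUNNERS = {
    "baseline": baseline,
    "retrograde_sweep": retrograde_sweep,
    "dysfunction_heatmap": dysfunction_heatmap,
    "transition_map": transition_map,
    "hysteresis": hysteresis,
}


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> dict:
    """Run the configured experiment and write its outputs; returns the
    manifest."""
    t0 = time.perf_counter()
    tables, payloads = _RUNNERS[cfg.experiment](cfg)
    return write_outputs(cfg, out_dir or cfg.out_dir, tables, payloads,
                         time.perf_counter() - t0)
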