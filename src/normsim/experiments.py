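"""Predefined experiment suite, config handling and output files.

An :class:`ExperimentConfig` bundles one simulation condition (the model
parameters, the (l, h) grid, replication count and stationarity
settings).  :func:`run_experiment` executes the sweep and optionally
writes three plain-text artifacts to the output directory:

``histograms.csv``
    columns ``l, h, bin, quantity, freq_mean, freq_sd`` — averaged
    final-state histograms per grid cell.
``convergence.csv``
    per-replication convergence step and a converged flag.
``summary.json``
    condition name, pooled mean donation, equality index, raw Gini,
    run counts and convergence diagnostics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import engine
from .engine import RunResult, replication_rng, run_to_stationarity
from .metrics import SweepResult, pool_sweep
from .model_core import ModelParams

__all__ = [
    "ExperimentConfig",
    "predefined_conditions",
    "get_condition",
    "run_sweep",
    "run_experiment",
    "load_config",
    "SMALL_SCALE",
]

logger = logging.getLogger(__name__)

GENERAL_GRID = (0.2, 0.4, 0.6, 0.8)

#: reduced problem size for desk-scale runs: the stationary distributions
#: of a well-mixed population are insensitive to N, so a smaller
#: population and fewer replications change only the sampling noise.
SMALL_SCALE = dict(n_agents=200, n_reps=10, transient=5_000)


@dataclass
class ExperimentConfig:
    """One named simulation condition plus its sweep and run settings."""

    name: str = "custom"
    endowment: float = 1.0
    noise_scale: float = 0.0
    envy_probability: float = 0.0
    n_free_riders: int = 0
    free_rider_donation: float = 0.0
    n_agents: int = 1000
    grid_l: Sequence[float] = GENERAL_GRID
    grid_h: Sequence[float] = GENERAL_GRID
    n_reps: int = 100
    transient: int = engine.DEFAULT_TRANSIENT
    window: int = engine.DEFAULT_WINDOW
    slope_tol: float = engine.DEFAULT_SLOPE_TOL
    max_steps: int = engine.DEFAULT_MAX_STEPS
    seed: int = 0

    def __post_init__(self) -> None:
        for g in (*self.grid_l, *self.grid_h):
            if not (0.0 <= g <= 1.0):
                raise ValueError(f"grid value {g} outside [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def model_params(self, l: float, h: float) -> ModelParams:
        return ModelParams(
            endowment=self.endowment,
            learning_rate=l,
            habituation=h,
            noise_scale=self.noise_scale,
            envy_probability=self.envy_probability,
            n_free_riders=self.n_free_riders,
            free_rider_donation=self.free_rider_donation,
            n_agents=self.n_agents,
        )

    def scaled(self, scale: str) -> "ExperimentConfig":
        """Return a copy at the requested scale: ``"full"`` or ``"small"``.

        ``"small"`` reduces the population to 200, the transient to 5000
        and the replication count to 10; only the sampling precision
        changes, not which statistics are computed.  Conditions with
        frozen free-riders are an exception: a single frozen agent is an
        O(1/N) perturbation, so shrinking N changes the collapse
        dynamics of the donation norm itself, not just the noise.  For
        those conditions the population and transient stay at their
        full-scale values and only the replication count is reduced
        (to 5, to compensate the larger per-run cost).
        """
        if scale == "full":
            return dataclasses.replace(self)
        if scale == "small":
            if self.n_free_riders > 0:
                return dataclasses.replace(self, n_reps=5)
            return dataclasses.replace(self, **SMALL_SCALE)
        raise ValueError(f"unknown scale {scale!r} (use 'small' or 'full')")


def predefined_conditions() -> List[ExperimentConfig]:
    """The seven standard conditions at full scale.

    Deterministic and stochastic baselines, a small-noise check, the
    inequity-aversion variant and the single-free-rider variant, each
    without and with trembling-hand noise of scale 0.1; all on the
    general-regime grid l, h in {0.2, 0.4, 0.6, 0.8} with N = 1000 and
    100 replications per cell.
    """
    base = dict(n_agents=1000, n_reps=100)
    return [
        ExperimentConfig(name="deterministic", noise_scale=0.0, **base),
        ExperimentConfig(name="stochastic", noise_scale=0.1, **base),
        ExperimentConfig(name="small_noise", noise_scale=0.01, **base),
        ExperimentConfig(name="envy", envy_probability=0.05, noise_scale=0.0, **base),
        ExperimentConfig(name="envy_noise", envy_probability=0.05, noise_scale=0.1, **base),
        ExperimentConfig(name="free_rider", n_free_riders=1, noise_scale=0.0, **base),
        ExperimentConfig(name="free_rider_noise", n_free_riders=1, noise_scale=0.1, **base),
    ]


def get_condition(name: str) -> ExperimentConfig:
    for cfg in predefined_conditions():
        if cfg.name == name:
            return cfg
    raise KeyError(f"unknown condition {name!r}; see list-conditions")


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML (or JSON) mapping.

    Keys mirror the dataclass field names exactly; missing keys take the
    defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**data)


def run_sweep(config: ExperimentConfig,
              seed: Optional[int] = None) -> Dict[Tuple[float, float], List[RunResult]]:
    """Run every (l, h) cell of the grid with ``n_reps`` replications each.

    RNG streams are spawned per (cell index, replication index) from the
    root seed, so the sweep is deterministic and cells are independent.
    """
    root_seed = config.seed if seed is None else seed
    results: Dict[Tuple[float, float], List[RunResult]] = {}
    cell = 0
    for l in config.grid_l:
        for h in config.grid_h:
            params = config.model_params(l, h)
            runs = []
            for rep in range(config.n_reps):
                rng = replication_rng(root_seed, cell, rep)
                runs.append(run_to_stationarity(
                    params, rng,
                    transient=config.transient, window=config.window,
                    slope_tol=config.slope_tol, max_steps=config.max_steps))
            logger.info("cell l=%.2f h=%.2f: %d reps, mean convergence %d steps",
                        l, h, config.n_reps,
                        int(sum(r.converged_at for r in runs) / len(runs)))
            for r in runs:
                if not r.converged:
                    logger.warning("non-converged run in cell l=%.2f h=%.2f", l, h)
            results[(l, h)] = runs
            cell += 1
    return results


def run_experiment(config: ExperimentConfig, seed: Optional[int] = None,
                   outdir: Optional[str | Path] = None) -> SweepResult:
    """Execute a condition sweep, pool it, and write the output files."""
    raw = run_sweep(config, seed=seed)
    sweep = pool_sweep(raw)
    sweep.summary["condition"] = config.name
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sweep.histograms.to_csv(outdir / "histograms.csv", index=False)
        sweep.convergence.to_csv(outdir / "convergence.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(sweep.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("wrote %s", outdir / "summary.json")
    return sweep
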