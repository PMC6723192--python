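"""Run configuration and the end-to-end analysis pipeline.

A run is described by a small YAML (or JSON) config; an empty file means the
default study setup: reference parameterization, constitutive DUSP topology,
d5 scan over {1, 10, 20, 50, 100, 500}.  ``run_pipeline`` chains the stages —
inhibition scan, regime classification, synthetic cell-count and qPCR
experiments, fold-change quantification, and model-experiment concordance —
and writes every artifact with provenance (config hash, seeds, package
version), so two runs with the same config produce byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .calibrate import fit_parameters
from .model import (
    ConfigurationError,
    Topology,
    ValidationError,
    build_parameters,
    eventual_survival_slope,
)
from .simulation import SolverOptions, inhibition_scan
from .stats import concordance, delta_delta_ct
from .synth import noisy_trajectories, synth_cell_count_experiment, synth_qpcr
from .trajectories import eventual_decrease_threshold

__all__ = ["RunConfig", "DEFAULT_D5_GRID", "load_config", "run_pipeline"]

log = logging.getLogger("duspkin")

#: The published inhibition-strength grid.
DEFAULT_D5_GRID = (1.0, 10.0, 20.0, 50.0, 100.0, 500.0)

#: Silencing condition -> DUSP induction topology used for its model
#: prediction: DUSP16 has no known inducer (constitutive activation), DUSP8
#: is modelled as ERK1/2-induced.
CONDITION_TOPOLOGY = {"shDUSP16": Topology.CONSTITUTIVE,
                      "shDUSP8": Topology.ERK12}


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one pipeline run."""

    params: dict = field(default_factory=dict)  # overrides on the reference set
    topology: Topology = Topology.CONSTITUTIVE
    d5_grid: tuple[float, ...] = DEFAULT_D5_GRID
    solver: SolverOptions = field(default_factory=SolverOptions)
    eps_frac: float = 0.01
    delta_frac: float = 0.05
    seed: int = 0
    noise_sd: float = 0.05
    n_reps: int = 2
    ct_noise_sd: float = 0.1
    alpha: float = 0.05
    output_dir: str = "results"


_TOP_KEYS = {
    "params", "topology", "d5_grid", "solver", "eps_frac", "delta_frac",
    "seed", "noise_sd", "n_reps", "ct_noise_sd", "alpha", "output_dir",
}
_SOLVER_KEYS = {"t_end", "n_points", "rel_tol", "abs_tol", "method"}


def _config_from_mapping(raw: dict) -> RunConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown config keys: {sorted(unknown)}; known keys: "
            f"{sorted(_TOP_KEYS)}"
        )
    solver_raw = dict(raw.get("solver") or {})
    bad = set(solver_raw) - _SOLVER_KEYS
    if bad:
        raise ConfigurationError(
            f"unknown solver keys: {sorted(bad)}; known: {sorted(_SOLVER_KEYS)}"
        )
    solver = SolverOptions(**solver_raw)
    params = dict(raw.get("params") or {})
    build_parameters(params)  # validate names and values eagerly
    grid = tuple(float(v) for v in raw.get("d5_grid", DEFAULT_D5_GRID))
    cfg = RunConfig(
        params=params,
        topology=Topology.coerce(raw.get("topology", "CONSTITUTIVE")),
        d5_grid=grid,
        solver=solver,
        eps_frac=float(raw.get("eps_frac", 0.01)),
        delta_frac=float(raw.get("delta_frac", 0.05)),
        seed=int(raw.get("seed", 0)),
        noise_sd=float(raw.get("noise_sd", 0.05)),
        n_reps=int(raw.get("n_reps", 2)),
        ct_noise_sd=float(raw.get("ct_noise_sd", 0.1)),
        alpha=float(raw.get("alpha", 0.05)),
        output_dir=str(raw.get("output_dir", "results")),
    )
    if not (0 < cfg.alpha < 1):
        raise ValidationError(f"alpha must lie in (0, 1), got {cfg.alpha}")
    if cfg.n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {cfg.n_reps}")
    if cfg.noise_sd < 0 or cfg.ct_noise_sd < 0:
        raise ValidationError("noise levels must be >= 0")
    return cfg


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a run config; an empty or absent file yields all
    defaults (the published scan setup).  Unknown keys are rejected by name.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(
                f"config root must be a mapping, got {type(loaded).__name__}"
            )
        raw = loaded
    return _config_from_mapping(raw)


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if isinstance(o, Topology):
            return o.name
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {
        "config_sha256": _config_hash(cfg),
        "seed": cfg.seed,
        "package": "duspkin",
        "version": __version__,
    }


def run_pipeline(cfg: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute scan -> classification -> synthetic experiments -> statistics
    and write every artifact under ``output_dir``.

    Returns a dict of artifact paths plus the in-memory results.  Raises on
    the first unrecoverable stage failure (individual scan entries may still
    fail independently and are recorded in the scan summary).
    """
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DuspkinIOError(f"output directory {out} is not writable: {exc}") from exc

    prov = _provenance(cfg)
    params = build_parameters(cfg.params)

    log.info("scanning d5 grid %s under %s topology", cfg.d5_grid,
             cfg.topology.name)
    scan = inhibition_scan(params, cfg.topology, list(cfg.d5_grid),
                           cfg.solver, cfg.eps_frac, cfg.delta_frac)
    threshold = eventual_decrease_threshold(scan, cfg.eps_frac)

    paths: dict[str, Path] = {}
    for entry in scan.entries:
        if entry.ok:
            p = out / f"trajectory_d5_{entry.d5:g}.csv"
            entry.trajectory.to_csv(p)
            paths[f"trajectory_d5_{entry.d5:g}"] = p

    scan_payload = {
        "provenance": prov,
        "topology": cfg.topology.name,
        "d5_grid": list(cfg.d5_grid),
        "eventual_decrease_threshold": threshold,
        "entries": json.loads(scan.to_json())["entries"],
    }
    paths["scan"] = out / "scan.json"
    paths["scan"].write_text(json.dumps(scan_payload, indent=2) + "\n")

    regimes = scan.summary()[["d5", "regime"]]
    paths["regimes"] = out / "regimes.tsv"
    regimes.to_csv(paths["regimes"], sep="\t", index=False, lineterminator="\n")

    log.info("generating synthetic experiments (seed=%d)", cfg.seed)
    counts = synth_cell_count_experiment(
        noise_sd=cfg.noise_sd, n_reps=cfg.n_reps, seed=cfg.seed)
    paths["cell_counts"] = out / "cell_counts.csv"
    counts.to_csv(paths["cell_counts"])

    qpcr = synth_qpcr(ct_noise_sd=cfg.ct_noise_sd, n_reps=cfg.n_reps,
                      seed=cfg.seed + 1)
    paths["qpcr"] = out / "qpcr_ct.csv"
    qpcr.to_csv(paths["qpcr"])

    folds = delta_delta_ct(qpcr)
    paths["fold_changes"] = out / "fold_changes.csv"
    folds.to_csv(paths["fold_changes"])

    # Model predictions per silencing condition: does any scanned inhibition
    # strength give a negative asymptotic survival slope under that
    # condition's induction topology?
    predictions = {}
    for cond, top in CONDITION_TOPOLOGY.items():
        slopes = [
            eventual_survival_slope(build_parameters({**cfg.params, "d5": d5}),
                                    top)
            for d5 in cfg.d5_grid
        ]
        predictions[cond] = any(s < 0 for s in slopes)

    report = concordance(predictions, counts, alpha=cfg.alpha)
    paths["concordance"] = out / "concordance.json"
    payload = json.loads(report.to_json())
    payload["provenance"] = prov
    paths["concordance"].write_text(json.dumps(payload, indent=2) + "\n")
    paths["concordance_txt"] = out / "concordance.txt"
    paths["concordance_txt"].write_text(report.to_text() + "\n")

    log.info("pipeline complete: threshold d5 = %s; artifacts in %s",
             threshold, out)
    return {
        "paths": paths,
        "scan": scan,
        "threshold": threshold,
        "cell_counts": counts,
        "qpcr": qpcr,
        "fold_changes": folds,
        "concordance": report,
        "provenance": prov,
    }


class DuspkinIOError(ValidationError):
    """Output location unusable."""


def fit_from_config(cfg: RunConfig, free: "list[str]",
                    init_guess: dict | None = None):
    """Convenience used by the CLI ``fit`` subcommand: generate observations
    at the configured noise level and fit the requested parameters."""
    params = build_parameters(cfg.params)
    obs = noisy_trajectories(
        params, cfg.topology, noise_sd=cfg.noise_sd,
        n_reps=max(cfg.n_reps, 1), seed=cfg.seed, options=cfg.solver,
    )
    return fit_parameters(obs, free, init_guess=init_guess)
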