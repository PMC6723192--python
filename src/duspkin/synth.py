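"""Seeded synthetic data with the structure of the study's measurements.

Three generators stand in for the wet-lab readouts:

* ``noisy_trajectories`` — replicate observations of model state variables
  with multiplicative Gaussian noise, for parameter-recovery experiments;
* ``synth_cell_count_experiment`` — 72-h relative cell-count tables for
  sensitive/resistant cells under non-targeting, DUSP8- or DUSP16-silencing
  shRNA, with or without Herceptin, with lognormal replicate noise;
* ``synth_qpcr`` — qPCR Ct tables (target DUSPs plus two housekeeping genes)
  constructed so the noiseless ddCt fold change equals the configured
  knockdown.

All generators are pure functions of their inputs and a seed.  Noise is
multiplicative on counts and trajectories because those quantities are
positive; Ct noise is additive Gaussian on the cycle scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    KineticParameters,
    STATE_NAMES,
    Topology,
    ValidationError,
)
from .simulation import SolverOptions, Trajectory, simulate

__all__ = [
    "NoisyObservations",
    "CellCountTable",
    "CtTable",
    "SENSITIVITIES",
    "SILENCINGS",
    "HOUSEKEEPING_GENES",
    "TARGET_GENES",
    "DEFAULT_EFFECT_MAP",
    "DEFAULT_KNOCKDOWN",
    "noisy_trajectories",
    "synth_cell_count_experiment",
    "synth_qpcr",
]

SENSITIVITIES = ("sensitive", "resistant")
SILENCINGS = ("NT", "shDUSP8", "shDUSP16")
HOUSEKEEPING_GENES = ("ACTB", "GAPDH")
TARGET_GENES = ("DUSP8", "DUSP16")

#: True 72-h relative cell numbers (end count / start count, normalized
#: within each sensitive/resistant pair to the sensitive value) encoding the
#: study's qualitative findings: resistant cells keep growing under Herceptin
#: unless DUSP16 is silenced (decrease vs NT), while DUSP8 silencing
#: increases their growth further.  Without the drug all lines grow alike.
DEFAULT_EFFECT_MAP: dict[tuple[str, str, bool], float] = {
    ("sensitive", "NT", True): 1.0,
    ("resistant", "NT", True): 1.8,
    ("sensitive", "shDUSP8", True): 1.0,
    ("resistant", "shDUSP8", True): 2.3,
    ("sensitive", "shDUSP16", True): 1.0,
    ("resistant", "shDUSP16", True): 1.0,
    ("sensitive", "NT", False): 1.0,
    ("resistant", "NT", False): 1.0,
    ("sensitive", "shDUSP8", False): 1.0,
    ("resistant", "shDUSP8", False): 1.1,
    ("sensitive", "shDUSP16", False): 1.0,
    ("resistant", "shDUSP16", False): 1.0,
}

#: Default shRNA knockdown fractions; the study retained only vectors
#: achieving > 70% suppression of their target mRNA.
DEFAULT_KNOCKDOWN: dict[str, float] = {"shDUSP8": 0.75, "shDUSP16": 0.75}

# Noiseless baseline Ct values on the 40-cycle scale.
_BASE_CT = {"ACTB": 18.0, "GAPDH": 20.0, "DUSP8": 25.0, "DUSP16": 25.0}


@dataclass(frozen=True)
class NoisyObservations:
    """Replicate observations of selected state variables.

    ``replicates`` maps each observed species to an (n_reps, n_points) array;
    ``truth`` is the noise-free trajectory the observations were drawn around.
    """

    species: tuple[str, ...]
    time: np.ndarray
    replicates: dict[str, np.ndarray]
    noise_sd: float
    seed: int
    params: KineticParameters
    topology: Topology
    options: SolverOptions
    truth: Trajectory

    @property
    def n_reps(self) -> int:
        return next(iter(self.replicates.values())).shape[0]


@dataclass(frozen=True)
class CellCountTable:
    """Replicate relative cell numbers per condition (long format)."""

    data: pd.DataFrame  # sensitivity, silencing, herceptin, replicate, rel_count
    seed: int
    noise_sd: float
    effect_map: dict[tuple[str, str, bool], float]

    def condition(self, sensitivity: str, silencing: str,
                  herceptin: bool) -> np.ndarray:
        m = self.data
        sel = (
            (m["sensitivity"] == sensitivity)
            & (m["silencing"] == silencing)
            & (m["herceptin"] == herceptin)
        )
        if not sel.any():
            raise ValidationError(
                f"no rows for condition ({sensitivity}, {silencing}, "
                f"herceptin={herceptin})"
            )
        return m.loc[sel, "rel_count"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")
        sidecar = Path(path).with_suffix(".meta.json")
        sidecar.write_text(json.dumps({
            "seed": self.seed,
            "noise_model": "lognormal-multiplicative",
            "noise_sd": self.noise_sd,
        }, indent=2) + "\n")


@dataclass(frozen=True)
class CtTable:
    """qPCR threshold-cycle values, one row per (sample, gene, replicate)."""

    data: pd.DataFrame  # sample, sensitivity, silencing, gene, replicate, ct
    seed: int
    ct_noise_sd: float
    knockdown: dict[str, float]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")
        sidecar = Path(path).with_suffix(".meta.json")
        sidecar.write_text(json.dumps({
            "seed": self.seed,
            "noise_model": "gaussian-additive-ct",
            "ct_noise_sd": self.ct_noise_sd,
            "knockdown": self.knockdown,
        }, indent=2) + "\n")


def noisy_trajectories(
    params: KineticParameters,
    topology: Topology | str,
    observed: "tuple[str, ...] | list[str]" = ("DUSPac", "Survival"),
    noise_sd: float = 0.05,
    n_reps: int = 3,
    seed: int = 0,
    options: SolverOptions | None = None,
) -> NoisyObservations:
    """Simulate the true trajectory, then draw replicate observations with
    independent multiplicative Gaussian noise: obs = true * (1 + sd * Z).

    Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    observed = tuple(observed)
    unknown = [s for s in observed if s not in STATE_NAMES]
    if unknown:
        raise ConfigurationError(
            f"unknown species {unknown}; valid names: {list(STATE_NAMES)}"
        )
    topology = Topology.coerce(topology)
    options = options or SolverOptions()
    truth = simulate(params, topology, options)
    rng = np.random.default_rng(seed)
    reps: dict[str, np.ndarray] = {}
    for sp in observed:
        base = truth[sp]
        z = rng.standard_normal((n_reps, base.size))
        reps[sp] = base[None, :] * (1.0 + noise_sd * z)
    return NoisyObservations(
        species=observed, time=truth.time, replicates=reps,
        noise_sd=noise_sd, seed=seed, params=params, topology=topology,
        options=options, truth=truth,
    )


def synth_cell_count_experiment(
    effect_map: dict[tuple[str, str, bool], float] | None = None,
    noise_sd: float = 0.05,
    n_reps: int = 2,
    seed: int = 0,
) -> CellCountTable:
    """72-h relative cell-count table with lognormal replicate noise.

    Each replicate is truth * exp(sd * Z) so counts stay positive; the
    default two replicates per condition mirror duplicate independent
    experiments.
    """
    effect_map = dict(DEFAULT_EFFECT_MAP if effect_map is None else effect_map)
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    for cond, truth in effect_map.items():
        if not (truth > 0 and math.isfinite(truth)):
            raise ValidationError(
                f"true relative count for {cond} must be > 0, got {truth}"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for (sens, sil, herc), truth in sorted(effect_map.items()):
        noise = rng.standard_normal(n_reps)
        for r in range(n_reps):
            rows.append({
                "sensitivity": sens,
                "silencing": sil,
                "herceptin": herc,
                "replicate": r + 1,
                "rel_count": truth * math.exp(noise_sd * noise[r]),
            })
    return CellCountTable(
        data=pd.DataFrame(rows), seed=seed, noise_sd=noise_sd,
        effect_map=effect_map,
    )


def synth_qpcr(
    knockdown: dict[str, float] | None = None,
    ct_noise_sd: float = 0.0,
    n_reps: int = 2,
    seed: int = 0,
) -> CtTable:
    """Ct table for all sample lines over target DUSPs plus two housekeeping
    genes (beta-actin, GAPDH).

    Ct values are built so that the noiseless ddCt fold change of each
    silenced sample's target gene, relative to the matching non-targeting
    (NT) sample, equals 1 - knockdown fraction: the target Ct is shifted up
    by -log2(1 - kd) cycles.  Gaussian noise (sd in cycles) is then added and
    values clipped to the instrument range (0, 40].
    """
    knockdown = dict(DEFAULT_KNOCKDOWN if knockdown is None else knockdown)
    for cond, kd in knockdown.items():
        if cond not in SILENCINGS or cond == "NT":
            raise ConfigurationError(
                f"knockdown condition {cond!r} must be one of "
                f"{[s for s in SILENCINGS if s != 'NT']}"
            )
        if not (0.0 <= kd < 1.0):
            raise ValidationError(
                f"knockdown fraction for {cond} must lie in [0, 1), got {kd}"
            )
    if ct_noise_sd < 0:
        raise ValidationError(f"ct_noise_sd must be >= 0, got {ct_noise_sd}")
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")

    rng = np.random.default_rng(seed)
    rows = []
    genes = TARGET_GENES + HOUSEKEEPING_GENES
    for sens in SENSITIVITIES:
        for sil in SILENCINGS:
            sample = f"{sens}_{sil}"
            for gene in genes:
                ct0 = _BASE_CT[gene]
                # silencing raises only its own target's Ct
                if sil != "NT" and gene == sil.removeprefix("sh"):
                    kd = knockdown.get(sil, 0.0)
                    ct0 = ct0 - math.log2(1.0 - kd) if kd > 0 else ct0
                noise = rng.standard_normal(n_reps)
                for r in range(n_reps):
                    ct = ct0 + ct_noise_sd * noise[r]
                    rows.append({
                        "sample": sample,
                        "sensitivity": sens,
                        "silencing": sil,
                        "gene": gene,
                        "replicate": r + 1,
                        "ct": float(np.clip(ct, 1e-6, 40.0)),
                    })
    return CtTable(
        data=pd.DataFrame(rows), seed=seed, ct_noise_sd=ct_noise_sd,
        knockdown=knockdown,
    )
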