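"""Mass-action kinetic model of DUSP-regulated HER2/MAPK signalling.

The network couples five two-state (active/inactive) proteins — HER2, ERK1/2,
JNK1/2, p38 and a single DUSP node standing for DUSP8/16 — to a scalar
``Survival`` score that integrates pro-proliferative ERK1/2 signalling against
the cooperative anti-proliferative action of JNK1/2 and p38:

    dHER2ac/dt   = k1*HER2i  - d1*HER2ac*Herceptin
    dERK12ac/dt  = k2*ERK12i*HER2ac - d2*ERK12ac
    dJNK12ac/dt  = k3*JNK12i*HER2ac - d3*JNK12ac*DUSPac
    dP38ac/dt    = k4*P38i*HER2ac   - d4*P38ac*DUSPac
    dDUSPac/dt   = k5*DUSPi*I       - d5*DUSPac
    dSurvival/dt = s1*ERK12ac - s2*(JNK12ac*P38ac)**hill

with each inactive form obeying the mirrored equation (so every active+inactive
pair is conserved exactly), Herceptin a constant input, and ``I`` the DUSP
induction factor: 1 for the constitutive topology, ERK12ac or JNK12ac for the
two inducible topologies.  Raising the DUSP inactivation rate ``d5`` emulates
pharmacological or shRNA inhibition of the phosphatase.

This module defines the parameter/state containers, the three topologies, the
right-hand side, and closed-form steady states (the DUSP/JNK pair reduces to a
quadratic under JNK induction), including the asymptotic survival slope that
predicts whether the survival trajectory eventually decreases.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "DuspkinError",
    "ConfigurationError",
    "ValidationError",
    "NumericsError",
    "Topology",
    "KineticParameters",
    "ModelState",
    "SteadyState",
    "PROTEINS",
    "STATE_NAMES",
    "build_parameters",
    "initial_state",
    "derivatives",
    "rhs",
    "steady_state",
    "eventual_survival_slope",
    "dusp_active_closed_form",
]


class DuspkinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DuspkinError):
    """Unknown option, key, or name supplied by the caller."""


class ValidationError(DuspkinError):
    """A value violates a domain constraint (sign, range, feasibility)."""


class NumericsError(DuspkinError):
    """A numerical procedure failed (integration, root finding)."""


class Topology(enum.Enum):
    """Which signal induces DUSP activation.

    CONSTITUTIVE reproduces the baseline model (DUSP activation independent of
    the kinases); ERK12 and JNK12 multiply the DUSP activation flux by the
    inducing kinase's active amount.
    """

    CONSTITUTIVE = "CONSTITUTIVE"
    ERK12 = "ERK12"
    JNK12 = "JNK12"

    @classmethod
    def coerce(cls, value: "Topology | str") -> "Topology":
        if isinstance(value, Topology):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ConfigurationError(
                f"unknown topology {value!r}; expected one of "
                f"{[t.name for t in cls]}"
            ) from None


#: Protein pair names, in state-vector order.
PROTEINS = ("HER2", "ERK12", "JNK12", "P38", "DUSP")

#: Full state-vector layout: active/inactive per protein, then Survival.
STATE_NAMES = (
    "HER2ac", "HER2i",
    "ERK12ac", "ERK12i",
    "JNK12ac", "JNK12i",
    "P38ac", "P38i",
    "DUSPac", "DUSPi",
    "Survival",
)

N_STATES = len(STATE_NAMES)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants, survival weights and conserved totals.

    k1..k5 are activation rates, d1..d5 inactivation rates (d5 is the DUSP
    inhibition knob), s1/s2 weight the survival gain and loss terms, ``hill``
    is the cooperativity exponent on the JNK12ac*P38ac product, ``herceptin``
    the constant drug input, and ``totals`` the conserved active+inactive
    amount of each protein.
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    k4: float = 1.0
    k5: float = 1.0
    d1: float = 1.0
    d2: float = 1.0
    d3: float = 1.0
    d4: float = 1.0
    d5: float = 1.0
    s1: float = 1.0
    s2: float = 1.0
    hill: float = 0.6
    herceptin: float = 100.0
    totals: dict[str, float] = field(
        default_factory=lambda: {p: 100.0 for p in PROTEINS}
    )

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("totals",):
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValidationError(f"parameter {f.name} must be finite, got {v!r}")
            if f.name == "hill":
                if v <= 0:
                    raise ValidationError(f"hill must be > 0, got {v}")
            elif v < 0:
                raise ValidationError(f"parameter {f.name} must be >= 0, got {v}")
        if set(self.totals) != set(PROTEINS):
            raise ValidationError(
                f"totals must cover exactly {PROTEINS}, got {sorted(self.totals)}"
            )
        for p, t in self.totals.items():
            if not (math.isfinite(t) and t >= 0):
                raise ValidationError(f"total for {p} must be finite and >= 0, got {t}")

    def with_overrides(self, **overrides: float) -> "KineticParameters":
        return build_parameters(overrides, base=self)


_SCALAR_FIELDS = tuple(
    f.name for f in fields(KineticParameters) if f.name != "totals"
)


def build_parameters(
    overrides: dict[str, float] | None = None,
    base: KineticParameters | None = None,
) -> KineticParameters:
    """Return the reference parameterization with ``overrides`` applied.

    The reference point sets every rate constant and survival weight to 1,
    hill = 0.6, herceptin = 100 and all protein totals to 100.  Overrides are
    keyed by scalar field name (``"d5"``, ``"herceptin"``, ...) or by
    ``"total_<PROTEIN>"`` for conserved totals.

    Raises ConfigurationError for unknown names and ValidationError for
    out-of-domain values.
    """
    base = base if base is not None else KineticParameters()
    if not overrides:
        return base
    scalars: dict[str, float] = {}
    totals = dict(base.totals)
    for name, value in overrides.items():
        if name in _SCALAR_FIELDS:
            scalars[name] = float(value)
        elif name.startswith("total_") and name[len("total_"):] in PROTEINS:
            totals[name[len("total_"):]] = float(value)
        else:
            known = list(_SCALAR_FIELDS) + [f"total_{p}" for p in PROTEINS]
            raise ConfigurationError(
                f"unknown parameter name {name!r}; known names: {known}"
            )
    return replace(base, totals=totals, **scalars)


@dataclass(frozen=True)
class ModelState:
    """Amounts of the ten protein forms plus the Survival score at one time."""

    HER2ac: float
    HER2i: float
    ERK12ac: float
    ERK12i: float
    JNK12ac: float
    JNK12i: float
    P38ac: float
    P38i: float
    DUSPac: float
    DUSPi: float
    Survival: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATES,):
            raise ValidationError(f"state vector must have shape ({N_STATES},)")
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})


@dataclass(frozen=True)
class SteadyState:
    """Steady active amounts of the protein subsystem and the asymptotic
    survival slope s1*ERK12ac* - s2*(JNK12ac* * P38ac*)**hill."""

    HER2ac: float
    ERK12ac: float
    JNK12ac: float
    P38ac: float
    DUSPac: float
    eventual_survival_slope: float


def initial_state(params: KineticParameters) -> ModelState:
    """Initial condition: HER2, ERK1/2 and DUSP start fully active (100 each
    at reference totals), JNK1/2 and p38 fully inactive; each inactive pool is
    the protein total minus the active amount; Survival starts at 0."""
    active = {
        "HER2": 100.0,
        "ERK12": 100.0,
        "JNK12": 0.0,
        "P38": 0.0,
        "DUSP": 100.0,
    }
    vals: dict[str, float] = {}
    for p in PROTEINS:
        ac = active[p]
        total = params.totals[p]
        if total < ac:
            raise ValidationError(
                f"total for {p} ({total}) is smaller than its prescribed "
                f"initial active amount ({ac})"
            )
        vals[f"{p}ac"] = ac
        vals[f"{p}i"] = total - ac
    return ModelState(Survival=0.0, **vals)


def _survival_loss(jnk_ac: float, p38_ac: float, params: KineticParameters) -> float:
    prod = jnk_ac * p38_ac
    if prod <= 0.0:
        # (x)**0.6 at x = 0 is taken as 0; tiny negative round-off clamped.
        return 0.0
    return params.s2 * prod ** params.hill


def rhs(t: float, y: np.ndarray, params: KineticParameters,
        topology: Topology) -> np.ndarray:
    """ODE right-hand side on the raw state vector (solver-facing).

    Each protein pair's flux is computed once and applied with opposite signs,
    so d(ac)/dt + d(i)/dt = 0 holds exactly in floating point.
    """
    (her2ac, her2i, erkac, erki, jnkac, jnki,
     p38ac, p38i, duspac, duspi, _surv) = y
    p = params

    if topology is Topology.CONSTITUTIVE:
        induction = 1.0
    elif topology is Topology.ERK12:
        induction = erkac
    else:  # Topology.JNK12
        induction = jnkac

    f_her2 = p.k1 * her2i - p.d1 * her2ac * p.herceptin
    f_erk = p.k2 * erki * her2ac - p.d2 * erkac
    f_jnk = p.k3 * jnki * her2ac - p.d3 * jnkac * duspac
    f_p38 = p.k4 * p38i * her2ac - p.d4 * p38ac * duspac
    f_dusp = p.k5 * duspi * induction - p.d5 * duspac
    f_surv = p.s1 * erkac - _survival_loss(jnkac, p38ac, p)

    return np.array([
        f_her2, -f_her2,
        f_erk, -f_erk,
        f_jnk, -f_jnk,
        f_p38, -f_p38,
        f_dusp, -f_dusp,
        f_surv,
    ])


def derivatives(
    state: ModelState,
    params: KineticParameters,
    topology: Topology | str = Topology.CONSTITUTIVE,
) -> ModelState:
    """Instantaneous rate of change of every state field.

    Raises ValidationError if any protein amount is negative.
    """
    topology = Topology.coerce(topology)
    y = state.to_array()
    if np.any(y[:-1] < 0):
        bad = [n for n, v in zip(STATE_NAMES[:-1], y[:-1]) if v < 0]
        raise ValidationError(f"negative protein amounts: {bad}")
    return ModelState.from_array(rhs(0.0, y, params, topology))


# --- closed-form steady states ---------------------------------------------


def _pair_steady(k_act: float, d_eff: float, total: float, label: str) -> float:
    """Steady active amount of a two-state pair with activation rate k_act
    and effective inactivation rate d_eff: k_act*(T - x) = d_eff*x."""
    denom = k_act + d_eff
    if denom <= 0.0:
        raise NumericsError(
            f"{label}: activation and inactivation rates are both zero; "
            "the pair has no unique steady state"
        )
    return k_act * total / denom


def _dusp_steady(params: KineticParameters, topology: Topology,
                 her2ac: float, erkac: float) -> float:
    p = params
    t_d = p.totals["DUSP"]
    if topology is Topology.CONSTITUTIVE:
        return _pair_steady(p.k5, p.d5, t_d, "DUSP")
    if topology is Topology.ERK12:
        return _pair_steady(p.k5 * erkac, p.d5, t_d, "DUSP(ERK12-induced)")
    # JNK12 induction couples DUSP to JNK: substituting the JNK quasi-steady
    # amount a*T_J/(a + d3*x), a = k3*HER2ac*, into k5*(T_D - x)*JNK = d5*x
    # gives d5*d3*x**2 + (d5*a + k5*a*T_J)*x - k5*a*T_J*T_D = 0.
    a = p.k3 * her2ac
    t_j = p.totals["JNK12"]
    qa = p.d5 * p.d3
    qb = p.d5 * a + p.k5 * a * t_j
    qc = -p.k5 * a * t_j * t_d
    if qa == 0.0:
        if qb == 0.0:
            raise NumericsError("JNK12-induced DUSP steady state is degenerate")
        x = -qc / qb
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0.0:
            raise NumericsError("JNK12-induced DUSP quadratic has no real root")
        x = (-qb + math.sqrt(disc)) / (2.0 * qa)
    if x < -1e-12 or x > t_d * (1 + 1e-12):
        raise NumericsError(
            f"JNK12-induced DUSP steady state {x} outside [0, {t_d}]"
        )
    return min(max(x, 0.0), t_d)


def steady_state(
    params: KineticParameters,
    topology: Topology | str = Topology.CONSTITUTIVE,
) -> SteadyState:
    """Unique nonnegative fixed point of the protein subsystem, plus the
    asymptotic survival slope there.

    The cascade solves sequentially: HER2 sees only Herceptin; ERK1/2 sees
    HER2; DUSP sees its inducer; JNK1/2 and p38 see HER2 and DUSP.  Raises
    NumericsError when a pair's rates make the fixed point non-unique.
    """
    topology = Topology.coerce(topology)
    p = params
    her2ac = _pair_steady(p.k1, p.d1 * p.herceptin, p.totals["HER2"], "HER2")
    erkac = _pair_steady(p.k2 * her2ac, p.d2, p.totals["ERK12"], "ERK12")
    duspac = _dusp_steady(p, topology, her2ac, erkac)
    jnkac = _pair_steady(p.k3 * her2ac, p.d3 * duspac, p.totals["JNK12"], "JNK12")
    p38ac = _pair_steady(p.k4 * her2ac, p.d4 * duspac, p.totals["P38"], "P38")
    slope = p.s1 * erkac - _survival_loss(jnkac, p38ac, p)
    return SteadyState(
        HER2ac=her2ac, ERK12ac=erkac, JNK12ac=jnkac, P38ac=p38ac,
        DUSPac=duspac, eventual_survival_slope=slope,
    )


def eventual_survival_slope(
    params: KineticParameters,
    topology: Topology | str = Topology.CONSTITUTIVE,
) -> float:
    """Asymptotic dSurvival/dt once the protein subsystem has equilibrated.

    Negative slope predicts an eventually-decreasing survival trajectory
    (re-sensitization to the drug); positive slope predicts sustained growth.
    """
    return steady_state(params, topology).eventual_survival_slope


def dusp_active_closed_form(
    t: np.ndarray | float, params: KineticParameters
) -> np.ndarray | float:
    """Exact DUSPac(t) for the constitutive topology.

    The constitutive DUSP pair is autonomous and linear, so from the standard
    initial state DUSPac(t) = C + (D0 - C) * exp(-(k5 + d5) t) with
    C = k5*T/(k5 + d5) and D0 = 100.  Serves as the integrator oracle.
    """
    p = params
    total = p.totals["DUSP"]
    rate = p.k5 + p.d5
    if rate <= 0.0:
        return np.full_like(np.asarray(t, dtype=float), 100.0)
    c = p.k5 * total / rate
    d0 = 100.0
    return c + (d0 - c) * np.exp(-rate * np.asarray(t, dtype=float))
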