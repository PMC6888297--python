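"""Core ODE model of the AMPK–mTORC1–ULK1–ATG regulatory triangle.

Four dimensionless state variables track the *active* fraction of each
species: ``A`` (AMPK phosphorylated at Thr-172), ``M`` (active mTORC1,
read out experimentally via p70S6K-P), ``U`` (ULK1 phosphorylated at
Ser-555) and ``G`` (the lumped autophagy activator, ATG).  Each species
is a covalent-modification (Goldbeter–Koshland) cycle: a Michaelis–Menten
activation flux acting on the inactive pool ``(X_T - X)`` balanced
against a Michaelis–Menten inactivation flux acting on ``X``.  Activating
edges of the wiring diagram add to the activation rate, inhibitory edges
add to the inactivation rate.

The network carries three interlocking feedback loops:

* AMPK ┤ mTOR ┤ AMPK — a double-negative (toggle) loop; the mTOR ┤ AMPK
  arm is switchable (``ModelVariant.mtor_inhibits_ampk``) so the model
  can be ablated back to the template network that lacks it,
* ULK1 ┤ mTOR ┤ ULK1 — a second double-negative loop,
* AMPK → ULK1 ┤ AMPK — a delayed negative feedback that makes the AMPK
  response to mTOR inhibition transient.

Rate constants (``k``-prefixed) are in min⁻¹; Michaelis constants
(``J``-prefixed) and total levels (``*T``) are dimensionless.  ULK1 has
no basal activation term: its activation strictly requires AMPK.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "ModelVariant",
    "ModelState",
    "SPECIES",
    "InvalidParameterError",
    "InvalidStateError",
    "default_parameters",
    "rhs",
    "rhs_vector",
    "validate",
]

#: Canonical ordering of the state variables everywhere in the package.
SPECIES = ("A", "M", "U", "G")

_STATE_TOL = 1e-6  # slack allowed outside [0, total] before an error


class InvalidParameterError(ValueError):
    """A parameter set violates the model's type invariants."""


class InvalidStateError(ValueError):
    """A state lies outside [0, total] beyond tolerance."""


@dataclass(kw_only=True)
class ModelParameters:
    """Rate constants, Michaelis constants, totals and the stress input.

    Defaults are the shipped calibrated set (see the calibration module
    and ``data/default_parameters.yaml``); ``kamtor`` and the totals are
    fixed by the modelling conventions (baseline kamtor = 0.025, i.e.
    half the hyper-activated 0.05; one unit of each protein).
    """

    # AMPK cycle
    kaA: float = 0.06     # basal AMPK activation (min^-1), scaled by S
    S: float = 1.0       # dimensionless stress/energy input (1 = physiological)
    kiA: float = 0.012    # basal AMPK inactivation
    kiAU: float = 0.156   # ULK1-catalysed AMPK inactivation
    kiAM: float = 0.18    # mTOR-catalysed AMPK inactivation (the orange edge)
    # mTOR cycle
    kamtor: float = 0.025  # mTOR activation; 0.05 = hyper-activation
    kiM: float = 0.022     # basal mTOR inactivation
    kiMA: float = 0.01     # AMPK-catalysed mTOR inactivation
    kiMU: float = 0.07     # ULK1-catalysed mTOR inactivation
    # ULK1 cycle (no basal activation: activation requires AMPK)
    kaUA: float = 0.03   # AMPK-catalysed ULK1 activation
    kiU: float = 0.0003   # basal ULK1 inactivation
    kiUM: float = 0.12   # mTOR-catalysed ULK1 inactivation
    # ATG cycle
    kaG0: float = 0.005  # basal ATG activation (residual autophagy)
    kaGU: float = 0.05   # ULK1-catalysed ATG activation
    kiG: float = 0.01    # basal ATG inactivation
    kiGM: float = 0.2    # mTOR-catalysed ATG inactivation
    # Michaelis constants
    JaA: float = 0.01
    JiA: float = 0.005
    JaM: float = 0.1
    JiM: float = 0.1
    JaU: float = 0.05
    JiU: float = 0.2
    JaG: float = 0.01
    JiG: float = 0.01
    # Total levels (one unit each)
    AT: float = 1.0
    MT: float = 1.0
    UT: float = 1.0
    GT: float = 1.0

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter field(s): {sorted(unknown)}"
            )
        return cls(**{k: float(v) for k, v in data.items()})

    def replace(self, **overrides: float) -> "ModelParameters":
        d = self.to_dict()
        unknown = set(overrides) - set(d)
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter field(s): {sorted(unknown)}"
            )
        d.update(overrides)
        return ModelParameters(**d)


_RATE_FIELDS = (
    "kaA", "kiA", "kiAU", "kiAM", "kamtor", "kiM", "kiMA", "kiMU",
    "kaUA", "kiU", "kiUM", "kaG0", "kaGU", "kiG", "kiGM",
)
_MICHAELIS_FIELDS = ("JaA", "JiA", "JaM", "JiM", "JaU", "JiU", "JaG", "JiG")
_TOTAL_FIELDS = ("AT", "MT", "UT", "GT")


@dataclass(kw_only=True)
class ModelVariant:
    """Edge switches for the wiring diagram.

    ``mtor_inhibits_ampk`` is the newly proposed (orange) edge; with it
    off and every other switch on, the system is exactly the template
    network.  The remaining switches correspond to edges a–g and exist
    for ablation studies; turning one off is numerically identical to
    zeroing that edge's coefficient.
    """

    mtor_inhibits_ampk: bool = True   # orange edge: mTOR ┤ AMPK (kiAM)
    ampk_activates_ulk1: bool = True  # a: AMPK → ULK1 (kaUA)
    ulk1_inhibits_ampk: bool = True   # b: ULK1 ┤ AMPK (kiAU)
    mtor_inhibits_ulk1: bool = True   # c: mTOR ┤ ULK1 (kiUM)
    ulk1_inhibits_mtor: bool = True   # d: ULK1 ┤ mTOR (kiMU)
    ampk_inhibits_mtor: bool = True   # e: AMPK ┤ mTOR (kiMA)
    mtor_inhibits_atg: bool = True    # f: mTOR ┤ ATG (kiGM)
    ulk1_activates_atg: bool = True   # g: ULK1 → ATG (kaGU)

    def to_dict(self) -> dict[str, bool]:
        return {k: bool(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelVariant":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown variant field(s): {sorted(unknown)}"
            )
        return cls(**{k: bool(v) for k, v in data.items()})


#: The template network (mTOR ┤ AMPK edge absent, everything else intact).
TEMPLATE_VARIANT = ModelVariant(mtor_inhibits_ampk=False)


@dataclass
class ModelState:
    """Active levels of the four species at one instant."""

    A: float
    M: float
    U: float
    G: float

    def to_array(self) -> np.ndarray:
        return np.array([self.A, self.M, self.U, self.G], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(v) for v in y))

    def to_dict(self) -> dict[str, float]:
        return {"A": self.A, "M": self.M, "U": self.U, "G": self.G}


def validate(
    params: ModelParameters, variant: ModelVariant | None = None
) -> list[str]:
    """Return a list of invariant violations (empty iff valid).

    Violations are returned, not raised; each message names the
    offending field.
    """
    violations: list[str] = []
    for name in _RATE_FIELDS:
        v = getattr(params, name)
        if not np.isfinite(v) or v < 0:
            violations.append(f"{name}: rate constant must be >= 0, got {v}")
    for name in _MICHAELIS_FIELDS:
        v = getattr(params, name)
        if not np.isfinite(v) or v <= 0:
            violations.append(f"{name}: Michaelis constant must be > 0, got {v}")
    for name in _TOTAL_FIELDS:
        v = getattr(params, name)
        if not np.isfinite(v) or v < 0:
            violations.append(f"{name}: total level must be >= 0, got {v}")
    if not np.isfinite(params.S) or params.S < 0:
        violations.append(f"S: stress input must be >= 0, got {params.S}")
    if params.kaG0 > params.kaGU * params.UT and params.kaG0 > 0.05:
        violations.append(
            "kaG0: basal ATG activation must stay small relative to "
            f"kaGU*UT (kaG0={params.kaG0}, kaGU*UT={params.kaGU * params.UT})"
        )
    return violations


def _check_params(params: ModelParameters, variant: ModelVariant) -> None:
    violations = validate(params, variant)
    if violations:
        raise InvalidParameterError("; ".join(violations))


def _coefficients(
    params: ModelParameters, variant: ModelVariant
) -> tuple[float, ...]:
    """Edge coefficients with variant switches folded in.

    Switching an edge off multiplies its coefficient by exactly 0.0, so
    ablation-by-switch and ablation-by-zero-coefficient are bitwise
    identical.
    """
    p, v = params, variant
    return (
        p.kaA * p.S,
        p.kiA,
        (p.kiAU if v.ulk1_inhibits_ampk else 0.0),
        (p.kiAM if v.mtor_inhibits_ampk else 0.0),
        p.kamtor,
        p.kiM,
        (p.kiMA if v.ampk_inhibits_mtor else 0.0),
        (p.kiMU if v.ulk1_inhibits_mtor else 0.0),
        (p.kaUA if v.ampk_activates_ulk1 else 0.0),
        p.kiU,
        (p.kiUM if v.mtor_inhibits_ulk1 else 0.0),
        p.kaG0,
        (p.kaGU if v.ulk1_activates_atg else 0.0),
        p.kiG,
        (p.kiGM if v.mtor_inhibits_atg else 0.0),
    )


def make_rhs(params: ModelParameters, variant: ModelVariant):
    """Compile the RHS to a closure over plain floats (the hot path)."""
    (kaAS, kiA, kiAU, kiAM, kamtor, kiM, kiMA, kiMU,
     kaUA, kiU, kiUM, kaG0, kaGU, kiG, kiGM) = _coefficients(params, variant)
    p = params
    JaA, JiA, JaM, JiM = p.JaA, p.JiA, p.JaM, p.JiM
    JaU, JiU, JaG, JiG = p.JaU, p.JiU, p.JaG, p.JiG
    AT, MT, UT, GT = p.AT, p.MT, p.UT, p.GT

    def f(y: np.ndarray) -> np.ndarray:
        A, M, U, G = y
        return np.array([
            kaAS * (AT - A) / (JaA + AT - A)
            - (kiA + kiAU * U + kiAM * M) * A / (JiA + A),
            kamtor * (MT - M) / (JaM + MT - M)
            - (kiM + kiMA * A + kiMU * U) * M / (JiM + M),
            kaUA * A * (UT - U) / (JaU + UT - U)
            - (kiU + kiUM * M) * U / (JiU + U),
            (kaG0 + kaGU * U) * (GT - G) / (JaG + GT - G)
            - (kiG + kiGM * M) * G / (JiG + G),
        ])

    return f


def rhs_vector(
    y: np.ndarray, params: ModelParameters, variant: ModelVariant
) -> np.ndarray:
    """Time derivatives (min⁻¹) for a raw state vector [A, M, U, G].

    No validation; see :func:`rhs` for the checked public entry point
    and :func:`make_rhs` for the compiled closure the solvers use.
    """
    return make_rhs(params, variant)(np.asarray(y, dtype=float))


def rhs(
    state: ModelState,
    params: ModelParameters,
    variant: ModelVariant | None = None,
) -> np.ndarray:
    """Validated right-hand side: derivatives of (A, M, U, G) in min⁻¹."""
    if variant is None:
        variant = ModelVariant()
    _check_params(params, variant)
    y = state.to_array()
    totals = np.array([params.AT, params.MT, params.UT, params.GT])
    if np.any(y < -_STATE_TOL) or np.any(y > totals + _STATE_TOL):
        raise InvalidStateError(
            f"state {y.tolist()} outside [0, total] bounds {totals.tolist()}"
        )
    return rhs_vector(y, params, variant)


@lru_cache(maxsize=1)
def _load_default_yaml() -> dict:
    text = (
        resources.files("ampktoggle")
        .joinpath("data", "default_parameters.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def default_parameters() -> ModelParameters:
    """The shipped calibrated parameter set.

    Loaded from the versioned config ``data/default_parameters.yaml``
    produced by the calibration module.  At these values the extended
    model rests at a physiological steady state (mTOR active, AMPK /
    ULK1 / ATG inactive at S = 1) and reproduces the full qualitative
    phenotype matrix.
    """
    cfg = _load_default_yaml()
    return ModelParameters.from_dict(cfg["parameters"])
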