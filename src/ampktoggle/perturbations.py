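"""Experimental manipulations encoded as timed parameter overrides.

Each wet-lab treatment maps to a small set of parameter overrides:

* siULK1 — total ULK1 knocked down to 0.001 units,
* siTSC1/2 — loss of the upstream mTOR brake, i.e. kamtor = 0.05
  (a 2-fold increase over the 0.025 baseline),
* rapamycin — the pool of active-capable mTOR collapses (MT -> 0.01),
* Compound C — the AMPK activation rate constant is scaled down 20-fold,
* starvation / resveratrol — both act through the stress input S
  (AMPK activators); doses are fixed override magnitudes, there is no
  pharmacokinetics.

A :class:`Protocol` is an ordered sequence of stages; overrides
accumulate across stages (a pre-treatment stays in force when the main
treatment starts).  Protocols are pure data and serialise to YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import InvalidParameterError, ModelParameters

__all__ = [
    "Treatment",
    "Protocol",
    "ProtocolError",
    "UnknownTreatmentError",
    "treatment_library",
    "get_treatment",
    "apply",
    "standard_protocol",
    "EPS_MTOR",
    "EPS_COMPOUND_C",
    "S_STARVE",
    "S_RESVERATROL",
    "S_AMPK_HYPER",
]

# Override magnitudes for the drug/stress treatments (package conventions;
# the doses printed for the experiments map to these fixed values).
EPS_MTOR = 0.01        # residual total mTOR under rapamycin
EPS_COMPOUND_C = 0.05  # multiplicative reduction of kaA under Compound C
S_STARVE = 2.6         # stress input under carbohydrate starvation
S_RESVERATROL = 2.6    # resveratrol acts like starvation through S
S_AMPK_HYPER = 6.0     # direct AMPK hyper-activation


class ProtocolError(ValueError):
    """Invalid protocol structure or conflicting treatment overrides."""


class UnknownTreatmentError(KeyError):
    """A treatment name is not in the library."""


@dataclass(frozen=True)
class Treatment:
    """A named set of parameter overrides.

    ``mode`` is ``"replace"`` (the override value is assigned) or
    ``"multiply"`` (the current value is scaled).  Replace wins over
    multiply on the same field within one stage.
    """

    name: str
    overrides: dict[str, float]
    mode: str = "replace"

    def __post_init__(self) -> None:
        if self.mode not in ("replace", "multiply"):
            raise ProtocolError(f"{self.name}: unknown mode {self.mode!r}")
        valid = set(ModelParameters().to_dict())
        unknown = set(self.overrides) - valid
        if unknown:
            raise InvalidParameterError(
                f"{self.name}: unknown parameter field(s) {sorted(unknown)}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "overrides": dict(self.overrides),
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Treatment":
        return cls(
            name=data["name"],
            overrides={k: float(v) for k, v in data["overrides"].items()},
            mode=data.get("mode", "replace"),
        )


def treatment_library() -> dict[str, Treatment]:
    """The named treatments used throughout the scenario suite."""
    lib = [
        Treatment("si_ulk1", {"UT": 0.001}),
        Treatment("si_tsc12", {"kamtor": 0.05}),
        # mTOR hyper-activation proper: a 2-fold increase of kamtor
        # (numerically identical to si_tsc12 at the 0.025 baseline).
        Treatment("mtor_hyper", {"kamtor": 2.0}, mode="multiply"),
        Treatment("rapamycin", {"MT": EPS_MTOR}),
        Treatment("starvation", {"S": S_STARVE}),
        Treatment("resveratrol", {"S": S_RESVERATROL}),
        Treatment("compound_c", {"kaA": EPS_COMPOUND_C}, mode="multiply"),
        Treatment("ampk_hyper", {"S": S_AMPK_HYPER}),
    ]
    return {t.name: t for t in lib}


def get_treatment(name: str) -> Treatment:
    lib = treatment_library()
    if name not in lib:
        raise UnknownTreatmentError(
            f"unknown treatment {name!r}; known: {sorted(lib)}"
        )
    return lib[name]


def apply(
    params: ModelParameters, treatments: list[Treatment]
) -> ModelParameters:
    """Apply treatments to a parameter set, returning a new set.

    The input is untouched.  Within the list, replace-mode overrides win
    over multiply-mode ones on the same field; two replace overrides
    with different values for the same field are a conflict error.
    Applying a replace treatment twice equals applying it once.
    """
    replaced: dict[str, float] = {}
    multiplied: dict[str, float] = {}
    for t in treatments:
        for name, value in t.overrides.items():
            if t.mode == "replace":
                if name in replaced and replaced[name] != value:
                    raise ProtocolError(
                        f"conflicting replace values for {name!r}: "
                        f"{replaced[name]} vs {value}"
                    )
                replaced[name] = float(value)
            else:
                multiplied[name] = multiplied.get(name, 1.0) * float(value)
    out = params.to_dict()
    for name, factor in multiplied.items():
        out[name] = out[name] * factor
    # replace wins over multiply on the same field
    out.update(replaced)
    return ModelParameters(**out)


@dataclass
class Protocol:
    """A timed sequence of treatment stages.

    ``stages`` is an ordered list of ``(onset_min, [Treatment, ...])``
    with strictly increasing onsets starting at 0.  Overrides accumulate:
    the parameters in force during stage k are ``apply(base, all
    treatments of stages 0..k)``.  ``initial_policy`` is
    ``"physiological"`` (start from the resting steady state) or
    ``"explicit"`` (caller supplies the state).
    """

    stages: list[tuple[float, list[Treatment]]]
    duration: float
    initial_policy: str = "physiological"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stages:
            raise ProtocolError("protocol needs at least one stage")
        onsets = [t for t, _ in self.stages]
        if onsets[0] != 0.0:
            raise ProtocolError(f"first stage must start at 0, got {onsets[0]}")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ProtocolError(f"onset times must strictly increase: {onsets}")
        if self.duration <= onsets[-1]:
            raise ProtocolError(
                f"duration {self.duration} must exceed last onset {onsets[-1]}"
            )
        if self.initial_policy not in ("physiological", "explicit"):
            raise ProtocolError(
                f"unknown initial-condition policy {self.initial_policy!r}"
            )

    def params_per_stage(
        self, base: ModelParameters
    ) -> list[tuple[float, float, ModelParameters]]:
        """Resolve to [(t_start, t_end, params)] windows covering [0, T]."""
        onsets = [t for t, _ in self.stages] + [self.duration]
        out = []
        accumulated: list[Treatment] = []
        for i, (_, treatments) in enumerate(self.stages):
            accumulated = accumulated + list(treatments)
            out.append((onsets[i], onsets[i + 1], apply(base, accumulated)))
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "duration": self.duration,
            "initial_policy": self.initial_policy,
            "stages": [
                {"onset": onset, "treatments": [t.to_dict() for t in ts]}
                for onset, ts in self.stages
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Protocol":
        return cls(
            stages=[
                (
                    float(st["onset"]),
                    [Treatment.from_dict(t) for t in st["treatments"]],
                )
                for st in data["stages"]
            ],
            duration=float(data["duration"]),
            initial_policy=data.get("initial_policy", "physiological"),
            name=data.get("name", ""),
        )


def standard_protocol(
    treatments: list[str],
    pre_treatments: list[str] | None = None,
    duration: float = 120.0,
    onset: float = 30.0,
) -> Protocol:
    """Build the standard one- or two-stage protocol.

    With pre-treatments, stage 0 applies them at t = 0 and the main
    treatments start at ``onset`` (default 30 min, the Compound C
    pre-incubation window); without, the main treatments start at t = 0.
    An empty treatment list yields the control protocol (no overrides).
    """
    pre = [get_treatment(n) for n in (pre_treatments or [])]
    main = [get_treatment(n) for n in treatments]
    name = "+".join((pre_treatments or []) + list(treatments)) or "control"
    if pre:
        stages = [(0.0, pre), (float(onset), main)]
    else:
        stages = [(0.0, main)]
    return Protocol(stages=stages, duration=float(duration), name=name)
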