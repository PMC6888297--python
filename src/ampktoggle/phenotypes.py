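"""Qualitative phenotype calls, the mutant-scenario matrix, and orderings.

Immunoblot read-outs in the underlying experiments are reported as
significant/non-significant band changes, not absolute numbers, so
trajectories are summarised by declared, configurable thresholds on the
active fractions: a read-out is HIGH if it ends at or above θ_high
(default 0.5 of total), LOW if it never reaches θ_high, and TRANSIENT if
it peaks at or above θ_high but ends at or below θ_low (default 0.25).
A trajectory that peaks high and ends between the thresholds fits none
of the three and is called PARTIAL; expectations never match it.

The scenario suite transcribes the expected qualitative outcome of every
single and combined treatment discussed for the model — 16 scenarios —
and `evaluate_matrix` scores a model variant against them.  Variant
comparisons (extended vs template network) start both variants from the
same reference resting state: the physiological steady state of the
extended model, which is the biological baseline the perturbation
experiments start from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ModelParameters,
    ModelState,
    ModelVariant,
    SPECIES,
    default_parameters,
)
from .perturbations import Protocol, standard_protocol
from .simulation import Trajectory, integrate, physiological_steady_state

__all__ = [
    "Thresholds",
    "PhenotypeCall",
    "ScenarioSpec",
    "MatrixReport",
    "EventOrdering",
    "classify",
    "scenario_suite",
    "evaluate_matrix",
    "compare_variants",
    "event_ordering",
]

LEVELS = ("LOW", "HIGH", "TRANSIENT", "PARTIAL")


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds as fractions of the nominal totals."""

    theta_high: float = 0.5
    theta_low: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_low < self.theta_high:
            raise ValueError(
                f"need 0 < theta_low < theta_high, got "
                f"{self.theta_low}, {self.theta_high}"
            )


@dataclass
class PhenotypeCall:
    """Qualitative level plus peak/final summaries per read-out."""

    levels: dict[str, str]
    peaks: dict[str, float]
    peak_times: dict[str, float]
    finals: dict[str, float]

    def __getitem__(self, species: str) -> str:
        return self.levels[species]


def _call_one(x: np.ndarray, t: np.ndarray, hi: float, lo: float):
    peak = float(x.max())
    t_peak = float(t[int(x.argmax())])
    final = float(x[-1])
    if final >= hi:
        level = "HIGH"
    elif peak >= hi and final <= lo:
        level = "TRANSIENT"
    elif peak < hi:
        level = "LOW"
    else:
        level = "PARTIAL"
    return level, peak, t_peak, final


def classify(
    traj: Trajectory,
    thresholds: Thresholds | None = None,
    *,
    totals: dict[str, float] | None = None,
) -> PhenotypeCall:
    """Classify each read-out of a trajectory as LOW/HIGH/TRANSIENT.

    Thresholds are taken relative to the *nominal* totals (one unit per
    species by default) rather than any treatment-reduced total, so a
    knocked-down species reads LOW rather than "high fraction of almost
    nothing".  Boundary values resolve by the >= / < conventions of
    `_call_one`.  The call is invariant to resampling the trajectory at
    1-min or finer resolution.
    """
    thresholds = thresholds or Thresholds()
    if traj.protocol is not None and traj.duration < traj.protocol.duration:
        raise ValueError(
            f"trajectory ends at {traj.duration} min but the protocol "
            f"runs to {traj.protocol.duration} min"
        )
    totals = totals or {s: 1.0 for s in SPECIES}
    levels, peaks, peak_times, finals = {}, {}, {}, {}
    for s in SPECIES:
        hi = thresholds.theta_high * totals[s]
        lo = thresholds.theta_low * totals[s]
        levels[s], peaks[s], peak_times[s], finals[s] = _call_one(
            traj.series(s), traj.times, hi, lo
        )
    return PhenotypeCall(levels, peaks, peak_times, finals)


@dataclass
class ScenarioSpec:
    """A named perturbation with its expected qualitative outcome.

    ``expected`` maps read-outs to the *set* of acceptable levels; a
    read-out absent from the map (or mapped to None) is a wildcard.
    ``provenance`` records where the expectation is stated: ``main-text``
    expectations are always gated, ``appendix``/``predicted`` ones can be
    toggled out.
    """

    id: str
    treatments: list[str]
    pre_treatments: list[str]
    duration: float
    expected: dict[str, set[str] | None]
    provenance: str = "main-text"

    def protocol(self) -> Protocol:
        return standard_protocol(
            self.treatments, self.pre_treatments, self.duration
        )

    def matches(self, call: PhenotypeCall) -> tuple[bool, dict[str, str]]:
        """Match a call; returns (ok, {readout: 'got!=expected'} diffs)."""
        diffs = {}
        for s, allowed in self.expected.items():
            if allowed is None:
                continue
            if call[s] not in allowed:
                diffs[s] = f"{call[s]} not in {sorted(allowed)}"
        return (not diffs), diffs


def _exp(A=None, M=None, U=None, G=None) -> dict[str, set[str] | None]:
    def norm(x):
        if x is None:
            return None
        return {x} if isinstance(x, str) else set(x)

    return {"A": norm(A), "M": norm(M), "U": norm(U), "G": norm(G)}


def scenario_suite() -> list[ScenarioSpec]:
    """The 16-scenario mutant/treatment matrix.

    Single treatments run 120 min (drugs) or 6 h (starvation-class
    stresses, matching the experimental windows); combined siRNA/drug
    protocols put the silencing 30 min ahead of the drug.  ACTIVE below
    abbreviates {HIGH, TRANSIENT} — used where the expectation is
    "becomes significantly active" without committing to persistence.
    """
    ACTIVE = {"HIGH", "TRANSIENT"}
    # OFF: inactive at the end of the window.  M starts at its high
    # physiological baseline, so "switched off" reads as TRANSIENT when a
    # pre-stage keeps it up for a while and LOW when the drug acts at t=0.
    OFF = {"LOW", "TRANSIENT"}
    S = ScenarioSpec
    suite = [
        # -- untreated control: mTOR active, everything else off
        S("control", [], [], 120.0,
          _exp(A="LOW", M="HIGH", U="LOW", G="LOW")),
        # -- single stresses/drugs
        S("rapamycin", ["rapamycin"], [], 120.0,
          _exp(A="TRANSIENT", M="LOW", U="HIGH", G="HIGH")),
        S("starvation", ["starvation"], [], 360.0,
          _exp(A="TRANSIENT", M=OFF, U="HIGH", G="HIGH")),
        S("resveratrol", ["resveratrol"], [], 360.0,
          _exp(A="TRANSIENT", M=OFF, U="HIGH", G="HIGH"),
          provenance="predicted"),
        S("compound_c", ["compound_c"], [], 120.0,
          _exp(A="LOW", M="HIGH", U="LOW", G="LOW")),
        # -- silencing / hyper-activation: AMPK-P must NOT rise
        S("si_ulk1", ["si_ulk1"], [], 360.0,
          _exp(A="LOW", M="HIGH", U="LOW", G="LOW")),
        S("si_tsc12", ["si_tsc12"], [], 360.0,
          _exp(A="LOW", M="HIGH", U="LOW", G="LOW")),
        S("mtor_hyper", ["mtor_hyper"], [], 360.0,
          _exp(A="LOW", M="HIGH", U="LOW", G="LOW")),
        S("ampk_hyper", ["ampk_hyper"], [], 360.0,
          _exp(A=ACTIVE, M=OFF, U="HIGH", G="HIGH")),
        # -- ULK1 silencing combined with mTOR inhibition / AMPK activation:
        #    AMPK-P permanently high, yet no autophagy
        S("si_ulk1+rapamycin", ["rapamycin"], ["si_ulk1"], 150.0,
          _exp(A="HIGH", M=OFF, U="LOW", G="LOW")),
        S("si_ulk1+starvation", ["starvation"], ["si_ulk1"], 390.0,
          _exp(A="HIGH", M=OFF, U="LOW", G="LOW")),
        S("si_ulk1+resveratrol", ["resveratrol"], ["si_ulk1"], 390.0,
          _exp(A="HIGH", M=OFF, U="LOW", G="LOW"),
          provenance="predicted"),
        # -- TSC1/2 silencing combinations: rapamycin wins over
        #    hyper-activation, milder AMPK activators do not
        S("si_tsc12+rapamycin", ["rapamycin"], ["si_tsc12"], 150.0,
          _exp(A=ACTIVE, M=OFF, U=None, G=ACTIVE)),
        S("si_tsc12+starvation", ["starvation"], ["si_tsc12"], 390.0,
          _exp(A="LOW", M="HIGH", U="LOW", G="LOW")),
        S("si_tsc12+resveratrol", ["resveratrol"], ["si_tsc12"], 390.0,
          _exp(A="LOW", M="HIGH", U="LOW", G="LOW")),
        # -- AMPK inhibition blocks the whole cascade even without mTOR
        S("compound_c+rapamycin", ["rapamycin"], ["compound_c"], 150.0,
          _exp(A="LOW", M=OFF, U="LOW", G="LOW")),
    ]
    return suite


@dataclass
class MatrixReport:
    """Scored comparison of simulations against the scenario suite."""

    variant: ModelVariant
    rows: list[dict]
    matched: int
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"matched {self.matched} of {self.total} scenarios"]
        for r in self.rows:
            status = "ok  " if r["match"] else "MISS"
            calls = " ".join(f"{s}={r[f'call_{s}']}" for s in SPECIES)
            extra = f"  [{r['diffs']}]" if r["diffs"] else ""
            lines.append(f"  {status} {r['scenario']:24s} {calls}{extra}")
        return "\n".join(lines)


def _reference_state(
    params: ModelParameters, n_starts: int = 64, seed: int = 0
) -> ModelState:
    """Physiological resting state of the extended model at base params."""
    return physiological_steady_state(
        params, ModelVariant(), n_starts=n_starts, seed=seed
    )


def evaluate_matrix(
    suite: list[ScenarioSpec] | None = None,
    params: ModelParameters | None = None,
    variant: ModelVariant | None = None,
    *,
    thresholds: Thresholds | None = None,
    include_provenance: tuple[str, ...] = (
        "main-text", "appendix", "predicted",
    ),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> MatrixReport:
    """Run, classify, and diff every scenario against its expectation.

    Simulation failures are recorded per-scenario and count as
    mismatches.  All scenarios start from the reference resting state
    (see module docstring), so an ablated variant is scored on how the
    *response* differs, not on a different baseline.
    """
    suite = suite if suite is not None else scenario_suite()
    if not suite:
        raise ValueError("scenario suite is empty")
    params = params or default_parameters()
    variant = variant or ModelVariant()
    thresholds = thresholds or Thresholds()
    suite = [s for s in suite if s.provenance in include_provenance]
    y0 = _reference_state(params)

    rows = []
    matched = 0
    for spec in suite:
        row = {"scenario": spec.id, "provenance": spec.provenance}
        try:
            traj = integrate(
                spec.protocol(), params, variant,
                initial_state=y0, rtol=rtol, atol=atol,
            )
            call = classify(traj, thresholds)
            ok, diffs = spec.matches(call)
        except Exception as exc:  # recorded, counted as mismatch
            row.update(
                {f"call_{s}": "ERROR" for s in SPECIES}
            )
            row.update(match=False, diffs=f"simulation failed: {exc}")
            rows.append(row)
            continue
        for s in SPECIES:
            row[f"call_{s}"] = call[s]
            row[f"final_{s}"] = call.finals[s]
            row[f"peak_{s}"] = call.peaks[s]
        row["match"] = ok
        row["diffs"] = "; ".join(f"{k}: {v}" for k, v in diffs.items())
        matched += ok
        rows.append(row)
    return MatrixReport(
        variant=variant, rows=rows, matched=matched, total=len(suite)
    )


def compare_variants(
    scenario: ScenarioSpec | str,
    params: ModelParameters | None = None,
    *,
    thresholds: Thresholds | None = None,
) -> dict:
    """Final levels for the extended vs template variant, shared start.

    Both variants run the identical protocol from the same reference
    resting state; the headline statistic is the difference in final
    AMPK-P (template minus extended), the read-out on which the two
    wirings disagree for the silencing/hyper-activation experiments.
    """
    params = params or default_parameters()
    thresholds = thresholds or Thresholds()
    if isinstance(scenario, str):
        matches = [s for s in scenario_suite() if s.id == scenario]
        if not matches:
            raise KeyError(f"unknown scenario {scenario!r}")
        scenario = matches[0]
    y0 = _reference_state(params)
    out: dict = {"scenario": scenario.id}
    for key, variant in (
        ("extended", ModelVariant()),
        ("template", ModelVariant(mtor_inhibits_ampk=False)),
    ):
        traj = integrate(
            scenario.protocol(), params, variant, initial_state=y0
        )
        call = classify(traj, thresholds)
        out[key] = {
            "levels": dict(call.levels),
            "finals": dict(call.finals),
            "peaks": dict(call.peaks),
        }
    out["ampk_final_difference"] = (
        out["template"]["finals"]["A"] - out["extended"]["finals"]["A"]
    )
    return out


@dataclass
class EventOrdering:
    """First-crossing times (min); None where never crossed.

    ``rise[s]`` is the first time read-out s reaches θ_high from below;
    ``fall[s]`` the first time it drops to θ_low after having been above.
    """

    rise: dict[str, float | None]
    fall: dict[str, float | None]


def event_ordering(
    traj: Trajectory,
    thresholds: Thresholds | None = None,
    *,
    totals: dict[str, float] | None = None,
    baseline: ModelState | None = None,
) -> EventOrdering:
    """Threshold-crossing times per read-out.

    ``baseline`` (default: the trajectory's own first sample) is the
    pre-treatment state the fall events are judged against: a read-out
    only "falls" if it was above θ_low at baseline or earlier in the
    trajectory.  Passing the resting state catches falls completed by
    the conservation clamp at treatment onset (e.g. active mTOR at
    rapamycin addition).
    """
    thresholds = thresholds or Thresholds()
    totals = totals or {s: 1.0 for s in SPECIES}
    base = (
        baseline.to_dict()
        if baseline is not None
        else {s: traj.series(s)[0] for s in SPECIES}
    )
    rise: dict[str, float | None] = {}
    fall: dict[str, float | None] = {}
    for s in SPECIES:
        x = traj.series(s)
        hi = thresholds.theta_high * totals[s]
        lo = thresholds.theta_low * totals[s]
        up = np.nonzero(x >= hi)[0]
        rise[s] = float(traj.times[up[0]]) if up.size else None
        fall[s] = None
        above = np.nonzero(x > lo)[0]
        start = None
        if base[s] > lo:
            start = 0
        elif above.size:
            start = int(above[0])
        if start is not None:
            after = np.nonzero((np.arange(x.size) >= start) & (x <= lo))[0]
            if after.size:
                fall[s] = float(traj.times[after[0]])
    return EventOrdering(rise=rise, fall=fall)
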