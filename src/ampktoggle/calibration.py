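"""Parameter calibration from qualitative constraints, and time-course fits.

Two distinct jobs live here:

* :func:`calibrate` — derive/verify a parameter set against *qualitative*
  constraints (the phenotype matrix plus the existence of a bistable
  stress window).  The shipped defaults are the product of this
  procedure: Latin-hypercube screening over log-uniform ranges followed
  by coordinate-wise multiplicative refinement.  Values the modelling
  conventions fix (kamtor = 0.025, unit totals, no basal ULK1
  activation) are never searched.
* :func:`fit_time_course` — ordinary multi-start least squares of
  selected rate constants against (synthetic) densitometry tables, used
  for parameter-recovery experiments.  Identifiability is not assumed:
  more than three simultaneous free parameters triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats.qmc import LatinHypercube

from .model import ModelParameters, ModelVariant, default_parameters, validate
from .phenotypes import (
    ScenarioSpec,
    Thresholds,
    classify,
    evaluate_matrix,
    scenario_suite,
)
from .simulation import integrate, physiological_steady_state
from .bifurcation import scan

__all__ = [
    "QualitativeConstraint",
    "CalibrationResult",
    "FitResult",
    "InfeasibleConstraintsError",
    "default_constraints",
    "calibrate",
    "fit_time_course",
]


class InfeasibleConstraintsError(ValueError):
    """The constraint set is self-contradictory."""


@dataclass(frozen=True)
class QualitativeConstraint:
    """Require a scenario read-out to land in an allowed level set."""

    scenario_id: str
    readout: str
    allowed: frozenset[str]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.readout not in ("A", "M", "U", "G"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if not self.allowed:
            raise ValueError("allowed level set is empty")


def default_constraints(
    suite: list[ScenarioSpec] | None = None,
) -> list[QualitativeConstraint]:
    """Flatten the scenario suite's expectations into constraints."""
    out = []
    for spec in suite if suite is not None else scenario_suite():
        for readout, allowed in spec.expected.items():
            if allowed is None:
                continue
            out.append(
                QualitativeConstraint(
                    spec.id, readout, frozenset(allowed)
                )
            )
    return out


def _check_feasible(constraints: list[QualitativeConstraint]) -> None:
    joint: dict[tuple[str, str], frozenset] = {}
    for c in constraints:
        key = (c.scenario_id, c.readout)
        joint[key] = joint.get(key, c.allowed) & c.allowed
        if not joint[key]:
            raise InfeasibleConstraintsError(
                f"contradictory constraints on {key[0]}/{key[1]}"
            )


def _margin_shortfall(
    level: str, peak: float, final: float, allowed: frozenset[str],
    thresholds: Thresholds,
) -> float:
    """How far (in level units) a call is from satisfying a constraint."""
    if level in allowed:
        return 0.0
    hi, lo = thresholds.theta_high, thresholds.theta_low
    short = []
    for want in allowed:
        if want == "HIGH":
            short.append(max(hi - final, 0.0))
        elif want == "LOW":
            short.append(max(peak - hi, 0.0))
        elif want == "TRANSIENT":
            short.append(max(hi - peak, 0.0) + max(final - lo, 0.0))
    return min(short) if short else 1.0


@dataclass
class CalibrationResult:
    params: ModelParameters
    score: float
    n_violations: int
    violations: list[str]
    evaluations: int
    seed: int
    converged: bool
    #: best score after each accepted step (monotone non-increasing)
    history: list[float] = field(default_factory=list)


def _penalty(
    params: ModelParameters,
    variant: ModelVariant,
    constraints: list[QualitativeConstraint],
    thresholds: Thresholds,
    suite_by_id: dict[str, ScenarioSpec],
    require_bistability: bool,
    bistability_range: tuple[float, float],
) -> tuple[float, list[str]]:
    """Weighted violation count + margin shortfalls (0 = all satisfied)."""
    if validate(params):
        return float("inf"), ["invalid parameters"]
    score = 0.0
    violated: list[str] = []
    needed = sorted({c.scenario_id for c in constraints})
    calls = {}
    try:
        y0 = physiological_steady_state(params, variant)
    except Exception as exc:
        return float("inf"), [f"no physiological steady state: {exc}"]
    for sid in needed:
        spec = suite_by_id[sid]
        try:
            traj = integrate(
                spec.protocol(), params, variant, initial_state=y0,
                rtol=1e-6, atol=1e-9,
            )
            calls[sid] = classify(traj, thresholds)
        except Exception:
            calls[sid] = None
    for c in constraints:
        call = calls[c.scenario_id]
        if call is None:
            score += c.weight * 2.0
            violated.append(f"{c.scenario_id}/{c.readout}: simulation failed")
            continue
        shortfall = _margin_shortfall(
            call[c.readout], call.peaks[c.readout],
            call.finals[c.readout], c.allowed, thresholds,
        )
        if call[c.readout] not in c.allowed:
            score += c.weight * (1.0 + shortfall)
            violated.append(
                f"{c.scenario_id}/{c.readout}: {call[c.readout]} "
                f"not in {sorted(c.allowed)}"
            )
    if require_bistability:
        d = scan("S", bistability_range, 25, params, variant,
                 n_starts=12, seed=0)
        if not d.bistable_intervals:
            score += 1.0
            violated.append("no bistable S window in "
                            f"{list(bistability_range)}")
    return score, violated


# parameters that calibration may touch; conventions fix the rest
_SEARCHABLE = (
    "kaA", "kiA", "kiAU", "kiAM", "kiM", "kiMA", "kiMU",
    "kaUA", "kiU", "kiUM", "kaG0", "kaGU", "kiG", "kiGM",
    "JaA", "JiA", "JaM", "JiM", "JaU", "JiU", "JaG", "JiG",
)


def calibrate(
    constraints: list[QualitativeConstraint] | None = None,
    search_space: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    budget: int = 5000,
    *,
    params: ModelParameters | None = None,
    variant: ModelVariant | None = None,
    thresholds: Thresholds | None = None,
    require_bistability: bool = False,
    bistability_range: tuple[float, float] = (0.8, 2.4),
) -> CalibrationResult:
    """Search parameters until the qualitative constraints are satisfied.

    ``search_space`` maps parameter names to (lo, hi) bounds sampled
    log-uniformly; an empty/None space scores the starting parameters
    and returns them unchanged.  The search is Latin-hypercube screening
    (half the budget) followed by coordinate-wise multiplicative
    refinement, reproducible from ``seed``.  If the budget runs out with
    violations remaining, the best-found set is returned with
    ``converged=False``.
    """
    constraints = (
        constraints if constraints is not None else default_constraints()
    )
    if not constraints:
        raise ValueError("need at least one constraint")
    _check_feasible(constraints)
    params = params or default_parameters()
    variant = variant or ModelVariant()
    thresholds = thresholds or Thresholds()
    suite_by_id = {s.id: s for s in scenario_suite()}
    missing = {c.scenario_id for c in constraints} - set(suite_by_id)
    if missing:
        raise KeyError(f"constraints reference unknown scenarios: {missing}")
    for name in search_space or {}:
        if name not in _SEARCHABLE:
            raise KeyError(
                f"{name!r} is not searchable (fixed by convention or unknown)"
            )

    def score_of(p):
        return _penalty(
            p, variant, constraints, thresholds, suite_by_id,
            require_bistability, bistability_range,
        )

    best_params = params
    best_score, best_viol = score_of(params)
    history = [best_score]
    evals = 1

    if search_space and best_score > 0.0:
        names = sorted(search_space)
        lo = np.log(np.array([search_space[n][0] for n in names]))
        hi = np.log(np.array([search_space[n][1] for n in names]))
        rng = np.random.default_rng(seed)

        n_screen = max(min(budget // 2, budget - 1), 0)
        if n_screen:
            lhs = LatinHypercube(d=len(names), seed=seed)
            samples = np.exp(lo + lhs.random(n_screen) * (hi - lo))
            for row in samples:
                cand = params.replace(**dict(zip(names, row)))
                s, v = score_of(cand)
                evals += 1
                if s < best_score:
                    best_params, best_score, best_viol = cand, s, v
                    history.append(s)
                if best_score == 0.0:
                    break

        # coordinate-wise multiplicative refinement around the incumbent
        step = 1.5
        while evals < budget and best_score > 0.0 and step > 1.01:
            improved = False
            for name in names:
                if evals >= budget:
                    break
                cur = getattr(best_params, name)
                for factor in (step, 1.0 / step):
                    val = float(
                        np.clip(cur * factor,
                                search_space[name][0], search_space[name][1])
                    )
                    cand = best_params.replace(**{name: val})
                    s, v = score_of(cand)
                    evals += 1
                    if s < best_score:
                        best_params, best_score, best_viol = cand, s, v
                        history.append(s)
                        improved = True
                        break
            if not improved:
                step = step ** 0.5
            _ = rng  # rng reserved for future stochastic moves

    return CalibrationResult(
        params=best_params,
        score=best_score,
        n_violations=len(best_viol),
        violations=best_viol,
        evaluations=evals,
        seed=seed,
        converged=(best_score == 0.0),
        history=history,
    )


@dataclass
class FitResult:
    """Outcome of a least-squares time-course fit."""

    estimates: dict[str, float]
    loss: float
    relative_errors: dict[str, float] | None
    n_evaluations: int
    n_starts: int
    success: bool
    seed: int


def fit_time_course(
    table,
    free_params: list[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    *,
    params: ModelParameters | None = None,
    variant: ModelVariant | None = None,
    truth: ModelParameters | None = None,
    n_starts: int = 3,
    max_nfev: int = 200,
) -> FitResult:
    """Fit selected parameters to a densitometry table.

    The loss is the sum of squared differences between the table's
    replicate-mean read-out values and the model's read-outs at the
    table's time points, integrated under the table's own protocol.
    Optimisation is multi-start trust-region least squares in
    log-parameter space; starts are reproducible from ``seed``.  With
    ``truth`` given (recovery experiments), per-parameter relative
    errors are reported.
    """
    from .synthetic import model_readout_values  # local: avoid cycle

    params = params or default_parameters()
    variant = variant or ModelVariant()
    if len(free_params) == 0:
        loss = _table_loss(table, params, variant, model_readout_values)
        return FitResult(
            estimates={}, loss=loss, relative_errors=None,
            n_evaluations=1, n_starts=0, success=True, seed=seed,
        )
    unknown = set(free_params) - set(params.to_dict())
    if unknown:
        raise KeyError(f"unknown free parameter(s): {sorted(unknown)}")
    if len(free_params) > 3:
        warnings.warn(
            "fitting more than 3 parameters simultaneously is rarely "
            "identifiable from a 5-point time course",
            stacklevel=2,
        )
    bounds = bounds or {}
    lo = np.array([
        np.log(bounds.get(n, (getattr(params, n) / 30.0,))[0])
        for n in free_params
    ])
    hi = np.array([
        np.log(bounds.get(n, (None, getattr(params, n) * 30.0))[-1])
        for n in free_params
    ])

    target = _table_target(table)
    nfev_total = 0

    def residuals(logx):
        values = dict(zip(free_params, np.exp(logx)))
        p = params.replace(**values)
        try:
            model = model_readout_values(
                table.protocol, p, variant, table.timepoints,
                rtol=1e-6, atol=1e-9,
            )
        except Exception:
            return np.full(target[1].size, 1e3)
        return (
            np.array([model[r] for r in target[0]]).ravel() - target[1]
        )

    rng = np.random.default_rng(seed)
    x0s = [np.log(np.array([getattr(params, n) for n in free_params]))]
    x0s += [lo + rng.random(len(free_params)) * (hi - lo)
            for _ in range(n_starts - 1)]

    best = None
    for x0 in x0s:
        sol = least_squares(
            residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
            max_nfev=max_nfev, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        nfev_total += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("optimizer failed from all starts")

    estimates = dict(zip(free_params, np.exp(best.x)))
    rel = None
    if truth is not None:
        rel = {
            n: abs(estimates[n] - getattr(truth, n))
            / abs(getattr(truth, n))
            for n in free_params
        }
    return FitResult(
        estimates=estimates,
        loss=float(2 * best.cost),
        relative_errors=rel,
        n_evaluations=nfev_total,
        n_starts=len(x0s),
        success=bool(best.success),
        seed=seed,
    )


def _table_target(table):
    """(readout order, flat replicate-mean values) for the loss."""
    means = table.replicate_means()
    readouts = sorted(means)
    flat = np.concatenate([means[r] for r in readouts])
    return readouts, flat


def _table_loss(table, params, variant, model_readout_values) -> float:
    readouts, flat = _table_target(table)
    model = model_readout_values(
        table.protocol, params, variant, table.timepoints
    )
    pred = np.concatenate([model[r] for r in readouts])
    return float(np.sum((pred - flat) ** 2))
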