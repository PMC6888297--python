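"""One-parameter steady-state scans, hysteresis, and nullclines.

The AMPK–mTOR mutual antagonism (AMPK ┤ mTOR ┤ AMPK) makes the system a
candidate bistable toggle: over a window of the stress input S two
stable steady states coexist — a growth state (mTOR active) and an
autophagy state (ULK1/ATG active) — separated by a saddle.  The scan
tracks steady states across a parameter range by brute-force multi-start
root finding seeded from neighbouring columns (no dedicated continuation
solver: the system is 4-D and desk-scale).  Fold locations are reported
as grid brackets, not refined to machine precision.

Nullclines live in the (A, M) plane with U and G at quasi-steady state;
the reduction is for visualisation — every quantitative claim uses the
full 4-D system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .model import (
    ModelParameters,
    ModelState,
    ModelVariant,
    SPECIES,
    rhs_vector,
)
from .simulation import (
    integrate_to_steady,
    jacobian,
    physiological_steady_state,
    steady_states,
)

__all__ = [
    "BifurcationDiagram",
    "NullclineSet",
    "HysteresisResult",
    "scan",
    "hysteresis_scan",
    "nullclines",
]


@dataclass
class BifurcationDiagram:
    """Steady states (with stability) per scanned parameter value."""

    param_name: str
    values: np.ndarray
    #: per scan value: list of (state, stable) pairs
    states: list[list[tuple[ModelState, bool]]]
    #: (lower, upper) grid brackets of scan values with >= 2 stable states
    bistable_intervals: list[tuple[float, float]]
    #: scan values where the steady-state search failed (reported, not fatal)
    failed_values: list[float] = field(default_factory=list)

    def n_stable(self) -> np.ndarray:
        return np.array(
            [sum(1 for _, ok in col if ok) for col in self.states]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, col in zip(self.values, self.states):
            for st, stable in col:
                rows.append(
                    {"param_value": v, **st.to_dict(), "stable": stable}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "param_name", self.param_name)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BifurcationDiagram":
        df = pd.read_csv(path)
        name = str(df["param_name"].iloc[0])
        values = np.array(sorted(df["param_value"].unique()))
        states = []
        for v in values:
            sub = df[df["param_value"] == v]
            states.append(
                [
                    (ModelState(r.A, r.M, r.U, r.G), bool(r.stable))
                    for r in sub.itertuples()
                ]
            )
        diagram = cls(
            param_name=name, values=values, states=states,
            bistable_intervals=[],
        )
        diagram.bistable_intervals = _bistable_intervals(
            values, diagram.n_stable()
        )
        return diagram

    def verify_roots(
        self,
        params: ModelParameters,
        variant: ModelVariant,
        tol: float = 1e-8,
    ) -> bool:
        """Re-check that every recorded state is an RHS root."""
        for v, col in zip(self.values, self.states):
            p = params.replace(**{self.param_name: float(v)})
            for st, _ in col:
                if np.max(np.abs(rhs_vector(st.to_array(), p, variant))) > tol:
                    return False
        return True


def _bistable_intervals(
    values: np.ndarray, n_stable: np.ndarray
) -> list[tuple[float, float]]:
    """Maximal runs of scan values carrying >= 2 stable states."""
    intervals = []
    in_run = False
    lo = 0.0
    for v, n in zip(values, n_stable):
        if n >= 2 and not in_run:
            in_run, lo = True, float(v)
        elif n < 2 and in_run:
            intervals.append((lo, float(prev)))
            in_run = False
        prev = v
    if in_run:
        intervals.append((lo, float(values[-1])))
    return intervals


def scan(
    param_name: str,
    value_range: tuple[float, float],
    n_points: int,
    params: ModelParameters,
    variant: ModelVariant | None = None,
    *,
    n_starts: int = 32,
    seed: int = 0,
) -> BifurcationDiagram:
    """Steady-state scan over one parameter.

    Each column's multi-start root search is additionally seeded with
    every root of the neighbouring (previous) column, which tracks
    branches through folds at grid resolution.
    """
    if variant is None:
        variant = ModelVariant()
    if param_name not in params.to_dict():
        raise KeyError(f"unknown parameter {param_name!r}")
    lo, hi = value_range
    if hi < lo:
        raise ValueError(f"scan range reversed: [{lo}, {hi}]")
    if n_points < 1 or (n_points < 3 and hi > lo):
        raise ValueError("need n_points >= 3 (or a single-point range)")
    values = np.linspace(lo, hi, n_points)

    columns: list[list[tuple[ModelState, bool]]] = []
    failed: list[float] = []
    prev_roots: list[np.ndarray] = []
    for v in values:
        p = params.replace(**{param_name: float(v)})
        try:
            col = steady_states(
                p, variant, n_starts=n_starts, seed=seed,
                extra_starts=prev_roots or None,
            )
        except Exception:
            failed.append(float(v))
            columns.append([])
            continue
        columns.append(col)
        prev_roots = [st.to_array() for st, _ in col]

    n_stable = np.array([sum(1 for _, ok in c if ok) for c in columns])
    return BifurcationDiagram(
        param_name=param_name,
        values=values,
        states=columns,
        bistable_intervals=_bistable_intervals(values, n_stable),
        failed_values=failed,
    )


@dataclass
class HysteresisResult:
    """Forward/backward quasi-static sweeps over a parameter."""

    param_name: str
    values: np.ndarray
    forward: np.ndarray   # states selected sweeping lo -> hi
    backward: np.ndarray  # states selected sweeping hi -> lo
    #: scan values where forward and backward selections differ
    disagreement: np.ndarray

    @property
    def window(self) -> tuple[float, float] | None:
        vals = self.values[self.disagreement]
        if vals.size == 0:
            return None
        return float(vals.min()), float(vals.max())


def hysteresis_scan(
    param_name: str,
    value_range: tuple[float, float],
    n_points: int,
    params: ModelParameters,
    variant: ModelVariant | None = None,
    *,
    state_tol: float = 0.1,
) -> HysteresisResult:
    """Quasi-static forward and backward sweeps.

    Each sweep carries the relaxed state of the previous value as the
    initial condition and integrates to steady state, mimicking a slow
    ramp of the parameter.  Disagreement between the two sweeps brackets
    the bistable (hysteresis) window.
    """
    if variant is None:
        variant = ModelVariant()
    lo, hi = value_range
    if hi <= lo:
        raise ValueError(f"need an increasing range, got [{lo}, {hi}]")
    values = np.linspace(lo, hi, n_points)

    def sweep(vals):
        out = np.empty((vals.size, len(SPECIES)))
        y = None
        for i, v in enumerate(vals):
            p = params.replace(**{param_name: float(v)})
            if y is None:
                y = physiological_steady_state(p, variant).to_array()
            y = integrate_to_steady(p, variant, y)
            out[i] = y
        return out

    fwd = sweep(values)
    bwd = sweep(values[::-1])[::-1]
    disagreement = np.max(np.abs(fwd - bwd), axis=1) > state_tol
    return HysteresisResult(
        param_name=param_name,
        values=values,
        forward=fwd,
        backward=bwd,
        disagreement=disagreement,
    )


# ---------------------------------------------------------------------------
# Phase-plane reduction: (A, M) with U and G at quasi-steady state


def _qss_u(A: float, M: float, params: ModelParameters,
           variant: ModelVariant) -> float:
    """Quasi-steady ULK1-P level for frozen (A, M); unique in [0, UT]."""
    p = params
    kaUA = p.kaUA if variant.ampk_activates_ulk1 else 0.0
    kiUM = p.kiUM if variant.mtor_inhibits_ulk1 else 0.0

    def du(U):
        return (
            kaUA * A * (p.UT - U) / (p.JaU + p.UT - U)
            - (p.kiU + kiUM * M) * U / (p.JiU + U)
        )

    if du(0.0) <= 0.0:
        return 0.0
    if du(p.UT) >= 0.0:
        return p.UT
    return brentq(du, 0.0, p.UT, xtol=1e-14)


def _qss_g(U: float, M: float, params: ModelParameters,
           variant: ModelVariant) -> float:
    p = params
    kaGU = p.kaGU if variant.ulk1_activates_atg else 0.0
    kiGM = p.kiGM if variant.mtor_inhibits_atg else 0.0

    def dg(G):
        return (
            (p.kaG0 + kaGU * U) * (p.GT - G) / (p.JaG + p.GT - G)
            - (p.kiG + kiGM * M) * G / (p.JiG + G)
        )

    if dg(0.0) <= 0.0:
        return 0.0
    if dg(p.GT) >= 0.0:
        return p.GT
    return brentq(dg, 0.0, p.GT, xtol=1e-14)


def reduced_field(
    A: float, M: float, params: ModelParameters, variant: ModelVariant
) -> np.ndarray:
    """(dA/dt, dM/dt) with U, G replaced by their quasi-steady values."""
    U = _qss_u(A, M, params, variant)
    G = _qss_g(U, M, params, variant)
    d = rhs_vector(np.array([A, M, U, G]), params, variant)
    return np.array([d[0], d[1]])


@dataclass
class NullclineSet:
    """Sampled dA/dt = 0 and dM/dt = 0 curves in the reduced (A, M) plane."""

    a_nullcline: np.ndarray  # (n, 2) points (A, M) where dA/dt = 0
    m_nullcline: np.ndarray  # (n, 2) points (A, M) where dM/dt = 0
    intersections: list[tuple[ModelState, bool]]
    #: ratio of the slowest U/G relaxation rate to the fastest A/M rate;
    #: >> 1 means the quasi-steady-state reduction is well separated
    timescale_ratio: float
    failures: list[tuple[float, float]] = field(default_factory=list)


def nullclines(
    params: ModelParameters,
    variant: ModelVariant | None = None,
    grid: int = 101,
    *,
    seed: int = 0,
) -> NullclineSet:
    """Sample both nullclines and locate their intersections.

    Curve points come from per-gridline sign changes refined by Brent's
    method; intersections are polished on the reduced 2-D system and
    tagged with the *full* system's stability at the lifted state.
    """
    if variant is None:
        variant = ModelVariant()
    p = params
    a_vals = np.linspace(0.0, p.AT, grid)
    m_vals = np.linspace(0.0, p.MT, grid)

    def dA(A, M):
        return reduced_field(A, M, p, variant)[0]

    def dM(A, M):
        return reduced_field(A, M, p, variant)[1]

    failures: list[tuple[float, float]] = []

    def trace(fun, outer_vals, inner_vals, outer_is_m):
        pts = []
        for ov in outer_vals:
            g = []
            for iv in inner_vals:
                A, M = (iv, ov) if outer_is_m else (ov, iv)
                try:
                    g.append(fun(A, M))
                except Exception:
                    failures.append((A, M))
                    g.append(np.nan)
            g = np.asarray(g)
            for i in range(len(inner_vals) - 1):
                if np.isnan(g[i]) or np.isnan(g[i + 1]):
                    continue
                if g[i] == 0.0:
                    root = inner_vals[i]
                elif g[i] * g[i + 1] < 0:
                    f1 = (lambda x: fun(x, ov)) if outer_is_m else (
                        lambda x: fun(ov, x))
                    root = brentq(f1, inner_vals[i], inner_vals[i + 1],
                                  xtol=1e-12)
                else:
                    continue
                pts.append((root, ov) if outer_is_m else (ov, root))
        return np.array(pts) if pts else np.empty((0, 2))

    # dA/dt = 0: solve for A along lines of constant M, and vice versa,
    # so folds in either direction are captured
    a_null = np.concatenate([
        trace(dA, m_vals, a_vals, outer_is_m=True),
        trace(dA, a_vals, m_vals, outer_is_m=False),
    ])
    m_null = np.concatenate([
        trace(dM, m_vals, a_vals, outer_is_m=True),
        trace(dM, a_vals, m_vals, outer_is_m=False),
    ])

    # intersections: polish the reduced system from near-coincidences
    seeds = []
    if a_null.size and m_null.size:
        for ax, ay in a_null[:: max(len(a_null) // 200, 1)]:
            d2 = (m_null[:, 0] - ax) ** 2 + (m_null[:, 1] - ay) ** 2
            if d2.min() < (2.0 / grid) ** 2:
                seeds.append((ax, ay))
    roots: list[np.ndarray] = []
    for s in seeds:
        sol = least_squares(
            lambda x: reduced_field(x[0], x[1], p, variant),
            np.clip(s, 0.0, [p.AT, p.MT]),
            bounds=([0, 0], [p.AT, p.MT]),
            xtol=3e-16, ftol=3e-16, gtol=3e-16,
        )
        r = sol.x
        if np.max(np.abs(reduced_field(r[0], r[1], p, variant))) > 1e-10:
            continue
        if not any(np.max(np.abs(r - q)) < 1e-5 for q in roots):
            roots.append(r)

    intersections = []
    for A, M in roots:
        U = _qss_u(A, M, p, variant)
        G = _qss_g(U, M, p, variant)
        y = np.array([A, M, U, G])
        eig = np.linalg.eigvals(jacobian(y, p, variant))
        intersections.append(
            (ModelState.from_array(y), bool(np.all(eig.real < 0.0)))
        )

    # time-scale diagnostic at the physiological state
    try:
        y0 = physiological_steady_state(p, variant).to_array()
        J = jacobian(y0, p, variant)
        fast = max(abs(J[2, 2]), abs(J[3, 3]))
        slow = max(abs(J[0, 0]), abs(J[1, 1]))
        ratio = float(fast / slow) if slow > 0 else np.inf
    except Exception:
        ratio = float("nan")
    return NullclineSet(
        a_nullcline=a_null,
        m_nullcline=m_null,
        intersections=intersections,
        timescale_ratio=ratio,
        failures=failures,
    )
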