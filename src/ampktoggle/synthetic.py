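"""Synthetic densitometry: immunoblot-like tables from model trajectories.

The generator emulates quantified, loading-control-normalised band
intensities for the read-outs the experiments track:

==============  =================  =================================
table read-out  model species      mapping
==============  =================  =================================
AMPK_pT172      A                  identity (normalised to total AMPK)
p70S6K_P        M                  identity (proxy for mTORC1 activity)
ULK1_pS555      U                  identity (normalised to total ULK1)
LC3II           G                  identity (autophagosome marker)
p62             G                  baseline·(1−G) + floor — p62 is
                                   *degraded* by autophagy; the floor
                                   (0.1·baseline) keeps residual signal
==============  =================  =================================

Noise is multiplicative lognormal, mean-corrected so every noisy cell is
unbiased for its noise-free value, with a per-lane loading-control
factor shared across the read-outs of one replicate at one time point
(one gel lane, one GAPDH band).  Replicates default to 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParameters, ModelVariant, default_parameters
from .perturbations import Protocol, standard_protocol
from .simulation import Trajectory, integrate

__all__ = [
    "READOUTS",
    "NoiseModel",
    "DensitometryTable",
    "readout_transform",
    "model_readout_values",
    "generate",
    "fixture_suite",
]

P62_BASELINE = 1.0
P62_FLOOR = 0.1 * P62_BASELINE

#: read-out name -> model species it derives from
READOUTS = {
    "AMPK_pT172": "A",
    "p70S6K_P": "M",
    "ULK1_pS555": "U",
    "LC3II": "G",
    "p62": "G",
}


def readout_transform(readout: str, level: np.ndarray) -> np.ndarray:
    """Noise-free band intensity for a read-out given the species level."""
    if readout == "p62":
        return P62_BASELINE * (1.0 - np.asarray(level)) + P62_FLOOR
    return np.asarray(level)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise for band densitometry.

    ``cv`` is the per-read-out coefficient of variation (a single float
    applies to all read-outs); ``loading_cv`` the per-lane normalisation
    CV.  Both lognormal factors are mean-corrected (E[factor] = 1), so
    the expected value of a noisy cell is its noise-free value.
    """

    cv: float = 0.10
    loading_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.loading_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need n_replicates >= 1")

    def _factor(self, rng: np.random.Generator, cv: float, size) -> np.ndarray:
        if cv == 0.0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(cv ** 2))
        return np.exp(rng.normal(0.0, sigma, size) - sigma ** 2 / 2.0)


@dataclass
class DensitometryTable:
    """Tidy replicate table of band intensities.

    ``data`` columns: time_min, readout, replicate, value.  The protocol
    that produced the underlying trajectory travels with the table so
    fitting can re-simulate it.
    """

    data: pd.DataFrame
    timepoints: np.ndarray
    protocol: Protocol
    noise: NoiseModel | None = None

    def __post_init__(self) -> None:
        if (self.data["value"] <= 0).any():
            raise ValueError("band intensities must be > 0")

    def values(self, readout: str) -> np.ndarray:
        """(n_timepoints, n_replicates) matrix for one read-out."""
        sub = self.data[self.data["readout"] == readout]
        wide = sub.pivot(index="time_min", columns="replicate",
                         values="value")
        return wide.loc[list(self.timepoints)].to_numpy()

    def replicate_means(self) -> dict[str, np.ndarray]:
        return {r: self.values(r).mean(axis=1) for r in READOUTS}

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, protocol: Protocol) -> "DensitometryTable":
        df = pd.read_csv(path)
        return cls(
            data=df,
            timepoints=np.array(sorted(df["time_min"].unique(), key=float)),
            protocol=protocol,
        )


DEFAULT_TIMEPOINTS = (0.0, 30.0, 60.0, 90.0, 120.0)


def model_readout_values(
    protocol: Protocol,
    params: ModelParameters,
    variant: ModelVariant,
    timepoints,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Noise-free read-out values at the given time points.

    Uses a coarse output grid (the sample spacing) — cheap enough for
    the inner loop of least-squares fitting.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    dt = max(float(np.min(np.diff(timepoints))), 1.0) if timepoints.size > 1 else 1.0
    traj = integrate(
        protocol, params, variant, rtol=rtol, atol=atol, grid_dt=dt / 2,
    )
    return trajectory_readout_values(traj, timepoints)


def trajectory_readout_values(
    traj: Trajectory, timepoints
) -> dict[str, np.ndarray]:
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.min() < traj.times[0] or timepoints.max() > traj.times[-1]:
        raise ValueError(
            f"timepoints {timepoints} outside trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    out = {}
    for readout, species in READOUTS.items():
        levels = np.interp(timepoints, traj.times, traj.series(species))
        out[readout] = readout_transform(readout, levels)
    return out


def generate(
    traj: Trajectory,
    noise: NoiseModel | None = None,
    timepoints=DEFAULT_TIMEPOINTS,
) -> DensitometryTable:
    """Sample a replicate densitometry table from a trajectory.

    cell value = noise-free read-out × lognormal(cv) × lane factor
    (lognormal(loading_cv), shared by all read-outs of one lane).
    Identical seeds give identical tables.
    """
    noise = noise or NoiseModel()
    if traj.protocol is None:
        raise ValueError("trajectory carries no protocol provenance")
    clean = trajectory_readout_values(traj, timepoints)
    timepoints = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(noise.seed)
    n_t, n_r = timepoints.size, noise.n_replicates
    # one lane per (time point, replicate)
    lane = noise._factor(rng, noise.loading_cv, (n_t, n_r))
    rows = []
    for readout in READOUTS:
        cell = noise._factor(rng, noise.cv, (n_t, n_r))
        values = clean[readout][:, None] * cell * lane
        for i, t in enumerate(timepoints):
            for r in range(n_r):
                rows.append(
                    {
                        "time_min": float(t),
                        "readout": readout,
                        "replicate": r + 1,
                        "value": float(values[i, r]),
                    }
                )
    return DensitometryTable(
        data=pd.DataFrame(rows),
        timepoints=timepoints,
        protocol=traj.protocol,
        noise=noise,
    )


#: protocols mirrored by the fixture tables: mTOR inhibition alone,
#: with ULK1 silenced, and with AMPK inhibited
FIXTURE_PROTOCOLS = {
    "rapamycin": ([], "rapamycin", 120.0, DEFAULT_TIMEPOINTS),
    "si_ulk1+rapamycin": (
        ["si_ulk1"], "rapamycin", 150.0, (30.0, 60.0, 90.0, 120.0, 150.0),
    ),
    "compound_c+rapamycin": (
        ["compound_c"], "rapamycin", 150.0, (30.0, 60.0, 90.0, 120.0, 150.0),
    ),
}


def fixture_suite(
    seed: int = 0,
    *,
    params: ModelParameters | None = None,
    variant: ModelVariant | None = None,
    noise: NoiseModel | None = None,
) -> dict[str, DensitometryTable]:
    """Three densitometry tables for the time-course experiment designs.

    Time points sit at 30-min spacing across the 2-h drug window
    (offset by the 30-min pre-treatment where there is one).
    """
    params = params or default_parameters()
    variant = variant or ModelVariant()
    out = {}
    for i, (name, (pre, main, duration, tps)) in enumerate(
        FIXTURE_PROTOCOLS.items()
    ):
        protocol = standard_protocol([main], pre, duration)
        traj = integrate(protocol, params, variant)
        nm = noise or NoiseModel(seed=seed + i)
        if noise is not None:
            nm = NoiseModel(
                cv=noise.cv, loading_cv=noise.loading_cv,
                n_replicates=noise.n_replicates, seed=seed + i,
            )
        out[name] = generate(traj, nm, tps)
    return out
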