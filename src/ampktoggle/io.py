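"""Configuration files, result serialisation, digests and plotting glue.

Everything on disk is plain text (YAML/JSON/CSV).  Unknown keys in a
config are an error — a typo never silently falls back to a default.
Every artifact written by the CLI carries provenance metadata: package
version, parameter digest, and the run seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .model import ModelParameters, ModelVariant
from .perturbations import Protocol

__all__ = [
    "load_parameters",
    "save_parameters",
    "load_variant",
    "save_variant",
    "load_protocol",
    "save_protocol",
    "parameter_digest",
    "run_metadata",
    "plot_trajectory",
    "plot_scan",
    "plot_nullclines",
]


def _read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format: {path.suffix!r}")


def _write_config(path, data: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")


def load_parameters(path) -> ModelParameters:
    """Read a parameter config (YAML/JSON; `parameters:` wrapper optional)."""
    data = _read_config(path)
    if "parameters" in data:
        data = data["parameters"]
    return ModelParameters.from_dict(data)


def save_parameters(params: ModelParameters, path) -> None:
    _write_config(path, {"parameters": params.to_dict()})


def load_variant(path) -> ModelVariant:
    data = _read_config(path)
    if "variant" in data:
        data = data["variant"]
    return ModelVariant.from_dict(data)


def save_variant(variant: ModelVariant, path) -> None:
    _write_config(path, {"variant": variant.to_dict()})


def load_protocol(path) -> Protocol:
    return Protocol.from_dict(_read_config(path))


def save_protocol(protocol: Protocol, path) -> None:
    _write_config(path, protocol.to_dict())


def parameter_digest(
    params: ModelParameters, variant: ModelVariant | None = None
) -> str:
    """Short stable hash identifying a (parameters, variant) pair."""
    payload = {"parameters": params.to_dict()}
    if variant is not None:
        payload["variant"] = variant.to_dict()
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_metadata(
    params: ModelParameters,
    variant: ModelVariant,
    seed: int | None = None,
    **extra,
) -> dict:
    from . import __version__

    meta = {
        "package": "ampktoggle",
        "version": __version__,
        "parameter_digest": parameter_digest(params, variant),
        "seed": seed,
    }
    meta.update(extra)
    return meta


# ---------------------------------------------------------------------------
# plotting (Agg backend; headless-safe)


def _axes(figsize=(6.0, 4.0)):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


_COLORS = {"A": "tab:red", "M": "tab:green", "U": "tab:blue", "G": "tab:purple"}
_LABELS = {
    "A": "AMPK-Thr172-P",
    "M": "mTOR (active)",
    "U": "ULK1-Ser555-P",
    "G": "autophagy (ATG)",
}


def plot_trajectory(traj, path) -> None:
    """Time-course panel in the style of the simulation figures."""
    fig, ax = _axes()
    for s in "AMUG":
        ax.plot(traj.times, traj.series(s), color=_COLORS[s],
                label=_LABELS[s])
    ax.set_xlabel("time (min)")
    ax.set_ylabel("relative activity")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(loc="best", fontsize=8)
    if traj.protocol is not None and traj.protocol.name:
        ax.set_title(traj.protocol.name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)


def plot_scan(diagram, path, species: str = "A") -> None:
    """Branch diagram: stable solid, unstable open, per scan value."""
    fig, ax = _axes()
    idx = "AMUG".index(species)
    for v, col in zip(diagram.values, diagram.states):
        for st, stable in col:
            level = st.to_array()[idx]
            ax.plot(v, level, "o" if stable else ".",
                    color="k" if stable else "0.6",
                    markersize=4 if stable else 3)
    for lo, hi in diagram.bistable_intervals:
        ax.axvspan(lo, hi, color="tab:orange", alpha=0.15)
    ax.set_xlabel(diagram.param_name)
    ax.set_ylabel(f"{_LABELS[species]} steady state")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)


def plot_nullclines(nset, path) -> None:
    fig, ax = _axes()
    if nset.a_nullcline.size:
        order = np.argsort(nset.a_nullcline[:, 1])
        ax.plot(nset.a_nullcline[order, 0], nset.a_nullcline[order, 1],
                ".", ms=2, color="tab:red", label="dA/dt = 0")
    if nset.m_nullcline.size:
        order = np.argsort(nset.m_nullcline[:, 0])
        ax.plot(nset.m_nullcline[order, 0], nset.m_nullcline[order, 1],
                ".", ms=2, color="tab:green", label="dM/dt = 0")
    for st, stable in nset.intersections:
        ax.plot(st.A, st.M, "ko" if stable else "kx", ms=7)
    ax.set_xlabel("AMPK-P (A)")
    ax.set_ylabel("active mTOR (M)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)
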