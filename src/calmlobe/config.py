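"""Configuration loading (TOML or YAML) for the tunable analysis settings.

Recognized sections and keys::

    [lobes]
    n_lobe = [1, 81]
    c_lobe = [82, 149]
    ef_hand_loops = [[21, 32], [57, 68], [94, 105], [130, 141]]

    [burden]
    mpc_threshold = 2.0

    [buffer]            # pH-apparent association constants, M^-1
    total_egta = 0.5e-3
    total_nta = 2.0e-3
    k_ca_egta = 3.0e6
    ...

    [scqc]
    min_genes_per_cell = 800
    ...
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import yaml

from .buffers import BufferSystem
from .catalog import LobeMap


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh)
    raise ValueError(f"unsupported config format: {path.suffix!r}")


def lobe_map_from_config(cfg: dict) -> LobeMap:
    sec = cfg.get("lobes", {})
    kwargs = {}
    if "n_lobe" in sec:
        kwargs["n_lobe_range"] = tuple(sec["n_lobe"])
    if "c_lobe" in sec:
        kwargs["c_lobe_range"] = tuple(sec["c_lobe"])
    if "ef_hand_loops" in sec:
        kwargs["ca_coordinating"] = frozenset(
            p for lo, hi in sec["ef_hand_loops"] for p in range(lo, hi + 1)
        )
    return LobeMap(**kwargs)


def buffer_system_from_config(cfg: dict) -> BufferSystem:
    return BufferSystem(**cfg.get("buffer", {}))


def qc_params_from_config(cfg: dict):
    from .scqc import QCParams

    return QCParams(**cfg.get("scqc", {}))
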