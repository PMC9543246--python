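"""YAML model-configuration loading.

Schema (all keys optional; omitted values fall back to preset/defaults)::

    preset: updated_model
    species:
      - name: IRF4
        half_life_protein_h: 48
        half_life_mrna_h: 2
      - name: MYC
        half_life_protein_h: "30 min"    # minutes accepted with a suffix
    edges:
      - {source: MYC, target: IRF4, sign: activation, K: 1, h: 1, w: 2}
    drug:
      targets: [MYC]        # MYC | IRF4 | both
      epsilon: 0.8
      onset_h: 0
    solver:
      rtol: 1.0e-8
      atol: 1.0e-10

Hours are the canonical time unit; minutes are accepted only with an
explicit ``min`` suffix and converted on load.
"""

from __future__ import annotations

import re

import yaml

from .network import (
    DrugPerturbation,
    NetworkParameters,
    RegulationEdge,
    build_parameters,
)

__all__ = ["parse_duration_hours", "load_config"]

_DURATION_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(h|hr|hours?|m|min|minutes?)?\s*$")


def parse_duration_hours(value) -> float:
    """Parse a duration as hours; strings may carry an ``h`` or ``min`` suffix."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _DURATION_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse duration {value!r}")
    num = float(m.group(1))
    unit = m.group(2) or "h"
    if unit.startswith("m"):
        return num / 60.0
    return num


def _parse_drug(block: dict) -> DrugPerturbation:
    raw = block.get("targets", [])
    if isinstance(raw, str):
        raw = [raw]
    targets: list[str] = []
    for t in raw:
        t = str(t).upper()
        if t == "BOTH":
            targets.extend(["MYC", "IRF4"])
        else:
            targets.append(t)
    return DrugPerturbation(
        targets=tuple(dict.fromkeys(targets)),
        epsilon=float(block.get("epsilon", 0.8)),
        onset_h=parse_duration_hours(block.get("onset_h", 0.0)),
    )


def load_config(path) -> tuple[NetworkParameters, DrugPerturbation | None, dict]:
    """Load a model config file.

    Returns (parameters, perturbation or None, solver options dict).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}

    protein: dict[str, float] = {}
    mrna: dict[str, float] = {}
    for entry in cfg.get("species", []) or []:
        name = entry.get("name")
        if name is None:
            raise ValueError("species entry missing 'name'")
        if "half_life_protein_h" in entry:
            protein[name] = parse_duration_hours(entry["half_life_protein_h"])
        if "half_life_mrna_h" in entry:
            mrna[name] = parse_duration_hours(entry["half_life_mrna_h"])

    edges = None
    if cfg.get("edges"):
        edges = tuple(
            RegulationEdge(
                source=e["source"], target=e["target"], sign=e["sign"],
                K=float(e.get("K", 1.0)), h=float(e.get("h", 1.0)),
                w=float(e.get("w", 2.0)),
            )
            for e in cfg["edges"]
        )

    params = build_parameters(
        cfg.get("preset"),
        protein_half_life=protein or None,
        mrna_half_life=mrna or None,
        edges=edges,
    )
    drug = _parse_drug(cfg["drug"]) if cfg.get("drug") else None
    solver = {
        "rtol": float(cfg.get("solver", {}).get("rtol", 1e-8)),
        "atol": float(cfg.get("solver", {}).get("atol", 1e-10)),
    }
    return params, drug, solver
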