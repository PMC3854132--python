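"""Readers and writers: parameter tables (CSV), observation tables (CSV),
wiring audit document (YAML) and small report helpers (JSON)."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterDomainError
from .model_core import (
    DECAY_DERIVED,
    DECAY_FREE_CONSTANT,
    DECAY_TIME_SCALED,
    INHIBITOR_TARGET_REACTION,
    INHIBITORS,
    REACTION_NAMES,
    SPECIES,
    ApoptosisParams,
    ParameterSet,
)

__all__ = [
    "write_parameter_table",
    "read_parameter_table",
    "export_wiring",
    "write_wiring_yaml",
    "config_hash",
    "write_report",
]

PARAM_COLUMNS = ("name", "value", "unit", "source")

_REAC = "1 2 3 4 5 6 7 8 9 10 11 12 13a 13b".split()


def _units() -> dict[str, str]:
    u: dict[str, str] = {}
    for s in _REAC:
        u[f"V{s}"] = "1/h"
        u[f"K{s}"] = "dimensionless"
        u[f"n{s}"] = "dimensionless"
    for i in DECAY_TIME_SCALED:
        u[f"d{i+1}"] = "1/h^2"
    for i in (*DECAY_FREE_CONSTANT, *DECAY_DERIVED):
        u[f"d{i+1}"] = "1/h"
    u.update({
        "k_a": "1/h^2", "bad_total": "dimensionless", "k_bad": "dimensionless",
        "n_bad": "dimensionless", "w_s136": "dimensionless",
        "k_creb": "dimensionless", "n_creb": "dimensionless",
    })
    return u


def write_parameter_table(p: ParameterSet, path) -> pd.DataFrame:
    """Write a parameter CSV with columns (name, value, unit, source).

    ``source`` is ``fitted`` for the 37 + 7 free parameters, ``fixed`` for
    the structural Hill exponents and ``derived`` for the steady-state-closed
    decay rates.  The layout round-trips through
    :func:`read_parameter_table`.
    """
    units = _units()
    free = set(ParameterSet.free_names())
    rows = []
    for name, value in p.to_dict(include_derived=True).items():
        if name in free:
            source = "fitted"
        elif name.startswith("n"):
            source = "fixed"
        else:
            source = "derived"
        rows.append({"name": name, "value": value, "unit": units[name], "source": source})
    frame = pd.DataFrame(rows, columns=list(PARAM_COLUMNS))
    frame.to_csv(path, index=False)
    return frame


def read_parameter_table(path) -> ParameterSet:
    """Read a parameter CSV back into a :class:`ParameterSet`.

    Derived decay rates present in the file are cross-checked against the
    recomputed closure (warning on >1e-6 relative mismatch); missing derived
    entries are recomputed silently.  Unknown names and non-positive values
    are rejected.
    """
    frame = pd.read_csv(path)
    missing = set(PARAM_COLUMNS[:2]) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"parameter table {path} lacks column(s) {sorted(missing)}")
    values = dict(zip(frame["name"].astype(str), frame["value"].astype(float)))

    derived_names = {f"d{i+1}" for i in DECAY_DERIVED}
    file_derived = {k: values.pop(k) for k in list(values) if k in derived_names}

    bad = {k: v for k, v in values.items() if not np.isfinite(v) or v <= 0}
    if bad:
        raise ParameterDomainError(f"non-positive or non-finite parameter value(s): {bad}")
    p = ParameterSet.from_dict(values)

    recomputed = dict(zip(sorted(derived_names, key=lambda s: int(s[1:])),
                          [None] * len(derived_names)))
    closed = p.decay_derived
    for j, i in enumerate(DECAY_DERIVED):
        recomputed[f"d{i+1}"] = closed[j]
    for name, file_value in file_derived.items():
        rel = abs(file_value - recomputed[name]) / max(abs(recomputed[name]), 1e-300)
        if rel > 1e-6:
            warnings.warn(
                f"derived decay {name} in {path} ({file_value:g}) differs from "
                f"steady-state closure ({recomputed[name]:g}) by {rel:.2e} relative; "
                "using the recomputed value",
                stacklevel=2,
            )
    return p


# ---------------------------------------------------------------------------
# Wiring audit document
# ---------------------------------------------------------------------------

def export_wiring() -> dict:
    """The network wiring and inhibitor-target map as a plain dict (for YAML)."""
    edges = [
        {"from": "EGF", "to": "EGFR", "reaction": "V1"},
        {"from": "EGFR", "to": "Raf", "reaction": "V2"},
        {"from": "Raf", "to": "ERK12", "reaction": "V3"},
        {"from": "ERK12", "to": "KinaseX", "reaction": "V4"},
        {"from": "EGF", "to": "Rac", "reaction": "V5"},
        {"from": "Rac", "to": "PAK", "reaction": "V6"},
        {"from": "basal", "to": "PI3K", "reaction": "V7"},
        {"from": "PI3K", "to": "AKT", "reaction": "V8"},
        {"from": "stress", "to": "cAMP", "reaction": "V9"},
        {"from": "cAMP", "to": "PKA", "reaction": "V10"},
        {"from": "PKA", "to": "CREB", "reaction": "V11"},
        {"from": "KinaseX + PKA + partial AKT", "to": "pS112BAD", "reaction": "V12"},
        {"from": "PAK", "to": "pS136BAD", "reaction": "V13a"},
        {"from": "AKT", "to": "pS136BAD", "reaction": "V13b"},
    ]
    inhibitor_targets = {
        name: REACTION_NAMES[idx] for name, idx in INHIBITOR_TARGET_REACTION.items()
    }
    inhibitor_targets["BADS112A"] = "d12 (pS112BAD dephosphorylation)"
    return {
        "species": list(SPECIES),
        "edges": edges,
        "inhibitors": list(INHIBITORS),
        "inhibitor_targets": inhibitor_targets,
    }


def write_wiring_yaml(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(export_wiring(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_report(path, payload: dict) -> None:
    """Write a JSON report, creating parent directories as needed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
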