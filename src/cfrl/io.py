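"""Flat-file I/O: trial-level datasets (CSV), task designs (YAML/JSON) and
parameter files (YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .task import DATASET_COLUMNS, ContextSpec, TaskDesign, build_schedule

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_design",
    "write_design",
    "read_params",
]


def write_dataset(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False, columns=DATASET_COLUMNS)


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset file missing columns {sorted(missing)}")
    return df


def _design_to_dict(design: TaskDesign) -> dict:
    return {
        "n_sessions": design.n_sessions,
        "trials_per_context": design.trials_per_context,
        "feedback": design.feedback,
        "contexts": [
            {
                "label": c.label,
                "p_a": c.p_a,
                "p_b": c.p_b,
                "reversal_trial": c.reversal_trial,
            }
            for c in design.contexts
        ],
        "order": [list(seq) for seq in design.order],
    }


def write_design(design: TaskDesign, path) -> None:
    path = Path(path)
    payload = _design_to_dict(design)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_design(path, seed: int = 0) -> TaskDesign:
    """Load a design file.  A file without a materialised ``order`` is
    scheduled with ``build_schedule`` under ``seed``."""
    path = Path(path)
    raw = path.read_text()
    payload = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    contexts = tuple(
        ContextSpec(
            label=c["label"],
            p_a=float(c["p_a"]),
            p_b=float(c["p_b"]),
            reversal_trial=c.get("reversal_trial"),
        )
        for c in payload["contexts"]
    )
    common = dict(
        contexts=contexts,
        n_sessions=int(payload.get("n_sessions", 2)),
        trials_per_context=int(payload.get("trials_per_context", 24)),
        feedback=payload.get("feedback", "complete"),
    )
    if payload.get("order"):
        return TaskDesign(order=tuple(tuple(s) for s in payload["order"]), **common)
    return build_schedule(seed=seed, **common)


def read_params(path) -> dict:
    """Free-parameter mapping from a YAML/JSON file."""
    path = Path(path)
    raw = path.read_text()
    payload = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(payload, dict):
        raise ValueError("parameter file must map parameter names to values")
    return {str(k): float(v) for k, v in payload.items()}
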