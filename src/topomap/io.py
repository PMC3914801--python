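"""Reading and writing sampled maps and tuning curves as delimited text.

A *map table* is a CSV/TSV with columns ``x``, ``y``, ``feature`` and an
optional ``subject_id``; a *tuning table* has ``cell_id``, ``cell_class``,
``stimulus``, ``response`` with one row per stimulus presentation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import SampledMap
from .exceptions import InvalidInputError
from .tuning import TuningCurve

_MAP_COLUMNS = ("x", "y", "feature")
_TUNING_COLUMNS = ("cell_id", "cell_class", "stimulus", "response")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_map_table(
    path,
    periodic: bool = False,
    period: Optional[float] = None,
) -> List[SampledMap]:
    """Load one SampledMap per subject from a delimited map table.

    A file without a ``subject_id`` column yields a single anonymous
    subject; row order is preserved within each subject.
    """
    df = _read_table(path)
    for col in _MAP_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"map table {path} is missing column {col!r}")
    for col in _MAP_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any() or values.isna().any():
            row = int(np.flatnonzero(values.isna())[0])
            raise InvalidInputError(
                f"non-numeric or missing value in column {col!r}, row {row}"
            )
        df[col] = values
    if "subject_id" in df.columns:
        groups = [(str(s), g) for s, g in df.groupby("subject_id", sort=False)]
    else:
        groups = [(None, df)]
    maps = []
    for subject, g in groups:
        maps.append(
            SampledMap(
                positions=g[["x", "y"]].to_numpy(),
                labels=g["feature"].to_numpy(),
                periodic=periodic,
                period=period,
                subject_id=subject,
            )
        )
    return maps


def save_map_table(maps, path) -> None:
    """Write one or several SampledMaps to a delimited map table
    (full float precision round-trip)."""
    if isinstance(maps, SampledMap):
        maps = [maps]
    frames = []
    for k, m in enumerate(maps):
        frame = pd.DataFrame(
            {"x": m.positions[:, 0], "y": m.positions[:, 1], "feature": m.labels}
        )
        if m.subject_id is not None or len(maps) > 1:
            frame.insert(0, "subject_id", m.subject_id if m.subject_id is not None else k)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


def load_tuning_table(path) -> Dict[str, TuningCurve]:
    """Load tuning curves keyed by cell id from a delimited tuning table."""
    df = _read_table(path)
    for col in _TUNING_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"tuning table {path} is missing column {col!r}")
    curves = {}
    for cell, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("stimulus")
        classes = g["cell_class"].unique()
        if len(classes) != 1:
            raise InvalidInputError(f"cell {cell!r} has inconsistent cell_class")
        curves[str(cell)] = TuningCurve(
            stimulus=g["stimulus"].to_numpy(float),
            response=g["response"].to_numpy(float),
            cell_class=str(classes[0]),
        )
    return curves


def write_results_json(payload: dict, path) -> None:
    """Write a results payload (with config echo) as indented JSON."""

    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
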