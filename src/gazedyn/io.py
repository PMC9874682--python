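"""Delimited-text and JSON persistence for pipeline artifacts.

All tables are written as comma-separated text with ``NA`` marking absent
values (skipped-word first-pass measures and the like), so every artifact
is diffable and round-trips exactly through pandas.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GroundTruth, LogisticEventModel, SegmentedEffect

NA = "NA"

__all__ = ["write_table", "read_table", "write_ground_truth",
           "read_ground_truth", "write_json"]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep=NA)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[NA], keep_default_na=True)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_Encoder)
                    + "\n")
    return path


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    return write_json(truth, path)


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        baseline_duration=d["baseline_duration"],
        length_effect=SegmentedEffect(**d["length_effect"]),
        position_effect=SegmentedEffect(**d["position_effect"]),
        interaction_coefficients=d["interaction_coefficients"],
        skip_model=LogisticEventModel(**d["skip_model"]),
        regression_model=LogisticEventModel(**d["regression_model"]),
        refixation_model=LogisticEventModel(**d["refixation_model"]),
        duration_noise=d["duration_noise"],
    )
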