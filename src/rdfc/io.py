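"""Tabular / JSON serialization of patterns, reference sets and results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import ThresholdCalibration
from .core import RdfcPattern
from .matching import MatchResult, ReferenceSet

__all__ = [
    "patterns_to_frame",
    "frame_to_patterns",
    "save_patterns",
    "load_patterns",
    "save_reference_set",
    "load_reference_set",
    "save_calibration",
    "load_calibration",
    "match_results_to_frame",
]

_COORD_COLS = [f"{ax}{i}" for i in range(1, 6) for ax in ("x", "y", "z")]


def patterns_to_frame(patterns: Sequence[RdfcPattern]) -> pd.DataFrame:
    """One row per pattern: metadata columns then x1..z5 coordinates."""
    rows = []
    for p in patterns:
        if p.points.shape[0] != 5:
            raise ValueError("tabular pattern format holds 5-order patterns")
        meta = p.meta
        row = {
            "label1": meta.get("labels", ("", "", ""))[0],
            "label2": meta.get("labels", ("", "", ""))[1],
            "label3": meta.get("labels", ("", "", ""))[2],
            "permutation_id": meta.get("permutation_id", 1),
            "epoch_start": meta.get("epoch_start", 0.0),
            "window": meta.get("window", 0),
            "rate": meta.get("rate", 0.0),
        }
        row.update(dict(zip(_COORD_COLS, p.points.ravel())))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_patterns(df: pd.DataFrame) -> list[RdfcPattern]:
    patterns = []
    for _, row in df.iterrows():
        points = np.array([row[c] for c in _COORD_COLS], dtype=float).reshape(5, 3)
        patterns.append(
            RdfcPattern(
                points=points,
                meta={
                    "labels": (row["label1"], row["label2"], row["label3"]),
                    "permutation_id": int(row["permutation_id"]),
                    "epoch_start": float(row["epoch_start"]),
                    "window": int(row["window"]),
                    "rate": float(row["rate"]),
                },
            )
        )
    return patterns


def save_patterns(patterns: Sequence[RdfcPattern], path: str | Path) -> Path:
    path = Path(path)
    patterns_to_frame(patterns).to_csv(path, index=False)
    return path


def load_patterns(path: str | Path) -> list[RdfcPattern]:
    return frame_to_patterns(pd.read_csv(path))


def save_reference_set(refs: ReferenceSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "provenance": refs.provenance,
        "mapping": {str(k): v for k, v in refs.mapping.items()},
        "patterns": [
            {"reference_id": i + 1, "points": p.points.tolist(), "meta": _json_meta(p.meta)}
            for i, p in enumerate(refs.patterns)
        ],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def _json_meta(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, tuple):
            v = list(v)
        if isinstance(v, (np.integer, np.floating)):
            v = v.item()
        out[k] = v
    return out


def load_reference_set(path: str | Path) -> ReferenceSet:
    payload = json.loads(Path(path).read_text())
    patterns = [
        RdfcPattern(points=np.asarray(p["points"]), meta=p.get("meta", {}))
        for p in sorted(payload["patterns"], key=lambda p: p["reference_id"])
    ]
    mapping = {int(k): int(v) for k, v in payload["mapping"].items()}
    return ReferenceSet(patterns=patterns, provenance=payload.get("provenance", ""), mapping=mapping)


def save_calibration(cal: ThresholdCalibration, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(cal.to_dict(), indent=2))
    return path


def load_calibration(path: str | Path) -> ThresholdCalibration:
    d = json.loads(Path(path).read_text())
    return ThresholdCalibration(
        threshold=d["threshold"],
        n_patterns=d["n_patterns"],
        percentile=d["percentile"],
        seed=d["seed"],
    )


def match_results_to_frame(results: Iterable[MatchResult]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "pattern_id": i,
                "score_ref1": r.scores[0],
                "score_ref2": r.scores[1],
                "score_ref3": r.scores[2],
                "best_id": r.best_id,
                "best_score": r.best_score,
                "significant": r.significant,
                "exclusive": r.exclusive,
            }
        )
    return pd.DataFrame(rows)
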