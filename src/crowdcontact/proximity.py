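"""Proximity scoring: distancing violations from ground-plane detections.

A person commits a distancing violation when at least one other person
stands within the mandated threshold (1.5 m) of them in the same still
frame.  This module computes, per person, the number of others within the
threshold and the derived binary indicators (at least 1 other; at least 2
others, a proxy that discounts household companions), plus per-frame
aggregates: the number of violating persons and the number of violating
pairs.

The normative definition is the brute-force pairwise Euclidean distance
with a closed ball (distance <= threshold counts); the implementation uses
a k-d tree for the neighbor search, which is exact for this query.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .scene import DETECTION_COLUMNS, FrameRecord

__all__ = [
    "FrameSummary",
    "filter_frames",
    "neighbor_counts",
    "score_frame",
    "summarize_frame",
    "score_dataset",
    "PERSON_COLUMNS",
    "FRAME_COLUMNS",
]

PERSON_COLUMNS = [
    "camera_id",
    "frame_id",
    "person_id",
    "n_present",
    "n_within_threshold",
    "violation",
    "violation2",
]
FRAME_COLUMNS = ["camera_id", "frame_id", "n_present", "n_violators", "n_violating_pairs"]

_FRAME_KEY = ["camera_id", "frame_id"]


class FrameSummary(NamedTuple):
    camera_id: str
    frame_id: str
    n_present: int
    n_violators: int
    n_violating_pairs: int


def _check_schema(detections: pd.DataFrame) -> None:
    missing = [c for c in DETECTION_COLUMNS if c not in detections.columns]
    if missing:
        raise ValueError(f"detection table is missing columns {missing}")
    bad = detections[["x_m", "y_m"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} detection rows have missing coordinates; "
            "malformed rows are an error, not silently dropped"
        )


def filter_frames(detections: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop frames with fewer than 2 persons.

    A person alone in a frame cannot be involved in a close encounter, so
    such frames carry no outcome information.  Returns the filtered table
    (rows otherwise untouched) and the number of frames dropped.
    """
    _check_schema(detections)
    if len(detections) == 0:
        return detections.copy(), 0
    sizes = detections.groupby(_FRAME_KEY, sort=False)["person_id"].transform("size")
    kept = detections.loc[sizes >= 2].reset_index(drop=True)
    n_frames_before = len(detections.drop_duplicates(_FRAME_KEY))
    n_frames_after = len(kept.drop_duplicates(_FRAME_KEY)) if len(kept) else 0
    return kept, n_frames_before - n_frames_after


def neighbor_counts(points: np.ndarray, threshold_m: float) -> tuple[np.ndarray, int]:
    """Per-person count of others within ``threshold_m`` and the pair total.

    Exact closed-ball neighbor query via a k-d tree.  Returns the counts
    (length n) and the number of unordered violating pairs; by symmetry the
    counts sum to twice the pair count.
    """
    if not threshold_m > 0:
        raise ValueError("threshold_m must be positive")
    points = np.asarray(points, dtype=float)
    n = len(points)
    counts = np.zeros(n, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=threshold_m, output_type="ndarray")
    if len(pairs):
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    return counts, len(pairs)


def score_frame(frame: FrameRecord, threshold_m: float) -> pd.DataFrame:
    """Score one frame: one person-outcome row per detection."""
    if frame.n_present < 2:
        raise ValueError("frame must contain at least 2 detections")
    counts, _ = neighbor_counts(frame.positions, threshold_m)
    return pd.DataFrame(
        {
            "camera_id": frame.camera_id,
            "frame_id": frame.frame_id,
            "person_id": frame.person_id,
            "n_present": frame.n_present,
            "n_within_threshold": counts,
            "violation": (counts >= 1).astype(np.int8),
            "violation2": (counts >= 2).astype(np.int8),
        }
    )


def summarize_frame(
    outcomes: pd.DataFrame, n_violating_pairs: int | None = None
) -> FrameSummary:
    """Aggregate person outcomes of a single frame.

    The violating-pair count may be supplied directly (e.g. from the
    neighbor search); otherwise it is recovered from the symmetry identity
    sum(n_within_threshold) = 2 x pairs, which holds exactly for any
    symmetric neighbor relation.
    """
    keys = outcomes[_FRAME_KEY].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("summarize_frame expects outcomes from exactly one frame")
    if n_violating_pairs is None:
        total = int(outcomes["n_within_threshold"].sum())
        n_violating_pairs = total // 2
    return FrameSummary(
        camera_id=keys.iloc[0, 0],
        frame_id=keys.iloc[0, 1],
        n_present=int(len(outcomes)),
        n_violators=int(outcomes["violation"].sum()),
        n_violating_pairs=int(n_violating_pairs),
    )


def score_dataset(
    detections: pd.DataFrame, threshold_m: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a filtered detection table.

    Returns the person-outcome table (one row per detection, original order
    preserved) and the frame-summary table (one row per frame).  Input that
    still contains frames with fewer than 2 persons is rejected: run
    :func:`filter_frames` first.
    """
    _check_schema(detections)
    if not threshold_m > 0:
        raise ValueError("threshold_m must be positive")
    if len(detections) == 0:
        return (
            pd.DataFrame(columns=PERSON_COLUMNS),
            pd.DataFrame(columns=FRAME_COLUMNS),
        )

    person_parts = []
    frame_rows = []
    for (cam, fid), grp in detections.groupby(_FRAME_KEY, sort=False):
        n = len(grp)
        if n < 2:
            raise ValueError(
                f"frame ({cam}, {fid}) has {n} person(s); run filter_frames first"
            )
        counts, n_pairs = neighbor_counts(grp[["x_m", "y_m"]].to_numpy(), threshold_m)
        part = pd.DataFrame(
            {
                "camera_id": cam,
                "frame_id": fid,
                "person_id": grp["person_id"].to_numpy(),
                "n_present": n,
                "n_within_threshold": counts,
                "violation": (counts >= 1).astype(np.int8),
                "violation2": (counts >= 2).astype(np.int8),
            },
            index=grp.index,
        )
        person_parts.append(part)
        frame_rows.append((cam, fid, n, int((counts >= 1).sum()), n_pairs))

    persons = pd.concat(person_parts).sort_index().reset_index(drop=True)
    frames = pd.DataFrame(frame_rows, columns=FRAME_COLUMNS)
    return persons, frames
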