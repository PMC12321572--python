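"""Scoring detected objects against simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..segmentation import ObjectTable
from .scene import SceneTruth

__all__ = ["MatchResult", "match_objects"]


@dataclass
class MatchResult:
    """Greedy one-to-one matching of detections to true puncta."""

    n_true: int
    n_detected: int
    tp: int
    fp: int
    fn: int
    matches: pd.DataFrame  # object_id, truth_id, distance_um

    @property
    def precision(self) -> float:
        return self.tp / self.n_detected if self.n_detected else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / self.n_true if self.n_true else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def match_objects(
    objects: ObjectTable,
    truth: SceneTruth,
    role: str,
    max_dist: float = 0.35,
    border_margin_xy: float = 0.5,
    border_margin_z: float = 0.25,
) -> MatchResult:
    """Match detected objects to true puncta of one role by centroid distance.

    Matching is greedy by increasing distance with a one-to-one constraint.
    Truth puncta and detections within the stated margins of the field
    border are excluded from the score: border puncta are partially imaged
    (and may leave the valid region after alignment), so they measure the
    field of view, not the segmentation.
    """
    p = truth.params
    tdf = truth.role(role)

    def _interior(df: pd.DataFrame) -> pd.DataFrame:
        return df[
            (df["cx"] >= border_margin_xy) & (df["cx"] <= p.field_x - border_margin_xy)
            & (df["cy"] >= border_margin_xy) & (df["cy"] <= p.field_y - border_margin_xy)
            & (df["cz"] >= border_margin_z) & (df["cz"] <= p.depth - border_margin_z)
        ]

    tdf = _interior(tdf)
    odf = _interior(objects.df)
    t_xyz = tdf[["cx", "cy", "cz"]].to_numpy(dtype=float)
    o_xyz = odf[["cx", "cy", "cz"]].to_numpy(dtype=float)
    if len(t_xyz) == 0 or len(o_xyz) == 0:
        return MatchResult(
            n_true=len(t_xyz), n_detected=len(o_xyz),
            tp=0, fp=len(o_xyz), fn=len(t_xyz),
            matches=pd.DataFrame(columns=["object_id", "truth_id", "distance_um"]),
        )

    tree = cKDTree(t_xyz)
    k = min(4, len(t_xyz))
    dists, idxs = tree.query(o_xyz, k=k)
    dists = np.atleast_2d(dists.T).T
    idxs = np.atleast_2d(idxs.T).T
    cand = [
        (dists[i, j], i, idxs[i, j])
        for i in range(len(o_xyz))
        for j in range(k)
        if dists[i, j] <= max_dist
    ]
    cand.sort()
    used_o: set[int] = set()
    used_t: set[int] = set()
    rows = []
    for d, oi, ti in cand:
        if oi in used_o or ti in used_t:
            continue
        used_o.add(oi)
        used_t.add(int(ti))
        rows.append(
            {
                "object_id": int(odf["id"].iloc[oi]),
                "truth_id": int(tdf["id"].iloc[int(ti)]),
                "distance_um": float(d),
            }
        )
    tp = len(rows)
    return MatchResult(
        n_true=len(t_xyz),
        n_detected=len(o_xyz),
        tp=tp,
        fp=len(o_xyz) - tp,
        fn=len(t_xyz) - tp,
        matches=pd.DataFrame(rows, columns=["object_id", "truth_id", "distance_um"]),
    )
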