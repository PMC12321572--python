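"""Synaptic pairing and the conditional tau-enrichment statistic.

A postsynaptic punctum is paired to its nearest presynaptic punctum when the
centroid-to-centroid distance is at most 0.5 um (inclusive), distances taken
in physical micrometres so voxel anisotropy is already accounted for.  A
presynapse may serve several postsynapses; pairing is post-centric.

The enrichment statistic asks: among paired postsynapses, how much more
likely is a postsynapse to contain tau when its presynaptic partner contains
tau, relative to the tau rate over *all* paired postsynapses (the
unconditional baseline)?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segmentation import ObjectTable

__all__ = ["PairTable", "EnrichmentResult", "find_pairs", "enrichment_ratio", "attach_tau_flags"]


@dataclass
class PairTable:
    """Post->pre pairings with centroid distances and per-side tau flags.

    ``df`` columns: ``post_id, pre_id, distance_um`` and, once joined,
    ``tau_pre, tau_post`` booleans.  Each post appears at most once.
    """

    df: pd.DataFrame
    max_dist: float

    def __post_init__(self) -> None:
        if len(self.df) and self.df["post_id"].duplicated().any():
            raise ValueError("each post may be paired at most once")
        if len(self.df) and (self.df["distance_um"] > self.max_dist + 1e-12).any():
            raise ValueError("pair distance exceeds max_dist")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class EnrichmentResult:
    """Conditional vs baseline tau probabilities for paired postsynapses.

    ``p_cond``: % tau+ posts among posts whose paired pre is tau+.
    ``p_base``: % tau+ posts among all paired posts, regardless of the
    partner's tau status.  ``ratio = p_cond / p_base``.  A secondary
    ``ratio_vs_tau_negative_pre`` uses only tau- -pre posts as baseline.
    Degenerate denominators leave the result undefined with a reason, never
    silently 0 or infinite.
    """

    n_paired_posts: int
    n_paired_posts_tau: int
    n_posts_with_tau_pre: int
    n_posts_with_tau_pre_and_tau: int
    p_cond: float
    p_base: float
    ratio: float
    percent_pairs_tau_both_sides: float
    ratio_vs_tau_negative_pre: float
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


def find_pairs(
    post: ObjectTable | pd.DataFrame,
    pre: ObjectTable | pd.DataFrame,
    max_dist: float = 0.5,
) -> PairTable:
    """Pair each postsynapse to its nearest presynapse within ``max_dist`` um.

    The boundary is inclusive ("had to be <= 0.5 um").  Accepts object tables
    or bare DataFrames with ``id, cx, cy, cz`` columns.  Empty inputs produce
    an empty pair table.
    """
    post_df = post.df if isinstance(post, ObjectTable) else post
    pre_df = pre.df if isinstance(pre, ObjectTable) else pre
    cols = ["post_id", "pre_id", "distance_um"]
    if post_df.empty or pre_df.empty:
        return PairTable(df=pd.DataFrame(columns=cols), max_dist=max_dist)

    post_xyz = post_df[["cx", "cy", "cz"]].to_numpy(dtype=float)
    pre_xyz = pre_df[["cx", "cy", "cz"]].to_numpy(dtype=float)
    tree = cKDTree(pre_xyz)
    dist, idx = tree.query(post_xyz, k=1)
    keep = dist <= max_dist
    df = pd.DataFrame(
        {
            "post_id": post_df["id"].to_numpy()[keep],
            "pre_id": pre_df["id"].to_numpy()[idx[keep]],
            "distance_um": dist[keep],
        }
    )
    return PairTable(df=df, max_dist=max_dist)


def attach_tau_flags(
    pairs: PairTable,
    tau_pre: pd.Series | dict,
    tau_post: pd.Series | dict,
) -> PairTable:
    """Join per-object tau colocalization flags onto a pair table.

    ``tau_pre``/``tau_post`` map object id -> bool (e.g. the ``colocalized``
    flags of a :class:`~arraytomo.quantify.ColocResult` against the tau mask).
    """
    df = pairs.df.copy()
    pre_map = pd.Series(tau_pre)
    post_map = pd.Series(tau_post)
    df["tau_pre"] = df["pre_id"].map(pre_map).astype(bool)
    df["tau_post"] = df["post_id"].map(post_map).astype(bool)
    return PairTable(df=df, max_dist=pairs.max_dist)


def enrichment_ratio(pairs: PairTable) -> EnrichmentResult:
    """Conditional tau-enrichment of paired postsynapses.

    Requires ``tau_pre``/``tau_post`` columns (see :func:`attach_tau_flags`).
    """
    df = pairs.df
    for col in ("tau_pre", "tau_post"):
        if col not in df.columns:
            raise ValueError(f"pair table lacks {col!r}; join tau flags first")
    n = len(df)
    n_tau_post = int(df["tau_post"].sum()) if n else 0
    n_tau_pre = int(df["tau_pre"].sum()) if n else 0
    n_both = int((df["tau_pre"] & df["tau_post"]).sum()) if n else 0

    reason = None
    if n == 0:
        reason = "no pairs"
    elif n_tau_pre == 0:
        reason = "no tau-positive presynapses"
    elif n_tau_post == 0:
        reason = "baseline tau rate is zero"

    p_cond = 100.0 * n_both / n_tau_pre if n_tau_pre else float("nan")
    p_base = 100.0 * n_tau_post / n if n else float("nan")
    ratio = p_cond / p_base if reason is None else float("nan")
    pct_both = 100.0 * n_both / n if n else float("nan")

    n_neg_pre = n - n_tau_pre
    n_neg_pre_tau = n_tau_post - n_both
    if reason is None and n_neg_pre > 0 and n_neg_pre_tau > 0:
        ratio_neg = (p_cond) / (100.0 * n_neg_pre_tau / n_neg_pre)
    else:
        ratio_neg = float("nan")

    return EnrichmentResult(
        n_paired_posts=n,
        n_paired_posts_tau=n_tau_post,
        n_posts_with_tau_pre=n_tau_pre,
        n_posts_with_tau_pre_and_tau=n_both,
        p_cond=float(p_cond),
        p_base=float(p_base),
        ratio=float(ratio),
        percent_pairs_tau_both_sides=float(pct_both),
        ratio_vs_tau_negative_pre=float(ratio_neg),
        undefined_reason=reason,
    )
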