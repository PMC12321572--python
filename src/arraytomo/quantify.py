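"""Per-stack measurements: burden, neuropil density, and colocalization.

Two colocalization currencies are computed every run, matching how array
tomography results are usually reported:

* object level — the fraction of channel-A puncta whose 3D volume overlaps
  the channel-B positive mask by at least a threshold fraction (25% by
  default, boundary inclusive);
* voxel level — the percentage of channel-A positive voxels (optionally
  excluding somatic aggregates) that fall inside the channel-B mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import BinaryStack, ObjectTable

__all__ = [
    "BurdenResult",
    "ColocResult",
    "burden",
    "density",
    "colocalize_objects",
    "volume_fraction_in",
]


@dataclass(frozen=True)
class BurdenResult:
    """Percentage of the analyzed volume occupied by positive staining."""

    channel: str
    percent_volume: float
    analyzed_volume: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_volume <= 100:
            raise ValueError("percent_volume must be within [0, 100]")


@dataclass
class ColocResult:
    """Object-level colocalization of channel A objects against mask B.

    ``per_object`` columns: ``id, overlap_fraction, colocalized, somatic``.
    Summary percentages are computed over non-somatic A objects.
    """

    channel_a: str
    channel_b: str
    threshold: float
    per_object: pd.DataFrame
    percent_objects_colocalized: float
    percent_volume_in_b: float

    @property
    def flags(self) -> pd.Series:
        return self.per_object.set_index("id")["colocalized"]


def burden(mask: BinaryStack) -> BurdenResult:
    """Staining burden: 100 x positive voxels / valid voxels."""
    valid = mask.valid()
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("degenerate input: no valid voxels in stack")
    positive = int((mask.mask & valid).sum())
    return BurdenResult(
        channel=mask.channel,
        percent_volume=100.0 * positive / n_valid,
        analyzed_volume=mask.analyzed_volume,
    )


def density(objects: ObjectTable, exclude_somatic: bool = True) -> float:
    """Object density in the neuropil, puncta per um^3."""
    if objects.analyzed_volume <= 0:
        raise ValueError("analyzed volume must be > 0")
    df = objects.df
    if exclude_somatic:
        df = df[~df["somatic"]]
    return len(df) / objects.analyzed_volume


def colocalize_objects(
    objects_a: ObjectTable, mask_b: BinaryStack, threshold: float = 0.25
) -> ColocResult:
    """Object-level colocalization of A puncta with the B mask.

    For each A object the overlap fraction is ``|voxels(A) ∩ positive(B)| /
    |voxels(A)|``; the object is colocalized iff the fraction reaches the
    threshold (inclusive).  B enters as a mask union, so how B was split into
    objects cannot change the result.  Summary percentages are over
    non-somatic A objects.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if objects_a.labels is None:
        raise ValueError("objects_a must carry a labelled volume (segmented origin)")
    if objects_a.labels.shape != mask_b.mask.shape:
        raise ValueError(
            f"geometry mismatch: labels {objects_a.labels.shape} vs mask {mask_b.mask.shape}"
        )
    df = objects_a.df
    ids = df["id"].to_numpy()
    if len(ids):
        inter = ndimage.sum_labels(
            mask_b.mask.astype(np.float64), labels=objects_a.labels, index=ids
        )
        frac = inter / df["n_voxels"].to_numpy(dtype=float)
    else:
        frac = np.zeros(0)
    flags = frac >= threshold
    per_object = pd.DataFrame(
        {
            "id": ids,
            "overlap_fraction": frac,
            "colocalized": flags,
            "somatic": df["somatic"].to_numpy(),
        }
    )
    neuropil = per_object[~per_object["somatic"]]
    pct_obj = 100.0 * neuropil["colocalized"].mean() if len(neuropil) else float("nan")

    labels = objects_a.labels
    somatic_ids = df.loc[df["somatic"], "id"].to_numpy()
    a_voxels = np.isin(labels, df.loc[~df["somatic"], "id"].to_numpy()) if len(somatic_ids) else labels > 0
    n_a = int(a_voxels.sum())
    pct_vol = 100.0 * int((a_voxels & mask_b.mask).sum()) / n_a if n_a else float("nan")

    return ColocResult(
        channel_a=objects_a.channel,
        channel_b=mask_b.channel,
        threshold=threshold,
        per_object=per_object,
        percent_objects_colocalized=float(pct_obj),
        percent_volume_in_b=float(pct_vol),
    )


def volume_fraction_in(
    mask_a: BinaryStack,
    mask_b: BinaryStack,
    exclude: np.ndarray | None = None,
) -> float:
    """Percentage of A-positive voxels lying inside the B mask.

    ``exclude`` is an optional boolean stack of A voxels to leave out (e.g.
    somatic aggregates, per "neuropil only" analyses).  Returns NaN with a
    warning when no A voxels remain: an empty denominator is reported as
    missing, never as 0.
    """
    if mask_a.mask.shape != mask_b.mask.shape:
        raise ValueError("masks must share geometry and shape")
    a = mask_a.mask
    if exclude is not None:
        a = a & ~exclude
    n_a = int(a.sum())
    if n_a == 0:
        warnings.warn("volume_fraction_in: channel A mask is empty; result undefined")
        return float("nan")
    return 100.0 * int((a & mask_b.mask).sum()) / n_a
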