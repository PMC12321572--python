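"""End-to-end orchestration: stack in, tidy result tables out.

The canonical order is align -> segment -> extract -> flag somatic ->
quantify (burden, density, colocalization) -> pair -> enrichment.  Each step
is a pure function from the corresponding module; this module only wires
them together and shapes the outputs into per-stack tidy rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .pairing import EnrichmentResult, PairTable, attach_tau_flags, enrichment_ratio, find_pairs
from .quantify import burden, colocalize_objects, density, volume_fraction_in
from .registration import align_stack
from .segmentation import BinaryStack, ObjectTable, extract_objects, flag_somatic, segment_channel
from .stacks import MultiChannelStack

__all__ = ["StackResults", "run_pipeline"]


@dataclass
class StackResults:
    """All per-stack outputs of one pipeline run."""

    masks: dict[str, BinaryStack]
    objects: dict[str, ObjectTable]
    burden: pd.DataFrame
    density: pd.DataFrame
    coloc: pd.DataFrame
    pairs: PairTable | None
    enrichment: EnrichmentResult | None
    transforms: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        """Tidy tables ready for :func:`arraytomo.config.write_tables`."""
        out = {
            "burden": self.burden,
            "density": self.density,
            "colocalization": self.coloc,
            "objects": pd.concat([t.df for t in self.objects.values()], ignore_index=True),
        }
        if self.transforms is not None:
            out["transforms"] = self.transforms
        if self.pairs is not None:
            out["pairs"] = self.pairs.df
        if self.enrichment is not None:
            e = self.enrichment
            out["enrichment"] = pd.DataFrame(
                [
                    {
                        "n_paired_posts": e.n_paired_posts,
                        "n_paired_posts_tau": e.n_paired_posts_tau,
                        "n_posts_with_tau_pre": e.n_posts_with_tau_pre,
                        "n_posts_with_tau_pre_and_tau": e.n_posts_with_tau_pre_and_tau,
                        "p_cond_percent": e.p_cond,
                        "p_base_percent": e.p_base,
                        "ratio": e.ratio,
                        "percent_pairs_tau_both_sides": e.percent_pairs_tau_both_sides,
                        "ratio_vs_tau_negative_pre": e.ratio_vs_tau_negative_pre,
                        "undefined_reason": e.undefined_reason or "",
                    }
                ]
            )
        return out


def run_pipeline(
    stack: MultiChannelStack,
    config: PipelineConfig | None = None,
    align: bool = True,
) -> StackResults:
    """Run the full analysis on one multichannel stack.

    Channels are interpreted through ``config.channel_roles``; the tau
    channel provides the pathology mask, the pre/post channels the synaptic
    object tables.  Pairing and enrichment are computed when both synaptic
    roles are present.
    """
    config = config or PipelineConfig()
    transforms = None
    if align and not stack.aligned:
        reference = config.reference_channel
        if reference not in stack.channels:
            reference = stack.channel_names[0]
        stack, transforms = align_stack(stack, reference_channel=reference)

    roles: dict[str, str] = {}
    for ch, role in config.channel_roles.items():
        if ch in stack.channels:
            roles[role] = ch

    masks: dict[str, BinaryStack] = {}
    objects: dict[str, ObjectTable] = {}
    burden_rows, density_rows = [], []
    for ch in stack.channel_names:
        m = segment_channel(stack, ch, config)
        masks[ch] = m
        b = burden(m)
        burden_rows.append(
            {"channel": ch, "percent_volume": b.percent_volume,
             "analyzed_volume_um3": b.analyzed_volume}
        )
        objs = extract_objects(m, config)
        objs = flag_somatic(objs, config.somatic_volume_threshold)
        objects[ch] = objs
        density_rows.append(
            {"channel": ch, "density_per_um3": density(objs, exclude_somatic=True),
             "n_objects": len(objs)}
        )

    coloc_rows = []
    tau_ch = roles.get("tau")
    for role in ("pre", "post"):
        ch = roles.get(role)
        if ch is None or tau_ch is None:
            continue
        res = colocalize_objects(objects[ch], masks[tau_ch], config.coloc_min_overlap)
        coloc_rows.append(
            {
                "channel_a": ch, "channel_b": tau_ch,
                "percent_objects_colocalized": res.percent_objects_colocalized,
                "percent_volume_in_b": res.percent_volume_in_b,
                "threshold": config.coloc_min_overlap,
            }
        )
    if tau_ch is not None:
        for role in ("pre", "post"):
            ch = roles.get(role)
            if ch is None:
                continue
            somatic_ids = objects[tau_ch].df.loc[objects[tau_ch].df["somatic"], "id"]
            exclude = None
            if len(somatic_ids) and objects[tau_ch].labels is not None:
                import numpy as np

                exclude = np.isin(objects[tau_ch].labels, somatic_ids.to_numpy())
            coloc_rows.append(
                {
                    "channel_a": tau_ch, "channel_b": ch,
                    "percent_objects_colocalized": float("nan"),
                    "percent_volume_in_b": volume_fraction_in(
                        masks[tau_ch], masks[ch], exclude=exclude
                    ),
                    "threshold": float("nan"),
                }
            )
    astro_ch = roles.get("astro")
    if astro_ch is not None:
        for role in ("pre", "post"):
            ch = roles.get(role)
            if ch is None:
                continue
            res = colocalize_objects(objects[ch], masks[astro_ch], config.coloc_min_overlap)
            coloc_rows.append(
                {
                    "channel_a": ch, "channel_b": astro_ch,
                    "percent_objects_colocalized": res.percent_objects_colocalized,
                    "percent_volume_in_b": res.percent_volume_in_b,
                    "threshold": config.coloc_min_overlap,
                }
            )

    pairs = None
    enrich = None
    pre_ch, post_ch = roles.get("pre"), roles.get("post")
    if pre_ch is not None and post_ch is not None:
        pairs = find_pairs(objects[post_ch], objects[pre_ch], config.pair_max_dist)
        if tau_ch is not None and len(pairs):
            pre_flags = colocalize_objects(
                objects[pre_ch], masks[tau_ch], config.coloc_min_overlap
            ).flags
            post_flags = colocalize_objects(
                objects[post_ch], masks[tau_ch], config.coloc_min_overlap
            ).flags
            pairs = attach_tau_flags(pairs, pre_flags, post_flags)
            enrich = enrichment_ratio(pairs)

    return StackResults(
        masks=masks,
        objects=objects,
        burden=pd.DataFrame(burden_rows),
        density=pd.DataFrame(density_rows),
        coloc=pd.DataFrame(coloc_rows),
        pairs=pairs,
        enrichment=enrich,
        transforms=transforms,
    )
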