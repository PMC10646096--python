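"""Summaries of knockdown effects over an annotated peroxisomal proteome.

Restricts differential tables to a curated peroxisomal annotation (with
peroxins — PEX biogenesis/import factors — flagged), and derives the two
screen-level read-outs: the cumulative transcription-independent log2
fold-change of PEX proteins per knockdown, and per-PEX counts of how many
knockdowns modulate it in each direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential_omics import ModulationCalls

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """Curated protein list with a peroxin flag per member."""

    members: set
    is_pex: set = field(default_factory=set)
    source: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)
        self.is_pex = set(self.is_pex)
        if not self.is_pex <= self.members:
            raise ValueError("is_pex must be a subset of members")


def subset_panel(diff: pd.DataFrame, annotation: AnnotationSet) -> pd.DataFrame:
    """Differential rows restricted to annotated members, volcano-ready.

    Adds ``neg_log10_p`` and ``is_pex``; the number of members detected in
    the table is logged and attached as ``n_detected``.
    """
    detected = diff.index.intersection(pd.Index(sorted(annotation.members)))
    if len(detected) == 0:
        logger.warning("no annotated member detected in the differential table")
    out = diff.loc[detected].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    out["is_pex"] = out.index.isin(annotation.is_pex)
    out.attrs["n_detected"] = len(detected)
    out.attrs["n_annotation"] = len(annotation.members)
    logger.info("panel: %d/%d annotated members detected",
                len(detected), len(annotation.members))
    return out


def cumulative_pex_log2fc(calls: ModulationCalls, annotation: AnnotationSet,
                          require_txn_independent: bool = True,
                          split_directions: bool = False) -> pd.DataFrame:
    """Per-condition cumulative log2 fold-change over PEX proteins.

    Only significant calls contribute (transcription-independent ones by
    default); everything else contributes 0.  Sums are signed, so ups and
    downs can cancel; ``split_directions`` adds separate up/down sums.
    """
    t = calls.table
    pex = t[t["protein"].isin(annotation.is_pex)].copy()
    sig = pex["direction"] != "none"
    if require_txn_independent:
        sig &= pex["transcription_independent"]
    pex["contrib"] = np.where(sig, pex["log2fc"], 0.0)

    conditions = sorted(t["condition"].unique())
    grouped = pex.groupby("condition")
    total = grouped["contrib"].sum().reindex(conditions).fillna(0.0)
    out = pd.DataFrame({"cumulative_log2fc": total})
    if split_directions:
        up = pex[pex["contrib"] > 0].groupby("condition")["contrib"].sum()
        down = pex[pex["contrib"] < 0].groupby("condition")["contrib"].sum()
        out["cumulative_up"] = up.reindex(conditions).fillna(0.0)
        out["cumulative_down"] = down.reindex(conditions).fillna(0.0)
    out.index.name = "condition"
    return out


def pex_regulator_counts(calls: ModulationCalls,
                         annotation: AnnotationSet) -> pd.DataFrame:
    """Per-PEX counts of conditions with transcription-independent calls,
    split by direction (n_up, n_down)."""
    t = calls.table
    hits = t[t["protein"].isin(annotation.is_pex)
             & (t["direction"] != "none")
             & t["transcription_independent"]]
    pex_ids = sorted(annotation.is_pex)
    up = (hits[hits["direction"] == "up"].groupby("protein")["condition"]
          .nunique().reindex(pex_ids).fillna(0).astype(int))
    down = (hits[hits["direction"] == "down"].groupby("protein")["condition"]
            .nunique().reindex(pex_ids).fillna(0).astype(int))
    return pd.DataFrame({"n_up": up, "n_down": down}).rename_axis("protein")
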