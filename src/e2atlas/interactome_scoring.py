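"""Spectral-count interaction scoring and network assembly for IP-MS data.

Bait pull-downs are scored against no-bait control purifications.  Counts
are first normalised for protein size (counts per residue) and rescaled to
the median prey length, then each bait replicate is compared against the
control background with a Poisson mid-p enrichment probability.  An
externally computed probability column (e.g. SAINT output) can override the
built-in score.  Significant pairs (probability >= 0.65 by default) are
optionally filtered further against a contaminant-frequency table and a
max-spectral-count excess rule before assembly into an annotated network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Bait label marking no-bait control purifications.
CONTROL = "CONTROL"

#: Inclusive probability threshold for a significantly enriched interactor.
DEFAULT_THRESHOLD = 0.65

#: Floor on the control Poisson rate, in rescaled counts; keeps the score
#: defined for preys never seen in controls.
DEFAULT_PSEUDO_RATE = 0.1

ROLES = ("UBL", "E1", "E2", "E3", "DUB", "proteasome", "autophagy", "other")


@dataclass
class SpectralCountTable:
    """Long-format spectral counts plus prey lengths.

    ``counts`` columns: run, bait (bait label or ``CONTROL``), prey, count
    (non-negative integer).  ``lengths`` maps every prey appearing in
    ``counts`` to its residue count.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        required = {"run", "bait", "prey", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"counts table lacks columns: {sorted(missing)}")
        c = self.counts["count"]
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("spectral counts must be non-negative integers")
        preys = set(self.counts["prey"])
        no_length = preys - set(self.lengths.index)
        if no_length:
            raise ValueError(f"preys without a length entry: {sorted(no_length)[:5]}")
        if (self.lengths <= 0).any():
            raise ValueError("protein lengths must be positive")
        if not (self.counts["bait"] == CONTROL).any():
            raise ValueError("need at least one control run")

    @property
    def baits(self) -> list[str]:
        return sorted(set(self.counts["bait"]) - {CONTROL})

    def runs_of(self, bait: str) -> list[str]:
        return sorted(self.counts.loc[self.counts["bait"] == bait, "run"].unique())


def normalize_spectral_counts(table: SpectralCountTable) -> pd.DataFrame:
    """Add a counts-per-residue column; raw counts are kept alongside."""
    out = table.counts.copy()
    out["norm_count"] = out["count"] / out["prey"].map(table.lengths)
    return out


def _run_by_prey(table: SpectralCountTable, runs: list[str],
                 preys: pd.Index) -> np.ndarray:
    """Dense runs x preys count matrix (absent entries are zero counts)."""
    sub = table.counts[table.counts["run"].isin(runs)]
    pivot = sub.pivot_table(index="run", columns="prey", values="count",
                            aggfunc="sum", fill_value=0)
    pivot = pivot.reindex(index=runs, columns=preys, fill_value=0)
    return pivot.to_numpy(float)


def enrichment_probability(table: SpectralCountTable, bait: str,
                           pseudo_rate: float = DEFAULT_PSEUDO_RATE,
                           preys: list | None = None,
                           external_scores: pd.Series | None = None
                           ) -> pd.DataFrame:
    """Poisson mid-p enrichment probability of each prey for one bait.

    Counts are length-normalised and rescaled to the median prey length; the
    control background rate for a prey is the mean of its rescaled control
    counts, floored at ``pseudo_rate``.  Each bait replicate with rescaled
    count k contributes P(X < k) + 0.5 P(X = k) under X ~ Poisson(rate), and
    the score is the mean over replicates — in [0, 1] and monotone
    non-decreasing in every bait replicate count.

    ``external_scores`` (prey -> probability, e.g. SAINT output) overrides
    the built-in score where present; the source is recorded per row.
    Returns one row per prey: mean_norm_sc, max_sc_bait, max_sc_control,
    score, score_source.
    """
    bait_runs = table.runs_of(bait)
    if not bait_runs:
        raise ValueError(f"bait {bait!r} has no runs")
    ctrl_runs = table.runs_of(CONTROL)

    if preys is None:
        seen = table.counts[(table.counts["bait"] == bait)
                            & (table.counts["count"] > 0)]["prey"]
        # the bait protein itself is always scored so self-enrichment is
        # checkable even when it was not detected in its own runs
        preys = sorted(set(seen) | ({bait} if bait in table.lengths.index else set()))
    preys = pd.Index(preys)

    median_len = float(table.lengths.median())
    scale = median_len / table.lengths.reindex(preys).to_numpy(float)

    bait_counts = _run_by_prey(table, bait_runs, preys)      # reps x preys
    ctrl_counts = _run_by_prey(table, ctrl_runs, preys)      # ctrls x preys

    rate = np.maximum(ctrl_counts.mean(axis=0) * scale, pseudo_rate)
    k = np.round(bait_counts * scale[None, :])
    score = np.mean(stats.poisson.cdf(k, rate[None, :])
                    - 0.5 * stats.poisson.pmf(k, rate[None, :]), axis=0)

    out = pd.DataFrame(
        {"bait": bait,
         "mean_norm_sc": bait_counts.mean(axis=0) / table.lengths.reindex(preys).to_numpy(float),
         "max_sc_bait": bait_counts.max(axis=0).astype(int),
         "max_sc_control": ctrl_counts.max(axis=0).astype(int),
         "score": np.clip(score, 0.0, 1.0),
         "score_source": "midp"},
        index=preys.rename("prey"))
    if external_scores is not None:
        ext = external_scores.reindex(preys)
        use = ext.notna().to_numpy()
        out.loc[use, "score"] = ext[use].astype(float)
        out.loc[use, "score_source"] = "external"
    return out


def score_all_baits(table: SpectralCountTable,
                    pseudo_rate: float = DEFAULT_PSEUDO_RATE,
                    external_scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Concatenated enrichment table over every bait in the table.

    ``external_scores``: optional long DataFrame (bait, prey, score) of
    externally computed probabilities taking precedence over the stand-in.
    """
    frames = []
    for bait in table.baits:
        ext = None
        if external_scores is not None:
            sub = external_scores[external_scores["bait"] == bait]
            ext = sub.set_index("prey")["score"]
        frames.append(enrichment_probability(table, bait, pseudo_rate,
                                             external_scores=ext).reset_index())
    return pd.concat(frames, ignore_index=True)


def filter_interactions(scores: pd.DataFrame,
                        threshold: float = DEFAULT_THRESHOLD,
                        max_contaminant_freq: float | None = None,
                        contaminant_freq: pd.Series | None = None,
                        require_max_sc_excess: bool = False) -> pd.DataFrame:
    """Retain significantly enriched (bait, prey) pairs.

    A pair survives iff score >= threshold (inclusive), and — when the
    corresponding filters are enabled — its contaminant frequency is at most
    ``max_contaminant_freq`` and its maximum bait spectral count strictly
    exceeds the maximum control spectral count.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = scores.copy()
    if "prey" not in out.columns:
        out = out.reset_index()
    keep = out["score"] >= threshold
    if max_contaminant_freq is not None:
        freq = (out["prey"].map(contaminant_freq).fillna(0.0)
                if contaminant_freq is not None
                else out.get("contaminant_freq", pd.Series(0.0, index=out.index)))
        out["contaminant_freq"] = freq
        keep &= freq <= max_contaminant_freq
    if require_max_sc_excess:
        keep &= out["max_sc_bait"] > out["max_sc_control"]
    return out[keep].reset_index(drop=True)


def bait_self_enrichment_check(scores: pd.DataFrame,
                               bait_protein: dict | None = None,
                               threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Report baits whose own protein misses the threshold in their pull-down.

    ``bait_protein`` maps bait label -> protein id (identity by default).
    On well-formed data every bait is enriched in its own purification and
    the report is empty.  A bait absent from its own score rows is reported
    with score NaN.
    """
    failures = []
    for bait in sorted(scores["bait"].unique()):
        own = bait_protein.get(bait, bait) if bait_protein else bait
        rows = scores[(scores["bait"] == bait) & (scores["prey"] == own)]
        self_score = float(rows["score"].max()) if len(rows) else np.nan
        if not (self_score >= threshold):
            failures.append({"bait": bait, "self_score": self_score})
    return pd.DataFrame(failures, columns=["bait", "self_score"])


def build_network(edges: pd.DataFrame, roles: pd.Series | dict | None = None
                  ) -> nx.DiGraph:
    """Assemble the annotated bait -> prey interaction network.

    Each node carries a functional role (UBL, E1, E2, E3, DUB, proteasome,
    autophagy, other); endpoints missing from ``roles`` default to "other"
    with a logged warning.  Edge attributes keep the probability score.
    """
    roles = pd.Series(dtype=object) if roles is None else pd.Series(roles)
    net = nx.DiGraph()
    missing = []
    for _, row in edges.iterrows():
        for node in (row["bait"], row["prey"]):
            if node not in net:
                if node in roles.index:
                    role = roles[node]
                else:
                    role = "other"
                    missing.append(node)
                net.add_node(node, role=role)
        net.add_edge(row["bait"], row["prey"], score=float(row["score"]))
    if missing:
        logger.warning("no role annotation for %d proteins (set to 'other'): %s",
                       len(missing), sorted(set(missing))[:5])
    return net


def role_subnetwork(net: nx.DiGraph, keep_roles: set[str]) -> nx.DiGraph:
    """Subnetwork induced on nodes of the given roles (e.g. {"E2"} for the
    E2-E2 cross-interaction map)."""
    nodes = [n for n, d in net.nodes(data=True) if d.get("role") in keep_roles]
    return net.subgraph(nodes).copy()
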