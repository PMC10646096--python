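"""Cross-comparison statistics over E2 knockdown responses and interactomes.

For every pair of knockdown conditions the proteome response similarity is
the squared Pearson correlation (R^2) of their log2 fold-change profiles
over the regulated-protein selection, scaled by the number of regulated
proteins in the comparison (similarity score S = R^2 x n).  Because scores
from the same multiplexed TMT set share batch structure, each pair is
standardised within its own group: pairs from one set form that set's
intra-batch group, all cross-set pairs pool into the extra-batch group, and
z = (S - group mean) / group sample SD.  Interactome similarity applies the
same R^2 to enrichment-probability vectors, and pairwise global-alignment
sequence identity provides the third comparison layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .differential_omics import ModulationCalls

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: How the per-pair regulated count n is restricted:
#: "either"       — regulated by at least one of the two conditions (default)
#: "union"        — regulated by at least one condition anywhere in the screen
#: "intersection" — regulated by both conditions of the pair
PAIR_UNIVERSES = ("either", "union", "intersection")

EXTRA_BATCH_GROUP = "extra"


@dataclass
class SimilarityMatrix:
    """Symmetric condition x condition similarity layer.

    ``kind`` is one of {"r2", "score", "zscore"}.  ``n_regulated`` carries
    the per-pair regulated-protein count and ``group_of`` the z-scoring
    group label ("intra:<batch>" or "extra").  The diagonal is excluded
    from every statistic and stored as NaN.
    """

    values: pd.DataFrame
    kind: str
    n_regulated: pd.DataFrame | None = None
    group_of: pd.DataFrame | None = None

    @property
    def labels(self) -> list:
        return list(self.values.index)

    def pairs(self) -> pd.DataFrame:
        """Tidy upper-triangle view: one row per unordered pair."""
        rows = []
        for a, b in itertools.combinations(self.labels, 2):
            rows.append({
                "a": a, "b": b, self.kind: self.values.loc[a, b],
                "n_regulated": (self.n_regulated.loc[a, b]
                                if self.n_regulated is not None else np.nan),
                "group": (self.group_of.loc[a, b]
                          if self.group_of is not None else ""),
            })
        return pd.DataFrame(rows)


def _symmetric_frame(labels: list, fill=np.nan) -> pd.DataFrame:
    return pd.DataFrame(fill, index=pd.Index(labels), columns=pd.Index(labels))


# ---------------------------------------------------------------------------
# regulated-protein selection and R^2
# ---------------------------------------------------------------------------

def select_regulated_union(calls: ModulationCalls) -> set:
    """Proteins significantly modulated by at least one knockdown."""
    return set(calls.regulated()["protein"])


def regulated_by_condition(calls: ModulationCalls) -> dict[str, set]:
    reg = calls.regulated()
    return {c: set(g["protein"]) for c, g in reg.groupby("condition")}


def pairwise_r2(fc_a: pd.Series, fc_b: pd.Series, proteins: set | None = None,
                regulated_a: set | None = None, regulated_b: set | None = None,
                pair_universe: str = "either") -> tuple[float, int]:
    """Squared Pearson correlation of two fold-change profiles.

    The comparison is restricted to ``proteins`` (the regulated selection)
    quantified (non-NaN) in both conditions.  n_pair counts, within that
    restriction, the proteins regulated per ``pair_universe`` (see
    PAIR_UNIVERSES); without per-condition regulated sets it falls back to
    the size of the restriction.  Returns (NaN, n) for fewer than 3 shared
    proteins or a constant profile.
    """
    if pair_universe not in PAIR_UNIVERSES:
        raise ValueError(f"pair_universe must be one of {PAIR_UNIVERSES}")
    shared = fc_a.index.intersection(fc_b.index)
    if proteins is not None:
        shared = shared.intersection(pd.Index(sorted(proteins)))
    a = fc_a.reindex(shared)
    b = fc_b.reindex(shared)
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]

    if regulated_a is None and regulated_b is None:
        n_pair = len(a)
    else:
        reg_a = regulated_a or set()
        reg_b = regulated_b or set()
        in_comparison = set(a.index)
        if pair_universe == "intersection":
            n_pair = len(in_comparison & reg_a & reg_b)
        elif pair_universe == "either":
            n_pair = len(in_comparison & (reg_a | reg_b))
        else:  # union: whole selection, already applied via `proteins`
            n_pair = len(in_comparison)

    if len(a) < 3 or a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        return np.nan, n_pair
    r = np.corrcoef(a.to_numpy(float), b.to_numpy(float))[0, 1]
    return float(r * r), n_pair


def similarity_score(r2: float, n_pair: int) -> float:
    """S = R^2 x number of regulated proteins in the comparison."""
    if n_pair < 0:
        raise ValueError("n_pair must be >= 0")
    if np.isnan(r2):
        return np.nan
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise ValueError("r2 must lie in [0, 1]")
    return float(r2) * int(n_pair)


def proteome_similarity(fc_table: pd.DataFrame, calls: ModulationCalls,
                        pair_universe: str = "either"
                        ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Per-pair R^2 and similarity-score matrices from fold-change profiles.

    ``fc_table`` holds per-protein log2 fold-changes, one column per
    condition.  Returns (r2_matrix, score_matrix) with the per-pair
    regulated counts attached.
    """
    labels = list(fc_table.columns)
    selection = select_regulated_union(calls)
    per_cond = regulated_by_condition(calls)
    r2_m = _symmetric_frame(labels)
    n_m = _symmetric_frame(labels, fill=0.0)
    s_m = _symmetric_frame(labels)
    for a, b in itertools.combinations(labels, 2):
        r2, n = pairwise_r2(fc_table[a], fc_table[b], proteins=selection,
                            regulated_a=per_cond.get(a, set()),
                            regulated_b=per_cond.get(b, set()),
                            pair_universe=pair_universe)
        s = similarity_score(r2, n) if not np.isnan(r2) else np.nan
        r2_m.loc[a, b] = r2_m.loc[b, a] = r2
        n_m.loc[a, b] = n_m.loc[b, a] = n
        s_m.loc[a, b] = s_m.loc[b, a] = s
    return (SimilarityMatrix(r2_m, "r2", n_regulated=n_m),
            SimilarityMatrix(s_m, "score", n_regulated=n_m))


# ---------------------------------------------------------------------------
# batch-aware z-scores
# ---------------------------------------------------------------------------

def batch_zscores(s_matrix: SimilarityMatrix,
                  batch_of: dict) -> SimilarityMatrix:
    """Standardise similarity values within batch-defined groups.

    Pairs whose two conditions share a TMT set form that set's intra-batch
    group; all remaining pairs pool into one extra-batch group.  Within each
    group z = (value - group mean) / group sample SD; groups with fewer
    than two values or zero SD yield NaN.  The diagonal never enters any
    group.
    """
    labels = s_matrix.labels
    group_name = _symmetric_frame(labels, fill="")
    values: dict[str, list[tuple]] = {}
    for a, b in itertools.combinations(labels, 2):
        if batch_of[a] == batch_of[b]:
            g = f"intra:{batch_of[a]}"
        else:
            g = EXTRA_BATCH_GROUP
        group_name.loc[a, b] = group_name.loc[b, a] = g
        v = s_matrix.values.loc[a, b]
        values.setdefault(g, []).append((a, b, v))

    z_m = _symmetric_frame(labels)
    for g, triples in values.items():
        vals = np.array([v for _, _, v in triples], float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        for a, b, v in triples:
            z = (v - mean) / sd if not np.isnan(v) else np.nan
            z_m.loc[a, b] = z_m.loc[b, a] = z
    return SimilarityMatrix(z_m, "zscore", n_regulated=s_matrix.n_regulated,
                            group_of=group_name)


# ---------------------------------------------------------------------------
# interactome similarity
# ---------------------------------------------------------------------------

def interactome_r2(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """R^2 of two enrichment-probability vectors over the prey union.

    Preys scored for only one bait enter as 0.  Constant vectors give NaN;
    with a universe of fewer than 3 preys the two-point fit degeneracy
    (R^2 = 1 for any two distinct points) applies and is left to the caller
    to flag.
    """
    universe = scores_a.index.union(scores_b.index)
    a = scores_a.reindex(universe).fillna(0.0).to_numpy(float)
    b = scores_b.reindex(universe).fillna(0.0).to_numpy(float)
    if len(universe) < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def interactome_similarity(scores: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise interactome R^2 from a long (bait, prey, score) table."""
    baits = sorted(scores["bait"].unique())
    vectors = {b: g.set_index("prey")["score"] for b, g in scores.groupby("bait")}
    r2_m = _symmetric_frame(baits)
    for a, b in itertools.combinations(baits, 2):
        r2_m.loc[a, b] = r2_m.loc[b, a] = interactome_r2(vectors[a], vectors[b])
    return SimilarityMatrix(r2_m, "r2")


# ---------------------------------------------------------------------------
# global-alignment sequence identity
# ---------------------------------------------------------------------------

def sequence_identity(seq_a: str, seq_b: str, match: float = 1.0,
                      mismatch: float = 0.0, gap: float = -1.0) -> float:
    """Percent identity from a global (Needleman-Wunsch) alignment.

    identity = matches / alignment length x 100, with linear gap cost.
    Among equal-score alignments the one maximising matches, then
    minimising alignment length, is taken — this makes identity a
    well-defined function of the sequences rather than an artefact of
    traceback order.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for s in (seq_a, seq_b):
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"non amino-acid letters: {sorted(bad)}")
    n, m = len(seq_a), len(seq_b)
    # dp[j] = (score, matches, diag_steps); lexicographic maximisation.
    # Maximising diagonal steps minimises alignment length (= n+m-diag).
    prev = [(j * gap, 0, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(i * gap, 0, 0)] * (m + 1)
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            is_match = ai == seq_b[j - 1]
            ds, dm, dd = prev[j - 1]
            diag = (ds + (match if is_match else mismatch),
                    dm + (1 if is_match else 0), dd + 1)
            us, um, ud = prev[j]
            up = (us + gap, um, ud)
            ls, lm, ld = cur[j - 1]
            left = (ls + gap, lm, ld)
            cur[j] = max(diag, up, left)
        prev = cur
    score, matches, diag_steps = prev[m]
    aln_len = n + m - diag_steps
    return 100.0 * matches / aln_len


def identity_matrix(sequences: dict[str, str], **kwargs) -> pd.DataFrame:
    """Symmetric percent-identity matrix over named sequences."""
    labels = sorted(sequences)
    out = _symmetric_frame(labels)
    for a, b in itertools.combinations(labels, 2):
        ident = sequence_identity(sequences[a], sequences[b], **kwargs)
        out.loc[a, b] = out.loc[b, a] = ident
    for a in labels:
        out.loc[a, a] = np.nan  # diagonal excluded from all statistics
    return out


# ---------------------------------------------------------------------------
# layer comparison
# ---------------------------------------------------------------------------

def compare_similarity_layers(layers: dict[str, SimilarityMatrix | pd.DataFrame]
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-pair table and Spearman rank correlations between layers.

    Missing entries are excluded pairwise; a constant layer yields NaN
    (undefined, not zero).  Raises if no pair is shared across layers.
    """
    frames = {}
    for name, layer in layers.items():
        frames[name] = layer.values if isinstance(layer, SimilarityMatrix) else layer
    labels = None
    for f in frames.values():
        idx = set(f.index)
        labels = idx if labels is None else labels & idx
    labels = sorted(labels or set())
    pairs = list(itertools.combinations(labels, 2))
    if not pairs:
        raise ValueError("no overlapping pairs between layers")

    tidy = pd.DataFrame({"a": [p[0] for p in pairs], "b": [p[1] for p in pairs]})
    for name, f in frames.items():
        tidy[name] = [f.loc[a, b] for a, b in pairs]

    names = list(frames)
    corr = pd.DataFrame(np.nan, index=names, columns=names)
    np.fill_diagonal(corr.values, 1.0)
    for x, y in itertools.combinations(names, 2):
        both = tidy[[x, y]].dropna()
        if len(both) < 3 or both[x].nunique() < 2 or both[y].nunique() < 2:
            rho = np.nan
        else:
            rho = stats.spearmanr(both[x], both[y]).statistic
        corr.loc[x, y] = corr.loc[y, x] = rho
    return tidy, corr
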