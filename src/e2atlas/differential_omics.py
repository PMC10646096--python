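"""Differential abundance calling for multiplexed proteomics and RNA-seq.

Protein-level changes are tested per knockdown condition against the
non-targeting controls carried in the same multiplexed (TMT) set, with a
two-sample t-test on log2 abundances.  Gene-level changes are tested with a
Kruskal-Wallis / Dunn rank procedure on log2(TPM + 1).  The two layers are
then integrated to flag *transcription-independent* protein modulation:
a significant protein change with no corresponding mRNA change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Smallest p-value reported; keeps p in (0, 1] even for infinite statistics.
_P_FLOOR = np.nextafter(0.0, 1.0)

#: Default call thresholds: significance level and absolute log2 fold-change.
DEFAULT_ALPHA = 0.05
DEFAULT_FC = 0.2

#: Regulator-count bins: a protein modulated by k conditions falls in the
#: first bin whose (lo, hi) interval contains k.
REGULATOR_BINS = (("1", 1, 1), ("2-4", 2, 4), ("5-9", 5, 9), (">=10", 10, np.inf))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Proteins x samples log2 abundances with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, one column per sample, log2 scale.
        Missing quantifications are NaN.
    sample_meta
        DataFrame indexed by sample id with columns ``condition``, ``batch``,
        ``replicate`` and boolean ``is_control``.  Every batch must carry at
        least two control samples so the in-batch comparison is defined.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match value columns")
        required = {"condition", "batch", "replicate", "is_control"}
        missing = required - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta lacks columns: {sorted(missing)}")
        if self.sample_meta["batch"].isna().any():
            raise ValueError("every sample needs a batch")
        n_ctrl = self.sample_meta.groupby("batch")["is_control"].sum()
        if (n_ctrl < 2).any():
            bad = n_ctrl[n_ctrl < 2].index.tolist()
            raise ValueError(f"batches with <2 control samples: {bad}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    def conditions(self) -> list[str]:
        meta = self.sample_meta
        return sorted(meta.loc[~meta["is_control"], "condition"].unique())

    def batch_of(self, condition: str) -> object:
        meta = self.sample_meta
        batches = meta.loc[meta["condition"] == condition, "batch"].unique()
        if len(batches) == 0:
            raise KeyError(f"condition {condition!r} absent from sample_meta")
        if len(batches) > 1:
            raise ValueError(f"condition {condition!r} spans several batches")
        return batches[0]

    def group_columns(self, condition: str) -> tuple[list[str], list[str]]:
        """Sample ids of the knockdown group and its in-batch controls."""
        meta = self.sample_meta
        batch = self.batch_of(condition)
        case = meta.index[(meta["condition"] == condition) & ~meta["is_control"]]
        ctrl = meta.index[(meta["batch"] == batch) & meta["is_control"]]
        return list(case), list(ctrl)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM with the same sample-metadata layout."""

    tpm: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.tpm.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match tpm columns")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    def group_columns(self, condition: str) -> tuple[list[str], list[str]]:
        meta = self.sample_meta
        batches = meta.loc[meta["condition"] == condition, "batch"].unique()
        if len(batches) == 0:
            raise KeyError(f"condition {condition!r} absent from sample_meta")
        case = meta.index[(meta["condition"] == condition) & ~meta["is_control"]]
        ctrl = meta.index[meta["batch"].isin(batches) & meta["is_control"]]
        return list(case), list(ctrl)


@dataclass
class ModulationCalls:
    """Long-format per-(protein, condition) modulation calls.

    ``table`` columns: protein, condition, direction ({up, down, none}),
    transcription_independent, p_value, log2fc, rna_p_value, rna_log2fc.
    The thresholds used are recorded verbatim.
    """

    table: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    fc: float = DEFAULT_FC
    test: str = "student"
    rna_test: str = "dunn"
    n_unmapped: int = 0

    def regulated(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "none"]


# ---------------------------------------------------------------------------
# protein differential (t-test)
# ---------------------------------------------------------------------------

def _two_sample_t(case: np.ndarray, ctrl: np.ndarray, equal_var: bool
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised row-wise two-sample t-test with NaN-aware groups.

    Returns (log2fc, t, p, n_case, n_control); rows with fewer than two
    observations in either group come back NaN.  Zero pooled variance with
    equal means yields p = 1 (degenerate, information-free comparison);
    zero variance with distinct means yields p at the floor.
    """
    n1 = np.sum(~np.isnan(case), axis=1).astype(float)
    n2 = np.sum(~np.isnan(ctrl), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(np.where(np.isnan(case), np.nan, case), axis=1)
        m2 = np.nanmean(np.where(np.isnan(ctrl), np.nan, ctrl), axis=1)
        v1 = _nanvar(case, n1)
        v2 = _nanvar(ctrl, n2)
    diff = m1 - m2
    ok = (n1 >= 2) & (n2 >= 2)

    t = np.full(diff.shape, np.nan)
    p = np.full(diff.shape, np.nan)
    if equal_var:
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.where(df > 0, df, np.nan)
        se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, diff / se, np.nan)
    zero_se = ok & ~(se > 0)
    t = np.where(zero_se & (diff == 0), 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (diff != 0), np.copysign(np.inf, diff), t)
    with np.errstate(invalid="ignore"):
        p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, np.nan)), np.nan)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    p = np.where(zero_se & (diff != 0), _P_FLOOR, p)
    p = np.where(ok, np.clip(p, _P_FLOOR, 1.0), np.nan)
    diff = np.where(ok, diff, np.nan)
    return diff, t, p, n1, n2


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        out = np.where(n >= 2, np.nanvar(x, axis=1, ddof=1), np.nan)
    return out


def protein_differential(matrix: AbundanceMatrix, condition: str,
                         equal_var: bool = True) -> pd.DataFrame:
    """Per-protein differential table for one knockdown condition.

    log2fc is mean(condition samples) - mean(in-batch control samples);
    p comes from a two-sided pooled-variance (Student) t-test by default
    (``equal_var=False`` switches to Welch).  Proteins with fewer than two
    quantified replicates in either group are reported as missing (NaN).
    """
    case_cols, ctrl_cols = matrix.group_columns(condition)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"condition {condition!r}: need >=2 replicates per group "
            f"(got {len(case_cols)} vs {len(ctrl_cols)})")
    case = matrix.values[case_cols].to_numpy(float)
    ctrl = matrix.values[ctrl_cols].to_numpy(float)
    fc, t, p, n1, n2 = _two_sample_t(case, ctrl, equal_var=equal_var)
    out = pd.DataFrame(
        {"log2fc": fc, "p_value": p, "statistic": t,
         "n_case": n1.astype(int), "n_control": n2.astype(int)},
        index=matrix.protein_ids)
    out.attrs["condition"] = condition
    out.attrs["test"] = "student" if equal_var else "welch"
    return out


# ---------------------------------------------------------------------------
# RNA differential (Kruskal-Wallis + Dunn)
# ---------------------------------------------------------------------------

def _rank_stats(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Kruskal-Wallis H and p, and Dunn's z and p for the first two groups.

    Tie-corrected throughout.  All-tied input returns H = 0, p = 1 (the
    comparison carries no rank information).
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))

    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]

    h = (12.0 / (n_total * (n_total + 1))
         * sum(n_i * rbar**2 for n_i, rbar in zip(sizes, mean_ranks))
         - 3.0 * (n_total + 1))
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction <= 0:  # every observation tied
        return 0.0, 1.0, 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    p_kw = float(stats.chi2.sf(h, df=len(groups) - 1))
    p_kw = min(max(p_kw, _P_FLOOR), 1.0)

    # Dunn's z for group 0 vs group 1, tie-corrected variance
    var = ((n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1)))
           * (1.0 / sizes[0] + 1.0 / sizes[1]))
    if var <= 0:
        return h, p_kw, 0.0, 1.0
    z = (mean_ranks[0] - mean_ranks[1]) / np.sqrt(var)
    p_dunn = float(min(max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR), 1.0))
    return h, p_kw, float(z), p_dunn


def rna_differential(tpm: ExpressionMatrix, condition: str,
                     p_from: str = "dunn") -> pd.DataFrame:
    """Per-gene differential table on log2(TPM + 1) for one condition.

    Kruskal-Wallis H is computed across the {condition, control} groups
    (equivalent to a Wilcoxon rank-sum with two groups) and Dunn's
    tie-corrected pairwise z compares condition vs control.  ``p_from``
    selects which p populates the p_value column ({"dunn", "kw"}); both are
    reported.  log2fc is the difference of group means of log2(TPM + 1).
    """
    if p_from not in {"dunn", "kw"}:
        raise ValueError("p_from must be 'dunn' or 'kw'")
    case_cols, ctrl_cols = tpm.group_columns(condition)
    if len(case_cols) + len(ctrl_cols) < 3:
        raise ValueError("need at least 3 samples in total")
    log_case = np.log2(tpm.tpm[case_cols].to_numpy(float) + 1.0)
    log_ctrl = np.log2(tpm.tpm[ctrl_cols].to_numpy(float) + 1.0)

    n_genes = log_case.shape[0]
    h_arr = np.empty(n_genes)
    pkw_arr = np.empty(n_genes)
    z_arr = np.empty(n_genes)
    pdunn_arr = np.empty(n_genes)
    for i in range(n_genes):
        h_arr[i], pkw_arr[i], z_arr[i], pdunn_arr[i] = _rank_stats(
            [log_case[i], log_ctrl[i]])

    p = pdunn_arr if p_from == "dunn" else pkw_arr
    out = pd.DataFrame(
        {"log2fc": log_case.mean(axis=1) - log_ctrl.mean(axis=1),
         "p_value": p, "statistic": h_arr,
         "p_kw": pkw_arr, "p_dunn": pdunn_arr, "dunn_z": z_arr,
         "n_case": len(case_cols), "n_control": len(ctrl_cols)},
        index=tpm.gene_ids)
    out.attrs["condition"] = condition
    out.attrs["test"] = f"kruskal-dunn ({p_from})"
    return out


# ---------------------------------------------------------------------------
# integration: transcription-independent calls
# ---------------------------------------------------------------------------

def call_transcription_independent(protein: pd.DataFrame, rna: pd.DataFrame | None,
                                   alpha: float = DEFAULT_ALPHA,
                                   fc: float = DEFAULT_FC,
                                   mapping: pd.Series | None = None) -> pd.DataFrame:
    """Classify each protein's change and flag transcription independence.

    direction is "up" iff p < alpha and log2fc > fc, "down" iff p < alpha
    and log2fc < -fc, else "none".  A significant protein change is
    transcription-independent unless its gene shows a *corresponding* mRNA
    change: significant at the same alpha with |log2fc| > fc and the same
    sign.  ``mapping`` maps protein id -> gene id (identity by default);
    proteins without a mapped gene in ``rna`` are treated as lacking mRNA
    evidence and keep their protein-level call.
    """
    cond_p = protein.attrs.get("condition")
    cond_r = rna.attrs.get("condition") if rna is not None else cond_p
    if cond_p is not None and cond_r is not None and cond_p != cond_r:
        raise ValueError(f"condition mismatch: protein {cond_p!r} vs rna {cond_r!r}")

    p = protein["p_value"].to_numpy(float)
    lfc = protein["log2fc"].to_numpy(float)
    up = (p < alpha) & (lfc > fc)
    down = (p < alpha) & (lfc < -fc)
    direction = np.where(up, "up", np.where(down, "down", "none"))

    n_unmapped = 0
    if rna is None:
        rna_p = np.full(len(protein), np.nan)
        rna_fc = np.full(len(protein), np.nan)
        n_unmapped = len(protein)
    else:
        gene_ids = (protein.index.to_series().map(mapping)
                    if mapping is not None else protein.index.to_series())
        rna_p = rna["p_value"].reindex(gene_ids).to_numpy(float)
        rna_fc = rna["log2fc"].reindex(gene_ids).to_numpy(float)
        n_unmapped = int(np.isnan(rna_p).sum())
    if n_unmapped:
        logger.info("%d/%d proteins lack mRNA evidence; treated as no "
                    "corresponding mRNA change", n_unmapped, len(protein))

    with np.errstate(invalid="ignore"):
        corresponding = ((rna_p < alpha) & (np.abs(rna_fc) > fc)
                         & (np.sign(rna_fc) == np.sign(lfc)))
    corresponding = np.where(np.isnan(rna_p), False, corresponding)
    txn_independent = (direction != "none") & ~corresponding

    out = pd.DataFrame(
        {"direction": direction, "transcription_independent": txn_independent,
         "p_value": p, "log2fc": lfc, "rna_p_value": rna_p, "rna_log2fc": rna_fc},
        index=protein.index)
    out.attrs.update({"alpha": alpha, "fc": fc, "condition": cond_p,
                      "n_unmapped": n_unmapped})
    return out


def modulation_calls(abundance: AbundanceMatrix, expression: ExpressionMatrix | None,
                     alpha: float = DEFAULT_ALPHA, fc: float = DEFAULT_FC,
                     mapping: pd.Series | None = None, equal_var: bool = True,
                     rna_p_from: str = "dunn") -> ModulationCalls:
    """Run the full per-condition differential + integration pipeline."""
    rows = []
    total_unmapped = 0
    for condition in abundance.conditions():
        prot = protein_differential(abundance, condition, equal_var=equal_var)
        rna = (rna_differential(expression, condition, p_from=rna_p_from)
               if expression is not None else None)
        calls = call_transcription_independent(prot, rna, alpha=alpha, fc=fc,
                                               mapping=mapping)
        total_unmapped += calls.attrs["n_unmapped"]
        calls = calls.reset_index(names="protein")
        calls.insert(1, "condition", condition)
        rows.append(calls)
    table = pd.concat(rows, ignore_index=True)
    return ModulationCalls(table=table, alpha=alpha, fc=fc,
                           test="student" if equal_var else "welch",
                           rna_test=rna_p_from, n_unmapped=total_unmapped)


# ---------------------------------------------------------------------------
# regulator counts and over-representation
# ---------------------------------------------------------------------------

def count_regulators(calls: ModulationCalls) -> pd.DataFrame:
    """Per-protein count of conditions with a transcription-independent call.

    Returns a DataFrame indexed by protein with columns ``n_regulators`` and
    ``bin`` (1, 2-4, 5-9, >=10).  Proteins never called are excluded.
    """
    t = calls.table
    hit = t[(t["direction"] != "none") & t["transcription_independent"]]
    counts = hit.groupby("protein")["condition"].nunique()
    counts = counts[counts > 0]

    def binned(k: int) -> str:
        for name, lo, hi in REGULATOR_BINS:
            if lo <= k <= hi:
                return name
        raise AssertionError(k)

    return pd.DataFrame({"n_regulators": counts,
                         "bin": counts.map(binned)}).rename_axis("protein")


def overrepresentation(hits: set, universe: set,
                       gene_sets: dict[str, set]) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set among the hits.

    p is the upper-tail probability of drawing at least the observed overlap
    when sampling |hits| proteins from the universe; q is Benjamini-Hochberg
    across the tested sets.  Each set is intersected with the universe first.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    m_total = len(universe)
    n_hits = len(hits)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        k = len(in_universe & hits)
        n_set = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, m_total, n_set, n_hits)) if n_set else 1.0
        p = min(max(p, _P_FLOOR), 1.0)
        expected = n_hits * n_set / m_total
        fold = k / expected if expected > 0 else np.nan
        rows.append({"gene_set": name, "n_set": n_set, "n_overlap": k,
                     "fold_enrichment": fold, "p_value": p})
    out = pd.DataFrame(rows).set_index("gene_set")
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
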