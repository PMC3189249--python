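"""Integration of methylation calls with histone states and expression.

Promoters are classified into four histone states per sample — H3K4me3
only, H3K27me3 only, bivalent, or neither — from peak overlap with the TSS
± 2 kb window; gene-level methylation flags come from CMR calls whose
midpoint falls in the core promoter (-1.5 kb..+0.5 kb).  Cross-tabulations
give the percentage of methylated genes per histone state, state-transition
tables between samples (with destination-sample methylation counts), and
Welch t-test comparisons of expression between gene groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .cmr import METHYLATED

STATE_K4 = "K4"
STATE_K27 = "K27"
STATE_BIV = "bivalent"
STATE_NONE = "none"
STATES = (STATE_K4, STATE_K27, STATE_BIV, STATE_NONE)


def _overlap_genes(
    peaks: pd.DataFrame, genes: pd.DataFrame, window: int
) -> np.ndarray:
    """Boolean per gene: does any peak cover >= 1 bp of the closed window
    [tss - window, tss + window]?  Peaks are half-open, so a peak [s, e)
    overlaps iff s <= tss + window and e - 1 >= tss - window."""
    flags = np.zeros(len(genes), dtype=bool)
    trees: dict[str, IntervalTree] = {}
    for row in peaks.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree())[row.start : row.end] = True
    for i, g in enumerate(genes.itertuples(index=False)):
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        # closed window [tss-w, tss+w] -> half-open query [tss-w, tss+w+1)
        if tree.overlap(g.tss - window, g.tss + window + 1):
            flags[i] = True
    return flags


def assign_histone_state(
    k4_peaks: pd.DataFrame,
    k27_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 2000,
) -> pd.Series:
    """Four-state histone classification per gene.

    K4-only overlap → ``K4``; K27-only → ``K27``; both → ``bivalent``;
    neither → ``none``.  Overlap means >= 1 bp intersection with the closed
    TSS ± ``window`` interval.
    """
    has_k4 = _overlap_genes(k4_peaks, genes, window)
    has_k27 = _overlap_genes(k27_peaks, genes, window)
    state = np.where(
        has_k4 & has_k27,
        STATE_BIV,
        np.where(has_k4, STATE_K4, np.where(has_k27, STATE_K27, STATE_NONE)),
    )
    return pd.Series(state, index=genes["gene_id"].to_numpy(), name="state")


def gene_methylation_calls(
    cmrs: pd.DataFrame,
    genes: pd.DataFrame,
    sample: str,
    core_promoter: tuple[int, int] = (-1500, 500),
) -> pd.Series:
    """Gene-level methylation flag from region calls.

    A gene is methylated in ``sample`` when any CMR with a methylated state
    there has its midpoint inside the strand-aware core promoter window.
    """
    flags = pd.Series(False, index=genes["gene_id"].to_numpy())
    sub = cmrs[cmrs[f"state_{sample}"] == METHYLATED]
    if len(sub) == 0:
        return flags
    lo, hi = core_promoter
    g = genes.set_index("gene_id")
    for r in sub.itertuples(index=False):
        mid = (r.start + r.end) // 2
        cand = g[g["chrom"] == r.chrom]
        off = (mid - cand["tss"]) * cand["strand"].astype(int)
        flags.loc[cand.index[(off >= lo) & (off <= hi)]] = True
    return flags


def methylation_by_state(
    state_map: pd.Series, gene_calls: pd.Series
) -> pd.DataFrame:
    """Percentage of methylated genes within each histone state.

    Returns one row per state with ``n_genes, n_methylated, pct_methylated``
    (pct 0 for empty states); the counts sum to the gene universe.
    """
    calls = gene_calls.reindex(state_map.index, fill_value=False)
    rows = []
    for st in STATES:
        mask = (state_map == st).to_numpy()
        n = int(mask.sum())
        nm = int((mask & calls.to_numpy()).sum())
        rows.append(
            {
                "state": st,
                "n_genes": n,
                "n_methylated": nm,
                "pct_methylated": 100.0 * nm / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def transition_table(
    states_a: pd.Series, states_b: pd.Series, calls_b: pd.Series
) -> pd.DataFrame:
    """Histone-state transition counts between two samples.

    16 rows (state_a → state_b) with the number of genes taking each
    transition and how many of them are methylated in the destination
    sample; totals sum to the shared gene universe.
    """
    if not states_a.index.equals(states_b.index):
        raise ValueError("state maps must share the same gene universe")
    calls = calls_b.reindex(states_a.index, fill_value=False).to_numpy()
    a = states_a.to_numpy()
    b = states_b.to_numpy()
    rows = []
    for sa in STATES:
        for sb in STATES:
            mask = (a == sa) & (b == sb)
            rows.append(
                {
                    "from": sa,
                    "to": sb,
                    "total": int(mask.sum()),
                    "methylated": int((mask & calls).sum()),
                }
            )
    return pd.DataFrame(rows)


def compare_expression(
    expression: pd.DataFrame,
    group_a,
    group_b,
    sample: str,
) -> dict:
    """Welch two-sample t-test between gene groups on log2(signal + 1).

    Returns the t statistic, two-sided p-value, group sizes and the
    box-plot descriptive statistics (median, quartiles, 10th/90th
    percentiles) of the raw signals.
    """
    a = expression.loc[list(group_a), sample].to_numpy(dtype=float)
    b = expression.loc[list(group_b), sample].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two genes")
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    t, p = stats.ttest_ind(la, lb, equal_var=False)
    if np.isnan(t):  # zero variance in both groups
        t, p = (0.0, 1.0) if la.mean() == lb.mean() else (np.inf, 0.0)

    def describe(x):
        q = np.percentile(x, [10, 25, 50, 75, 90])
        return {
            "p10": q[0],
            "q1": q[1],
            "median": q[2],
            "q3": q[3],
            "p90": q[4],
        }

    return {
        "t": float(t),
        "p_value": float(p),
        "n_a": len(a),
        "n_b": len(b),
        "a": describe(a),
        "b": describe(b),
    }
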