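"""Candidate methylated region (CMR) calling and tri-state methylation calls.

A CMR starts life as a maximal run of probes scoring above the call
threshold (2.5) in one sample; runs from all samples are merged into single
regions wherever they overlap.  Regions are then gated twice: the mean
probe CpG density must exceed 5% (the analysis is restricted to CpG-rich
regions) and the best per-sample region score must exceed the
high-confidence threshold 3.0 in at least one sample.  Within surviving
regions the per-sample call is tri-state: score > 2.5 methylated,
score < 1.5 hypomethylated, in between (or missing) indeterminate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

METHYLATED = "methylated"
HYPO = "hypomethylated"
INDETERMINATE = "indeterminate"


def call_state(
    score: float, call_threshold: float = 2.5, hypo_threshold: float = 1.5
) -> str:
    """Tri-state methylation call for a region score.

    Strictly above ``call_threshold`` → methylated; strictly below
    ``hypo_threshold`` → hypomethylated; anything else — including the
    boundary values and missing scores — is indeterminate.
    """
    if score is None or not np.isfinite(score):
        return INDETERMINATE
    if score > call_threshold:
        return METHYLATED
    if score < hypo_threshold:
        return HYPO
    return INDETERMINATE


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals into a minimal disjoint set.

    Touching-but-not-overlapping intervals ([a,b) and [b,c)) are kept
    separate.  Idempotent and independent of input order.
    """
    if len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    df = intervals.sort_values(["chrom", "start", "end"], kind="mergesort")
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.chrom == cur[0] and row.start < cur[2]:
            cur[2] = max(cur[2], row.end)
        else:
            if cur is not None:
                out.append(tuple(cur))
            cur = [row.chrom, row.start, row.end]
    out.append(tuple(cur))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _sample_runs(track: pd.DataFrame, threshold: float, max_gap_bp: int) -> pd.DataFrame:
    """Maximal runs of above-threshold probes separated by <= max_gap_bp."""
    hits = track[track["score"] > threshold].sort_values(["chrom", "start"])
    if len(hits) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    chrom = hits["chrom"].to_numpy()
    start = hits["start"].to_numpy()
    end = hits["end"].to_numpy()
    gap_break = np.ones(len(hits), dtype=bool)
    gap_break[1:] = (chrom[1:] != chrom[:-1]) | (start[1:] - end[:-1] > max_gap_bp)
    run_id = np.cumsum(gap_break)
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": end, "run": run_id})
    runs = df.groupby("run").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    return runs.reset_index(drop=True)


def call_candidate_regions(
    score_table: pd.DataFrame,
    samples: list[str],
    call_threshold: float = 2.5,
    max_gap_bp: int = 300,
) -> pd.DataFrame:
    """Candidate methylated regions across a panel of samples.

    ``score_table`` holds the probe layout plus one ``score_<sample>``
    column per sample.  Per sample, probe runs above ``call_threshold``
    (gaps <= ``max_gap_bp``) become intervals; intervals overlapping across
    any samples are merged into single regions.  Order of samples does not
    affect the result.
    """
    pieces = []
    for s in samples:
        track = score_table[["chrom", "start", "end"]].copy()
        track["score"] = score_table[f"score_{s}"]
        pieces.append(_sample_runs(track, call_threshold, max_gap_bp))
    allruns = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    if len(allruns) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(allruns)


def region_scores(
    regions: pd.DataFrame, score_table: pd.DataFrame, samples: list[str]
) -> pd.DataFrame:
    """Per-sample region score = max member-probe score (probe centre inside
    the region); NaN when the region holds no scored probe."""
    centers = ((score_table["start"] + score_table["end"]) // 2).to_numpy()
    out = regions.reset_index(drop=True).copy()
    mats = {s: score_table[f"score_{s}"].to_numpy() for s in samples}
    for s in samples:
        out[f"score_{s}"] = np.nan
    order = np.argsort(centers)
    centers_sorted = centers[order]
    chrom_arr = score_table["chrom"].to_numpy()
    for i, row in enumerate(out.itertuples(index=False)):
        lo = np.searchsorted(centers_sorted, row.start, side="left")
        hi = np.searchsorted(centers_sorted, row.end, side="left")
        member = order[lo:hi]
        member = member[chrom_arr[member] == row.chrom]
        if len(member) == 0:
            continue
        for s in samples:
            vals = mats[s][member]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                out.iat[i, out.columns.get_loc(f"score_{s}")] = vals.max()
    return out


def region_cpg_density(
    regions: pd.DataFrame, probes: pd.DataFrame, stat: str = "mean"
) -> np.ndarray:
    """Region CpG density (%) summarised over member probes' 500-bp window
    densities; ``stat`` is 'mean' (default) or 'max'."""
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    centers = ((probes["start"] + probes["end"]) // 2).to_numpy()
    dens = probes["cpg_density"].to_numpy()
    order = np.argsort(centers)
    centers_sorted = centers[order]
    chrom_arr = probes["chrom"].to_numpy()
    out = np.full(len(regions), np.nan)
    for i, row in enumerate(regions.itertuples(index=False)):
        lo = np.searchsorted(centers_sorted, row.start, side="left")
        hi = np.searchsorted(centers_sorted, row.end, side="left")
        member = order[lo:hi]
        member = member[chrom_arr[member] == row.chrom]
        if len(member):
            vals = dens[member]
            out[i] = vals.mean() if stat == "mean" else vals.max()
    return out


def filter_cmrs(
    regions: pd.DataFrame,
    score_table: pd.DataFrame,
    samples: list[str],
    min_cpg_density: float = 5.0,
    hc_threshold: float = 3.0,
    call_threshold: float = 2.5,
    hypo_threshold: float = 1.5,
    density_stat: str = "mean",
) -> pd.DataFrame:
    """Apply the CpG-density and high-confidence gates; emit scored,
    tri-state-called CMRs.

    Keeps regions whose CpG density exceeds ``min_cpg_density`` (%) and
    whose best per-sample score exceeds ``hc_threshold`` in at least one
    sample; appends per-sample ``score_<s>`` and ``state_<s>`` columns.
    """
    scored = region_scores(regions, score_table, samples)
    scored["cpg_density"] = region_cpg_density(regions, score_table, stat=density_stat)
    score_cols = [f"score_{s}" for s in samples]
    best = scored[score_cols].max(axis=1)
    keep = (scored["cpg_density"] > min_cpg_density) & (best > hc_threshold)
    out = scored[keep].reset_index(drop=True)
    for s in samples:
        out[f"state_{s}"] = [
            call_state(v, call_threshold, hypo_threshold) for v in out[f"score_{s}"]
        ]
    return out
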