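"""Evaluation of calls against the planted truth.

Used by the test-bench side of the package: recovery (recall/precision) of
planted methylated regions, capture of the commonly methylated germline
class, T-DMR recovery, and realized probe-level false-discovery fractions.

A planted region only counts towards recall when the array interrogates it
(at least ``min_probes_in_region`` probe centres inside the interval):
planted-region placement is uniform out past the probed span so that
TSS-profile coverage stays flat to the array edges, and a region lying
(mostly) beyond the outermost probes cannot be recovered by any method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import (
    CLASS_CLUSTER,
    CLASS_COMMON,
    CLASS_ES_SOMATIC,
    CLASS_IMPRINTED,
    CLASS_LOW_CPG,
    CLASS_TDMR,
    SimulatedStudy,
    TrueMethylome,
)

HIGH_CPG_CLASSES = (CLASS_COMMON, CLASS_TDMR, CLASS_IMPRINTED, CLASS_CLUSTER, CLASS_ES_SOMATIC)


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: overlaps >= 1 bp of any target interval
    (same single chromosome assumed; intervals half-open)."""
    if len(targets) == 0:
        return np.zeros(len(query), dtype=bool)
    starts = targets["start"].to_numpy()
    ends = targets["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    max_end = np.maximum.accumulate(ends)
    out = np.zeros(len(query), dtype=bool)
    qs = query["start"].to_numpy()
    qe = query["end"].to_numpy()
    for i in range(len(query)):
        j = np.searchsorted(starts, qe[i], side="left") - 1
        out[i] = j >= 0 and max_end[j] > qs[i]
    return out


def probes_in_regions(regions: pd.DataFrame, probes: pd.DataFrame) -> np.ndarray:
    """Number of probe centres inside each region."""
    centers = np.sort(((probes["start"] + probes["end"]) // 2).to_numpy())
    lo = np.searchsorted(centers, regions["start"].to_numpy(), side="left")
    hi = np.searchsorted(centers, regions["end"].to_numpy(), side="left")
    return hi - lo


def planted_methylated_regions(
    truth: TrueMethylome,
    samples: list[str],
    classes=HIGH_CPG_CLASSES,
    min_level: float = 0.5,
) -> pd.DataFrame:
    """Planted regions of the given classes methylated in >= 1 arrayed sample."""
    reg = truth.regions
    lv = truth.levels.loc[reg["region_id"], list(samples)].to_numpy()
    mask = (lv >= min_level).any(axis=1) & reg["meth_class"].isin(classes).to_numpy()
    return reg[mask].reset_index(drop=True)


def region_recovery(
    study: SimulatedStudy,
    cmrs: pd.DataFrame,
    min_probes_in_region: int = 3,
) -> dict:
    """Recall and precision of CMR calling against the planted truth.

    recall: fraction of probed planted methylated CpG-rich regions
    overlapped by an emitted CMR; precision: fraction of emitted CMRs
    overlapping a planted methylated region (any class, since CpG-poor
    planted regions are also genuinely methylated).  Also reports how many
    emitted CMRs overlap planted regions whose CpG density class is low
    (these should be removed by the CpG gate).
    """
    samples = list(study.config.samples)
    planted_hi = planted_methylated_regions(study.truth, samples, HIGH_CPG_CLASSES)
    probed = probes_in_regions(planted_hi, study.annotation.probes) >= min_probes_in_region
    planted_hi = planted_hi[probed].reset_index(drop=True)
    planted_low = planted_methylated_regions(study.truth, samples, (CLASS_LOW_CPG,))
    planted_any = planted_methylated_regions(
        study.truth, samples, HIGH_CPG_CLASSES + (CLASS_LOW_CPG,)
    )
    recall = float(overlaps_any(planted_hi, cmrs).mean()) if len(planted_hi) else np.nan
    precision = float(overlaps_any(cmrs, planted_any).mean()) if len(cmrs) else np.nan
    low_called = int(overlaps_any(planted_low, cmrs).sum())
    return {
        "recall": recall,
        "precision": precision,
        "n_planted": int(len(planted_hi)),
        "n_cmrs": int(len(cmrs)),
        "n_low_cpg_planted": int(len(planted_low)),
        "n_low_cpg_called": low_called,
    }


def common_germline_capture(
    study: SimulatedStudy,
    cmrs: pd.DataFrame,
    min_probes_in_region: int = 3,
) -> dict:
    """Fraction of probed planted common-germline regions overlapped by a
    CMR categorised ``somatic_common`` or ``all_positive``."""
    reg = study.truth.regions
    common = reg[reg["meth_class"] == CLASS_COMMON].reset_index(drop=True)
    probed = probes_in_regions(common, study.annotation.probes) >= min_probes_in_region
    common = common[probed].reset_index(drop=True)
    good = cmrs[cmrs["category"].isin(["somatic_common", "all_positive"])]
    frac = float(overlaps_any(common, good).mean()) if len(common) else np.nan
    return {"captured": frac, "n_common": int(len(common))}


def tdmr_recovery(
    study: SimulatedStudy,
    tdmrs: pd.DataFrame,
    min_probes_in_region: int = 3,
) -> dict:
    """Fraction of probed planted T-DMRs recovered by T-DMR extraction."""
    reg = study.truth.regions
    td = reg[reg["meth_class"] == CLASS_TDMR].reset_index(drop=True)
    probed = probes_in_regions(td, study.annotation.probes) >= min_probes_in_region
    td = td[probed].reset_index(drop=True)
    frac = float(overlaps_any(td, tdmrs).mean()) if len(td) else np.nan
    return {"recovered": frac, "n_tdmr": int(len(td))}


def realized_probe_fdr(
    study: SimulatedStudy,
    score_track: pd.DataFrame,
    sample: str,
    threshold: float,
    pad_bp: int = 400,
    min_level: float = 0.5,
) -> dict:
    """Realized false-positive fraction among probe calls at a threshold.

    A called probe is a true positive when its centre lies within
    ``pad_bp`` of a planted region methylated in the sample (the window
    score pools probes across ± window/2, so probes flanking a methylated
    region carry genuine signal); otherwise it is a false positive.
    """
    reg = study.truth.regions
    lv = study.truth.levels.loc[reg["region_id"], sample].to_numpy()
    meth = reg[lv >= min_level]
    padded = meth[["chrom", "start", "end"]].copy()
    padded["start"] = padded["start"] - pad_bp
    padded["end"] = padded["end"] + pad_bp
    track = score_track[np.isfinite(score_track["score"])]
    calls = track[track["score"] >= threshold]
    if len(calls) == 0:
        return {"n_calls": 0, "realized_fdr": np.nan}
    near = overlaps_any(calls[["chrom", "start", "end"]], padded)
    return {
        "n_calls": int(len(calls)),
        "realized_fdr": float((~near).mean()),
    }
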