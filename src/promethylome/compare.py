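"""Cross-sample methylome comparison.

TSS-distance methylation-frequency profiles, CpG-island / promoter-zone
summary tables, common-vs-variable categorisation of CMRs across the sample
panel, and tissue-specific DMR extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import assign_regions_to_tss
from .cmr import HYPO, INDETERMINATE, METHYLATED

CAT_ALL = "all_positive"
CAT_SPERM_ANY = "sperm_any_others_positive"
CAT_SOMATIC = "somatic_common"
CAT_EARLY = "early_diff_only"
CAT_VARIABLE = "variable"
CAT_OTHER = "other"

CATEGORIES = (CAT_ALL, CAT_SPERM_ANY, CAT_SOMATIC, CAT_EARLY, CAT_VARIABLE, CAT_OTHER)


@dataclass(frozen=True)
class SampleRoles:
    """Role of each sample in the panel.

    ``somatic`` = germ layers ∪ adult somatic tissues; ES lines are not
    somatic for categorisation purposes.
    """

    es: tuple[str, ...]
    germ_layers: tuple[str, ...]
    adult_somatic: tuple[str, ...]
    sperm: str

    def __post_init__(self):
        if not (self.es and self.germ_layers and self.adult_somatic and self.sperm):
            raise ValueError("every sample role must be assigned")

    @property
    def somatic(self) -> tuple[str, ...]:
        return tuple(self.germ_layers) + tuple(self.adult_somatic)

    @property
    def all_samples(self) -> tuple[str, ...]:
        return tuple(self.es) + self.somatic + (self.sperm,)

    @property
    def non_sperm(self) -> tuple[str, ...]:
        return tuple(self.es) + self.somatic


# --------------------------------------------------------------------------
# TSS profile
# --------------------------------------------------------------------------

def tss_profile(
    score_track: pd.DataFrame,
    threshold: float = 2.5,
    bin_bp: int = 250,
    smooth_bp: int = 200,
    span: tuple[int, int] = (-6000, 2500),
) -> pd.DataFrame:
    """Methylation frequency as a function of TSS distance.

    ``score_track`` must carry a strand-aware ``offset`` column (bp relative
    to the TSS, negative upstream) and a ``score`` column.  Per ``bin_bp``
    bin the frequency is (probes with score > threshold) / (total probes in
    the bin); empty bins are omitted.  The smoothed curve is a positional
    moving average: for each bin, counts are pooled over all probes within
    ± ``smooth_bp``/2 of the bin centre, so smoothing a constant profile
    returns it unchanged.

    Returns a DataFrame ``position, n_probes, n_methylated, frequency,
    smoothed`` with ``position`` at bin centres.
    """
    t = score_track[np.isfinite(score_track["score"])]
    t = t[(t["offset"] >= span[0]) & (t["offset"] <= span[1])]
    if len(t) == 0:
        return pd.DataFrame(
            columns=["position", "n_probes", "n_methylated", "frequency", "smoothed"]
        )
    offs = t["offset"].to_numpy()
    meth = (t["score"].to_numpy() > threshold).astype(int)
    bins = np.floor((offs - span[0]) / bin_bp).astype(int)
    df = pd.DataFrame({"bin": bins, "meth": meth})
    g = df.groupby("bin").agg(n_probes=("meth", "size"), n_methylated=("meth", "sum"))
    g["position"] = span[0] + (g.index.to_numpy() + 0.5) * bin_bp
    g["frequency"] = g["n_methylated"] / g["n_probes"]

    order = np.argsort(offs)
    so, sm = offs[order], meth[order]
    half = smooth_bp / 2.0
    lo = np.searchsorted(so, g["position"].to_numpy() - half, side="left")
    hi = np.searchsorted(so, g["position"].to_numpy() + half, side="right")
    cum_m = np.concatenate(([0], np.cumsum(sm)))
    tot = hi - lo
    g["smoothed"] = np.where(tot > 0, (cum_m[hi] - cum_m[lo]) / np.maximum(tot, 1), g["frequency"])
    return g.reset_index(drop=True)[
        ["position", "n_probes", "n_methylated", "frequency", "smoothed"]
    ]


# --------------------------------------------------------------------------
# summary tables
# --------------------------------------------------------------------------

def cmr_count_table(
    cmrs: pd.DataFrame, samples: list[str], thresholds=(2.5, 3.0, 4.0)
) -> pd.DataFrame:
    """Number of CMRs per sample exceeding each score threshold."""
    rows = {}
    for s in samples:
        sc = cmrs[f"score_{s}"].to_numpy(dtype=float)
        rows[s] = {f"score>{t:g}": int((sc > t).sum()) for t in thresholds}
    return pd.DataFrame(rows).T.rename_axis("sample")


def island_methylation_table(
    cmrs: pd.DataFrame,
    cpg_islands: pd.DataFrame,
    samples: list[str],
    thresholds=(2.5, 3.0, 4.0),
) -> pd.DataFrame:
    """CpG-island methylation counts and frequencies per sample.

    For each sample and threshold: the number of islands overlapped by a
    CMR whose score in that sample exceeds the threshold, and the
    frequency as a percentage of all islands.  Counts are non-increasing
    in the threshold.
    """
    if len(cpg_islands) == 0:
        raise ValueError("island set is empty")
    tree = IntervalTree()
    for i, row in enumerate(cpg_islands.itertuples(index=False)):
        tree[row.start : row.end] = i
    n_islands = len(cpg_islands)
    rows = {}
    for s in samples:
        rows[s] = {}
        for t in thresholds:
            sub = cmrs[cmrs[f"score_{s}"] > t]
            hit: set[int] = set()
            for r in sub.itertuples(index=False):
                for iv in tree.overlap(r.start, r.end):
                    hit.add(iv.data)
            rows[s][f"count>{t:g}"] = len(hit)
            rows[s][f"pct>{t:g}"] = 100.0 * len(hit) / n_islands
    return pd.DataFrame(rows).T.rename_axis("sample")


def zone_table(
    cmrs: pd.DataFrame,
    genes: pd.DataFrame,
    samples: list[str],
    core_zone: tuple[int, int] = (-1000, 500),
) -> pd.DataFrame:
    """Distribution of methylated CMRs over promoter zones per sample.

    A CMR counts for a sample when its state there is methylated; its zone
    comes from the strand-aware offset of its midpoint to the nearest TSS
    (core = ``core_zone``, tss_up upstream, tss_down downstream).  The zone
    columns sum to the total for every sample.
    """
    assigned = assign_regions_to_tss(cmrs[["chrom", "start", "end"]], genes, core_zone)
    rows = {}
    for s in samples:
        meth = (cmrs[f"state_{s}"] == METHYLATED).to_numpy()
        z = assigned["zone"].to_numpy()[meth]
        rows[s] = {
            "total": int(meth.sum()),
            "tss_up": int((z == "tss_up").sum()),
            "core": int((z == "core").sum()),
            "tss_down": int((z == "tss_down").sum()),
        }
    return pd.DataFrame(rows).T.rename_axis("sample")


# --------------------------------------------------------------------------
# commonality
# --------------------------------------------------------------------------

def categorize_commonality(cmrs: pd.DataFrame, roles: SampleRoles) -> pd.Series:
    """Classify each CMR by how widely it is methylated across the panel.

    Categories (checked in precedence order, mutually exclusive):

    - ``all_positive`` — methylated in every sample including sperm;
    - ``sperm_any_others_positive`` — methylated in every non-sperm sample,
      sperm unconstrained;
    - ``somatic_common`` — methylated in every somatic sample (germ layers
      and adult tissues); ES and sperm unconstrained;
    - ``early_diff_only`` — methylated in all three germ layers and
      hypomethylated in every adult somatic tissue;
    - ``variable`` — none of the above, decided states throughout the
      decisive (somatic) samples;
    - ``other`` — unclassifiable: no category matched and at least one
      somatic state is indeterminate.
    """
    for s in roles.all_samples:
        if f"state_{s}" not in cmrs.columns:
            raise ValueError(f"missing state column for sample {s!r}")

    def meth(r, ss):
        return all(getattr(r, f"state_{s}") == METHYLATED for s in ss)

    def hypo(r, ss):
        return all(getattr(r, f"state_{s}") == HYPO for s in ss)

    labels = []
    for r in cmrs.itertuples(index=False):
        if meth(r, roles.all_samples):
            labels.append(CAT_ALL)
        elif meth(r, roles.non_sperm):
            labels.append(CAT_SPERM_ANY)
        elif meth(r, roles.somatic):
            labels.append(CAT_SOMATIC)
        elif meth(r, roles.germ_layers) and hypo(r, roles.adult_somatic):
            labels.append(CAT_EARLY)
        elif any(
            getattr(r, f"state_{s}") == INDETERMINATE for s in roles.somatic
        ):
            labels.append(CAT_OTHER)
        else:
            labels.append(CAT_VARIABLE)
    return pd.Series(labels, index=cmrs.index, name="category")


def commonality_summary(
    cmrs: pd.DataFrame,
    categories: pd.Series,
    genes: pd.DataFrame,
    core_zone: tuple[int, int] = (-1000, 500),
) -> pd.DataFrame:
    """Per-category CMR counts, split by core vs non-core promoter zone."""
    assigned = assign_regions_to_tss(cmrs[["chrom", "start", "end"]], genes, core_zone)
    core = (assigned["zone"] == "core").to_numpy()
    rows = []
    for cat in CATEGORIES:
        mask = (categories == cat).to_numpy()
        rows.append(
            {
                "category": cat,
                "total": int(mask.sum()),
                "core": int((mask & core).sum()),
                "not_core": int((mask & ~core).sum()),
            }
        )
    out = pd.DataFrame(rows)
    total = {
        "category": "total",
        "total": len(cmrs),
        "core": int(core.sum()),
        "not_core": int((~core).sum()),
    }
    return pd.concat([pd.DataFrame([total]), out], ignore_index=True)


def extract_tdmrs(
    cmrs: pd.DataFrame, samples: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue-specific differentially methylated regions.

    A CMR is a T-DMR when at least one sample is methylated (> 2.5) and at
    least one other is hypomethylated (< 1.5); indeterminate samples
    contribute to neither side.  Also returns the pairwise contrast matrix
    ``counts[a, b]`` = number of T-DMRs methylated in *a* and
    hypomethylated in *b*.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    states = {s: cmrs[f"state_{s}"].to_numpy() for s in samples}
    any_meth = np.zeros(len(cmrs), dtype=bool)
    any_hypo = np.zeros(len(cmrs), dtype=bool)
    for s in samples:
        any_meth |= states[s] == METHYLATED
        any_hypo |= states[s] == HYPO
    is_tdmr = any_meth & any_hypo
    tdmrs = cmrs[is_tdmr].reset_index(drop=True)
    contrast = pd.DataFrame(0, index=samples, columns=samples)
    for a in samples:
        for b in samples:
            if a == b:
                continue
            contrast.loc[a, b] = int(
                ((states[a] == METHYLATED) & (states[b] == HYPO) & is_tdmr).sum()
            )
    return tdmrs, contrast
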