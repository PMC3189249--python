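"""Probe-level enrichment scoring and empirical FDR calibration.

The score is a windowed, robustly standardised enrichment statistic playing
the role MAT-style scores play for tiling arrays: each array is
median-centred and scaled to unit (consistent) median absolute deviation on
the log2 scale, per-probe MeDIP-minus-input differences are pooled across
replicates within a genomic window around each probe, and the score is the
trimmed mean of the pooled values times the square root of the effective
(post-trim) count.  Because the window mean is multiplied by sqrt(count),
the null variance of the score does not depend on how many values the
window holds, which keeps observed and label-swapped null tracks on the
same scale.

The empirical FDR at threshold *s* is ``100 * min(1, #null>=s / #observed>=s)``
with the null track obtained by scoring an input-replicate label swap
(input-vs-input), mirroring an INPUT-vs-MeDIP score distribution comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_MAD_SCALE = 1.4826  # consistent with the normal sd


@dataclass
class IntensityMatrix:
    """Probe × array log2 intensities with array metadata.

    Attributes
    ----------
    probes : pandas.DataFrame
        Probe layout: ``probe_id, chrom, start, end`` (plus any extra
        columns such as ``gene_id``/``cpg_density``), sorted by
        (chrom, start).
    values : numpy.ndarray, shape (n_probes, n_arrays)
        log2 intensities.
    arrays : pandas.DataFrame
        One row per array: ``name, sample, channel, replicate`` with channel
        in {"MeDIP", "input"}.
    """

    probes: pd.DataFrame
    values: np.ndarray
    arrays: pd.DataFrame

    def __post_init__(self):
        if self.values.shape != (len(self.probes), len(self.arrays)):
            raise ValueError("values shape does not match probes x arrays")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        for sample, grp in self.arrays.groupby("sample"):
            channels = set(grp["channel"])
            if not {"MeDIP", "input"} <= channels:
                raise ValueError(f"sample {sample} lacks a MeDIP or input array")

    def columns(self, sample: str, channel: str) -> np.ndarray:
        mask = (self.arrays["sample"] == sample) & (self.arrays["channel"] == channel)
        return np.flatnonzero(mask.to_numpy())

    @property
    def sample_names(self) -> list[str]:
        return list(dict.fromkeys(self.arrays["sample"]))


def standardize_arrays(matrix: IntensityMatrix) -> IntensityMatrix:
    """Median-centre and MAD-scale every array (robust z on log2 scale).

    Each column is transformed to ``(x - median) / (1.4826 * MAD)``; the
    transform is idempotent up to numerical noise and invariant to affine
    rescaling of an array.  A constant array (MAD = 0) raises ``ValueError``.
    """
    v = matrix.values
    med = np.median(v, axis=0)
    mad = np.median(np.abs(v - med), axis=0)
    if np.any(mad == 0):
        bad = matrix.arrays["name"].to_numpy()[mad == 0]
        raise ValueError(f"constant array(s): {', '.join(map(str, bad))}")
    out = (v - med) / (_MAD_SCALE * mad)
    return IntensityMatrix(matrix.probes, out, matrix.arrays.copy())


def _trimmed_window_scores(
    positions: np.ndarray,
    chrom_codes: np.ndarray,
    diffs: np.ndarray,
    window_bp: int,
    trim_frac: float,
    min_values: int,
) -> np.ndarray:
    """Windowed trimmed-mean × sqrt(n) score for every probe.

    ``diffs`` has one row per probe and one column per pooled replicate
    difference.  Probes whose centre lies within ``window_bp/2`` of probe
    *i* (same chromosome) contribute all their columns to window *i*.
    """
    n, reps = diffs.shape
    half = window_bp / 2.0
    # windows never cross chromosome boundaries: probes are sorted by
    # (chrom, position), so bound the search within each chromosome block
    lo = np.searchsorted(positions + chrom_codes * 1e12, positions + chrom_codes * 1e12 - half, side="left")
    hi = np.searchsorted(positions + chrom_codes * 1e12, positions + chrom_codes * 1e12 + half, side="right")
    width = hi - lo
    wmax = int(width.max(initial=0))
    idx = lo[:, None] + np.arange(wmax)[None, :]
    valid = idx < hi[:, None]
    idx = np.clip(idx, 0, n - 1)
    vals = diffs[idx]  # (n, wmax, reps)
    vals = np.where(valid[:, :, None], vals, np.nan).reshape(n, wmax * reps)
    counts = width * reps
    order = np.sort(vals, axis=1)  # NaNs sort to the end
    scores = np.full(n, np.nan)
    for c in np.unique(counts):
        if c < max(min_values, 1):
            continue
        k = int(np.floor(trim_frac * c))
        rows = counts == c
        core = order[rows, k : c - k]
        n_eff = c - 2 * k
        scores[rows] = core.mean(axis=1) * np.sqrt(n_eff)
    return scores


def _prepare(matrix: IntensityMatrix):
    probes = matrix.probes
    centers = ((probes["start"] + probes["end"]) // 2).to_numpy(dtype=float)
    codes = pd.factorize(probes["chrom"])[0].astype(float)
    return centers, codes


def score_probes(
    matrix: IntensityMatrix,
    sample: str,
    window_bp: int = 800,
    trim_frac: float = 0.1,
    min_probes: int = 4,
) -> pd.DataFrame:
    """Score one sample's probes from a standardised intensity matrix.

    For each probe, the standardised (MeDIP − input-mean) differences of all
    probes within ±``window_bp``/2 are pooled across MeDIP replicates; the
    score is their ``trim_frac``-trimmed mean times sqrt(effective count).
    Windows holding fewer than ``min_probes`` values yield a missing score.

    Returns a DataFrame ``probe_id, chrom, start, end, score``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not 0 <= trim_frac < 0.5:
        raise ValueError("trim_frac must lie in [0, 0.5)")
    medip = matrix.columns(sample, "MeDIP")
    inputs = matrix.columns(sample, "input")
    if len(medip) == 0 or len(inputs) == 0:
        raise ValueError(f"sample {sample!r} has no MeDIP/input arrays")
    input_mean = matrix.values[:, inputs].mean(axis=1)
    diffs = matrix.values[:, medip] - input_mean[:, None]
    centers, codes = _prepare(matrix)
    scores = _trimmed_window_scores(centers, codes, diffs, window_bp, trim_frac, min_probes)
    out = matrix.probes[["probe_id", "chrom", "start", "end"]].copy()
    out["score"] = scores
    return out


def null_scores(
    matrix: IntensityMatrix,
    sample: str,
    window_bp: int = 800,
    trim_frac: float = 0.1,
    min_probes: int = 4,
) -> pd.DataFrame:
    """Null score track from an input-replicate label swap.

    The sample's input replicates are split in two halves; the first half is
    treated as pseudo-MeDIP against the mean of the second.  The swap halves
    the number of values per window, so the missing-score gate is applied at
    ``min_probes / 2`` (rounded up); the score's null variance is unaffected
    because the window mean is scaled by sqrt(count).
    """
    inputs = matrix.columns(sample, "input")
    if len(inputs) < 2:
        raise ValueError("null construction needs at least two input replicates")
    k = len(inputs) // 2
    pseudo_ip, pseudo_in = inputs[:k], inputs[k:]
    input_mean = matrix.values[:, pseudo_in].mean(axis=1)
    diffs = matrix.values[:, pseudo_ip] - input_mean[:, None]
    centers, codes = _prepare(matrix)
    min_values = max(2, int(np.ceil(min_probes / 2)))
    scores = _trimmed_window_scores(centers, codes, diffs, window_bp, trim_frac, min_values)
    out = matrix.probes[["probe_id", "chrom", "start", "end"]].copy()
    out["score"] = scores
    return out


@dataclass
class FdrCurve:
    """Empirical FDR (%) as a function of the score threshold."""

    thresholds: np.ndarray
    fdr_pct: np.ndarray  # NaN where undefined (no observed calls)

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fdr_pct = np.asarray(self.fdr_pct, dtype=float)
        ok = self.fdr_pct[np.isfinite(self.fdr_pct)]
        if len(ok) and (ok.min() < 0 or ok.max() > 100):
            raise ValueError("FDR% must lie in [0, 100]")

    def at(self, threshold: float) -> float:
        """FDR% at an exact tabulated threshold."""
        i = np.flatnonzero(np.isclose(self.thresholds, threshold))
        if len(i) == 0:
            raise KeyError(f"threshold {threshold} not tabulated")
        return float(self.fdr_pct[i[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fdr_pct": self.fdr_pct})


def estimate_fdr(
    observed: pd.DataFrame | np.ndarray,
    null: pd.DataFrame | np.ndarray,
    thresholds,
) -> FdrCurve:
    """Empirical FDR curve from observed and null score tracks.

    ``FDR%(s) = 100 * min(1, #null >= s / #observed >= s)``; thresholds with
    no observed call get a missing (NaN) FDR.  The curve is regularised to
    be monotone non-increasing in the threshold by a running minimum over
    ascending thresholds.
    """
    obs = _scores_array(observed)
    nul = _scores_array(null)
    if len(obs) == 0 or len(nul) == 0:
        raise ValueError("both score tracks must be non-empty")
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    obs_sorted = np.sort(obs)
    nul_sorted = np.sort(nul)
    n_obs = len(obs_sorted) - np.searchsorted(obs_sorted, thresholds, side="left")
    n_nul = len(nul_sorted) - np.searchsorted(nul_sorted, thresholds, side="left")
    fdr = np.full(len(thresholds), np.nan)
    has = n_obs > 0
    fdr[has] = 100.0 * np.minimum(1.0, n_nul[has] / n_obs[has])
    # monotone non-increasing in the threshold
    running = np.inf
    for i in range(len(fdr)):
        if np.isfinite(fdr[i]):
            running = min(running, fdr[i])
            fdr[i] = running
    return FdrCurve(thresholds, fdr)


def _scores_array(track) -> np.ndarray:
    if isinstance(track, pd.DataFrame):
        a = track["score"].to_numpy(dtype=float)
    else:
        a = np.asarray(track, dtype=float)
    return a[np.isfinite(a)]
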