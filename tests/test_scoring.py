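"""Array standardisation, window scores and empirical FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from promethylome.scoring import (
    estimate_fdr,
    null_scores,
    score_probes,
    standardize_arrays,
)
from conftest import toy_matrix


def random_matrix(seed=0, n=500):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(0, 60_000, 40), size=n, replace=False))
    return toy_matrix(
        {
            "S.MeDIP.1": rng.normal(0, 1, n),
            "S.MeDIP.2": rng.normal(0, 1, n),
            "S.input.1": rng.normal(0, 1, n),
            "S.input.2": rng.normal(0, 1, n),
        },
        pos,
    )


class TestStandardize:
    def test_median_zero_consistent_mad_one(self):
        m = standardize_arrays(random_matrix(1))
        med = np.median(m.values, axis=0)
        mad = np.median(np.abs(m.values - med), axis=0)
        assert np.allclose(med, 0, atol=1e-12)
        assert np.allclose(1.4826 * mad, 1, atol=1e-9)

    def test_idempotent(self):
        m1 = standardize_arrays(random_matrix(2))
        m2 = standardize_arrays(m1)
        assert np.allclose(m1.values, m2.values, atol=1e-9)

    def test_affine_invariance(self):
        m = random_matrix(3)
        shifted = toy_matrix(
            {
                name: 3.5 * m.values[:, i] - 7.0
                for i, name in enumerate(m.arrays["name"])
            },
            m.probes["start"].to_numpy(),
        )
        assert np.allclose(
            standardize_arrays(m).values, standardize_arrays(shifted).values, atol=1e-9
        )

    def test_constant_array_errors(self):
        m = random_matrix(4)
        m.values[:, 0] = 5.0
        with pytest.raises(ValueError, match="constant"):
            standardize_arrays(m)


def brute_force_scores(matrix, sample, window_bp, trim_frac, min_values):
    """Independent oracle: per probe, gather window values by brute force,
    sort, drop floor(trim*n) from each tail, average, times sqrt(n_eff)."""
    medip = matrix.columns(sample, "MeDIP")
    inputs = matrix.columns(sample, "input")
    input_mean = matrix.values[:, inputs].mean(axis=1)
    diffs = matrix.values[:, medip] - input_mean[:, None]
    centers = ((matrix.probes["start"] + matrix.probes["end"]) // 2).to_numpy()
    out = np.full(len(centers), np.nan)
    for i, c in enumerate(centers):
        sel = np.abs(centers - c) <= window_bp / 2
        vals = sorted(diffs[sel].ravel().tolist())
        n = len(vals)
        if n < min_values:
            continue
        k = int(np.floor(trim_frac * n))
        core = vals[k : n - k]
        out[i] = float(np.mean(core)) * np.sqrt(len(core))
    return out


class TestScoreProbes:
    def test_constant_window_scores_mean_times_sqrt_n(self):
        # two probes within the window, MeDIP exactly input + 1 -> 4 values
        # of 1.0, any trim -> score 1.0 * sqrt(4) = 2.0
        pos = np.array([1000, 1200])
        base = np.array([0.3, -0.2])
        m = toy_matrix(
            {
                "S.MeDIP.1": base + 1.0,
                "S.MeDIP.2": base + 1.0,
                "S.input.1": base,
                "S.input.2": base,
            },
            pos,
        )
        tr = score_probes(m, "S", window_bp=800, trim_frac=0.1, min_probes=4)
        assert np.allclose(tr["score"], 2.0, atol=1e-12)

    def test_medip_identical_to_input_scores_zero(self):
        rng = np.random.default_rng(5)
        n = 2000
        pos = np.arange(n) * 300
        base = rng.normal(0, 1, n)
        m = toy_matrix(
            {
                "S.MeDIP.1": base,
                "S.MeDIP.2": base,
                "S.input.1": base,
                "S.input.2": base,
            },
            pos,
        )
        tr = score_probes(m, "S", window_bp=800, trim_frac=0.1, min_probes=2)
        assert np.nanmean(np.abs(tr["score"])) < 0.05

    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        m = standardize_arrays(random_matrix(seed, n=120))
        got = score_probes(m, "S", window_bp=700, trim_frac=0.1, min_probes=4)["score"].to_numpy()
        want = brute_force_scores(m, "S", 700, 0.1, 4)
        assert np.allclose(got, want, atol=1e-9, equal_nan=True)

    def test_trim_drops_one_value_each_side(self):
        # six-value window at trim 0.2: sort, drop one from each tail,
        # average, times sqrt(4) — checked against the hand computation
        pos = np.array([1000, 1100, 1200])
        vals = np.array([[5.0, 1.0, 2.0], [0.0, 3.0, 4.0]])  # MeDIP reps x probes
        base = np.zeros(3)
        m = toy_matrix(
            {
                "S.MeDIP.1": vals[0],
                "S.MeDIP.2": vals[1],
                "S.input.1": base,
                "S.input.2": base,
            },
            pos,
        )
        tr = score_probes(m, "S", window_bp=500, trim_frac=0.2, min_probes=4)
        window = sorted([5.0, 1.0, 2.0, 0.0, 3.0, 4.0])  # 6 values, drop 1 each side
        expected = np.mean(window[1:-1]) * np.sqrt(4)
        assert tr["score"].iloc[1] == pytest.approx(expected)

    def test_shift_equivariance_untrimmed(self):
        m = standardize_arrays(random_matrix(11, n=100))
        base = score_probes(m, "S", window_bp=700, trim_frac=0.0, min_probes=4)
        shifted = toy_matrix(
            {
                name: m.values[:, i] + (2.0 if "MeDIP" in name else 0.0)
                for i, name in enumerate(m.arrays["name"])
            },
            m.probes["start"].to_numpy(),
        )
        tr = score_probes(shifted, "S", window_bp=700, trim_frac=0.0, min_probes=4)
        centers = ((m.probes["start"] + m.probes["end"]) // 2).to_numpy()
        n_window = np.array(
            [(np.abs(centers - c) <= 350).sum() * 2 for c in centers], dtype=float
        )
        got = (tr["score"] - base["score"]).to_numpy()
        ok = np.isfinite(got)
        assert ok.any()
        assert np.allclose(got[ok], (2.0 * np.sqrt(n_window))[ok], atol=1e-9)

    def test_small_windows_are_missing(self):
        pos = np.array([0, 5000, 10_000])  # isolated probes
        m = toy_matrix(
            {
                "S.MeDIP.1": np.ones(3),
                "S.MeDIP.2": np.ones(3),
                "S.input.1": np.zeros(3),
                "S.input.2": np.zeros(3),
            },
            pos,
        )
        tr = score_probes(m, "S", window_bp=800, trim_frac=0.1, min_probes=4)
        assert tr["score"].isna().all()


class TestEstimateFdr:
    def test_counting_oracle(self):
        curve = estimate_fdr(np.array([1, 2, 3, 4.0]), np.array([1, 1, 2, 3.0]), [2.5])
        assert curve.at(2.5) == pytest.approx(50.0)

    def test_null_equals_observed_gives_100(self):
        x = np.arange(1.0, 5.0)
        curve = estimate_fdr(x, x, [0.0, 1.5, 3.0])
        assert np.allclose(curve.fdr_pct, 100.0)

    def test_null_below_observed_gives_0(self):
        curve = estimate_fdr(np.array([5.0, 6.0]), np.array([1.0, 2.0]), [3.0, 4.0])
        assert np.allclose(curve.fdr_pct, 0.0)

    def test_undefined_above_max_observed(self):
        curve = estimate_fdr(np.array([1.0, 2.0]), np.array([1.0]), [10.0])
        assert np.isnan(curve.fdr_pct[0])

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        obs = np.abs(rng.normal(0, 1.5, 4000))
        nul = np.abs(rng.normal(0, 1.0, 4000))
        thr = np.linspace(0, 4, 30)
        curve = estimate_fdr(obs, nul, thr)
        vals = curve.fdr_pct[np.isfinite(curve.fdr_pct)]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_call_counts_decrease_with_threshold(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(0, 1, 1000)
        counts = [(obs >= t).sum() for t in (0.5, 1.0, 2.0, 3.0)]
        assert counts == sorted(counts, reverse=True)


class TestNullTrack:
    def test_null_variance_matches_observed_null(self, null_study):
        """Input-swap null has the same score scale as a signal-free
        observed track (the score multiplies the window mean by
        sqrt(count), making its variance count-invariant)."""
        std = standardize_arrays(null_study.intensities)
        obs = score_probes(std, "Ect")["score"].to_numpy()
        nul = null_scores(std, "Ect")["score"].to_numpy()
        s_obs = np.nanstd(obs)
        s_nul = np.nanstd(nul)
        assert abs(s_obs - s_nul) / s_obs < 0.1

    def test_needs_two_input_replicates(self):
        pos = np.arange(10) * 100
        m = toy_matrix(
            {
                "S.MeDIP.1": np.zeros(10),
                "S.input.1": np.zeros(10) + np.arange(10),
            },
            pos,
        )
        with pytest.raises(ValueError, match="input replicates"):
            null_scores(m, "S")
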