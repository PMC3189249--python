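"""Generator invariants: determinism, planted classes, signal model,
expression normalisation and histone-state construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promethylome.config import SimulationConfig
from promethylome.scoring import standardize_arrays
from promethylome.simulate import (
    CLASS_COMMON,
    CLASS_IMPRINTED,
    CLASS_LOW_CPG,
    CLASS_TDMR,
    generate_annotation,
    generate_truth,
    probe_methylation,
    simulate_arrays,
    simulate_expression,
    simulate_study,
)


class TestAnnotation:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_genes=150, seed=1)
        a1 = generate_annotation(cfg)
        a2 = generate_annotation(cfg)
        pd.testing.assert_frame_equal(a1.genes, a2.genes)
        pd.testing.assert_frame_equal(a1.probes, a2.probes)
        assert a1.sequence == a2.sequence

    def test_no_imprinting_no_icrs(self):
        cfg = SimulationConfig(n_genes=150, seed=2, frac_imprinted=0.0)
        ann = generate_annotation(cfg)
        assert len(ann.icrs) == 0

    def test_planted_counts_are_exact_floors(self):
        cfg = SimulationConfig(n_genes=333, seed=3)
        ann = generate_annotation(cfg)
        counts = ann.genes["meth_class"].value_counts()
        assert counts.get(CLASS_COMMON, 0) == int(cfg.frac_common_germline * 333)
        assert counts.get(CLASS_TDMR, 0) == int(cfg.frac_tdmr * 333)
        assert counts.get(CLASS_IMPRINTED, 0) == int(cfg.frac_imprinted * 333)
        assert counts.get(CLASS_LOW_CPG, 0) == int(cfg.frac_low_cpg_constitutive * 333)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimulationConfig(n_genes=3, seed=0)

    def test_cpg_rich_fraction_matches_config(self, full_result):
        """Fraction of promoters with >= 25 CpG / 500 bp (i.e. >= 5%
        density at some probe) matches the configured high-CpG fraction."""
        ann = full_result.study.annotation
        cfg = full_result.config.sim
        merged = ann.probes.merge(ann.genes[["gene_id", "cpg_class"]], on="gene_id")
        rich = merged.groupby("gene_id")["cpg_count"].max() >= 25
        assert abs(rich.mean() - cfg.frac_high_cpg) <= 0.02
        # and the measured density tracks the generating labels
        by_class = merged.groupby("cpg_class")["cpg_count"].max()
        assert by_class["high"] >= 25
        assert by_class.get("mid", 0) < 25


@pytest.fixture(scope="module")
def truth_bundle():
    cfg = SimulationConfig(n_genes=400, seed=5)
    ann = generate_annotation(cfg)
    return cfg, ann, generate_truth(ann, cfg)


class TestTruth:

    def test_imprinted_half_methylated_everywhere(self, truth_bundle):
        cfg, ann, truth = truth_bundle
        reg = truth.regions
        imp = reg[reg["meth_class"] == CLASS_IMPRINTED]["region_id"]
        assert len(imp)
        assert np.allclose(truth.levels.loc[imp], 0.5)  # including sperm

    def test_common_germline_somatic_only(self, truth_bundle):
        cfg, ann, truth = truth_bundle
        reg = truth.regions
        com = reg[reg["meth_class"] == CLASS_COMMON]["region_id"]
        lv = truth.levels.loc[com]
        assert (lv[list(cfg.somatic_samples)] >= 0.8).all().all()
        assert (lv[[*cfg.es_samples, cfg.sperm_sample]] <= 0.1).all().all()

    def test_unmethylated_cores_stay_low(self, truth_bundle):
        cfg, ann, truth = truth_bundle
        reg = truth.regions
        un = reg[reg["meth_class"] == "unmethylated"]["region_id"]
        assert (truth.levels.loc[un] <= 0.05).all().all()

    def test_tdmr_methylated_in_exactly_one_germ_layer(self, truth_bundle):
        cfg, ann, truth = truth_bundle
        reg = truth.regions
        td = reg[reg["meth_class"] == CLASS_TDMR]
        lv = truth.levels.loc[td["region_id"], list(cfg.germ_layers)].to_numpy()
        assert ((lv >= 0.5).sum(axis=1) == 1).all()

    def test_no_tdmr_no_cluster_means_identical_somatic_truth(self):
        cfg = SimulationConfig(n_genes=200, seed=6, frac_tdmr=0.0, frac_cluster_mosaic=0.0)
        ann = generate_annotation(cfg)
        truth = generate_truth(ann, cfg)
        som = truth.levels[list(cfg.somatic_samples)].to_numpy()
        assert (som == som[:, :1]).all()


class TestArrays:
    def test_no_methylation_zero_mean_log_ratio(self, null_study):
        v = null_study.intensities
        medip = v.columns("Ect", "MeDIP")
        inputs = v.columns("Ect", "input")
        diffs = v.values[:, medip] - v.values[:, inputs].mean(axis=1, keepdims=True)
        sem = diffs.std() / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3 * sem

    def test_expected_ratio_monotone_in_cpg_below_saturation(self):
        cfg = SimulationConfig(n_genes=150, seed=7)
        sat = lambda c: c / (c + cfg.sat_halfway_cpg)
        assert sat(20) > sat(10) > sat(5)  # doubling CpG raises the mean

    def test_montecarlo_mean_matches_closed_form(self, small_study):
        """Sample mean of simulated log ratios at fixed (methylation, CpG)
        is within 3 SEM of slope * level * c/(c + c50)."""
        cfg = small_study.config
        ann = small_study.annotation
        v = small_study.intensities
        m = probe_methylation(small_study.truth, ann, "Ect")
        cpg = ann.probes["cpg_count"].to_numpy()
        sel = (m >= 0.9) & (cpg == 40)
        if sel.sum() < 20:
            sel = (m >= 0.9) & (np.abs(cpg - 40) <= 1)
        assert sel.sum() >= 20
        medip = v.columns("Ect", "MeDIP")
        inputs = v.columns("Ect", "input")
        diffs = (v.values[:, medip] - v.values[:, inputs].mean(axis=1, keepdims=True))[sel]
        expected = (
            cfg.enrichment_slope * m[sel] * cpg[sel] / (cpg[sel] + cfg.sat_halfway_cpg)
        ).mean()
        sem = diffs.std() / np.sqrt(diffs.size)
        assert abs(diffs.mean() - expected) < 3 * sem

    def test_null_log_ratio_distribution_matches_closed_form(self, null_study):
        """Marginal of MeDIP-minus-input-mean differences on a null study is
        N(0, noise_sd * sqrt(1 + 1/replicates)) (KS p > 0.01, n = 10000)."""
        cfg = null_study.config
        v = null_study.intensities
        medip = v.columns("Brain", "MeDIP")
        inputs = v.columns("Brain", "input")
        diffs = (
            v.values[:, medip] - v.values[:, inputs].mean(axis=1, keepdims=True)
        ).ravel()[:10_000]
        sd = cfg.noise_sd * np.sqrt(1 + 1 / cfg.replicates)
        assert stats.kstest(diffs, "norm", args=(0, sd)).pvalue > 0.01

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=100, noise_sd=-0.1)

    def test_replicates_have_independent_noise(self, small_study):
        # probe affinity and signal are shared between replicates, so the
        # replicate difference isolates the noise: var = 2 * noise_sd^2
        cfg = small_study.config
        v = small_study.intensities
        medip = v.columns("Liver", "MeDIP")
        d = v.values[:, medip[0]] - v.values[:, medip[1]]
        assert np.isclose(d.var(), 2 * cfg.noise_sd**2, rtol=0.1)


class TestExpression:
    def test_columns_normalised_to_mean_100(self, small_study):
        assert np.allclose(small_study.expression.mean(axis=0), 100.0, atol=1e-6)

    def test_core_methylated_genes_expressed_lower(self, small_study):
        truth, ann = small_study.truth, small_study.annotation
        expr = small_study.expression
        meth = truth.core_methylated(ann.genes, "Brain")
        meth = meth.reindex(expr.index, fill_value=False)
        assert expr.loc[meth, "Brain"].median() < expr.loc[~meth, "Brain"].median()

    def test_germline_genes_testis_specific(self, small_study):
        from promethylome.gsea import testis_score

        cfg = small_study.config
        ranked = testis_score(
            small_study.expression,
            somatic_columns=list(cfg.somatic_samples),
            testis_column=cfg.testis_sample,
        )
        scores = ranked.set_index("gene_id")["score"]
        germ = small_study.annotation.genes.loc[
            small_study.annotation.genes["meth_class"] == CLASS_COMMON, "gene_id"
        ]
        assert (scores.loc[germ] > 1).mean() >= 0.9


class TestHistone:
    def test_peak_emission_matches_state(self, small_study):
        states = small_study.histone_states
        peaks = small_study.histone_peaks
        genes = small_study.annotation.genes.set_index("gene_id")
        sample = small_study.config.histone_samples[0]
        k4_by_gene = set(peaks[(sample, "K4")]["name"])
        k27_by_gene = set(peaks[(sample, "K27")]["name"])
        for gene_id, st_ in states[sample].items():
            tss = genes.loc[gene_id, "tss"]
            if st_ == "bivalent":
                assert gene_id in k4_by_gene and gene_id in k27_by_gene
            elif st_ == "none":
                assert gene_id not in k4_by_gene and gene_id not in k27_by_gene
        # every emitted peak overlaps its gene's TSS +/- 2 kb window
        for (s, mark), df in peaks.items():
            tss = genes.loc[df["name"], "tss"].to_numpy()
            assert (df["start"].to_numpy() <= tss + 2000).all()
            assert (df["end"].to_numpy() - 1 >= tss - 2000).all()

    def test_p_methylated_given_k4_matches_model(self):
        """Realized P(methylated | K4) lands inside the binomial 95% CI of
        the value the conditional state model implies."""
        cfg = SimulationConfig(n_genes=3000, seed=13, p_k4_given_meth=0.2)
        study = simulate_study(cfg)
        sample = "Ect"
        meth = study.truth.core_methylated(study.annotation.genes, sample).to_numpy()
        k4 = (study.histone_states[sample] == "K4").to_numpy()
        pi = meth.mean()
        implied = (
            cfg.p_k4_given_meth
            * pi
            / (cfg.p_k4_given_meth * pi + cfg.p_k4_given_unmeth * (1 - pi))
        )
        realized = meth[k4].mean()
        ci = 1.96 * np.sqrt(implied * (1 - implied) / k4.sum())
        assert abs(realized - implied) <= ci

    def test_strict_exclusivity_by_default(self, small_study):
        """With the default model no methylated promoter carries H3K4me3."""
        for sample in small_study.config.histone_samples:
            meth = small_study.truth.core_methylated(
                small_study.annotation.genes, sample
            ).to_numpy()
            st_ = small_study.histone_states[sample].to_numpy()
            assert (st_[meth] != "K4").all()


class TestDeterminism:
    def test_full_study_byte_identical(self):
        cfg = SimulationConfig(n_genes=120, seed=9)
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert np.array_equal(s1.intensities.values, s2.intensities.values)
        pd.testing.assert_frame_equal(s1.expression, s2.expression)
        pd.testing.assert_frame_equal(s1.truth.levels, s2.truth.levels)
        pd.testing.assert_frame_equal(s1.histone_states, s2.histone_states)
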