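"""Configuration objects for the simulator and the analysis pipeline.

Two frozen dataclasses hold every tunable constant: :class:`SimulationConfig`
describes the synthetic study (sample panel, planted methylome classes, array
noise model) and :class:`PipelineConfig` holds the analysis parameters (score
window, call thresholds, CpG gate, promoter windows, permutation counts).
All analysis constants default to the values used throughout the method:
methylated > 2.5, hypomethylated < 1.5, high-confidence gate 3.0, CpG density
gate 5%, core promoter -1.5 kb..+0.5 kb, histone window TSS ± 2 kb, 1000 gene
permutations, expression arrays normalised to mean 100.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

#: Arrayed samples, in panel order: two ES lines, the three ES-derived germ
#: layers (ectoderm, endoderm, paraxial mesoderm), three adult somatic
#: tissues, and mature sperm.  Testis enters through expression only.
DEFAULT_SAMPLES = ("ES1", "ES2", "Ect", "End", "Pme", "Brain", "Liver", "Muscle", "Sperm")


def _astuple(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic MeDIP-chip study.

    The defaults define the study conditions: ~25 probes per promoter spanning
    -6 kb..+2.5 kb of the TSS, duplicate MeDIP and input arrays per sample,
    CpG-density-dependent MeDIP enrichment that saturates with probe CpG
    count, and planted methylome classes (commonly methylated germline genes,
    imprinting centres, germ-layer T-DMRs, mosaically methylated gene
    clusters, constitutively methylated CpG-poor promoters).
    """

    n_genes: int = 2000
    n_probes_per_promoter: int = 25
    promoter_span: tuple[int, int] = (-6000, 2500)
    probe_length: int = 60
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    es_samples: tuple[str, ...] = ("ES1", "ES2")
    germ_layers: tuple[str, ...] = ("Ect", "End", "Pme")
    adult_somatic: tuple[str, ...] = ("Brain", "Liver", "Muscle")
    sperm_sample: str = "Sperm"
    testis_sample: str = "Testis"

    # planted methylome classes (fractions of n_genes; counts are exact floors)
    frac_common_germline: float = 0.04
    frac_tdmr: float = 0.03
    frac_imprinted: float = 0.01
    frac_cluster_mosaic: float = 0.02
    frac_es_somatic: float = 0.02
    frac_low_cpg_constitutive: float = 0.15
    frac_tdmr_maintained: float = 0.10
    cluster_block_size: int = 8
    cluster_meth_prob: float = 0.8

    # promoter CpG-density composition and sequence model
    frac_high_cpg: float = 0.60
    frac_intermediate_cpg: float = 0.15
    cpg_density_high: float = 8.0
    cpg_density_mid: float = 4.2
    cpg_density_low: float = 2.0
    cpg_density_background: float = 1.0
    gene_slot_bp: int = 13000
    chrom_name: str = "chrS"

    # differentially methylated region placement (TSS-relative)
    dmr_width: int = 2000
    frac_dmr_core: float = 0.08
    frac_dmr_upstream: float = 0.70
    dmr_up_center_range: tuple[int, int] = (-7000, -500)
    dmr_down_center_range: tuple[int, int] = (500, 3500)

    # array signal model (log2 scale)
    enrichment_slope: float = 2.0
    sat_halfway_cpg: float = 10.0
    noise_sd: float = 0.25
    probe_effect_sd: float = 0.40
    replicates: int = 2

    # expression model (log2 scale before mean-100 normalisation)
    expr_base_log2: float = 6.0
    expr_gene_sd: float = 1.2
    expr_noise_sd: float = 0.3
    expr_meth_penalty_log2: float = 2.5
    expr_germline_base_log2: float = 3.5
    expr_testis_boost_log2: float = 3.0

    # histone model: state drawn conditionally on the core-promoter
    # methylation flag; p_k4_given_meth = 0 encodes strict exclusivity
    # (H3K4me3 shields promoters from de novo methylation)
    histone_samples: tuple[str, ...] = ("ES1", "Ect", "Brain")
    p_k4_given_meth: float = 0.0
    p_k4_given_unmeth: float = 0.75
    p_biv_given_unmeth: float = 0.12
    p_k27_given_unmeth: float = 0.03
    p_biv_given_meth: float = 0.15
    p_k27_given_meth: float = 0.25

    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "promoter_span", _astuple(self.promoter_span))
        object.__setattr__(self, "samples", _astuple(self.samples))
        object.__setattr__(self, "es_samples", _astuple(self.es_samples))
        object.__setattr__(self, "germ_layers", _astuple(self.germ_layers))
        object.__setattr__(self, "adult_somatic", _astuple(self.adult_somatic))
        object.__setattr__(self, "histone_samples", _astuple(self.histone_samples))
        object.__setattr__(self, "dmr_up_center_range", _astuple(self.dmr_up_center_range))
        object.__setattr__(self, "dmr_down_center_range", _astuple(self.dmr_down_center_range))
        for name in (
            "frac_common_germline",
            "frac_tdmr",
            "frac_imprinted",
            "frac_cluster_mosaic",
            "frac_es_somatic",
            "frac_low_cpg_constitutive",
            "frac_tdmr_maintained",
            "frac_high_cpg",
            "frac_intermediate_cpg",
            "frac_dmr_core",
            "frac_dmr_upstream",
            "cluster_meth_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.planted_fraction_total > 1.0:
            raise ValueError("planted class fractions sum to more than 1")
        if self.n_probes_per_promoter < 3:
            raise ValueError("n_probes_per_promoter must be >= 3")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.promoter_span[0] >= self.promoter_span[1]:
            raise ValueError("promoter_span must be an increasing interval")
        if self.n_genes < self.n_planted_classes:
            raise ValueError(
                f"n_genes={self.n_genes} is smaller than the number of planted "
                f"special classes ({self.n_planted_classes})"
            )

    @property
    def planted_fraction_total(self) -> float:
        return (
            self.frac_common_germline
            + self.frac_tdmr
            + self.frac_imprinted
            + self.frac_cluster_mosaic
            + self.frac_es_somatic
            + self.frac_low_cpg_constitutive
        )

    @property
    def n_planted_classes(self) -> int:
        return sum(
            f > 0
            for f in (
                self.frac_common_germline,
                self.frac_tdmr,
                self.frac_imprinted,
                self.frac_cluster_mosaic,
                self.frac_es_somatic,
                self.frac_low_cpg_constitutive,
            )
        )

    @property
    def somatic_samples(self) -> tuple[str, ...]:
        """Germ layers plus adult somatic tissues (ES and sperm excluded)."""
        return self.germ_layers + self.adult_somatic


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters for the full simulate → integrate pipeline."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)

    # probe scoring
    window_bp: int = 800
    trim_frac: float = 0.1
    min_probes: int = 4
    fdr_thresholds: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

    # region calling
    call_threshold: float = 2.5
    hc_threshold: float = 3.0
    hypo_threshold: float = 1.5
    min_cpg_density: float = 5.0
    max_gap_bp: int = 300
    region_density_stat: str = "mean"  # or "max"

    # promoter windows (TSS-relative, strand-aware)
    core_zone: tuple[int, int] = (-1000, 500)       # zone tables
    core_promoter: tuple[int, int] = (-1500, 500)   # gene-level methylation flag
    histone_window: int = 2000
    cpg_window_bp: int = 500

    # TSS profile
    profile_bin_bp: int = 250
    profile_smooth_bp: int = 200
    island_thresholds: tuple[float, ...] = (2.5, 3.0, 4.0)

    # enrichment
    n_perm: int = 1000
    gsea_weight: float = 1.0
    expr_floor: float = 1.0

    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "fdr_thresholds", _astuple(self.fdr_thresholds))
        object.__setattr__(self, "core_zone", _astuple(self.core_zone))
        object.__setattr__(self, "core_promoter", _astuple(self.core_promoter))
        object.__setattr__(self, "island_thresholds", _astuple(self.island_thresholds))
        if isinstance(self.sim, dict):
            object.__setattr__(self, "sim", SimulationConfig(**self.sim))
        if not (self.hypo_threshold < self.call_threshold <= self.hc_threshold):
            raise ValueError(
                "thresholds must be ordered: hypomethylated < methylated <= high-confidence"
            )
        if not 0.0 <= self.trim_frac < 0.5:
            raise ValueError("trim_frac must lie in [0, 0.5)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.region_density_stat not in ("mean", "max"):
            raise ValueError("region_density_stat must be 'mean' or 'max'")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def param_hash(self) -> str:
        """Stable hash of the full parameter set (for the run manifest)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
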