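"""Synthetic MeDIP-chip study generator with planted ground truth.

Generates, from a single :class:`~promethylome.config.SimulationConfig`, a
complete and internally consistent study: a synthetic chromosome with
controlled promoter CpG density, a promoter tiling-array layout, a planted
methylome (commonly methylated germline genes, imprinting centres,
germ-layer T-DMRs, mosaically methylated gene clusters, constitutively
methylated CpG-poor promoters), duplicate MeDIP/input array intensities, an
expression matrix in which core-promoter methylation suppresses expression
and germline genes are expressed only in testis, and H3K4me3/H3K27me3 peak
calls anti-correlated with promoter methylation.

Every output is deterministic for a fixed seed: the generator draws from
independent, stably keyed child streams of ``numpy.random.SeedSequence``.

Methylome classes
-----------------
``common_germline``
    Methylated (level 0.9) in every somatic sample — the three ES-derived
    germ layers and the adult tissues — but unmethylated in ES cells and in
    mature sperm; highly expressed only in testis.
``imprinted``
    Level 0.5 (allele-specific) in *all* samples including sperm; recorded
    as imprinting-centre regions in the annotation.
``tdmr``
    Methylated in exactly one germ layer; a configurable fraction is
    maintained in the matched adult tissue.
``cluster_mosaic``
    Blocks of neighbouring genes, each methylated in a random ~80% subset
    of the somatic samples (mosaic methylation of clustered gene families).
``es_somatic``
    Methylated in ES cells and every somatic sample but unmethylated in
    sperm — the pattern of constitutively methylated reproductive-organ
    gene clusters and of ES-line-acquired methylation.
``low_cpg_constitutive``
    CpG-poor promoters (density ~2%) methylated in every sample; these are
    removed by the analysis' 5% CpG-density gate by design.
``unmethylated``
    Hypomethylated CpG-rich core promoters (level 0.02 everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .config import SimulationConfig
from .scoring import IntensityMatrix

CLASS_COMMON = "common_germline"
CLASS_IMPRINTED = "imprinted"
CLASS_TDMR = "tdmr"
CLASS_CLUSTER = "cluster_mosaic"
CLASS_ES_SOMATIC = "es_somatic"
CLASS_LOW_CPG = "low_cpg_constitutive"
CLASS_UNMETH = "unmethylated"

_A, _C, _G, _T = 65, 67, 71, 84  # ASCII codes

# base composition (A, C, G, T); islands are GC-boosted so high-density
# promoters clear the HCP GC criterion
_BG_COMP = np.array([0.30, 0.25, 0.20, 0.25])
_ISLAND_COMP = np.array([0.20, 0.30, 0.28, 0.22])

# TSS placement inside each gene slot, per strand, leaving the full
# -6 kb..+2.5 kb probed span AND the widest planted-region overhang
# (upstream DMR centres down to -7 kb) inside the slot, so planted regions
# never bleed under a neighbouring promoter's probes
_TSS_OFFSET_PLUS = 8200
_TSS_OFFSET_MINUS = 4800


def _rng(config: SimulationConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


# --------------------------------------------------------------------------
# truth container
# --------------------------------------------------------------------------

@dataclass
class TrueMethylome:
    """Planted methylation levels per (region, sample).

    Attributes
    ----------
    regions : pandas.DataFrame
        ``region_id, gene_id, chrom, start, end, meth_class`` plus T-DMR
        bookkeeping (``tdmr_layer, tdmr_maintained``).
    levels : pandas.DataFrame
        Methylation level in [0, 1], indexed by region_id, one column per
        arrayed sample.
    """

    regions: pd.DataFrame
    levels: pd.DataFrame

    def __post_init__(self):
        if not self.regions["region_id"].is_unique:
            raise ValueError("region ids must be unique")
        lv = self.levels.to_numpy()
        if lv.min() < 0 or lv.max() > 1:
            raise ValueError("methylation levels must lie in [0, 1]")

    def relative_interval(self, genes: pd.DataFrame) -> pd.DataFrame:
        """Strand-aware TSS-relative (lo, hi) of each region."""
        g = genes.set_index("gene_id")
        tss = g.loc[self.regions["gene_id"], "tss"].to_numpy()
        strand = g.loc[self.regions["gene_id"], "strand"].to_numpy().astype(int)
        a = (self.regions["start"].to_numpy() - tss) * strand
        b = (self.regions["end"].to_numpy() - tss) * strand
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        return pd.DataFrame(
            {"region_id": self.regions["region_id"], "rel_lo": lo, "rel_hi": hi}
        )

    def core_methylated(
        self,
        genes: pd.DataFrame,
        sample: str,
        core_promoter: tuple[int, int] = (-1500, 500),
        min_level: float = 0.5,
    ) -> pd.Series:
        """Per-gene flag: planted region overlaps the core promoter window
        and is methylated (level >= ``min_level``) in ``sample``."""
        rel = self.relative_interval(genes)
        lo, hi = core_promoter
        overlaps = (rel["rel_lo"].to_numpy() < hi) & (rel["rel_hi"].to_numpy() > lo)
        meth = self.levels.loc[self.regions["region_id"], sample].to_numpy() >= min_level
        flags = pd.Series(overlaps & meth, index=self.regions["gene_id"].to_numpy())
        return flags.groupby(level=0).any().reindex(genes["gene_id"], fill_value=False)


# --------------------------------------------------------------------------
# annotation + sequence
# --------------------------------------------------------------------------

def _assign_classes(config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene methylome class and cluster id (-1 outside clusters).

    Planted class counts are exact floors of fraction × n_genes.
    """
    n = config.n_genes
    klass = np.full(n, CLASS_UNMETH, dtype=object)
    cluster_id = np.full(n, -1)

    n_cluster = int(config.frac_cluster_mosaic * n)
    bs = config.cluster_block_size
    if n_cluster:
        starts = np.arange(0, n - bs + 1, bs)
        rng.shuffle(starts)
        taken = 0
        block = 0
        for s in starts:
            if taken >= n_cluster:
                break
            size = min(bs, n_cluster - taken)
            klass[s : s + size] = CLASS_CLUSTER
            cluster_id[s : s + size] = block
            taken += size
            block += 1
        if taken < n_cluster:
            raise ValueError("not enough room for the requested cluster genes")

    free = np.flatnonzero(klass == CLASS_UNMETH)
    rng.shuffle(free)
    cursor = 0
    for frac, label in (
        (config.frac_common_germline, CLASS_COMMON),
        (config.frac_tdmr, CLASS_TDMR),
        (config.frac_imprinted, CLASS_IMPRINTED),
        (config.frac_es_somatic, CLASS_ES_SOMATIC),
        (config.frac_low_cpg_constitutive, CLASS_LOW_CPG),
    ):
        k = int(frac * n)
        klass[free[cursor : cursor + k]] = label
        cursor += k
    return klass, cluster_id


def _assign_cpg_classes(klass: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    """Promoter CpG-density class: planted classes are CpG-rich (except the
    constitutively methylated CpG-poor class); unmethylated promoters fill
    the configured high/intermediate/low composition."""
    n = len(klass)
    cpg = np.empty(n, dtype=object)
    planted_high = np.isin(
        klass, [CLASS_COMMON, CLASS_TDMR, CLASS_IMPRINTED, CLASS_CLUSTER, CLASS_ES_SOMATIC]
    )
    cpg[planted_high] = "high"
    cpg[klass == CLASS_LOW_CPG] = "low"
    free = np.flatnonzero(klass == CLASS_UNMETH)
    rng.shuffle(free)
    n_high = max(0, round(config.frac_high_cpg * n) - int(planted_high.sum()))
    n_mid = round(config.frac_intermediate_cpg * n)
    cpg[free[:n_high]] = "high"
    cpg[free[n_high : n_high + n_mid]] = "mid"
    cpg[free[n_high + n_mid :]] = "low"
    return cpg


def _place_dmrs(klass: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    """TSS-relative planted region (lo, hi) per gene.

    Methylated classes get a DMR of ``dmr_width`` bp: in the core promoter
    (-1.5 kb..+0.5 kb) with probability ``frac_dmr_core``, otherwise
    centred uniformly in the upstream or downstream flank (centre ranges
    extend past the probed span so flank coverage stays uniform out to the
    array edges).  CpG-poor constitutive regions never sit in the core.
    Unmethylated genes carry their (hypomethylated) core island.
    """
    n = len(klass)
    half = config.dmr_width // 2
    rel = np.zeros((n, 2), dtype=int)
    for i, kl in enumerate(klass):
        if kl == CLASS_UNMETH:
            rel[i] = (-500, 500)
            continue
        u = rng.random()
        if kl != CLASS_LOW_CPG and u < config.frac_dmr_core:
            rel[i] = (-1500, 500)
            continue
        if rng.random() < config.frac_dmr_upstream:
            lo, hi = config.dmr_up_center_range
        else:
            lo, hi = config.dmr_down_center_range
        c = int(rng.integers(lo, hi + 1))
        rel[i] = (c - half, c + half)
    return rel


def _build_sequence(
    genes: pd.DataFrame, config: SimulationConfig, rng
) -> tuple[str, np.ndarray]:
    """Synthetic chromosome with planted CpG density.

    Background bases carry no CpG (any background CG dinucleotide is
    broken); CpG dinucleotides are then planted on a near-regular lattice —
    systematic placement with uniform jitter — at the density assigned to
    each segment (background, CpG island, planted region).  The realised
    density of every window therefore tracks its target tightly, keeping
    the low/intermediate/high promoter classes well separated around the
    analysis' 4% and 5% boundaries.

    Returns the sequence and the CG-start indicator cumulative sum used for
    fast window counts.
    """
    genome_len = config.n_genes * config.gene_slot_bp
    # densities in 0.1% units
    density = np.full(genome_len, int(config.cpg_density_background * 10), dtype=np.int16)
    island_ranges = []
    for g in genes.itertuples(index=False):
        strand = int(g.strand)
        if g.cpg_class in ("high", "mid"):
            lo, hi = _rel_to_genomic(g.tss, strand, (-500, 500))
            d = config.cpg_density_high if g.cpg_class == "high" else config.cpg_density_mid
            density[lo:hi] = int(d * 10)
            if g.cpg_class == "high":
                island_ranges.append((lo, hi))
        if g.meth_class != CLASS_UNMETH:
            lo, hi = _rel_to_genomic(g.tss, strand, (g.region_start_rel, g.region_end_rel))
            lo, hi = max(0, lo), min(genome_len, hi)
            d = config.cpg_density_low if g.meth_class == CLASS_LOW_CPG else config.cpg_density_high
            density[lo:hi] = np.maximum(density[lo:hi], int(d * 10))

    # background bases, GC-boosted inside islands
    cum = np.cumsum(_BG_COMP)
    base = np.frombuffer(b"ACGT", dtype=np.uint8)[
        np.searchsorted(cum, rng.random(genome_len))
    ].copy()
    cum_isl = np.cumsum(_ISLAND_COMP)
    for lo, hi in island_ranges:
        base[lo:hi] = np.frombuffer(b"ACGT", dtype=np.uint8)[
            np.searchsorted(cum_isl, rng.random(hi - lo))
        ]
    # remove background CpGs so density is controlled entirely by planting
    cg = (base[:-1] == _C) & (base[1:] == _G)
    base[1:][cg] = _A

    # systematic CpG planting with jitter, per constant-density run
    edges = np.flatnonzero(np.diff(density)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [genome_len]))
    positions = []
    for s, e in zip(starts, ends):
        d = density[s] / 1000.0  # CpGs per bp
        k = int(round((e - s) * d))
        if k == 0:
            continue
        step = (e - s) / k
        centers = s + (np.arange(k) + 0.5) * step
        jitter = rng.uniform(-step / 4, step / 4, size=k)
        pos = np.clip(np.floor(centers + jitter).astype(np.int64), s, e - 2)
        positions.append(pos)
    pos = np.concatenate(positions)
    base[pos] = _C
    base[pos + 1] = _G

    cg_start = np.zeros(genome_len + 1, dtype=np.int64)
    cg_start[1:-1] = np.cumsum((base[:-1] == _C) & (base[1:] == _G))
    cg_start[-1] = cg_start[-2]
    return base.tobytes().decode("ascii"), cg_start


def _rel_to_genomic(tss: int, strand: int, rel: tuple[int, int]) -> tuple[int, int]:
    a, b = rel
    if strand == 1:
        return tss + a, tss + b
    return tss - b, tss - a


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Generate the synthetic genome annotation and probe layout.

    One synthetic chromosome holds ``n_genes`` equally spaced genes with
    random strands.  Each gene carries its generating labels: methylome
    class, promoter CpG-density class, and the genomic interval of its
    planted region.  CpG islands cover the core of every CpG-rich promoter;
    imprinting-centre records cover the planted imprinted regions.  The
    probe layout tiles each promoter with ``n_probes_per_promoter`` probes
    across ``promoter_span``, with per-probe CpG counts computed from the
    actual sequence in 500-bp windows.

    Deterministic for a fixed ``config.seed``.
    """
    rng = _rng(config, 0)
    n = config.n_genes
    slot = config.gene_slot_bp
    chrom = config.chrom_name

    strand = rng.choice([1, -1], size=n)
    slot_start = np.arange(n) * slot
    tss = np.where(strand == 1, slot_start + _TSS_OFFSET_PLUS, slot_start + _TSS_OFFSET_MINUS)
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    klass, cluster_id = _assign_classes(config, rng)
    cpg_class = _assign_cpg_classes(klass, config, rng)
    rel = _place_dmrs(klass, config, rng)

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "meth_class": klass,
            "cpg_class": cpg_class,
            "cluster_id": cluster_id,
            "region_start_rel": rel[:, 0],
            "region_end_rel": rel[:, 1],
        }
    )
    genomic = np.array(
        [
            _rel_to_genomic(t, int(s), (a, b))
            for t, s, a, b in zip(tss, strand, rel[:, 0], rel[:, 1])
        ]
    )
    genome_len = n * slot
    genes["region_start"] = np.clip(genomic[:, 0], 0, genome_len)
    genes["region_end"] = np.clip(genomic[:, 1], 0, genome_len)

    sequence, cg_cum = _build_sequence(genes, config, rng)

    islands = genes[genes["cpg_class"] == "high"]
    cpg_islands = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [
                _rel_to_genomic(t, int(s), (-500, 500))[0]
                for t, s in zip(islands["tss"], islands["strand"])
            ],
            "end": [
                _rel_to_genomic(t, int(s), (-500, 500))[1]
                for t, s in zip(islands["tss"], islands["strand"])
            ],
            "name": islands["gene_id"].to_numpy(),
        }
    ).sort_values("start").reset_index(drop=True)

    imp = genes[genes["meth_class"] == CLASS_IMPRINTED]
    icrs = pd.DataFrame(
        {
            "chrom": chrom,
            "start": imp["region_start"].to_numpy(),
            "end": imp["region_end"].to_numpy(),
            "name": imp["gene_id"].to_numpy(),
        }
    ).sort_values("start").reset_index(drop=True)

    probes = _probe_layout(genes, cg_cum, genome_len, config)
    return GenomeAnnotation(
        genes=genes,
        cpg_islands=cpg_islands,
        icrs=icrs,
        sequence={chrom: sequence},
        probes=probes,
    )


def _probe_layout(
    genes: pd.DataFrame, cg_cum: np.ndarray, genome_len: int, config: SimulationConfig
) -> pd.DataFrame:
    span0, span1 = config.promoter_span
    npp = config.n_probes_per_promoter
    offsets = np.round(span0 + np.arange(npp) * (span1 - span0) / (npp - 1)).astype(int)
    tss = genes["tss"].to_numpy()
    strand = genes["strand"].to_numpy().astype(int)
    centers = (tss[:, None] + strand[:, None] * offsets[None, :]).ravel()
    gene_rep = np.repeat(genes["gene_id"].to_numpy(), npp)
    off_rep = np.tile(offsets, len(genes))
    half_probe = config.probe_length // 2
    start = centers - half_probe
    end = start + config.probe_length
    wlo = np.clip(centers - 250, 0, genome_len)
    whi = np.clip(centers + 250, 0, genome_len)
    counts = cg_cum[whi] - cg_cum[wlo]
    density = 100.0 * counts / np.maximum(whi - wlo, 1)
    probes = pd.DataFrame(
        {
            "probe_id": [f"{g}:p{abs(o):05d}{'u' if o < 0 else 'd'}" for g, o in zip(gene_rep, off_rep)],
            "chrom": config.chrom_name,
            "start": start,
            "end": end,
            "gene_id": gene_rep,
            "offset": off_rep,
            "cpg_count": counts,
            "cpg_density": density,
        }
    )
    return probes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# --------------------------------------------------------------------------
# truth
# --------------------------------------------------------------------------

def generate_truth(annotation: GenomeAnnotation, config: SimulationConfig) -> TrueMethylome:
    """Planted methylation level per (region, sample).

    Class rules: imprinted regions sit at level 0.5 in every sample
    including sperm; commonly methylated germline regions are >= 0.8 in all
    somatic samples and <= 0.1 in ES and sperm; ES/somatic regions are
    methylated everywhere except sperm; T-DMRs are methylated in exactly
    one germ layer (a ``frac_tdmr_maintained`` subset also in the matched
    adult tissue); cluster genes are mosaically methylated across somatic
    samples; CpG-poor constitutive regions are methylated everywhere;
    everything else stays at the hypomethylated floor.
    """
    rng = _rng(config, 1)
    genes = annotation.genes
    samples = list(config.samples)
    n = len(genes)
    levels = np.full((n, len(samples)), 0.02)
    som = [samples.index(s) for s in config.somatic_samples]
    layer_idx = {s: samples.index(s) for s in config.germ_layers}
    adult_partner = dict(zip(config.germ_layers, config.adult_somatic))

    tdmr_layer = np.full(n, "", dtype=object)
    tdmr_maintained = np.zeros(n, dtype=bool)
    for i, g in enumerate(genes.itertuples(index=False)):
        kl = g.meth_class
        if kl == CLASS_COMMON:
            levels[i, som] = 0.9
        elif kl == CLASS_ES_SOMATIC:
            levels[i, :] = 0.9
            levels[i, samples.index(config.sperm_sample)] = 0.02
        elif kl == CLASS_IMPRINTED:
            levels[i, :] = 0.5
        elif kl == CLASS_LOW_CPG:
            levels[i, :] = 0.9
        elif kl == CLASS_TDMR:
            layer = rng.choice(config.germ_layers)
            tdmr_layer[i] = layer
            levels[i, layer_idx[layer]] = 0.9
            if rng.random() < config.frac_tdmr_maintained:
                tdmr_maintained[i] = True
                levels[i, samples.index(adult_partner[layer])] = 0.9
        elif kl == CLASS_CLUSTER:
            meth = rng.random(len(som)) < config.cluster_meth_prob
            levels[i, som] = np.where(meth, 0.9, 0.05)

    regions = pd.DataFrame(
        {
            "region_id": ["R:" + g for g in genes["gene_id"]],
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": genes["region_start"].to_numpy(),
            "end": genes["region_end"].to_numpy(),
            "meth_class": genes["meth_class"].to_numpy(),
            "tdmr_layer": tdmr_layer,
            "tdmr_maintained": tdmr_maintained,
        }
    )
    lv = pd.DataFrame(levels, index=regions["region_id"].to_numpy(), columns=samples)
    return TrueMethylome(regions=regions, levels=lv)


# --------------------------------------------------------------------------
# arrays
# --------------------------------------------------------------------------

def probe_methylation(
    truth: TrueMethylome, annotation: GenomeAnnotation, sample: str
) -> np.ndarray:
    """Per-probe planted methylation level for one sample (probe centre
    inside the gene's planted region, else 0)."""
    probes = annotation.probes
    reg = truth.regions.set_index("gene_id")
    lv = truth.levels
    r = reg.loc[probes["gene_id"]]
    centers = ((probes["start"] + probes["end"]) // 2).to_numpy()
    inside = (centers >= r["start"].to_numpy()) & (centers < r["end"].to_numpy())
    level = lv.loc[r["region_id"], sample].to_numpy()
    return np.where(inside, level, 0.0)


def simulate_arrays(
    truth: TrueMethylome, annotation: GenomeAnnotation, config: SimulationConfig
) -> IntensityMatrix:
    """Simulate duplicate MeDIP and input arrays for every arrayed sample.

    The expected MeDIP log2 ratio of a probe is ``enrichment_slope ×
    methylation × c/(c + sat_halfway_cpg)`` where *c* is the probe's CpG
    count per 500 bp — enrichment grows with CpG count and saturates, so
    allele-methylated (level 0.5) CpG-rich regions still score highly while
    CpG-poor methylated probes are attenuated.  Input arrays have zero
    expected log ratio.  Noise is additive Gaussian on the log2 scale
    (i.e. lognormal multiplicative intensity noise), independent across
    replicate arrays; a shared per-probe affinity effect cancels in the
    MeDIP-minus-input comparison.
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(config, 2)
    probes = annotation.probes
    n = len(probes)
    sat = probes["cpg_count"].to_numpy() / (
        probes["cpg_count"].to_numpy() + config.sat_halfway_cpg
    )
    probe_effect = rng.normal(0.0, config.probe_effect_sd, size=n)
    cols, meta = [], []
    for sample in config.samples:
        m = config.enrichment_slope * probe_methylation(truth, annotation, sample) * sat
        for channel, signal in (("MeDIP", m), ("input", np.zeros(n))):
            for rep in range(1, config.replicates + 1):
                noise = rng.normal(0.0, config.noise_sd, size=n)
                cols.append(10.0 + probe_effect + signal + noise)
                meta.append((f"{sample}.{channel}.{rep}", sample, channel, rep))
    values = np.column_stack(cols)
    arrays = pd.DataFrame(meta, columns=["name", "sample", "channel", "replicate"])
    return IntensityMatrix(probes=probes, values=values, arrays=arrays)


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def simulate_expression(
    truth: TrueMethylome, annotation: GenomeAnnotation, config: SimulationConfig
) -> pd.DataFrame:
    """Gene × sample expression matrix, globally normalised to mean 100.

    Genes whose planted region overlaps the core promoter
    (-1.5 kb..+0.5 kb) and is methylated in a sample are drawn from a
    low-expression distribution there (a ``expr_meth_penalty_log2`` log2
    deficit).  Commonly methylated germline genes are low everywhere except
    the testis column, which gets a ``expr_testis_boost_log2`` boost.
    After exponentiation every column is scaled so its mean is exactly 100.
    """
    rng = _rng(config, 3)
    genes = annotation.genes
    n = len(genes)
    samples = list(config.samples) + [config.testis_sample]
    germline = (genes["meth_class"] == CLASS_COMMON).to_numpy()
    base = rng.normal(config.expr_base_log2, config.expr_gene_sd, size=n)
    base[germline] = rng.normal(
        config.expr_germline_base_log2, 0.8, size=int(germline.sum())
    )
    log2 = base[:, None] + rng.normal(0.0, config.expr_noise_sd, size=(n, len(samples)))
    log2[germline, -1] += config.expr_testis_boost_log2
    for j, sample in enumerate(config.samples):
        meth = truth.core_methylated(genes, sample).to_numpy()
        log2[meth, j] -= config.expr_meth_penalty_log2
    linear = np.power(2.0, log2)
    linear *= 100.0 / linear.mean(axis=0, keepdims=True)
    return pd.DataFrame(linear, index=genes["gene_id"].to_numpy(), columns=samples)


# --------------------------------------------------------------------------
# histone states
# --------------------------------------------------------------------------

def simulate_histone(
    truth: TrueMethylome, annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Histone states and peak calls for the histone-profiled samples.

    States are drawn conditionally on the planted core-promoter methylation
    flag.  Unmethylated promoters are mostly H3K4me3-marked; methylated
    promoters carry K4 with probability ``config.p_k4_given_meth``
    (default 0: strict exclusivity, the K4 mark shielding promoters from
    de novo methylation), so the realised P(methylated | K4) is far below
    P(methylated | any other state) in every sample.  Because commonly
    methylated germline genes are unmethylated in ES cells and methylated
    after differentiation, they lose H3K4me3 between the ES-like and
    differentiated samples while gaining methylation.

    Returns ``(states, peaks)``: a gene × sample state table with values in
    {K4, K27, bivalent, none}, and per-(sample, mark) peak interval tables,
    each peak overlapping its gene's TSS ± 2 kb window.
    """
    rng = _rng(config, 4)
    genes = annotation.genes
    n = len(genes)
    states = {}
    peaks: dict[tuple[str, str], pd.DataFrame] = {}
    b = config.p_k4_given_unmeth
    for sample in config.histone_samples:
        meth = truth.core_methylated(genes, sample).to_numpy()
        cum_meth = np.cumsum(
            [config.p_k4_given_meth, config.p_biv_given_meth, config.p_k27_given_meth]
        )
        cum_unmeth = np.cumsum(
            [b, config.p_biv_given_unmeth, config.p_k27_given_unmeth]
        )
        u = rng.random(n)
        state = np.empty(n, dtype=object)
        labels = np.array(["K4", "bivalent", "K27", "none"], dtype=object)
        state[meth] = labels[np.searchsorted(cum_meth, u[meth])]
        state[~meth] = labels[np.searchsorted(cum_unmeth, u[~meth])]
        states[sample] = state

        tss = genes["tss"].to_numpy()
        j4 = rng.integers(-100, 101, size=n)
        j27 = rng.integers(-100, 101, size=n)
        has_k4 = np.isin(state, ["K4", "bivalent"])
        has_k27 = np.isin(state, ["K27", "bivalent"])
        for mark, has, lo, hi, jit in (
            ("K4", has_k4, -400, 600, j4),
            ("K27", has_k27, -800, 800, j27),
        ):
            peaks[(sample, mark)] = pd.DataFrame(
                {
                    "chrom": config.chrom_name,
                    "start": (tss + lo + jit)[has],
                    "end": (tss + hi + jit)[has],
                    "name": genes["gene_id"].to_numpy()[has],
                }
            ).sort_values("start").reset_index(drop=True)
    state_df = pd.DataFrame(states, index=genes["gene_id"].to_numpy())
    return state_df, peaks


# --------------------------------------------------------------------------
# one-call bundle
# --------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Everything one simulation run produces."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: TrueMethylome
    intensities: IntensityMatrix
    expression: pd.DataFrame
    histone_states: pd.DataFrame
    histone_peaks: dict[tuple[str, str], pd.DataFrame]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: annotation → truth → arrays → expression →
    histone.  Deterministic for a fixed seed."""
    annotation = generate_annotation(config)
    truth = generate_truth(annotation, config)
    intensities = simulate_arrays(truth, annotation, config)
    expression = simulate_expression(truth, annotation, config)
    states, peaks = simulate_histone(truth, annotation, config)
    return SimulatedStudy(
        config=config,
        annotation=annotation,
        truth=truth,
        intensities=intensities,
        expression=expression,
        histone_states=states,
        histone_peaks=peaks,
    )
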