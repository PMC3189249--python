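"""Genome annotation containers, interval I/O and promoter CpG utilities.

Coordinate conventions
----------------------
All in-memory intervals are 0-based, half-open ``[start, end)`` — the BED
convention.  GFF3 is written (and read) 1-based, closed, so a BED interval
``(100, 200)`` round-trips through GFF as ``start=101, end=200``.

TSS-relative offsets are strand-aware throughout: negative offsets are
upstream on the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end", "name"]

ZONE_CORE = "core"
ZONE_UP = "tss_up"
ZONE_DOWN = "tss_down"


@dataclass
class GenomeAnnotation:
    """Genes, CpG islands, imprinting centres and (optionally) sequence.

    Attributes
    ----------
    genes : pandas.DataFrame
        One row per gene with at least ``gene_id, chrom, tss, strand``.
        The simulator adds its generating labels (``meth_class``,
        ``cpg_class``, planted region coordinates) as extra columns.
    cpg_islands, icrs : pandas.DataFrame
        Interval tables (``chrom, start, end, name``), 0-based half-open.
    sequence : dict[str, str] or None
        Per-chromosome sequence; required for CpG-content computations.
    probes : pandas.DataFrame or None
        Probe layout (``probe_id, chrom, start, end, gene_id, offset,
        cpg_count, cpg_density``) when the annotation comes with an array
        design.
    """

    genes: pd.DataFrame
    cpg_islands: pd.DataFrame
    icrs: pd.DataFrame
    sequence: dict[str, str] | None = None
    probes: pd.DataFrame | None = None

    def __post_init__(self):
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"genes table lacks columns: {sorted(missing)}")
        for tbl, label in ((self.cpg_islands, "cpg_islands"), (self.icrs, "icrs")):
            if len(tbl) and (tbl["start"] >= tbl["end"]).any():
                raise ValueError(f"{label}: intervals must satisfy start < end")
        if self.sequence is not None:
            lengths = {c: len(s) for c, s in self.sequence.items()}
            bad = self.genes[
                self.genes.apply(
                    lambda g: not (0 <= g.tss < lengths.get(g.chrom, 0)), axis=1
                )
            ]
            if len(bad):
                raise ValueError(
                    f"{len(bad)} TSSs fall outside their chromosome sequence"
                )


# --------------------------------------------------------------------------
# interval I/O
# --------------------------------------------------------------------------

def read_intervals(path, fmt: str = "BED") -> pd.DataFrame:
    """Read an interval set into a sorted 0-based half-open table.

    Parameters
    ----------
    path : str or Path
    fmt : {"BED", "GFF", "TSV"}
        BED is 0-based half-open; GFF (GFF3) is 1-based closed and is
        converted on input; TSV expects a header with chrom/start/end
        (half-open) and an optional name column.

    Returns
    -------
    pandas.DataFrame with columns ``chrom, start, end, name``, sorted by
    (chrom, start, end).  Unsorted input is accepted.

    Raises
    ------
    ValueError
        On an unknown format or a malformed line (reported with its
        1-based line number).
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF", "TSV"):
        raise ValueError(f"unsupported interval format: {fmt!r}")
    rows = []
    with open(path) as fh:
        header_skipped = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if fmt == "BED":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else "."
                elif fmt == "GFF":
                    if len(parts) < 5:
                        raise ValueError("fewer than 5 GFF fields")
                    chrom = parts[0]
                    start = int(parts[3]) - 1  # 1-based closed -> half-open
                    end = int(parts[4])
                    name = parts[8] if len(parts) > 8 else "."
                else:  # TSV with header
                    if not header_skipped:
                        header_skipped = True
                        if not parts[1].lstrip("-").isdigit():
                            continue
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else "."
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed {fmt} line {lineno}: {exc}") from exc
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: empty or inverted interval [{start}, {end})"
                )
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_intervals(intervals: pd.DataFrame, path, fmt: str = "BED") -> None:
    """Write an interval table; the inverse of :func:`read_intervals`."""
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF", "TSV"):
        raise ValueError(f"unsupported interval format: {fmt!r}")
    df = intervals.copy()
    if "name" not in df.columns:
        df["name"] = "."
    with open(path, "w") as fh:
        if fmt == "TSV":
            fh.write("chrom\tstart\tend\tname\n")
        for row in df.itertuples(index=False):
            if fmt == "GFF":
                fh.write(
                    f"{row.chrom}\tpromethylome\tregion\t{row.start + 1}\t{row.end}"
                    f"\t.\t.\t.\t{row.name}\n"
                )
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\n")


# --------------------------------------------------------------------------
# CpG content
# --------------------------------------------------------------------------

def count_cpg(sequence: str) -> int:
    """Number of CpG dinucleotides, counted by a non-overlapping
    left-to-right scan (CG cannot overlap itself, so this equals the count
    of all CG occurrences)."""
    return sequence.upper().count("CG")


def probe_cpg_content(probe_center: int, sequence: str, window_bp: int = 500) -> float:
    """CpG density (%) in a window centred on a probe.

    The window is ``window_bp`` wide, centred on ``probe_center``; when it
    would extend past either end of the sequence it is truncated and the
    actual window length is used as denominator.

    Returns ``100 * n_CpG / window_length``; e.g. 20 CpGs in 500 bp → 4.0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    half = window_bp // 2
    lo = max(0, probe_center - half)
    hi = min(len(sequence), probe_center + window_bp - half)
    if hi <= lo:
        raise ValueError("window falls entirely outside the sequence")
    return 100.0 * count_cpg(sequence[lo:hi]) / (hi - lo)


def _window_stats(seq: str) -> tuple[float, float]:
    """(CpG observed/expected, GC fraction) of a sequence window."""
    seq = seq.upper()
    n = len(seq)
    nc = seq.count("C")
    ng = seq.count("G")
    ncpg = count_cpg(seq)
    gc = (nc + ng) / n if n else 0.0
    oe = (ncpg * n) / (nc * ng) if nc and ng else 0.0
    return oe, gc


def classify_promoter_cpg(
    tss: int,
    strand: int,
    sequence: str,
    *,
    region: tuple[int, int] = (-700, 200),
    window_bp: int = 500,
    step_bp: int = 10,
    hcp_oe: float = 0.75,
    lcp_oe: float = 0.48,
    hcp_gc: float = 0.55,
) -> str | None:
    """Classify a promoter as HCP / ICP / LCP from its sequence.

    Sliding ``window_bp`` windows (step ``step_bp``) are evaluated over the
    strand-aware ``region`` around the TSS.  The promoter is HCP if any
    window reaches CpG observed/expected >= ``hcp_oe`` *and* GC fraction >=
    ``hcp_gc`` (both inclusive); LCP if no window reaches observed/expected
    ``lcp_oe``; otherwise ICP.  CpG observed/expected and GC content are
    invariant under reverse complement, so minus-strand promoters are
    evaluated on the mirrored forward-strand window without complementing.

    Returns ``None`` (unclassified) when the sequence around the TSS is
    missing or shorter than one window.
    """
    if strand not in (1, -1):
        raise ValueError("strand must be +1 or -1")
    a, b = region
    if strand == 1:
        lo, hi = tss + a, tss + b
    else:
        lo, hi = tss - b, tss - a
    lo = max(0, lo)
    hi = min(len(sequence), hi)
    if hi - lo < window_bp:
        return None
    any_hcp = False
    any_mid = False
    for s in range(lo, hi - window_bp + 1, step_bp):
        oe, gc = _window_stats(sequence[s : s + window_bp])
        if oe >= hcp_oe and gc >= hcp_gc:
            any_hcp = True
            break
        if oe >= lcp_oe:
            any_mid = True
    if any_hcp:
        return "HCP"
    return "ICP" if any_mid else "LCP"


# --------------------------------------------------------------------------
# TSS zones
# --------------------------------------------------------------------------

def assign_region_to_tss(
    region: tuple[str, int, int],
    genes: pd.DataFrame,
    core_zone: tuple[int, int] = (-1000, 500),
) -> tuple[str, str]:
    """Assign a region to its nearest TSS and promoter zone.

    The nearest gene (same chromosome, by distance from the region midpoint)
    wins; an exact distance tie goes to the lexicographically smaller gene
    id.  The strand-aware signed offset of the midpoint decides the zone:
    ``core`` inside ``core_zone`` (inclusive), ``tss_up`` upstream of it,
    ``tss_down`` downstream.

    Returns ``(gene_id, zone)``.
    """
    if len(genes) == 0:
        raise ValueError("need at least one gene")
    chrom, start, end = region
    sub = genes[genes["chrom"] == chrom]
    if len(sub) == 0:
        sub = genes
    mid = (start + end) // 2
    dist = (sub["tss"] - mid).abs()
    best = dist.min()
    winners = sub.loc[dist == best].sort_values("gene_id")
    gene = winners.iloc[0]
    offset = (mid - gene.tss) * int(gene.strand)
    lo, hi = core_zone
    if lo <= offset <= hi:
        zone = ZONE_CORE
    elif offset < lo:
        zone = ZONE_UP
    else:
        zone = ZONE_DOWN
    return str(gene.gene_id), zone


def assign_regions_to_tss(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    core_zone: tuple[int, int] = (-1000, 500),
) -> pd.DataFrame:
    """Vectorised :func:`assign_region_to_tss` over an interval table.

    Returns a copy of ``regions`` with ``gene_id``, ``tss_offset`` and
    ``zone`` columns appended.
    """
    out = regions.copy()
    gene_ids = np.empty(len(out), dtype=object)
    offsets = np.zeros(len(out), dtype=int)
    zones = np.empty(len(out), dtype=object)
    lo, hi = core_zone
    for chrom, idx in out.groupby("chrom").groups.items():
        sub = genes[genes["chrom"] == chrom].sort_values(["tss", "gene_id"])
        if len(sub) == 0:
            sub = genes.sort_values(["tss", "gene_id"])
        tss = sub["tss"].to_numpy()
        mids = ((out.loc[idx, "start"] + out.loc[idx, "end"]) // 2).to_numpy()
        pos = np.searchsorted(tss, mids)
        left = np.clip(pos - 1, 0, len(tss) - 1)
        right = np.clip(pos, 0, len(tss) - 1)
        dl = np.abs(mids - tss[left])
        dr = np.abs(mids - tss[right])
        # exact tie -> smaller gene_id; genes are sorted by (tss, gene_id) so
        # the left candidate has the smaller id only if its id sorts first
        ids_l = sub["gene_id"].to_numpy()[left]
        ids_r = sub["gene_id"].to_numpy()[right]
        take_left = (dl < dr) | ((dl == dr) & (ids_l <= ids_r))
        choice = np.where(take_left, left, right)
        g = sub.iloc[choice]
        gene_ids[out.index.get_indexer(idx)] = g["gene_id"].to_numpy()
        off = (mids - g["tss"].to_numpy()) * g["strand"].to_numpy().astype(int)
        offsets[out.index.get_indexer(idx)] = off
        z = np.where(off < lo, ZONE_UP, np.where(off > hi, ZONE_DOWN, ZONE_CORE))
        zones[out.index.get_indexer(idx)] = z
    out["gene_id"] = gene_ids
    out["tss_offset"] = offsets
    out["zone"] = zones
    return out
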