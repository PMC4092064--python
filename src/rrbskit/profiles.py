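"""Genome-wide methylome summaries.

Region-level mean methylation histograms, TSS sliding-window meta-profiles
(gene-oriented, per-gene-then-across-genes averaging), TSS CpG-content
classification, and single-nucleotide histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calls import CpGCallTable
from .genome import Gene, Genome

logger = logging.getLogger(__name__)

Region = Tuple[str, int, int]

#: threshold (percent CG starts per bp of window) splitting promoters into
#: high and low CpG-content classes
CPG_CONTENT_THRESHOLD = 3.7


@dataclass
class MetaProfile:
    """Mean methylation per window offset from the TSS, gene-averaged.

    Window ``w`` covers gene-oriented coordinates
    ``[TSS + offsets[w], TSS + offsets[w] + window)``.  ``mean`` is NaN for
    windows to which no gene contributed.
    """

    offsets: np.ndarray
    mean: np.ndarray
    n_genes: np.ndarray
    window: int
    step: int
    flank: int

    @property
    def n_windows(self) -> int:
        return self.offsets.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "n_genes": self.n_genes}
        )


@dataclass(frozen=True)
class Histogram:
    """Counts per fixed-width bin of percent values; last bin closed at 100."""

    counts: np.ndarray
    edges: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def mode_bin(self) -> int:
        return int(np.argmax(self.counts))


def histogram_of_percents(values: Iterable[float], bin_width: int = 10) -> Histogram:
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    edges = np.arange(0, 100 + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    return Histogram(counts, edges)


def region_mean_methylation(
    calls: CpGCallTable,
    regions: Sequence[Region],
) -> List[Optional[float]]:
    """Unweighted mean of per-site percents inside each region.

    Regions with no passing site yield ``None`` ("no data" is not zero).
    """
    by_contig = calls.by_contig()
    out: List[Optional[float]] = []
    for contig, start, end in regions:
        if start < 0 or end <= start:
            raise ValueError(f"malformed region {(contig, start, end)}")
        if contig not in by_contig:
            out.append(None)
            continue
        pos, pct = by_contig[contig]
        lo, hi = np.searchsorted(pos, (start, end))
        out.append(float(pct[lo:hi].mean()) if hi > lo else None)
    return out


def intergenic_regions(
    genes: Iterable[Gene],
    contig_lengths: Mapping[str, int],
    min_length: int = 1_000,
) -> List[Region]:
    """Per-contig complement of gene spans; pieces shorter than
    ``min_length`` are dropped."""
    spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contig_lengths}
    for gene in genes:
        spans.setdefault(gene.contig, []).append((gene.start, gene.end))
    out: List[Region] = []
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        cursor = 0
        for start, end in sorted(spans.get(contig, [])):
            if start > cursor and start - cursor >= min_length:
                out.append((contig, cursor, start))
            cursor = max(cursor, end)
        if length > cursor and length - cursor >= min_length:
            out.append((contig, cursor, length))
    return out


def tss_meta_profile(
    calls: CpGCallTable,
    genes: Iterable[Gene],
    contig_lengths: Mapping[str, int],
    flank: int = 6_000,
    window: int = 1_000,
    step: int = 50,
) -> MetaProfile:
    """Sliding-window mean methylation around the TSS, averaged over genes.

    Windows are evaluated in gene orientation (minus-strand genes mirrored so
    negative offsets are biologically upstream).  Each gene contributes the
    mean of its site percents per window; the profile is the unweighted mean
    over contributing genes.  Genes whose TSS lies closer than ``flank`` to a
    contig edge are skipped.
    """
    if window > 2 * flank:
        raise ValueError("window must not exceed 2 * flank")
    offsets = np.arange(-flank, flank - window + 1, step, dtype=np.int64)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=np.int64)
    by_contig = calls.by_contig()
    n_skipped = 0
    for gene in genes:
        length = contig_lengths[gene.contig]
        if gene.tss - flank < 0 or gene.tss + flank > length:
            n_skipped += 1
            continue
        if gene.contig not in by_contig:
            continue
        pos, pct = by_contig[gene.contig]
        if gene.strand == "+":
            starts = gene.tss + offsets
            ends = starts + window
        else:
            # gene coordinate x maps to genomic tss - x
            ends = gene.tss - offsets + 1
            starts = ends - window
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        for w in range(offsets.size):
            if hi[w] > lo[w]:
                sums[w] += pct[lo[w]:hi[w]].mean()
                counts[w] += 1
    if n_skipped:
        logger.info("tss_meta_profile: skipped %d genes too close to a "
                    "contig edge", n_skipped)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetaProfile(offsets, mean, counts, window, step, flank)


@dataclass(frozen=True)
class TssCpG:
    gene_id: str
    percent: float
    label: str  # "high" or "low"


def tss_cpg_content(
    genome: Genome,
    genes: Iterable[Gene],
    half: int = 500,
    threshold: float = CPG_CONTENT_THRESHOLD,
) -> Dict[str, TssCpG]:
    """CG-dinucleotide content of ``[TSS-half, TSS+half)`` per gene.

    Percent = 100 x (CG starts in window) / window length; the high/low
    class boundary sits at ``threshold`` (strictly greater is high).  The
    window is taken on forward-strand coordinates regardless of gene strand
    (documented convention).  Out-of-bounds windows skip the gene.
    """
    out: Dict[str, TssCpG] = {}
    for gene in genes:
        seq = genome[gene.contig]
        lo, hi = gene.tss - half, gene.tss + half
        if lo < 0 or hi > len(seq):
            logger.warning("tss_cpg_content: window for %s out of bounds; "
                           "gene skipped", gene.gene_id)
            continue
        n_cg = _count_cg_starts(seq, lo, hi)
        percent = 100.0 * n_cg / (2 * half)
        label = "high" if percent > threshold else "low"
        out[gene.gene_id] = TssCpG(gene.gene_id, percent, label)
    return out


def _count_cg_starts(seq: str, lo: int, hi: int) -> int:
    """Number of CG dinucleotides whose C lies in [lo, hi)."""
    n = 0
    i = seq.find("CG", lo)
    while 0 <= i < hi:
        n += 1
        i = seq.find("CG", i + 1)
    return n


def single_site_histogram(
    calls: CpGCallTable,
    min_cov: int = 10,
    bin_width: int = 10,
) -> Histogram:
    """Histogram of per-site percent methylation at sites with at least
    ``min_cov`` observations."""
    from .calls import filter_by_coverage

    kept = filter_by_coverage(calls, min_cov)
    percents = [kept.percent(site) for site in kept.data]
    return histogram_of_percents(percents, bin_width)


def plot_profile(profile: MetaProfile, path: str, title: str = "") -> None:
    """Write a simple offset-vs-mean plot (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(profile.offsets, profile.mean, lw=1.5)
    ax.set_xlabel("offset from TSS (bp)")
    ax.set_ylabel("mean methylation (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
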