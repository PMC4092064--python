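"""Synthetic genome, annotation, methylome truth and expression generators.

The generators produce a toy genome whose statistical structure matches what
the downstream analyses assume: CpG-poor background sequence, CpG-dense
islands centred on gene starts, a bimodal truth methylome (hypomethylated
active promoters against a hypermethylated background), and an expression
count table in which a configurable fraction of genes is repressed.

Everything is driven by :class:`numpy.random.Generator` seeded explicitly,
so identical seeds reproduce identical output byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

from ._seq import A, C, G, T, codes_to_seq, cpg_positions

logger = logging.getLogger(__name__)

Genome = Dict[str, str]


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the synthetic genome generator.

    ``background_cpg_rate`` and ``island_cpg_rate`` are target densities of
    CG-dinucleotide starts per bp; islands span ``±island_half_width`` around
    each gene's TSS.  ``island_fraction`` controls the fraction of genes that
    actually receive an island (the rest keep background density, yielding
    low-CpG promoters for stratified analyses).
    """

    n_contigs: int = 4
    contig_length: int = 100_000
    background_cpg_rate: float = 0.01
    island_cpg_rate: float = 0.10
    island_half_width: int = 500
    n_genes: int = 20
    seed: int = 0
    gene_span: int = 5_000
    gene_spacing: int = 13_000
    tss_margin: int = 6_000
    island_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("n_contigs and contig_length must be positive")
        if self.contig_length < 10 * self.island_half_width:
            raise ValueError("contig_length must be at least 10 * island_half_width")
        # equality permitted so a no-island-signal control can be generated
        if not (0 <= self.background_cpg_rate <= self.island_cpg_rate <= 0.5):
            raise ValueError(
                "need 0 <= background_cpg_rate <= island_cpg_rate <= 0.5"
            )
        if not 0 <= self.island_fraction <= 1:
            raise ValueError("island_fraction must be in [0, 1]")
        if self.n_genes < 0 or self.gene_span < 1:
            raise ValueError("invalid gene geometry")


@dataclass(frozen=True)
class Gene:
    """A gene interval on a contig; 0-based half-open coordinates.

    The TSS of a ``+`` strand gene is ``start``; for a ``-`` strand gene it
    is ``end - 1``.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    has_island: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> int:
        return self.end - self.start


class MethylomeTruth:
    """Per-CpG ground-truth methylation probabilities.

    Sites are keyed by the forward-strand position of the C of each CG
    dinucleotide; the probability applies to both strands (symmetric CpG
    methylation).  Internally stored as sorted position/probability arrays
    per contig for fast interval queries.
    """

    def __init__(self, sites: Mapping[str, Tuple[np.ndarray, np.ndarray]],
                 active_genes: frozenset = frozenset()):
        self.sites = {
            contig: (np.asarray(pos, dtype=np.int64), np.asarray(m, dtype=np.float64))
            for contig, (pos, m) in sites.items()
        }
        self.active_genes = frozenset(active_genes)
        for contig, (pos, m) in self.sites.items():
            if pos.size != m.size:
                raise ValueError("position/probability length mismatch")
            if pos.size and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly sorted on {contig}")
            if m.size and ((m < 0) | (m > 1)).any():
                raise ValueError("methylation probabilities must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return sum(pos.size for pos, _ in self.sites.values())

    def m_at(self, contig: str, pos: int) -> float:
        positions, m = self.sites[contig]
        i = int(np.searchsorted(positions, pos))
        if i >= positions.size or positions[i] != pos:
            raise KeyError((contig, pos))
        return float(m[i])

    def __contains__(self, key) -> bool:
        contig, pos = key
        if contig not in self.sites:
            return False
        positions, _ = self.sites[contig]
        i = int(np.searchsorted(positions, pos))
        return i < positions.size and positions[i] == pos

    def items(self):
        for contig, (positions, m) in sorted(self.sites.items()):
            for p, v in zip(positions.tolist(), m.tolist()):
                yield (contig, p), v

    def in_interval(self, contig: str, start: int, end: int):
        """Positions and probabilities of sites with ``start <= pos < end``."""
        if contig not in self.sites:
            return np.empty(0, dtype=np.int64), np.empty(0)
        positions, m = self.sites[contig]
        lo, hi = np.searchsorted(positions, (start, end))
        return positions[lo:hi], m[lo:hi]


@dataclass
class ExpressionTable:
    """Raw read counts and expression class per gene.

    Invariant: ``class == "repressed"`` exactly when ``count < 10``.
    """

    counts: Dict[str, int]
    classes: Dict[str, str] = field(default_factory=dict)

    REPRESSED_MAX = 9

    def __post_init__(self) -> None:
        for gid, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {gid}")
        for gid, cls in self.classes.items():
            repressed = self.counts[gid] < 10
            if (cls == "repressed") != repressed:
                raise ValueError(f"class/count mismatch for {gid}")

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    """I.i.d. uniform ACGT codes with every CG dinucleotide destroyed.

    The G of each accidental CG is redrawn from {A, T}, which cannot create a
    new CG, so a single vectorised pass leaves the array CG-free and CpG
    placement is fully controlled by the planting step.
    """
    arr = rng.integers(0, 4, size=length, dtype=np.uint8)
    if length >= 2:
        cg = np.flatnonzero((arr[:-1] == C) & (arr[1:] == G))
        if cg.size:
            arr[cg + 1] = np.where(rng.random(cg.size) < 0.5, A, T).astype(np.uint8)
    return arr


def _plant_probability(rate: float) -> float:
    # Planted CpGs occupy 2 bp, so the realised density of a Bernoulli(p)
    # scan with a minimum gap of 2 is p/(1+p); invert to hit the target.
    return min(1.0, rate / (1.0 - rate)) if rate < 1.0 else 1.0


def _plant_cpgs(arr: np.ndarray, rate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Plant CG dinucleotides at Poisson-spaced positions.

    ``rate`` gives the target CpG-start density per position.  Collisions
    (candidate closer than 2 bp to the previous planted site) are skipped.
    Returns the planted positions.
    """
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    planted = []
    last = -2
    for p in hits.tolist():
        if p >= last + 2 and p + 1 < arr.size:
            arr[p] = C
            arr[p + 1] = G
            planted.append(p)
            last = p
    return np.asarray(planted, dtype=np.int64)


def _place_genes(spec: GenomeSpec, rng: np.random.Generator) -> List[Gene]:
    pitch = spec.gene_span + spec.gene_spacing
    usable = spec.contig_length - 2 * spec.tss_margin - spec.gene_span
    per_contig = 0 if usable < 0 else usable // pitch + 1
    if per_contig * spec.n_contigs < spec.n_genes:
        raise ValueError(
            f"genome too small: {spec.n_genes} genes requested but only "
            f"{per_contig * spec.n_contigs} fit "
            f"({per_contig} per contig x {spec.n_contigs} contigs)"
        )
    genes: List[Gene] = []
    idx = 0
    max_jitter = spec.gene_spacing // 4
    for ci in range(spec.n_contigs):
        contig = f"contig{ci:02d}"
        for k in range(per_contig):
            if idx >= spec.n_genes:
                break
            base = spec.tss_margin + k * pitch
            slack = spec.contig_length - spec.tss_margin - spec.gene_span - base
            jitter = int(rng.integers(0, min(max_jitter, slack) + 1))
            start = base + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            has_island = bool(rng.random() < spec.island_fraction)
            genes.append(Gene(f"g{idx:04d}", contig, strand, start,
                              start + spec.gene_span, has_island))
            idx += 1
    return genes


def generate_genome(spec: GenomeSpec) -> Tuple[Genome, List[Gene]]:
    """Generate contig sequences and a non-overlapping gene annotation.

    CpG density is ``island_cpg_rate`` within ``±island_half_width`` of the
    TSS of island-bearing genes and ``background_cpg_rate`` elsewhere.
    Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _place_genes(spec, rng)
    p_bg = _plant_probability(spec.background_cpg_rate)
    p_is = _plant_probability(spec.island_cpg_rate)
    genome: Genome = {}
    for ci in range(spec.n_contigs):
        contig = f"contig{ci:02d}"
        arr = _random_background(rng, spec.contig_length)
        rate = np.full(spec.contig_length, p_bg)
        for gene in genes:
            if gene.contig == contig and gene.has_island:
                lo = max(0, gene.tss - spec.island_half_width)
                hi = min(spec.contig_length, gene.tss + spec.island_half_width)
                rate[lo:hi] = p_is
        _plant_cpgs(arr, rate, rng)
        genome[contig] = codes_to_seq(arr)
    return genome, genes


# ---------------------------------------------------------------------------
# truth methylome
# ---------------------------------------------------------------------------

def generate_truth_methylome(
    genome: Genome,
    genes: Iterable[Gene],
    m_low: float = 0.05,
    m_high: float = 0.85,
    active_fraction: float = 0.5,
    jitter_sd: float = 0.03,
    promoter_upstream: int = 1_000,
    promoter_downstream: int = 1_000,
    seed: int = 0,
) -> MethylomeTruth:
    """Assign a truth methylation probability to every genomic CpG.

    A random ``active_fraction`` of genes is designated active; CpGs in the
    gene-oriented window ``[TSS - promoter_upstream, TSS +
    promoter_downstream)`` of an active gene get ``m_low``, all others
    ``m_high``, each plus truncated-normal jitter (sd ``jitter_sd``, clipped
    to [0, 1]).  The defaults give the symmetric ±1 kb hypomethylated
    promoter zone.  The active gene set is recorded on the returned object.
    """
    if not m_low < m_high:
        raise ValueError("need m_low < m_high")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    n_active = int(round(active_fraction * len(genes)))
    order = rng.permutation(len(genes))
    active = frozenset(genes[i].gene_id for i in order[:n_active])

    promoters: Dict[str, List[Tuple[int, int]]] = {}
    for gene in genes:
        if gene.gene_id in active:
            if gene.strand == "+":
                zone = (gene.tss - promoter_upstream,
                        gene.tss + promoter_downstream)
            else:  # mirrored: upstream is toward higher coordinates
                zone = (gene.tss - promoter_downstream + 1,
                        gene.tss + promoter_upstream + 1)
            promoters.setdefault(gene.contig, []).append(zone)

    sites: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for contig in sorted(genome):
        pos = cpg_positions(genome[contig])
        base = np.full(pos.size, m_high)
        for lo, hi in promoters.get(contig, []):
            base[(pos >= lo) & (pos < hi)] = m_low
        if jitter_sd > 0:
            base = base + rng.normal(0.0, jitter_sd, size=pos.size)
        sites[contig] = (pos, np.clip(base, 0.0, 1.0))
    return MethylomeTruth(sites, active_genes=active)


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def generate_expression(
    genes: Iterable[Gene],
    active_genes: Iterable[str] = (),
    repressed_fraction: float = 0.6,
    coupling: float = 0.8,
    seed: int = 0,
) -> ExpressionTable:
    """Draw raw read counts per gene with a fixed repressed fraction.

    Exactly ``round(n * repressed_fraction)`` genes receive counts below 10;
    the rest get counts spanning at least two orders of magnitude (evenly
    spread log-uniform draws).  With probability ``coupling`` an active gene
    is forced into the top (high-expression) half of the non-repressed
    counts, so ``coupling=1`` sends every active gene to the high class
    (subject to the 20% class size cap).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no genes supplied")
    if not 0 <= repressed_fraction <= 1:
        raise ValueError("repressed_fraction must be in [0, 1]")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    active = [gid for gid in sorted(set(active_genes)) if gid in set(gene_ids)]

    n = len(genes)
    n_rep = int(round(n * repressed_fraction))
    n_rest = n - n_rep
    n_high = n_rest // 2
    n_low = n_rest - n_high

    forced_high = [gid for gid in active if rng.random() < coupling]
    if len(forced_high) > n_high:
        logger.warning(
            "more coupled active genes (%d) than high-class slots (%d); "
            "truncating", len(forced_high), n_high,
        )
        forced_high = forced_high[:n_high]
    remaining = [gid for gid in gene_ids if gid not in set(forced_high)]
    remaining = list(rng.permutation(remaining))
    high_ids = forced_high + remaining[: n_high - len(forced_high)]
    rest = remaining[n_high - len(forced_high):]
    low_ids = rest[:n_low]
    rep_ids = rest[n_low:]

    counts: Dict[str, int] = {}
    classes: Dict[str, str] = {}
    for gid in rep_ids:
        counts[gid] = int(rng.integers(0, 10))
        classes[gid] = "repressed"

    # non-repressed counts: evenly spread log10 exponents in [1, 3.5] with
    # jitter, made distinct so the downstream median split is unambiguous
    if n_rest:
        exponents = np.linspace(1.0, 3.5, n_rest) if n_rest > 1 else np.array([2.0])
        exponents = exponents + rng.uniform(-0.05, 0.05, size=n_rest)
        raw = np.maximum(10, np.round(10 ** exponents).astype(int))
        raw.sort()
        for i in range(1, raw.size):
            if raw[i] <= raw[i - 1]:
                raw[i] = raw[i - 1] + 1
        low_counts, high_counts = raw[:n_low], raw[n_low:]
        for gid, cnt in zip(rng.permutation(low_ids), low_counts):
            counts[str(gid)] = int(cnt)
            classes[str(gid)] = "low"
        for gid, cnt in zip(rng.permutation(high_ids), high_counts):
            counts[str(gid)] = int(cnt)
            classes[str(gid)] = "high"

    counts = {gid: counts[gid] for gid in gene_ids}
    classes = {gid: classes[gid] for gid in gene_ids}
    return ExpressionTable(counts=counts, classes=classes)
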