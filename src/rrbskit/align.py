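"""Read trimming and a small bisulfite-aware paired-end aligner.

Mapping contract: one exact seed of length ``seed_len`` from the 5' end of
each mate, full-read verification at every seed hit, mismatches counted in
fully converted space (read C->T against genome C->T for top-strand
candidates, read G->A against genome G->A for bottom-strand candidates).  A
pair is accepted only when exactly one candidate fragment placement attains
the minimal total mismatch count, each mate has at most ``max_mismatch``
mismatches, the orientation is FR and the insert lies in
``[insert_min, insert_max]``.  The search is directional only (two
conversion spaces, not four).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple, Union

from ._seq import c_to_t, g_to_a, phred_to_scores, revcomp
from .genome import Genome
from .library import ReadPair

logger = logging.getLogger(__name__)

#: per-read mismatch count beyond which a candidate placement is abandoned
_MM_ABANDON = 5

REJECT_REASONS = (
    "unmapped", "ambiguous", "orientation", "insert_size",
    "too_many_mismatches", "too_short",
)

# the fill-in copies 2 bases of the neighbouring fragment, shifting
# bottom-strand read coordinates by this amount relative to the fragment
FILL_IN_LEN = 2


@dataclass(frozen=True)
class TrimResult:
    """Outcome of BWA-style 3' quality trimming (prefix kept)."""

    seq: str
    qual: str

    @property
    def kept_length(self) -> int:
        return len(self.seq)


def bwa_quality_trim(seq: str, qual: str, threshold: int = 20) -> TrimResult:
    """Trim low-quality 3' tails, BWA style.

    Chooses the cut ``x`` (keeping bases ``[0, x)``) that maximises
    ``S(x) = sum_{i>=x} (threshold - q_i)`` with ``S(L) = 0``, breaking ties
    toward keeping more bases.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    if not qual:
        raise ValueError("empty quality string")
    scores = phred_to_scores(qual)
    best, best_x = 0, len(seq)
    s = 0
    for x in range(len(seq) - 1, -1, -1):
        s += threshold - int(scores[x])
        if s > best:  # strict: ties resolve toward larger x
            best, best_x = s, x
    return TrimResult(seq[:best_x], qual[:best_x])


def trim_read2_fill_in(seq: str, qual: str) -> Optional[Tuple[str, str]]:
    """Remove the two fill-in artifact bases from the start of read_2.

    Returns ``None`` (caller discards the read) when the read is shorter
    than two bases.
    """
    if len(seq) < 2:
        logger.warning("read_2 shorter than 2 bases; discarded")
        return None
    return seq[2:], qual[2:]


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------

class BisulfiteIndex:
    """Exact-match seed lookup over the two converted genome texts."""

    def __init__(self, genome: Genome, seed_len: int = 50):
        if seed_len < 1:
            raise ValueError("seed_len must be positive")
        self.seed_len = seed_len
        self.ct_text: Dict[str, str] = {}
        self.ga_text: Dict[str, str] = {}
        self.contig_lengths: Dict[str, int] = {}
        self._ct_seeds: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        self._ga_seeds: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for contig in sorted(genome):
            seq = genome[contig]
            if len(seq) < seed_len:
                logger.warning("contig %s shorter than seed length; skipped",
                               contig)
                continue
            ct = c_to_t(seq)
            ga = g_to_a(seq)
            self.ct_text[contig] = ct
            self.ga_text[contig] = ga
            self.contig_lengths[contig] = len(seq)
            for i in range(len(seq) - seed_len + 1):
                self._ct_seeds[ct[i:i + seed_len]].append((contig, i))
                self._ga_seeds[ga[i:i + seed_len]].append((contig, i))
        self._ct_seeds = dict(self._ct_seeds)
        self._ga_seeds = dict(self._ga_seeds)

    def lookup(self, kmer: str, space: str) -> List[Tuple[str, int]]:
        seeds = self._ct_seeds if space == "ct" else self._ga_seeds
        return seeds.get(kmer, [])


def build_index(genome: Genome, seed_len: int = 50) -> BisulfiteIndex:
    """Build C->T and G->A converted texts plus their seed lookups."""
    return BisulfiteIndex(genome, seed_len=seed_len)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedAlignment:
    """An accepted unique FR placement of a trimmed pair.

    ``start``/``end`` are the fragment interval (MspI cut offsets) on the
    forward strand; ``strand`` records which original strand was sequenced.
    The trimmed read sequences are kept so methylation calls can be
    extracted downstream without re-reading the FASTQ.
    """

    name: str
    contig: str
    start: int
    end: int
    strand: str
    mm1: int
    mm2: int
    read1_seq: str
    read2_seq: str

    @property
    def insert(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Rejection:
    name: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REJECT_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass(frozen=True)
class TrimmedPair:
    name: str
    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str


def preprocess_pair(name: str, read1_seq: str, read1_qual: str,
                    read2_seq: str, read2_qual: str,
                    quality_threshold: int = 20,
                    min_length: int = 50) -> Union[TrimmedPair, Rejection]:
    """Fill-in trim read_2, quality-trim both mates, enforce the minimum
    post-trim length (= seed length by default)."""
    trimmed2 = trim_read2_fill_in(read2_seq, read2_qual)
    if trimmed2 is None:
        return Rejection(name, "too_short")
    r2s, r2q = trimmed2
    t1 = bwa_quality_trim(read1_seq, read1_qual, quality_threshold)
    if not r2s:
        return Rejection(name, "too_short")
    t2 = bwa_quality_trim(r2s, r2q, quality_threshold)
    if t1.kept_length < min_length or t2.kept_length < min_length:
        return Rejection(name, "too_short")
    return TrimmedPair(name, t1.seq, t1.qual, t2.seq, t2.qual)


def _mismatches(pattern: str, text: str, start: int,
                limit: int) -> Optional[int]:
    if start < 0 or start + len(pattern) > len(text):
        return None
    mm = 0
    for a, b in zip(pattern, text[start:start + len(pattern)]):
        if a != b:
            mm += 1
            if mm > limit:
                return None
    return mm


def _placements(pattern: str, seed_from_end: bool, space: str,
                index: BisulfiteIndex) -> List[Tuple[str, int, int]]:
    """Verified (contig, forward_start, mismatches) placements of *pattern*."""
    k = index.seed_len
    seed = pattern[-k:] if seed_from_end else pattern[:k]
    texts = index.ct_text if space == "ct" else index.ga_text
    out = []
    for contig, pos in index.lookup(seed, space):
        start = pos - (len(pattern) - k) if seed_from_end else pos
        mm = _mismatches(pattern, texts[contig], start, _MM_ABANDON)
        if mm is not None:
            out.append((contig, start, mm))
    return out


def align_pair(pair: TrimmedPair, index: BisulfiteIndex,
               max_mismatch: int = 1, insert_min: int = 150,
               insert_max: int = 250) -> Union[PairedAlignment, Rejection]:
    """Place a trimmed pair; accept only unique best FR placements."""
    k = index.seed_len
    L1, L2 = len(pair.read1_seq), len(pair.read2_seq)
    if L1 < k or L2 < k:
        return Rejection(pair.name, "too_short")

    # top-strand search: both mates in C->T space, forward orientation
    a_top = _placements(c_to_t(pair.read1_seq), False, "ct", index)
    b_top = _placements(c_to_t(revcomp(pair.read2_seq)), True, "ct", index)
    # bottom-strand search: both mates in G->A space
    a_bot = _placements(g_to_a(revcomp(pair.read1_seq)), True, "ga", index)
    b_bot = _placements(g_to_a(pair.read2_seq), False, "ga", index)

    # candidate fragment placements: (total_mm, strand, contig, s, e, mm1, mm2,
    # left_ok) where s/e are cut offsets
    candidates = []
    for c1, p, mm1 in a_top:
        for c2, q, mm2 in b_top:
            if c1 == c2:
                candidates.append(
                    (mm1 + mm2, "+", c1, p, q + L2, mm1, mm2, p <= q))
    for c1, h, mm1 in a_bot:
        for c2, g, mm2 in b_bot:
            if c1 == c2:
                s = g - FILL_IN_LEN
                e = h + L1 - FILL_IN_LEN
                candidates.append((mm1 + mm2, "-", c1, s, e, mm1, mm2, g <= h))
    if not candidates:
        return Rejection(pair.name, "unmapped")

    best_score = min(c[0] for c in candidates)
    best = [c for c in candidates if c[0] == best_score]
    if len(best) > 1:
        return Rejection(pair.name, "ambiguous")
    _, strand, contig, s, e, mm1, mm2, left_ok = best[0]
    if mm1 > max_mismatch or mm2 > max_mismatch:
        return Rejection(pair.name, "too_many_mismatches")
    if not left_ok or e <= s:
        return Rejection(pair.name, "orientation")
    if not insert_min <= e - s <= insert_max:
        return Rejection(pair.name, "insert_size")
    return PairedAlignment(pair.name, contig, s, e, strand, mm1, mm2,
                           pair.read1_seq, pair.read2_seq)


def align_library(
    index: BisulfiteIndex,
    pairs: Iterable[ReadPair],
    max_mismatch: int = 1,
    insert_min: int = 150,
    insert_max: int = 250,
    quality_threshold: int = 20,
) -> Tuple[List[PairedAlignment], List[Rejection]]:
    """Trim and align a stream of raw read pairs."""
    accepted: List[PairedAlignment] = []
    rejected: List[Rejection] = []
    for rp in pairs:
        pre = preprocess_pair(rp.name, rp.read1_seq, rp.read1_qual,
                              rp.read2_seq, rp.read2_qual,
                              quality_threshold=quality_threshold,
                              min_length=index.seed_len)
        if isinstance(pre, Rejection):
            rejected.append(pre)
            continue
        result = align_pair(pre, index, max_mismatch=max_mismatch,
                            insert_min=insert_min, insert_max=insert_max)
        if isinstance(result, PairedAlignment):
            accepted.append(result)
        else:
            rejected.append(result)
    return accepted, rejected
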