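"""In-silico MspI reduced representation and directional bisulfite reads.

The simulated chemistry follows the directional protocol: MspI cuts C^CGG
leaving 5'-CG overhangs, the recessed 3' ends are filled in with unmethylated
C/G, and bisulfite converts unprotected cytosines on each original strand.
read_1 always sequences the converted original strand 5'->3'; read_2 its
complement starting from the fill-in end, so read_2 carries two artifact
bases (complement of the filled G, then the complement of the converted,
always-unmethylated filled C) that downstream trimming must remove.

Because the fill-in copies the first two bases of the neighbouring fragment,
a molecule cut at ``[s, e)`` is modelled as the duplex over ``genome[s:e+2]``
with the CpG at ``e`` unmethylated on the top strand and the CpG at ``s``
unmethylated on the bottom strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional

import numpy as np

from ._seq import check_sequence, scores_to_phred
from .genome import Genome, MethylomeTruth

logger = logging.getLogger(__name__)

_CUT_RE = re.compile(r"(?=CCGG)")


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment; boundaries fall at MspI cut offsets except at
    contig ends.  0-based half-open."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LibraryParams:
    """Knobs of the read-pair simulator.

    ``meth_protection`` is the probability that a methylated C escapes
    conversion; ``conversion_efficiency`` the probability that an
    unmethylated C is converted.  ``depth_dispersion`` adds gamma-distributed
    per-fragment depth weights (0 = pure Poisson molecule counts), emulating
    amplification bias so that coverage varies across fragments.
    """

    insert_min: int = 150
    insert_max: int = 250
    read_len: int = 100
    conversion_efficiency: float = 0.995
    meth_protection: float = 1.0
    seq_error: float = 0.001
    mean_depth: float = 30.0
    depth_dispersion: float = 0.0
    q_high: int = 38
    low_qual_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_efficiency", "meth_protection", "seq_error",
                     "low_qual_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")
        if self.read_len > self.insert_min:
            raise ValueError("read_len must be <= insert_min")
        if self.mean_depth < 0 or self.depth_dispersion < 0:
            raise ValueError("mean_depth and depth_dispersion must be >= 0")


@dataclass(frozen=True)
class ReadPair:
    """A simulated pair plus its truth tag.

    ``read2_seq`` is ``read_len + 2`` long when the fragment carries a
    fill-in artifact.  ``strand`` is ``+`` when read_1 sequenced the
    converted top (forward) strand, ``-`` for the bottom strand.
    """

    name: str
    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str
    contig: str
    frag_start: int
    frag_end: int
    strand: str


def digest_mspi(sequence: str, contig: str = "contig") -> List[Fragment]:
    """Cut *sequence* at every C^CGG offset.

    Returns fragments tiling the contig exactly: intervals between
    successive cut offsets plus the two contig-end pieces.
    """
    check_sequence(sequence)
    cuts = [m.start() + 1 for m in _CUT_RE.finditer(sequence)]
    bounds = [0] + cuts + [len(sequence)]
    return [
        Fragment(contig, a, b)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]


def size_select(fragments: Iterable[Fragment], insert_min: int = 150,
                insert_max: int = 250) -> List[Fragment]:
    """Keep exactly the fragments with insert_min <= length <= insert_max."""
    return [f for f in fragments if insert_min <= f.length <= insert_max]


# ---------------------------------------------------------------------------
# read-pair simulation
# ---------------------------------------------------------------------------

_A, _C, _G, _T = ord("A"), ord("C"), ord("G"), ord("T")


def _convert_top(mol: np.ndarray, abs_start: int, cpg_pos: np.ndarray,
                 states: np.ndarray, unmeth_override: int,
                 params: LibraryParams, rng: np.random.Generator) -> np.ndarray:
    """Bisulfite image of the top strand of a molecule (forward orientation).

    ``cpg_pos``/``states`` give absolute CpG positions in the molecule and
    their per-molecule methylation states; ``unmeth_override`` marks the
    filled-in CpG C that is unmethylated regardless of truth.
    """
    out = mol.copy()
    c_idx = np.flatnonzero(out == _C)
    if not c_idx.size:
        return out
    abs_pos = c_idx + abs_start
    meth = np.zeros(c_idx.size, dtype=bool)
    if cpg_pos.size:
        hit = np.searchsorted(cpg_pos, abs_pos)
        ok = (hit < cpg_pos.size) & (cpg_pos[np.minimum(hit, cpg_pos.size - 1)] == abs_pos)
        meth[ok] = states[hit[ok]]
    meth[abs_pos == unmeth_override] = False
    u = rng.random(c_idx.size)
    convert = np.where(meth, u < 1.0 - params.meth_protection,
                       u < params.conversion_efficiency)
    out[c_idx[convert]] = _T
    return out


def _convert_bottom_fwd(mol: np.ndarray, abs_start: int, cpg_pos: np.ndarray,
                        states: np.ndarray, unmeth_override: int,
                        params: LibraryParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Bisulfite image of the bottom strand, kept in forward orientation.

    Bottom-strand cytosines sit opposite forward Gs; conversion shows up as
    G->A in the forward view.  A bottom C belongs to the CpG whose forward C
    is one base to its left.
    """
    out = mol.copy()
    g_idx = np.flatnonzero(out == _G)
    if not g_idx.size:
        return out
    site_pos = g_idx + abs_start - 1  # forward C position of the candidate CpG
    meth = np.zeros(g_idx.size, dtype=bool)
    if cpg_pos.size:
        hit = np.searchsorted(cpg_pos, site_pos)
        ok = (hit < cpg_pos.size) & (cpg_pos[np.minimum(hit, cpg_pos.size - 1)] == site_pos)
        meth[ok] = states[hit[ok]]
    meth[site_pos == unmeth_override] = False
    u = rng.random(g_idx.size)
    convert = np.where(meth, u < 1.0 - params.meth_protection,
                       u < params.conversion_efficiency)
    out[g_idx[convert]] = _A
    return out


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    comp = out.copy()
    comp[out == _A] = _T
    comp[out == _T] = _A
    comp[out == _C] = _G
    comp[out == _G] = _C
    return comp


def _apply_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        arr = arr.copy()
        alphabet = np.array([_A, _C, _G, _T], dtype=arr.dtype)
        for i in hit.tolist():
            choices = alphabet[alphabet != arr[i]]
            arr[i] = rng.choice(choices)
    return arr


def _qualities(n: int, params: LibraryParams, rng: np.random.Generator) -> str:
    q = np.full(n, params.q_high, dtype=np.int64)
    low = np.flatnonzero(rng.random(n) < params.low_qual_prob)
    if low.size:
        q[low] = rng.integers(2, 20, size=low.size)
    return scores_to_phred(q)


def simulate_read_pairs(
    genome: Genome,
    fragments: Iterable[Fragment],
    truth: MethylomeTruth,
    params: LibraryParams,
) -> Iterator[ReadPair]:
    """Simulate directional bisulfite read pairs from retained fragments.

    Per fragment, ``Poisson(mean_depth)`` molecules (optionally gamma-weighted
    per fragment) are drawn; each molecule picks the top or bottom original
    strand with probability 1/2, draws a shared Bernoulli methylation state
    per CpG from the truth, converts, and is read from both ends.  Fragments
    not flanked by MspI cuts on both sides (contig-end pieces) are skipped:
    they lack the overhangs required for adapter ligation.
    """
    fragments = list(fragments)
    if not fragments:
        logger.warning("empty fragment list: no reads simulated")
        return
    rng = np.random.default_rng(params.seed)
    serial = 0
    for frag in fragments:
        seq = genome[frag.contig]
        s, e = frag.start, frag.end
        if seq[s:s + 3] != "CGG" or seq[e - 1:e + 3] != "CCGG":
            logger.debug("skipping fragment %s:%d-%d without MspI ends",
                         frag.contig, s, e)
            continue
        weight = 1.0
        if params.depth_dispersion > 0:
            shape = 1.0 / params.depth_dispersion
            weight = rng.gamma(shape, 1.0 / shape)
        n_mol = int(rng.poisson(params.mean_depth * weight))
        if n_mol == 0:
            continue
        mol = np.frombuffer(seq[s:e + 2].encode("ascii"), dtype=np.uint8)
        cpg_pos, cpg_m = truth.in_interval(frag.contig, s, e + 2)
        L2 = params.read_len + 2
        for _ in range(n_mol):
            states = rng.random(cpg_pos.size) < cpg_m
            top = rng.random() < 0.5
            if top:
                conv = _convert_top(mol, s, cpg_pos, states, e, params, rng)
                r1 = conv[:params.read_len]
                r2 = _revcomp_codes(conv)[:L2]
                strand = "+"
            else:
                conv_fwd = _convert_bottom_fwd(mol, s, cpg_pos, states, s,
                                               params, rng)
                conv = _revcomp_codes(conv_fwd)  # bottom strand 5'->3'
                r1 = conv[:params.read_len]
                r2 = conv_fwd[:L2]
                strand = "-"
            r1 = _apply_errors(r1, params.seq_error, rng)
            r2 = _apply_errors(r2, params.seq_error, rng)
            yield ReadPair(
                name=f"rp{serial:07d}",
                read1_seq=r1.tobytes().decode("ascii"),
                read1_qual=_qualities(r1.size, params, rng),
                read2_seq=r2.tobytes().decode("ascii"),
                read2_qual=_qualities(r2.size, params, rng),
                contig=frag.contig,
                frag_start=s,
                frag_end=e,
                strand=strand,
            )
            serial += 1


def simulate_library(
    genome: Genome,
    truth: MethylomeTruth,
    params: LibraryParams,
) -> List[ReadPair]:
    """Digest every contig, size-select, and simulate reads in one call."""
    fragments: List[Fragment] = []
    for contig in sorted(genome):
        fragments.extend(digest_mspi(genome[contig], contig))
    retained = size_select(fragments, params.insert_min, params.insert_max)
    return list(simulate_read_pairs(genome, retained, truth, params))
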