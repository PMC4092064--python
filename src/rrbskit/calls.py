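"""Per-CpG methylation counts, conversion QC and replicate concordance.

Evidence rules (three-letter logic): over a genomic CpG, a top-strand read
base C is methylated evidence and T unmethylated; a bottom-strand read
(projected onto forward coordinates) gives G methylated / A unmethylated at
the G of the same CpG.  Both strands pool into one row keyed by the
forward-strand C.  Where mates of a pair overlap, each position is counted
once with read_1 preferred.  Bases over non-CpG cytosines feed the
bisulfite-conversion QC by the same rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .align import FILL_IN_LEN, PairedAlignment
from ._seq import revcomp
from .genome import Genome

logger = logging.getLogger(__name__)

Site = Tuple[str, int]


class CpGCallTable:
    """Methylated/unmethylated observation counts per CpG site."""

    def __init__(self, data: Optional[Dict[Site, List[int]]] = None):
        self.data: Dict[Site, List[int]] = data if data is not None else {}

    def add(self, contig: str, pos: int, methylated: bool) -> None:
        row = self.data.setdefault((contig, pos), [0, 0])
        row[0 if methylated else 1] += 1

    def coverage(self, site: Site) -> int:
        row = self.data.get(site)
        return 0 if row is None else row[0] + row[1]

    def percent(self, site: Site) -> float:
        meth, unmeth = self.data[site]
        total = meth + unmeth
        if total == 0:
            raise ValueError(f"site {site} has no observations")
        return 100.0 * meth / total

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, site: Site) -> bool:
        return site in self.data

    def sites(self) -> List[Site]:
        return sorted(self.data)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (contig, pos, m, u, 100.0 * m / (m + u))
            for (contig, pos), (m, u) in sorted(self.data.items())
        ]
        return pd.DataFrame(
            rows, columns=["contig", "pos", "meth", "unmeth", "percent"]
        )

    def by_contig(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Sorted positions and percents per contig (for interval queries)."""
        out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        per: Dict[str, List[Tuple[int, float]]] = {}
        for (contig, pos), (m, u) in self.data.items():
            per.setdefault(contig, []).append((pos, 100.0 * m / (m + u)))
        for contig, rows in per.items():
            rows.sort()
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            pct = np.array([r[1] for r in rows], dtype=np.float64)
            out[contig] = (pos, pct)
        return out


@dataclass
class ConversionQC:
    """Bisulfite conversion control from cytosines in non-CpG context."""

    total: int = 0
    unconverted: int = 0

    @property
    def non_cpg_methylation_percent(self) -> float:
        if self.total == 0:
            return float("nan")
        return 100.0 * self.unconverted / self.total


def extract_calls(
    alignments: Iterable[PairedAlignment],
    genome: Genome,
) -> Tuple[CpGCallTable, ConversionQC]:
    """Accumulate per-CpG counts and conversion QC from accepted alignments.

    Fill-in bases must already be trimmed (they are, by ``preprocess_pair``).
    An alignment extending past its contig raises: that indicates corrupt
    input rather than a rejectable read.
    """
    table = CpGCallTable()
    qc = ConversionQC()
    for aln in alignments:
        seq = genome[aln.contig]
        L = len(seq)
        L1, L2 = len(aln.read1_seq), len(aln.read2_seq)
        if aln.strand == "+":
            mates = [
                (aln.read1_seq, aln.start),
                (revcomp(aln.read2_seq), aln.end - L2),
            ]
        else:
            mates = [
                (revcomp(aln.read1_seq), aln.end + FILL_IN_LEN - L1),
                (aln.read2_seq, aln.start + FILL_IN_LEN),
            ]
        seen: set = set()
        for text, start in mates:
            if start < 0 or start + len(text) > L:
                raise ValueError(
                    f"alignment {aln.name} extends beyond contig {aln.contig}"
                )
            for i, base in enumerate(text):
                p = start + i
                if p in seen:
                    continue
                if aln.strand == "+":
                    if seq[p] != "C":
                        continue
                    seen.add(p)
                    is_cpg = p + 1 < L and seq[p + 1] == "G"
                    if base == "C":
                        if is_cpg:
                            table.add(aln.contig, p, True)
                        else:
                            qc.total += 1
                            qc.unconverted += 1
                    elif base == "T":
                        if is_cpg:
                            table.add(aln.contig, p, False)
                        else:
                            qc.total += 1
                else:
                    if seq[p] != "G":
                        continue
                    seen.add(p)
                    is_cpg = p > 0 and seq[p - 1] == "C"
                    if base == "G":
                        if is_cpg:
                            table.add(aln.contig, p - 1, True)
                        else:
                            qc.total += 1
                            qc.unconverted += 1
                    elif base == "A":
                        if is_cpg:
                            table.add(aln.contig, p - 1, False)
                        else:
                            qc.total += 1
    return table, qc


def filter_by_coverage(table: CpGCallTable, min_cov: int = 10) -> CpGCallTable:
    """Keep sites with at least ``min_cov`` observations (inclusive)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    kept = {
        site: list(row)
        for site, row in table.data.items()
        if row[0] + row[1] >= min_cov
    }
    return CpGCallTable(kept)


@dataclass(frozen=True)
class CorrelationResult:
    r: Optional[float]
    n_sites: int
    flag: Optional[str] = None


def replicate_correlation(
    table_a: CpGCallTable,
    table_b: CpGCallTable,
    min_cov: int = 10,
) -> CorrelationResult:
    """Pearson r of percent methylation over sites passing ``min_cov`` in
    both tables.

    Raises ``ValueError("insufficient_sites")`` with fewer than 3 shared
    sites; returns a flagged result (r=None) when either vector has zero
    variance.
    """
    fa = filter_by_coverage(table_a, min_cov)
    fb = filter_by_coverage(table_b, min_cov)
    shared = sorted(set(fa.data) & set(fb.data))
    if len(shared) < 3:
        raise ValueError("insufficient_sites")
    x = np.array([fa.percent(s) for s in shared])
    y = np.array([fb.percent(s) for s in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(None, len(shared), flag="zero_variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r, len(shared))


def call_summary(table: CpGCallTable, qc: ConversionQC) -> Dict[str, object]:
    """QC dictionary written as JSON by the CLI."""
    covs = [row[0] + row[1] for row in table.data.values()]
    return {
        "non_cpg_methylation_percent": (
            None if qc.total == 0 else round(qc.non_cpg_methylation_percent, 4)
        ),
        "non_cpg_observations": qc.total,
        "n_sites": len(table),
        "n_sites_cov_ge_10": sum(1 for c in covs if c >= 10),
        "n_sites_cov_ge_100": sum(1 for c in covs if c >= 100),
    }
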