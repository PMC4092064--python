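"""Expression grouping, stratified TSS profiles, paired t-tests and
cross-method concordance.

"Pairs" in every test are animals (n = 3 in the original design; any
n >= 2 is accepted).  Significance uses alpha = 0.05 with no
multiple-testing correction by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .calls import CpGCallTable
from .genome import ExpressionTable, Gene
from .profiles import MetaProfile, tss_meta_profile

logger = logging.getLogger(__name__)

EXPRESSION_CLASSES = ("repressed", "low", "high")
REPRESSED_THRESHOLD = 10  # raw read count below which a gene is repressed


def group_by_expression(
    counts: Union[ExpressionTable, Mapping[str, int]],
) -> Dict[str, str]:
    """Classify genes as repressed / low / high from raw read counts.

    Genes with fewer than 10 reads are repressed; the remainder is ranked by
    count and split at the median, lower half low and upper half high (the
    extra gene of an odd remainder goes to low).  Ties at the median break
    by gene id, so the grouping is invariant to input row order.
    """
    if isinstance(counts, ExpressionTable):
        counts = counts.counts
    if not counts:
        raise ValueError("empty expression table")
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative read count")
    groups: Dict[str, str] = {}
    rest = []
    for gid in sorted(counts):
        if counts[gid] < REPRESSED_THRESHOLD:
            groups[gid] = "repressed"
        else:
            rest.append(gid)
    if not rest:
        logger.warning("all genes repressed; low/high classes empty")
    rest.sort(key=lambda gid: (counts[gid], gid))
    n_low = (len(rest) + 1) // 2
    for i, gid in enumerate(rest):
        groups[gid] = "low" if i < n_low else "high"
    return groups


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test summary.

    ``sed`` is the standard error of the mean difference, ``sd(d)/sqrt(n)``.
    A degenerate test (zero variance of the differences) reports p = 1 when
    the mean difference is 0 and p = 0 otherwise, flagged via ``degenerate``.
    """

    n: int
    mean_diff: float
    sed: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t_test(differences: Sequence[float]) -> PairedTestResult:
    """Paired t-test on per-pair differences (pairs = animals)."""
    d = np.asarray(list(differences), dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("insufficient_pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        return PairedTestResult(n, mean, 0.0, t, df, p, degenerate=True)
    sed = sd / math.sqrt(n)
    t = mean / sed
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTestResult(n, mean, sed, t, df, min(p, 1.0))


def stratified_tss_profiles(
    calls_by_animal: Mapping[str, CpGCallTable],
    genes: Iterable[Gene],
    groups: Mapping[str, str],
    cpg_classes: Mapping[str, str],
    contig_lengths: Mapping[str, int],
    flank: int = 6_000,
    window: int = 1_000,
    step: int = 50,
) -> Dict[Tuple[str, str, str], Optional[MetaProfile]]:
    """TSS meta-profile per (expression class, CpG class, animal) stratum.

    Empty strata are flagged with ``None`` rather than raising.
    """
    genes = list(genes)
    out: Dict[Tuple[str, str, str], Optional[MetaProfile]] = {}
    cpg_labels = sorted(set(cpg_classes.values()))
    for expr_cls in EXPRESSION_CLASSES:
        for cpg_cls in cpg_labels:
            subset = [
                g for g in genes
                if groups.get(g.gene_id) == expr_cls
                and cpg_classes.get(g.gene_id) == cpg_cls
            ]
            for animal, calls in calls_by_animal.items():
                key = (expr_cls, cpg_cls, animal)
                if not subset:
                    logger.warning("empty stratum %s", key)
                    out[key] = None
                    continue
                out[key] = tss_meta_profile(
                    calls, subset, contig_lengths,
                    flank=flank, window=window, step=step,
                )
    return out


def window_difference_test(
    profiles_a: Sequence[MetaProfile],
    profiles_b: Sequence[MetaProfile],
) -> pd.DataFrame:
    """Per-window paired t-test between two strata across animals.

    ``profiles_a[i]`` and ``profiles_b[i]`` must come from the same animal.
    Windows where any animal lacks data in either stratum get NaN results.
    """
    if len(profiles_a) != len(profiles_b) or len(profiles_a) < 2:
        raise ValueError("need matched profiles for at least 2 animals")
    offsets = profiles_a[0].offsets
    rows = []
    for w in range(offsets.size):
        d = [
            pa.mean[w] - pb.mean[w]
            for pa, pb in zip(profiles_a, profiles_b)
        ]
        if any(math.isnan(x) for x in d):
            rows.append((int(offsets[w]), math.nan, math.nan, math.nan,
                         math.nan))
            continue
        res = paired_t_test(d)
        rows.append((int(offsets[w]), res.mean_diff, res.sed, res.t, res.p))
    return pd.DataFrame(rows, columns=["offset", "mean_diff", "sed", "t", "p"])


@dataclass
class ConcordanceResult:
    """Cross-method per-site comparison summary."""

    per_site: pd.DataFrame
    n_sites: int
    n_indistinguishable: int
    excluded: List[str]

    @property
    def summary(self) -> str:
        return f"{self.n_indistinguishable}/{self.n_sites}"


def method_concordance(
    method_a: pd.DataFrame,
    method_b: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> ConcordanceResult:
    """Per-site paired t-tests (pairs = animals) between two methods.

    Inputs are site-by-animal percent tables (index = site id, columns =
    animals).  A site is "indistinguishable" when its two-sided p value is
    at least alpha; no multiple-testing correction is applied unless
    ``bonferroni`` is set.  Sites present in only one table are excluded and
    logged.
    """
    animals = sorted(set(method_a.columns) & set(method_b.columns))
    if len(animals) < 2:
        raise ValueError("need at least 2 shared animals")
    shared = sorted(set(method_a.index) & set(method_b.index))
    excluded = sorted(
        set(method_a.index).symmetric_difference(set(method_b.index))
    )
    if excluded:
        logger.warning("%d sites present in only one method excluded",
                       len(excluded))
    threshold = alpha / len(shared) if (bonferroni and shared) else alpha
    rows = []
    for site in shared:
        d = (method_a.loc[site, animals] - method_b.loc[site, animals]).to_numpy(dtype=float)
        res = paired_t_test(d)
        rows.append((site, res.n, res.mean_diff, res.sed, res.t, res.p,
                     res.p >= threshold, res.degenerate))
    per_site = pd.DataFrame(
        rows,
        columns=["site", "n", "mean_diff", "sed", "t", "p",
                 "indistinguishable", "degenerate"],
    )
    n_ok = int(per_site["indistinguishable"].sum())
    return ConcordanceResult(per_site, len(shared), n_ok, excluded)
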