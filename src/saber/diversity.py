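"""Clone enumeration and diversity statistics on informative barcodes.

An HSC clone is an informative barcode with VAF above a flat cutoff
(default 0.02, VAF taken against all aligned reads of the sample).  The
weighted alternatives are Shannon entropy H' = -sum p_i ln p_i (effective
clone number exp(H')) and the inverse Simpson index 2D = 1 / sum p_i^2,
both computed by default over all informative barcodes of the sample with
proportions renormalised over that set.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .sharing import ReducedSampleTable, informative_fraction


def count_clones(table: ReducedSampleTable, vaf_cutoff: float = 0.02) -> int:
    """Number of informative variants with VAF strictly above the cutoff."""
    if table.aligned == 0:
        return 0
    vaf = table.informative / table.aligned
    return int((vaf > vaf_cutoff).sum())


def _proportions(proportions: Sequence[float]) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if (p <= 0).any():
        raise ValueError("proportions must be positive")
    return p / p.sum()


def shannon_entropy(proportions: Sequence[float]) -> float:
    """Natural-log Shannon entropy over renormalised proportions."""
    p = _proportions(proportions)
    return float(-(p * np.log(p)).sum())


def inverse_simpson(proportions: Sequence[float]) -> float:
    """Inverse Simpson diversity 1 / sum p_i^2."""
    p = _proportions(proportions)
    return float(1.0 / (p * p).sum())


@dataclass
class CloneSet:
    """Informative barcodes of one sample with VAFs and diversity summaries."""

    sample_id: str
    clones: List[Tuple[str, float]]  # (variant name, VAF vs aligned reads)
    B_cutoff: int
    shannon_H: float
    inv_simpson: float

    @property
    def effective_number(self) -> float:
        return float(np.exp(self.shannon_H))


def build_clone_set(table: ReducedSampleTable, vaf_cutoff: float = 0.02,
                    diversity_scope: str = "informative") -> CloneSet:
    """Summarise one sample: clones above the cutoff plus diversity indices.

    ``diversity_scope`` selects the proportion vector for H' and 2D:
    "informative" (default) renormalises over all informative barcodes;
    "clones" uses only the barcodes above the cutoff.
    """
    if table.informative.empty or table.informative.sum() == 0:
        raise ValueError(f"sample {table.sample_id}: no informative reads")
    vaf = table.informative / table.aligned
    kept = vaf[vaf > vaf_cutoff].sort_values(ascending=False, kind="stable")
    if diversity_scope == "informative":
        pool = table.informative[table.informative > 0]
    elif diversity_scope == "clones":
        pool = table.informative[vaf > vaf_cutoff]
    else:
        raise ValueError(f"unknown diversity scope: {diversity_scope!r}")
    if pool.empty:
        h, d2 = float("nan"), float("nan")
    else:
        h = shannon_entropy(pool.values)
        d2 = inverse_simpson(pool.values)
    return CloneSet(
        sample_id=table.sample_id,
        clones=list(kept.items()),
        B_cutoff=int(len(kept)),
        shannon_H=h,
        inv_simpson=d2,
    )


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    t_stat: float
    t_p: float


def group_compare(group_a: Sequence[float], group_b: Sequence[float],
                  equal_var: bool = True) -> GroupComparison:
    """Normality check (Shapiro-Wilk per group) followed by a two-tailed
    two-sample Student's t-test (pooled variance; Welch via flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups: t-test undefined")

    def shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            _warnings.warn("Shapiro-Wilk undefined on a constant group",
                           stacklevel=2)
            return float("nan")
        return float(stats.shapiro(x).pvalue)

    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        shapiro_p_a=shapiro_p(a), shapiro_p_b=shapiro_p(b),
        t_stat=float(t.statistic), t_p=float(t.pvalue),
    )
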