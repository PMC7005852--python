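"""Cross-sample variant sharing: the sharing coefficient, the Sharing
Factor, common-variant flagging at a VAF threshold theta_V, the theta_V
sweep with Z-score-product selection, and QC warnings.

A variant seen at high frequency in more than one animal cannot be
clade-specific -- it is a stereotypical DNA-repair outcome.  The pipeline
therefore flags every variant whose proportional abundance exceeds theta_V
in at least two samples as a "common variant", collapses its reads into a
single ``common variant sum`` row per sample, and treats only the remaining
per-sample-unique variants as informative barcodes.

For a sample pair with per-variant read counts v1, v2 the sharing
coefficient is ``s = 2*min(v1, v2) / (v1 + v2)``; pooling over the m
variants of the pair gives the Sharing Factor
``S = 2 * sum_i min(b_i1, b_i2) / sum_i (b_i1 + b_i2)``, the proportion of
the pair's reads attributable to shared variants.  theta_V is chosen by
standardising mean Phi (fraction of informative reads) and 1 - mean S
across the sweep and maximising their element-wise product.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import UNEDITED, SampleVariantTable

COMMON_SUM = "common variant sum"

#: theta_V sweep grid used throughout
DEFAULT_THETA_SWEEP = (0.0003, 0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0)

#: post-selection QC thresholds: warn when mean Sharing Factor exceeds
#: S_WARN or mean Phi falls below PHI_WARN
S_WARN = 0.01
PHI_WARN = 0.6


@dataclass
class VariantMatrix:
    """Read-count matrix C (variants x samples) with proportions P."""

    C: pd.DataFrame  # rows: variant names, columns: sample ids
    orientation: str = "variants_by_samples"

    def __post_init__(self):
        if (self.C.values < 0).any():
            raise ValueError("negative read count")

    @classmethod
    def from_tables(cls, tables: Sequence[SampleVariantTable]) -> "VariantMatrix":
        cols = {t.sample_id: t.counts for t in tables}
        C = pd.DataFrame(cols).fillna(0).astype(np.int64)
        return cls(C)

    @property
    def P(self) -> pd.DataFrame:
        return self.C / self.C.sum(axis=0)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.C.columns)

    @property
    def variant_names(self) -> List[str]:
        return list(self.C.index)

    def sample_table(self, sample_id: str) -> SampleVariantTable:
        col = self.C[sample_id]
        return SampleVariantTable(sample_id, col[col > 0])


@dataclass(frozen=True)
class CommonVariantSet:
    theta_v: float
    names: FrozenSet[str]

    def __contains__(self, name: str) -> bool:
        return name in self.names


@dataclass
class ReducedSampleTable:
    """Per-sample reduced count table C'_i: unedited reads, the aggregated
    common-variant sum, and each remaining (informative) variant."""

    sample_id: str
    unedited: int
    common_sum: int
    informative: pd.Series  # variant name -> count

    def __post_init__(self):
        self.informative = self.informative.astype(np.int64)
        if (self.informative < 0).any() or self.unedited < 0 or self.common_sum < 0:
            raise ValueError("negative read count")

    @property
    def aligned(self) -> int:
        return int(self.unedited + self.common_sum + self.informative.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [(UNEDITED, self.unedited), (COMMON_SUM, self.common_sum)]
        rows += list(self.informative.items())
        return pd.DataFrame(rows, columns=["row", "read_count"])


def sharing_coefficient(v1: float, v2: float) -> float:
    """Per-variant sharing for a sample pair: 2*min(v1,v2)/(v1+v2)."""
    if v1 < 0 or v2 < 0:
        raise ValueError("negative read count")
    if v1 + v2 == 0:
        raise ValueError("variant absent from both samples")
    return 2.0 * min(v1, v2) / (v1 + v2)


def flag_common_variants(matrix: VariantMatrix, theta_v: float) -> CommonVariantSet:
    """Names whose proportion strictly exceeds theta_v in >= 2 samples.

    The unedited allele is handled separately by the reduction and is never
    listed here.
    """
    if not (0 < theta_v <= 1):
        raise ValueError("theta_v must be in (0, 1]")
    P = matrix.P
    hits = (P > theta_v).sum(axis=1)
    names = frozenset(n for n in P.index[hits >= 2] if n != UNEDITED)
    return CommonVariantSet(theta_v, names)


def reduce_sample(table: SampleVariantTable,
                  common: CommonVariantSet) -> ReducedSampleTable:
    """Build C'_i: mark common variants, sum their reads into one row and
    drop the individual rows; reads are conserved exactly."""
    counts = table.counts
    unedited = int(counts.get(UNEDITED, 0))
    is_common = counts.index.isin(common.names)
    common_sum = int(counts[is_common].sum())
    informative = counts[~is_common & (counts.index != UNEDITED)]
    return ReducedSampleTable(table.sample_id, unedited, common_sum, informative)


def _row_vector(table: ReducedSampleTable, universe: str) -> pd.Series:
    if universe == "informative":
        return table.informative
    if universe == "all":
        extra = pd.Series({UNEDITED: table.unedited, COMMON_SUM: table.common_sum})
        return pd.concat([extra, table.informative])
    raise ValueError(f"unknown row universe: {universe!r}")


def sharing_factor(t1: ReducedSampleTable, t2: ReducedSampleTable,
                   universe: str = "informative") -> float:
    """Sharing Factor S for a sample pair over the union of its variants.

    ``universe`` selects the row set: "informative" uses only informative
    barcodes (post-selection convention); "all" additionally includes the
    unedited and common-variant-sum rows.
    """
    a = _row_vector(t1, universe)
    b = _row_vector(t2, universe)
    a, b = a.align(b, fill_value=0)
    denom = float((a + b).sum())
    if denom == 0:
        if universe == "informative":
            return 0.0  # no informative reads in either sample: nothing shared
        raise ValueError("both tables empty")
    return 2.0 * float(np.minimum(a, b).sum()) / denom


def informative_fraction(table: ReducedSampleTable) -> float:
    """Phi = (aligned - unedited - common variant sum) / aligned."""
    if table.aligned == 0:
        raise ValueError("no aligned reads")
    return float(table.informative.sum()) / table.aligned


def mean_pairwise_sharing(tables: Sequence[ReducedSampleTable],
                          universe: str = "informative") -> float:
    """Mean S over all unordered distinct pairs (self-pairs excluded)."""
    n = len(tables)
    if n < 2:
        raise ValueError("need at least two samples")
    vals = [sharing_factor(tables[i], tables[j], universe)
            for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(vals))


def pairwise_sharing_matrix(tables: Sequence[ReducedSampleTable],
                            universe: str = "informative") -> pd.DataFrame:
    ids = [t.sample_id for t in tables]
    M = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s = sharing_factor(tables[i], tables[j], universe)
            M.iloc[i, j] = M.iloc[j, i] = s
    return M


@dataclass
class SharingSweepResult:
    theta_values: List[float]
    mean_S: List[float]
    mean_phi: List[float]
    z_phi: List[float]
    z_one_minus_S: List[float]
    z_product: List[float]
    selected_theta: float
    warnings: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "theta_v": self.theta_values,
            "mean_S": self.mean_S,
            "mean_phi": self.mean_phi,
            "z_phi": self.z_phi,
            "z_one_minus_S": self.z_one_minus_S,
            "z_product": self.z_product,
        })


def _zscores(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return x.astype(float), True  # raw fallback, flagged by caller
    return (x - x.mean()) / sd, False


def sweep_theta(matrix: VariantMatrix,
                theta_values: Sequence[float] = DEFAULT_THETA_SWEEP,
                universe: str = "informative") -> SharingSweepResult:
    """Iterate the common-variant reduction over the theta_V grid and pick
    the threshold maximising z(mean Phi) * z(1 - mean S).

    Among exactly tied products the largest theta wins: the least stringent
    threshold achieving the optimum discards the least data.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least two samples")
    theta_values = sorted(theta_values)
    if len(theta_values) < 2:
        raise ValueError("need at least two theta values")
    tables = [matrix.sample_table(s) for s in matrix.sample_ids]
    mean_S, mean_phi = [], []
    for theta in theta_values:
        common = flag_common_variants(matrix, theta)
        reduced = [reduce_sample(t, common) for t in tables]
        mean_S.append(mean_pairwise_sharing(reduced, universe))
        mean_phi.append(float(np.mean([informative_fraction(r) for r in reduced])))
    warnings: List[str] = []
    z_phi, flat_phi = _zscores(np.asarray(mean_phi))
    z_oms, flat_s = _zscores(1.0 - np.asarray(mean_S))
    if flat_phi or flat_s:
        warnings.append(
            "z-score fallback: zero variance across the theta sweep; using "
            "raw (uncentered) values in the product")
    product = z_phi * z_oms
    # argmax with largest-theta preference on exact ties
    best = len(product) - 1 - int(np.argmax(product[::-1]))
    return SharingSweepResult(
        theta_values=list(theta_values),
        mean_S=mean_S,
        mean_phi=mean_phi,
        z_phi=list(z_phi),
        z_one_minus_S=list(z_oms),
        z_product=list(product),
        selected_theta=float(theta_values[best]),
        warnings=warnings,
    )


def qc_warnings(result: SharingSweepResult, post_selection_S: float,
                post_selection_phi: float, s_warn: float = S_WARN,
                phi_warn: float = PHI_WARN) -> List[str]:
    """Experiment-level QC: flag a theta_V selected at the top of the sweep,
    residual sharing above ``s_warn`` and an informative fraction below
    ``phi_warn``."""
    out = []
    nontrivial = [t for t in result.theta_values if t < 1]
    if nontrivial and result.selected_theta == max(nontrivial):
        out.append(
            f"selected theta_V = {result.selected_theta:g} is the largest "
            "non-trivial sweep value: sharing is likely driven by one or a "
            "few dominant common alleles")
    if post_selection_S > s_warn:
        out.append(
            f"post-selection mean Sharing Factor {post_selection_S:.4g} "
            f"exceeds {s_warn:g}: residual inter-sample sharing is high")
    if post_selection_phi < phi_warn:
        out.append(
            f"post-selection mean Phi {post_selection_phi:.4g} is below "
            f"{phi_warn:g}: few reads carry informative barcodes")
    return out
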