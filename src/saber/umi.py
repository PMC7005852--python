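"""Unique-molecular-identifier (UMI) handling and the standard-vs-UMI
variant-frequency comparison.

The UMI protocol tags each template molecule with a random barcode before
amplification; reads sharing a UMI are reduced to one per-position
majority-vote consensus read, removing PCR duplicates and most sequencing
error.  Grouping is exact-match by default with optional single-edit
merging (the smaller group is absorbed into the larger); singleton groups
are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .align import SampleVariantTable
from .reads import MergedRead


@dataclass
class UmiGroup:
    umi: str
    member_read_ids: List[str]
    members: List[MergedRead]

    @property
    def size(self) -> int:
        return len(self.members)


def extract_umi(read: MergedRead, umi_len: int) -> Optional[Tuple[str, MergedRead]]:
    """Split the first ``umi_len`` bases off as the UMI; the remainder
    proceeds through the standard pipeline.  Reads too short to contain a
    UMI are filtered (returns None)."""
    if umi_len < 1:
        raise ValueError("umi_len must be >= 1")
    if len(read) < umi_len + 1:
        return None
    trimmed = MergedRead(read.id, read.seq[umi_len:], read.qual[umi_len:],
                         read.overlap_len)
    return read.seq[:umi_len], trimmed


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return mism == 1


def group_by_umi(tagged: Sequence[Tuple[str, MergedRead]],
                 merge_one_edit: bool = False) -> List[UmiGroup]:
    """Group reads by UMI (exact match; optionally absorb 1-mismatch UMIs
    into the larger group)."""
    buckets: Dict[str, List[MergedRead]] = {}
    for umi, read in tagged:
        buckets.setdefault(umi, []).append(read)
    if merge_one_edit:
        by_size = sorted(buckets, key=lambda u: (-len(buckets[u]), u))
        absorbed: Dict[str, str] = {}
        for i, small in enumerate(reversed(by_size)):
            for big in by_size:
                if big == small or big in absorbed:
                    continue
                if len(buckets[big]) >= len(buckets[small]) and _hamming1(big, small):
                    absorbed[small] = big
                    break
        for small, big in absorbed.items():
            buckets[big].extend(buckets.pop(small))
    return [UmiGroup(umi, [r.id for r in reads], reads)
            for umi, reads in sorted(buckets.items())]


def consensus_read(group: UmiGroup) -> MergedRead:
    """Per-position majority base over the group members of the modal
    length; ties go to the base with the highest summed quality."""
    lengths = [len(r) for r in group.members]
    modal = max(set(lengths), key=lambda L: (lengths.count(L), L))
    members = [r for r in group.members if len(r) == modal]
    if len(members) == 1:
        r = members[0]
        return MergedRead(f"umi:{group.umi}", r.seq, r.qual, r.overlap_len)
    seqs = np.array([np.frombuffer(r.seq.encode("ascii"), np.uint8)
                     for r in members])
    quals = np.array([r.qual for r in members])
    out_seq = np.empty(modal, np.uint8)
    out_qual = np.empty(modal, np.int16)
    for j in range(modal):
        col = seqs[:, j]
        counts: Dict[int, Tuple[int, int]] = {}
        for base, q in zip(col, quals[:, j]):
            c, qs = counts.get(base, (0, 0))
            counts[base] = (c + 1, qs + int(q))
        best = max(counts, key=lambda b: (counts[b][0], counts[b][1], -int(b)))
        out_seq[j] = best
        out_qual[j] = max(int(q) for base, q in zip(col, quals[:, j])
                          if base == best)
    return MergedRead(f"umi:{group.umi}", out_seq.tobytes().decode("ascii"),
                      out_qual, members[0].overlap_len)


def deduplicate(groups: Sequence[UmiGroup]) -> List[MergedRead]:
    """One consensus read per UMI group."""
    return [consensus_read(g) for g in groups]


@dataclass
class VafRegression:
    slope: float
    intercept: float
    r_squared: float  # adjusted R^2
    n_variants: int


def compare_vafs(table_std: SampleVariantTable,
                 table_umi: SampleVariantTable) -> VafRegression:
    """OLS regression of UMI-path VAFs on standard-path VAFs over the union
    of variant names (absent variants enter at VAF 0)."""
    x, y = table_std.proportions.align(table_umi.proportions, fill_value=0.0)
    shared = table_std.counts.index.intersection(table_umi.counts.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared variants")
    n = len(x)
    if np.ptp(x.values) == 0:
        raise ValueError("standard-path VAFs are constant; slope undefined")
    res = stats.linregress(x.values, y.values)
    r2 = res.rvalue ** 2
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return VafRegression(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(adj), n_variants=n)
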