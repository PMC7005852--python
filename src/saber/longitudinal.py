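"""Longitudinal clone tracking: matching samples across timepoints to
individual animals and building normalised clone trajectories.

Samples are matched by the overlap of their top-k most frequent barcodes
(k defaults to 5).  The full score matrix is always produced -- the greedy
1-to-1 assignment is advisory and intended for manual review, because
barcode overlap cannot prove animal identity on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .diversity import CloneSet


def _top_k_names(clone_set: CloneSet, k: int) -> set:
    ordered = sorted(clone_set.clones, key=lambda c: (-c[1], c[0]))
    return {name for name, _vaf in ordered[:k]}


@dataclass
class MatchResult:
    scores: pd.DataFrame  # rows: timepoint-1 ids, columns: timepoint-2 ids
    assignment: List[Tuple[str, str, float]]


def match_samples(t1_sets: Sequence[CloneSet], t2_sets: Sequence[CloneSet],
                  k: int = 5) -> MatchResult:
    """Pairwise top-k barcode overlap scores plus a greedy 1-to-1 assignment.

    score(i, j) = |top-k(i) intersect top-k(j)| / k.  The greedy pass takes
    pairs in descending score order (ties broken by sample id) and never
    reuses a sample.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tops1 = {cs.sample_id: _top_k_names(cs, k) for cs in t1_sets}
    tops2 = {cs.sample_id: _top_k_names(cs, k) for cs in t2_sets}
    scores = pd.DataFrame(
        [[len(tops1[a] & tops2[b]) / k for b in tops2] for a in tops1],
        index=list(tops1), columns=list(tops2), dtype=float)
    pairs = sorted(
        ((scores.at[a, b], a, b) for a in scores.index for b in scores.columns),
        key=lambda t: (-t[0], t[1], t[2]))
    used1, used2 = set(), set()
    assignment = []
    for score, a, b in pairs:
        if a in used1 or b in used2:
            continue
        assignment.append((a, b, float(score)))
        used1.add(a)
        used2.add(b)
    return MatchResult(scores=scores, assignment=assignment)


@dataclass
class CloneTrajectory:
    fish_id: str
    timepoints: List[str]
    frequencies: pd.DataFrame  # rows: clone names, columns: timepoints

    def __post_init__(self):
        sums = self.frequencies.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("frequencies must sum to 1 at every timepoint")


def build_trajectory(pair: Tuple[CloneSet, CloneSet], vaf_cutoff: float = 0.02,
                     fish_id: str | None = None,
                     timepoints: Tuple[str, str] = ("t1", "t2")) -> CloneTrajectory:
    """Per timepoint, keep clones with VAF > cutoff and renormalise to a
    cumulative frequency of 1.0; clones absent at the other timepoint get
    frequency 0 there."""
    cs1, cs2 = pair
    fish_id = fish_id or f"{cs1.sample_id}|{cs2.sample_id}"
    cols = {}
    for cs, label in zip((cs1, cs2), timepoints):
        kept = {name: vaf for name, vaf in cs.clones if vaf > vaf_cutoff}
        if not kept:
            raise ValueError(
                f"sample {cs.sample_id}: no clones above VAF {vaf_cutoff:g}")
        total = sum(kept.values())
        cols[label] = {name: v / total for name, v in kept.items()}
    freqs = pd.DataFrame(cols).fillna(0.0)
    freqs = freqs.loc[freqs.max(axis=1).sort_values(ascending=False, kind="stable").index]
    return CloneTrajectory(fish_id=fish_id, timepoints=list(timepoints),
                           frequencies=freqs)
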