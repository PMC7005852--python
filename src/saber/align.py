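"""Global alignment of reads to the amplicon insert and indel variant calling.

Each surviving read is aligned to the primer-trimmed reference window with
an affine-gap Needleman-Wunsch (Gotoh) dynamic program (defaults: match +5,
mismatch -4, gap open 10, gap extension 0.25 -- the EDNAFULL/Needleall
convention, with a gap of length L costing open + (L-1)*extend).

A variant allele is named purely by its indels: substitutions are collapsed
into the unedited "no variant" class so that base miscalls cannot create
false barcodes.  Indels are left-aligned (shifted maximally 5' within
repeats) and named ``<1-based position>:<length><I|D>``; the position is the
first deleted reference base for deletions and the reference base
immediately after the insertion point for insertions.  Multi-indel alleles
join their components with "," in ascending position order, giving a
deterministic cross-sample identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._kernels import gotoh_global

UNEDITED = "no variant"

_OPS = "MDI"


@dataclass
class Alignment:
    """Global alignment of ``query`` against ``ref`` as a CIGAR."""

    cigar: List[Tuple[str, int]]
    score: float
    ref_start: int = 0
    query: str = ""
    ref: str = ""

    def __post_init__(self):
        ref_len = sum(n for op, n in self.cigar if op in "MD")
        query_len = sum(n for op, n in self.cigar if op in "MI")
        if self.ref and ref_len != len(self.ref):
            raise ValueError("CIGAR does not span the reference")
        if self.query and query_len != len(self.query):
            raise ValueError("CIGAR does not span the query")

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


@dataclass(frozen=True)
class VariantAllele:
    """A named indel pattern; the barcode identity of a read."""

    name: str
    components: Tuple[Tuple[int, int, str], ...] = ()  # (pos, length, kind)

    @property
    def is_unedited(self) -> bool:
        return not self.components


def nw_align(read: str, ref: str, match: float = 5.0, mismatch: float = -4.0,
             gap_open: float = 10.0, gap_extend: float = 0.25) -> Alignment:
    """Optimal affine-gap global alignment of ``read`` against ``ref``."""
    if not read or not ref:
        raise ValueError("empty sequence")
    a = np.frombuffer(read.upper().encode("ascii"), np.uint8)
    b = np.frombuffer(ref.upper().encode("ascii"), np.uint8)
    score, ops = gotoh_global(a, b, float(match), float(mismatch),
                              float(gap_open), float(gap_extend))
    cigar: List[Tuple[str, int]] = []
    for op in ops:
        ch = _OPS[op]
        if cigar and cigar[-1][0] == ch:
            cigar[-1] = (ch, cigar[-1][1] + 1)
        else:
            cigar.append((ch, 1))
    return Alignment(cigar=cigar, score=float(score), ref_start=0,
                     query=read.upper(), ref=ref.upper())


def _left_shift_deletion(ref: str, pos: int, length: int) -> int:
    # deleting ref[pos:pos+length]; shifting is valid while the flanking
    # base repeats the last deleted base
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos


def _left_shift_insertion(ref: str, pos: int, ins: str) -> Tuple[int, str]:
    # insertion before ref[pos]; rotate through a repeat context
    while pos > 0 and ins[-1] == ref[pos - 1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def call_variant(aln: Alignment) -> VariantAllele:
    """Reduce an alignment to its indel components and name the allele.

    Substitutions are ignored; an alignment without indels is the unedited
    allele ("no variant").
    """
    ref = aln.ref
    components = []
    rpos = 0  # 0-based reference cursor
    qpos = 0
    for op, n in aln.cigar:
        if op == "M":
            rpos += n
            qpos += n
        elif op == "D":
            p = _left_shift_deletion(ref, rpos, n) if ref else rpos
            components.append((p + 1, n, "D"))
            rpos += n
        else:  # I
            ins = aln.query[qpos:qpos + n]
            p = rpos
            if ref and ins:
                p, ins = _left_shift_insertion(ref, rpos, ins)
            components.append((p + 1, n, "I"))
            qpos += n
    if not components:
        return VariantAllele(UNEDITED)
    components.sort(key=lambda c: (c[0], c[2], c[1]))
    name = ",".join(f"{p}:{n}{k}" for p, n, k in components)
    return VariantAllele(name, tuple(components))


@dataclass
class SampleVariantTable:
    """Per-sample read counts and proportions per variant allele."""

    sample_id: str
    counts: pd.Series  # index: variant name, values: read counts

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if self.counts.empty or self.counts.sum() <= 0:
            raise ValueError("no aligned reads")
        if (self.counts < 0).any():
            raise ValueError("negative read count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> pd.Series:
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_name": self.counts.index,
            "read_count": self.counts.values,
            "proportion": self.proportions.values,
        })


def tabulate_sample(variants: Sequence[VariantAllele],
                    sample_id: str = "sample") -> SampleVariantTable:
    """Count reads per unique variant name for one sample."""
    if not variants:
        raise ValueError("no aligned reads")
    counts: dict = {}
    for v in variants:
        counts[v.name] = counts.get(v.name, 0) + 1
    series = pd.Series(counts).sort_values(ascending=False, kind="stable")
    return SampleVariantTable(sample_id, series)


def align_and_call(reads, insert: str, *, match: float = 5.0,
                   mismatch: float = -4.0, gap_open: float = 10.0,
                   gap_extend: float = 0.25,
                   min_score_frac: float = 0.4,
                   counts: Optional[Sequence[int]] = None,
                   _cache: Optional[dict] = None):
    """Align read sequences to the reference insert and call variants.

    Reads whose optimal score falls below ``min_score_frac`` times the
    maximum achievable (match * min(len(read), len(insert))) are counted as
    unaligned and excluded.  Identical sequences are aligned once.  Returns
    ``(variants, n_unaligned)`` with one entry per read (or per ``counts``
    weight when given).
    """
    cache = _cache if _cache is not None else {}
    variants: List[VariantAllele] = []
    n_unaligned = 0
    weights = counts if counts is not None else [1] * len(reads)
    for seq, w in zip(reads, weights):
        hit = cache.get(seq)
        if hit is None:
            aln = nw_align(seq, insert, match, mismatch, gap_open, gap_extend)
            floor = min_score_frac * match * min(len(seq), len(insert))
            allele = call_variant(aln) if aln.score >= floor else None
            cache[seq] = hit = allele
        if hit is None:
            n_unaligned += w
        else:
            variants.extend([hit] * w)
    return variants, n_unaligned


def write_sam(path, alignments: Sequence[Alignment], ids: Sequence[str],
              ref_name: str = "amplicon") -> None:
    """Export alignments as plain-text SAM (CIGAR with M/I/D only)."""
    import pysam

    if not alignments:
        raise ValueError("nothing to export")
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": ref_name, "LN": len(alignments[0].ref)}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rid, aln in zip(ids, alignments):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = rid
            rec.query_sequence = aln.query
            rec.reference_id = 0
            rec.reference_start = aln.ref_start
            rec.mapping_quality = 60
            rec.cigarstring = aln.cigar_string
            out.write(rec)
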