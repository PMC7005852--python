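"""FASTQ ingestion, paired-end merging, quality trimming and primer filtering.

The three preprocessing stages mirror the classic PEAR / Trimmomatic /
Cutadapt steps for fully spanned amplicons, implemented as explicit,
testable operations:

* :func:`merge_pair` -- highest-scoring ungapped overlap merge with
  quality-weighted resolution of overlap mismatches,
* :func:`sliding_window_trim` -- 5'->3' sliding-window quality truncation,
* :func:`primer_filter` -- orientation normalisation and removal of the two
  flanking primers, rejecting reads with absent, incorrect or multiple
  primer hits.

Phred qualities are Sanger-scale (Phred+33) throughout.  ``N`` bases never
match anything and carry effective quality 0.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import edlib
import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._kernels import best_ungapped_overlap

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


@dataclass
class ReadPair:
    """One paired-end record; qualities are integer Phred arrays."""

    id: str
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray

    def __post_init__(self):
        self.qual1 = np.asarray(self.qual1, dtype=np.int16)
        self.qual2 = np.asarray(self.qual2, dtype=np.int16)
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: np.ndarray
    overlap_len: int = 0

    def __post_init__(self):
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AmpliconReference:
    """Amplicon reference with its two flanking primers.

    ``fwd_primer`` must sit at (or very near) the 5' end of ``seq``; the
    reverse complement of ``rev_primer`` must sit at the 3' end.  ``insert``
    is the reference window between the primers, against which reads are
    aligned after primer removal.
    """

    seq: str
    fwd_primer: str
    rev_primer: str
    name: str = "amplicon"

    def __post_init__(self):
        self.seq = self.seq.upper()
        self.fwd_primer = self.fwd_primer.upper()
        self.rev_primer = self.rev_primer.upper()
        i = self.seq.find(self.fwd_primer)
        if i < 0 or i > 10:
            raise ValueError("fwd_primer is not at the 5' end of the reference")
        j = self.seq.rfind(revcomp(self.rev_primer))
        if j < 0 or j + len(self.rev_primer) < len(self.seq) - 10:
            raise ValueError("rev_primer (revcomp) is not at the 3' end of the reference")
        self._fwd_end = i + len(self.fwd_primer)
        self._rev_start = j

    @property
    def insert(self) -> str:
        return self.seq[self._fwd_end:self._rev_start]


def merge_pair(pair: ReadPair, min_overlap: int = 10,
               max_mismatch_frac: float = 0.1) -> Optional[MergedRead]:
    """Merge a read pair over its best ungapped overlap.

    Mate 2 is reverse-complemented, every overlap length from
    ``min_overlap`` up to the shorter read is scored as
    matches - mismatches, and the highest-scoring overlap whose mismatch
    fraction stays within ``max_mismatch_frac`` is taken (ties go to the
    longer overlap).  At mismatched overlap positions the base with the
    higher quality wins and keeps its quality; at agreeing positions the
    higher of the two qualities is retained.  Returns ``None`` when no
    acceptable overlap exists.
    """
    if len(pair.seq1) == 0 or len(pair.seq2) == 0:
        raise ValueError("empty read")
    s1 = _encode(pair.seq1)
    s2rc = _encode(revcomp(pair.seq2))
    q1 = pair.qual1
    q2rc = pair.qual2[::-1]
    o, _score = best_ungapped_overlap(s1, s2rc, int(min_overlap),
                                      float(max_mismatch_frac))
    if o == 0:
        return None
    n1 = s1.size
    a, b = s1[n1 - o:], s2rc[:o]
    qa, qb = q1[n1 - o:], q2rc[:o]
    qa_eff = np.where(a == ord("N"), 0, qa)
    qb_eff = np.where(b == ord("N"), 0, qb)
    eq = (a == b) & (a != ord("N"))
    take_b = qb_eff > qa_eff
    cons = np.where(eq, a, np.where(take_b, b, a)).astype(np.uint8)
    qcons = np.where(eq, np.maximum(qa, qb), np.where(take_b, qb, qa))
    seq = (s1[: n1 - o].tobytes() + cons.tobytes() + s2rc[o:].tobytes()).decode("ascii")
    qual = np.concatenate([q1[: n1 - o], qcons, q2rc[o:]])
    return MergedRead(pair.id, seq, qual, overlap_len=o)


def sliding_window_trim(read: MergedRead, window: int = 4, min_q: float = 15,
                        min_len: int = 100) -> Optional[MergedRead]:
    """Truncate at the first 5'->3' window whose mean quality drops below
    ``min_q``; drop the read if fewer than ``min_len`` bases survive."""
    if window < 1:
        raise ValueError("window must be >= 1")
    q = read.qual
    cut = len(read)
    if len(read) >= window:
        c = np.concatenate([[0], np.cumsum(q, dtype=np.int64)])
        means = (c[window:] - c[:-window]) / window
        bad = np.nonzero(means < min_q)[0]
        if bad.size:
            cut = int(bad[0])
    if cut < min_len:
        return None
    if cut == len(read):
        return read
    return MergedRead(read.id, read.seq[:cut], q[:cut], read.overlap_len)


def _occurrences(text: str, pattern: str, max_edits: int):
    """Distinct approximate occurrences of ``pattern`` in ``text`` within
    ``max_edits`` edit distance.  Returns a list of (start, end) spans
    (end inclusive); overlapping best-score locations are collapsed to one
    occurrence, and lower-scoring secondary hits elsewhere still count.
    """
    spans = []
    masked = text
    while True:
        res = edlib.align(pattern, masked, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            break
        # collapse overlapping co-optimal locations into distinct spans
        new = []
        for start, end in sorted(res["locations"]):
            if start is None:
                start = 0
            if new and start <= new[-1][1]:
                new[-1] = (new[-1][0], max(new[-1][1], end))
            else:
                new.append((start, end))
        spans.extend(new)
        if len(spans) > 1:
            break  # enough to know the read fails the exactly-one rule
        s, e = new[0]
        masked = masked[:s] + "#" * (e - s + 1) + masked[e + 1:]
    return sorted(spans)


def primer_filter(read: MergedRead, ref: AmpliconReference,
                  max_error_rate: float = 0.1,
                  end_slack: int = 16) -> Optional[MergedRead]:
    """Require exactly one forward-primer hit near the 5' end and exactly
    one reverse-primer hit near the 3' end, each within ``max_error_rate``
    edits per primer base; strip both primers.

    A read whose primers match only in the reverse-complement orientation
    is flipped before testing.  Reads with absent, incorrect or multiple
    hits of either primer return ``None``.
    """
    fwd = ref.fwd_primer
    rev_rc = revcomp(ref.rev_primer)
    k_fwd = int(max_error_rate * len(fwd))
    k_rev = int(max_error_rate * len(ref.rev_primer))

    def attempt(seq: str, qual: np.ndarray) -> Optional[MergedRead]:
        hits_f = _occurrences(seq, fwd, k_fwd)
        hits_r = _occurrences(seq, rev_rc, k_rev)
        if len(hits_f) != 1 or len(hits_r) != 1:
            return None
        (fs, fe), (rs, re_) = hits_f[0], hits_r[0]
        if fs > end_slack or re_ < len(seq) - 1 - end_slack:
            return None
        if rs <= fe:
            return None
        return MergedRead(read.id, seq[fe + 1:rs], qual[fe + 1:rs],
                          read.overlap_len)

    out = attempt(read.seq, read.qual)
    if out is not None:
        return out if len(out) > 0 else None
    # orientation normalisation: only try the flip when the forward
    # orientation shows no forward-primer hit at all
    if not _occurrences(read.seq, fwd, k_fwd):
        out = attempt(revcomp(read.seq), read.qual[::-1])
        if out is not None and len(out) > 0:
            return out
    return None


# ---------------------------------------------------------------------------
# FASTQ I/O and the per-sample preprocessing driver


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Iterate synchronised R1/R2 FASTQ records (gzip-transparent)."""
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        for (id1, s1, q1), (_id2, s2, q2) in zip(
                FastqGeneralIterator(h1), FastqGeneralIterator(h2)):
            yield ReadPair(
                id1.split()[0], s1, s2,
                np.frombuffer(q1.encode("ascii"), np.uint8).astype(np.int16) - 33,
                np.frombuffer(q2.encode("ascii"), np.uint8).astype(np.int16) - 33,
            )


def write_fastq(path, reads) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as h:
        for r in reads:
            qual = (np.asarray(r.qual, np.uint8) + 33).tobytes().decode("ascii")
            h.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


@dataclass
class ReadFates:
    """Per-sample read accounting through the preprocessing stages."""

    total: int = 0
    merged: int = 0
    trimmed_out: int = 0
    primer_fail: int = 0
    surviving: int = 0
    extra: dict = field(default_factory=dict)


def process_sample(pairs, ref: AmpliconReference, *, min_overlap: int = 10,
                   max_mismatch_frac: float = 0.1, trim_window: int = 4,
                   trim_min_q: float = 15, trim_min_len: int = 100,
                   primer_max_error_rate: float = 0.1,
                   umi_length: int = 0):
    """Run merge -> [UMI split] -> trim -> primer filter over an iterable of
    :class:`ReadPair`.

    Returns ``(survivors, fates)``; when ``umi_length`` > 0 each surviving
    read is the pair ``(umi, MergedRead)`` instead.
    """
    from .umi import extract_umi  # local import to avoid a cycle

    fates = ReadFates()
    out = []
    for pair in pairs:
        fates.total += 1
        merged = merge_pair(pair, min_overlap, max_mismatch_frac)
        if merged is None:
            continue
        fates.merged += 1
        umi = None
        if umi_length > 0:
            split = extract_umi(merged, umi_length)
            if split is None:
                fates.trimmed_out += 1
                continue
            umi, merged = split
        trimmed = sliding_window_trim(merged, trim_window, trim_min_q, trim_min_len)
        if trimmed is None:
            fates.trimmed_out += 1
            continue
        kept = primer_filter(trimmed, ref, primer_max_error_rate)
        if kept is None:
            fates.primer_fail += 1
            continue
        fates.surviving += 1
        out.append((umi, kept) if umi_length > 0 else kept)
    return out, fates
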