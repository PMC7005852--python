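"""Synthetic amplicon-barcode datasets with known truth.

The generator emulates a pulse-labelled lineage-tracing experiment read out
by paired-end amplicon sequencing: a synthetic 300-nt amplicon carrying 10
evenly spaced 23-nt CRISPR target sites, per-sample clone structure with
Dirichlet-skewed allele fractions, a fraction of unedited alleles,
"stereotypical repair" variants planted across samples, per-base
substitution/indel sequencing error, and optional UMI tags.  Every emitted
read is accounted for in the truth tables, so each pipeline stage and the
end-to-end run can be checked against ground truth without any downloads.

Default parameters are the study conditions exercised throughout the test
suite: 20 samples x 5,000 reads, ~4 clones per sample, 10% unedited
alleles, two planted shared variants (VAF 0.05 and 0.005), substitution
error 1e-3/base and indel error 1e-5/base.

Two failure-mode presets reproduce the archetypal uninterpretable
experiments: ``poor_labeling`` (96% unedited alleles) and
``dominant_shared_allele`` (one multi-site editing pattern at VAF 0.6 in
14/16 samples plus trace cross-sample carry-over), both of which must
trigger QC warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import UNEDITED, call_variant, nw_align
from .reads import AmpliconReference, revcomp

_BASES = np.frombuffer(b"ACGT", np.uint8)

_PRIMER_LEN = 20
_SITE_LEN = 23
_N_SITES = 10


def default_reference(seed: int = 987654321) -> AmpliconReference:
    """Deterministic 300-nt synthetic amplicon: 20-nt primers flanking a
    260-nt insert that carries 10 evenly spaced 23-nt target sites."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=300).tobytes().decode("ascii")
    return AmpliconReference(
        seq=seq,
        fwd_primer=seq[:_PRIMER_LEN],
        rev_primer=revcomp(seq[-_PRIMER_LEN:]),
        name="synthetic-amplicon",
    )


def target_site_starts(insert_len: int = 260) -> List[int]:
    """0-based start of each 23-nt target site within the insert."""
    return [3 + i * 26 for i in range(_N_SITES)]


def _cut_positions(insert_len: int = 260) -> List[int]:
    # nuclease cut ~3 nt from the PAM-proximal end of each site
    return [s + 17 for s in target_site_starts(insert_len)]


@dataclass(frozen=True)
class IndelPattern:
    """An editing outcome as insert-coordinate components (pos, len, kind,
    inserted-seq)."""

    components: Tuple[Tuple[int, int, str, str], ...]

    def apply(self, insert: str) -> str:
        s = insert
        for pos, length, kind, ins in sorted(self.components, reverse=True):
            if kind == "D":
                s = s[:pos] + s[pos + length:]
            else:
                s = s[:pos] + ins + s[pos:]
        return s


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment."""

    n_samples: int = 20
    reads_per_sample: int = 5000
    read_length: int = 250
    clones_per_sample_mean: float = 4.0
    clones_per_sample_sd: float = 1.0
    vaf_dirichlet_alpha: float = 1.0
    unedited_fraction: float = 0.10
    planted_common_vafs: Tuple[float, ...] = (0.05, 0.005)
    substitution_rate: float = 1e-3
    indel_error_rate: float = 1e-5
    base_quality: int = 35
    quality_droop: float = 0.0
    umi_length: int = 0
    umi_duplication: int = 5
    # failure-mode machinery (off by default)
    dominant_vaf: float = 0.0
    dominant_samples: int = 0
    cross_trace_vaf: float = 0.0
    main_clone_frac: float = 0.0
    seed: int = 20200207

    def __post_init__(self):
        total = (self.unedited_fraction + sum(self.planted_common_vafs)
                 + self.dominant_vaf + self.cross_trace_vaf)
        if not (0 <= total <= 1):
            raise ValueError("per-sample fractions must sum to <= 1")
        for f in (self.unedited_fraction, *self.planted_common_vafs,
                  self.dominant_vaf, self.cross_trace_vaf):
            if not (0 <= f <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.reads_per_sample < 1 or self.n_samples < 1:
            raise ValueError("need at least one sample and one read")


@dataclass
class SimulatedSample:
    sample_id: str
    r1_path: Path
    r2_path: Path
    truth: pd.DataFrame  # variant_name, count, vaf, category


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: AmpliconReference
    samples: List[SimulatedSample]
    truth_summary: pd.DataFrame
    sample_sheet: Path
    reference_fasta: Path
    outdir: Path


def _variant_name(allele_insert: str, ref_insert: str) -> str:
    """Canonical name of an editing outcome, via the same alignment and
    naming rules the pipeline applies."""
    return call_variant(nw_align(allele_insert, ref_insert)).name


def _draw_clone_pattern(rng: np.random.Generator, insert_len: int) -> IndelPattern:
    cuts = _cut_positions(insert_len)
    n_edit = 1 + rng.binomial(_N_SITES - 1, 0.25)
    sites = sorted(rng.choice(_N_SITES, size=n_edit, replace=False))
    comps = []
    for si in sites:
        cut = cuts[si]
        if rng.random() < 0.65:
            length = int(min(20, rng.geometric(0.2)))
            start = int(max(0, cut - rng.integers(0, 6)))
            start = min(start, insert_len - length)
            comps.append((start, length, "D", ""))
        else:
            length = int(min(12, rng.geometric(0.3)))
            ins = rng.choice(_BASES, size=length).tobytes().decode("ascii")
            comps.append((cut, length, "I", ins))
    return IndelPattern(tuple(comps))


def _planted_patterns(insert_len: int) -> List[IndelPattern]:
    """Fixed stereotypical-repair outcomes shared across samples: an 8-nt
    deletion at site 3 and a 2-nt insertion at site 7."""
    cuts = _cut_positions(insert_len)
    return [
        IndelPattern(((cuts[2] - 2, 8, "D", ""),)),
        IndelPattern(((cuts[6], 2, "I", "GT"),)),
    ]


def _dominant_pattern(insert_len: int) -> IndelPattern:
    """A single deletion spanning 5 target sites (the high-frequency
    multi-site repair archetype)."""
    cuts = _cut_positions(insert_len)
    start = cuts[2] - 2
    return IndelPattern(((start, cuts[6] - start + 2, "D", ""),))


def _distinct_umis(rng: np.random.Generator, n: int, length: int) -> List[str]:
    """n distinct random UMIs (collision-free within a sample)."""
    space = 4 ** length
    if n > space:
        raise ValueError("UMI space too small for the requested molecules")
    codes = rng.choice(space, size=n, replace=False)
    out = []
    for code in codes:
        chars = []
        for _ in range(length):
            chars.append("ACGT"[code % 4])
            code //= 4
        out.append("".join(chars))
    return out


def _quality_string(length: int, base_q: int, droop: float) -> str:
    if droop <= 0 or length < 2:
        q = np.full(length, base_q)
    else:
        q = base_q - droop * np.arange(length) / (length - 1)
    q = np.clip(np.round(q), 2, 41).astype(np.uint8) + 33
    return q.tobytes().decode("ascii")


class _SampleBuilder:
    """Draws one sample's allele spectrum and emits its error-free reads."""

    def __init__(self, rng, config, ref):
        self.rng = rng
        self.cfg = config
        self.ref = ref
        self.insert = ref.insert

    def draw_alleles(self, planted, dominant, carry, is_carrier):
        """Return (names, molecules, probabilities, categories)."""
        cfg, rng = self.cfg, self.rng
        names = [UNEDITED]
        mols = [self.ref.seq]
        probs = [cfg.unedited_fraction]
        cats = ["unedited"]
        for (name, mol), vaf in zip(planted, cfg.planted_common_vafs):
            names.append(name)
            mols.append(mol)
            probs.append(vaf)
            cats.append("planted")
        if is_carrier and dominant is not None:
            names.append(dominant[0])
            mols.append(dominant[1])
            probs.append(cfg.dominant_vaf)
            cats.append("planted")
        if carry is not None:
            names.append(carry[0])
            mols.append(carry[1])
            probs.append(cfg.cross_trace_vaf)
            cats.append("trace")
        mass = 1.0 - sum(probs)
        n_clones = max(1, int(round(rng.normal(cfg.clones_per_sample_mean,
                                               cfg.clones_per_sample_sd))))
        taken = set(names)
        clone_entries = []
        while len(clone_entries) < n_clones:
            pat = _draw_clone_pattern(rng, len(self.insert))
            allele = pat.apply(self.insert)
            name = _variant_name(allele, self.insert)
            if name in taken or name == UNEDITED:
                continue
            taken.add(name)
            mol = self.ref.seq[:_PRIMER_LEN] + allele + self.ref.seq[-_PRIMER_LEN:]
            clone_entries.append((name, mol))
        if cfg.main_clone_frac > 0 and n_clones > 1:
            rest = rng.dirichlet([cfg.vaf_dirichlet_alpha] * (n_clones - 1))
            shares = np.concatenate([[cfg.main_clone_frac],
                                     (1 - cfg.main_clone_frac) * rest])
        else:
            shares = rng.dirichlet([cfg.vaf_dirichlet_alpha] * n_clones)
        for (name, mol), share in zip(clone_entries, shares):
            names.append(name)
            mols.append(mol)
            probs.append(mass * share)
            cats.append("clone")
        return names, mols, np.asarray(probs), cats, clone_entries[0]


def _apply_errors(rng, r1_list, r2_list, cfg):
    """In-place substitution and single-base indel sequencing errors."""
    n = len(r1_list)
    L = cfg.read_length
    for reads, tag in ((r1_list, 0), (r2_list, 1)):
        n_sub = rng.binomial(n * L, cfg.substitution_rate)
        n_ind = rng.binomial(n * L, cfg.indel_error_rate)
        events: Dict[int, List[Tuple[str, int]]] = {}
        for _ in range(n_sub):
            events.setdefault(int(rng.integers(n)), []).append(
                ("S", int(rng.integers(L))))
        for _ in range(n_ind):
            events.setdefault(int(rng.integers(n)), []).append(
                ("X", int(rng.integers(L))))
        for i, evs in events.items():
            b = bytearray(reads[i], "ascii")
            for kind, pos in sorted(evs, reverse=True):
                if pos >= len(b):
                    continue
                if kind == "S":
                    old = b[pos]
                    choices = [c for c in b"ACGT" if c != old]
                    b[pos] = choices[rng.integers(3)]
                elif rng.random() < 0.5:
                    del b[pos]
                else:
                    b.insert(pos, _BASES[rng.integers(4)])
            reads[i] = b.decode("ascii")


def simulate_dataset(config: SimulationConfig,
                     outdir: Path) -> SimulatedDataset:
    """Emit paired FASTQ per sample plus truth tables and a sample sheet.

    Truth read counts equal emitted FASTQ record counts exactly, and the
    same seed reproduces byte-identical output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ref = default_reference()
    insert = ref.insert
    planted_pats = _planted_patterns(len(insert))[: len(config.planted_common_vafs)]
    planted = []
    for pat in planted_pats:
        allele = pat.apply(insert)
        planted.append((
            _variant_name(allele, insert),
            ref.seq[:_PRIMER_LEN] + allele + ref.seq[-_PRIMER_LEN:],
        ))
    dominant = None
    if config.dominant_vaf > 0:
        allele = _dominant_pattern(len(insert)).apply(insert)
        dominant = (_variant_name(allele, insert),
                    ref.seq[:_PRIMER_LEN] + allele + ref.seq[-_PRIMER_LEN:])
    builder = _SampleBuilder(rng, config, ref)

    planted_names = {name for name, _ in planted}
    if dominant is not None:
        planted_names.add(dominant[0])

    per_sample: List[Tuple[str, List[str], List[str], np.ndarray, List[str]]] = []
    carry = None
    for i in range(config.n_samples):
        sid = f"S{i + 1:03d}"
        is_carrier = i < config.dominant_samples
        use_carry = carry if config.cross_trace_vaf > 0 else None
        names, mols, probs, cats, main_clone = builder.draw_alleles(
            planted, dominant, use_carry, is_carrier)
        per_sample.append((sid, names, mols, probs, cats))
        carry = main_clone

    # dataset-level truth: an allele is informative iff it is not planted
    # and appears in exactly one sample.  With UMIs the template molecules
    # are the sampling unit and each one is read umi_duplication times, so
    # read proportions equal molecule proportions exactly.
    occurrence: Dict[str, int] = {}
    counts_per_sample = []
    dup = max(1, config.umi_duplication) if config.umi_length > 0 else 1
    for sid, names, mols, probs, cats in per_sample:
        counts = dup * rng.multinomial(config.reads_per_sample // dup,
                                       probs / probs.sum())
        counts_per_sample.append(counts)
        for name, c in zip(names, counts):
            if c > 0:
                occurrence[name] = occurrence.get(name, 0) + 1

    samples = []
    summary_rows = []
    for (sid, names, mols, probs, cats), counts in zip(per_sample,
                                                       counts_per_sample):
        r1_list: List[str] = []
        r2_list: List[str] = []
        L = config.read_length
        umis = iter(())
        if config.umi_length > 0:
            umis = iter(_distinct_umis(rng, int(counts.sum()) // dup,
                                       config.umi_length))
        for name, mol, c in zip(names, mols, counts):
            if c == 0:
                continue
            if config.umi_length > 0:
                for _ in range(c // dup):
                    frag = next(umis) + mol
                    frag_rc = revcomp(frag)
                    r1_list.extend([frag[:L]] * dup)
                    r2_list.extend([frag_rc[:L]] * dup)
            else:
                frag_rc = revcomp(mol)
                r1_list.extend([mol[:L]] * c)
                r2_list.extend([frag_rc[:L]] * c)
        _apply_errors(rng, r1_list, r2_list, config)
        order = rng.permutation(len(r1_list))
        r1_path = outdir / f"{sid}_R1.fastq"
        r2_path = outdir / f"{sid}_R2.fastq"
        for path, pool in ((r1_path, r1_list), (r2_path, r2_list)):
            with open(path, "w") as h:
                for k, j in enumerate(order):
                    seq = pool[j]
                    qual = _quality_string(len(seq), config.base_quality,
                                           config.quality_droop)
                    h.write(f"@{sid}.{k}\n{seq}\n+\n{qual}\n")
        truth = pd.DataFrame({
            "variant_name": names,
            "count": counts,
            "category": cats,
        })
        truth = truth[truth["count"] > 0].reset_index(drop=True)
        total = int(truth["count"].sum())
        truth["vaf"] = truth["count"] / total
        truth["informative"] = [
            cat in ("clone", "trace") and occurrence[name] == 1
            and name not in planted_names
            for name, cat in zip(truth["variant_name"], truth["category"])
        ]
        informative_reads = int(truth.loc[truth["informative"], "count"].sum())
        b002 = int((truth["informative"] & (truth["vaf"] > 0.02)).sum())
        summary_rows.append({
            "sample_id": sid,
            "total_reads": total,
            "unedited_reads": int(truth.loc[
                truth["variant_name"] == UNEDITED, "count"].sum()),
            "informative_reads": informative_reads,
            "phi_truth": informative_reads / total,
            "b002_truth": b002,
        })
        samples.append(SimulatedSample(sid, r1_path, r2_path, truth))

    truth_summary = pd.DataFrame(summary_rows)
    ref_fasta = outdir / "reference.fasta"
    with open(ref_fasta, "w") as h:
        h.write(f">{ref.name}\n{ref.seq}\n")
    sheet = outdir / "sample_sheet.tsv"
    pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "r1_path": [str(s.r1_path) for s in samples],
        "r2_path": [str(s.r2_path) for s in samples],
        "group": ["A"] * len(samples),
    }).to_csv(sheet, sep="\t", index=False)
    truth_summary.to_csv(outdir / "truth_summary.tsv", sep="\t", index=False)
    pd.concat([s.truth.assign(sample_id=s.sample_id) for s in samples]
              ).to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    return SimulatedDataset(config, ref, samples, truth_summary, sheet,
                            ref_fasta, outdir)


FAILURE_MODES = ("poor_labeling", "dominant_shared_allele")


def failure_mode_config(mode: str, seed: int = 20200207) -> SimulationConfig:
    """Preset study conditions for the two uninterpretable-experiment
    archetypes."""
    if mode == "poor_labeling":
        return SimulationConfig(
            n_samples=12, reads_per_sample=2000, unedited_fraction=0.96,
            planted_common_vafs=(), clones_per_sample_mean=3.0, seed=seed)
    if mode == "dominant_shared_allele":
        return SimulationConfig(
            n_samples=16, reads_per_sample=2000, unedited_fraction=0.05,
            planted_common_vafs=(), dominant_vaf=0.6, dominant_samples=14,
            cross_trace_vaf=0.002, main_clone_frac=0.6,
            clones_per_sample_mean=4.0, seed=seed)
    raise ValueError(f"unknown failure mode: {mode!r}")


def simulate_failure_modes(mode: str, outdir: Path,
                           seed: int = 20200207) -> SimulatedDataset:
    """Generate one of the failure-mode archetype datasets."""
    return simulate_dataset(failure_mode_config(mode, seed), outdir)
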