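"""End-to-end orchestration: reads -> align -> [UMI] -> sharing -> select
-> diversity, with per-stage outputs, structured QC JSON and warnings.

The run writes, under ``output_dir``:

* ``read_fates.tsv`` -- per-sample read accounting through preprocessing,
* ``variant_tables/<sample>.tsv`` -- per-sample variant counts/proportions,
* ``sweep.tsv``, ``common_variants.tsv``, ``pairwise_sharing.tsv``,
  ``reduced_tables/<sample>.tsv`` -- the theta_V sweep and its reduction,
* ``bootstrap_replicates.tsv``, ``classification.tsv`` -- sample selection,
* ``clone_sets.tsv``, ``group_comparison.json`` -- clone enumeration,
* ``qc.json`` -- theta_V, mean Phi and mean Sharing Factor (the three
  quality-control values every run must report), warnings and summaries,
* ``resolved_config.yaml`` -- the exact configuration of the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import align as align_mod
from . import diversity as div_mod
from . import reads as reads_mod
from . import select as select_mod
from . import sharing as share_mod
from . import umi as umi_mod
from .align import SampleVariantTable, tabulate_sample
from .reads import AmpliconReference
from .sharing import DEFAULT_THETA_SWEEP, PHI_WARN, S_WARN


@dataclass
class RunConfig:
    sample_sheet: str
    reference_fasta: str
    output_dir: str
    fwd_primer: str = ""
    rev_primer: str = ""
    theta_values: Tuple[float, ...] = DEFAULT_THETA_SWEEP
    vaf_cutoff: float = 0.02
    n_boot: int = 1000
    seed: int = select_mod.DEFAULT_SEED
    umi_length: int = 0
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1
    trim_window: int = 4
    trim_min_q: float = 15.0
    trim_min_len: int = 100
    primer_max_error_rate: float = 0.1
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.25
    min_score_frac: float = 0.4
    s_warn: float = S_WARN
    phi_warn: float = PHI_WARN

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as h:
            raw = yaml.safe_load(h) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "theta_values" in raw:
            cfg.theta_values = tuple(float(t) for t in raw["theta_values"])
        return cfg


@dataclass
class RunReport:
    config: RunConfig
    fates: pd.DataFrame
    tables: List[SampleVariantTable]
    sweep: share_mod.SharingSweepResult
    common: share_mod.CommonVariantSet
    reduced: List[share_mod.ReducedSampleTable]
    mean_phi: float
    mean_sharing_factor: float
    bootstrap: select_mod.BootstrapResult
    classification: select_mod.Classification
    clone_sets: List[div_mod.CloneSet]
    warnings: List[str]
    qc: dict
    ks: Optional[Tuple[float, float]] = None
    group_comparison: Optional[div_mod.GroupComparison] = None


def load_reference(fasta_path, fwd_primer: str = "",
                   rev_primer: str = "") -> AmpliconReference:
    """Read the amplicon reference; default primers are the terminal 20 nt
    of the reference on each side."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    seq = str(rec.seq).upper()
    fwd = fwd_primer or seq[:20]
    rev = rev_primer or reads_mod.revcomp(seq[-20:])
    return AmpliconReference(seq=seq, fwd_primer=fwd, rev_primer=rev,
                             name=rec.id)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "r1_path", "r2_path"}
    if sheet.empty:
        raise ValueError("empty sample sheet")
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet must provide columns {sorted(required)}")
    if "group" not in sheet.columns:
        sheet["group"] = "all"
    return sheet


def _process_one_sample(row, ref: AmpliconReference, cfg: RunConfig,
                        cache: dict) -> Tuple[SampleVariantTable, dict]:
    pairs = reads_mod.read_fastq_pairs(row.r1_path, row.r2_path)
    survivors, fates = reads_mod.process_sample(
        pairs, ref,
        min_overlap=cfg.min_overlap, max_mismatch_frac=cfg.max_mismatch_frac,
        trim_window=cfg.trim_window, trim_min_q=cfg.trim_min_q,
        trim_min_len=cfg.trim_min_len,
        primer_max_error_rate=cfg.primer_max_error_rate,
        umi_length=cfg.umi_length)
    if cfg.umi_length > 0:
        groups = umi_mod.group_by_umi(survivors)
        survivors = umi_mod.deduplicate(groups)
    seqs = [r.seq for r in survivors]
    variants, n_unaligned = align_mod.align_and_call(
        seqs, ref.insert, match=cfg.match, mismatch=cfg.mismatch,
        gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
        min_score_frac=cfg.min_score_frac, _cache=cache)
    if not variants:
        raise RuntimeError(
            f"sample {row.sample_id}: no reads aligned (stage: align)")
    table = tabulate_sample(variants, row.sample_id)
    fate_row = {
        "sample_id": row.sample_id, "total": fates.total,
        "merged": fates.merged, "trimmed_out": fates.trimmed_out,
        "primer_fail": fates.primer_fail, "surviving": fates.surviving,
        "unaligned": n_unaligned, "aligned": table.total,
    }
    return table, fate_row


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order and write all outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "variant_tables").mkdir(exist_ok=True)
    (outdir / "reduced_tables").mkdir(exist_ok=True)
    sheet = read_sample_sheet(config.sample_sheet)
    ref = load_reference(config.reference_fasta, config.fwd_primer,
                         config.rev_primer)

    cache: dict = {}
    tables, fate_rows = [], []
    for row in sheet.itertuples(index=False):
        try:
            table, fate_row = _process_one_sample(row, ref, config, cache)
        except Exception as exc:
            raise RuntimeError(
                f"sample {row.sample_id} failed: {exc}") from exc
        tables.append(table)
        fate_rows.append(fate_row)
        table.to_frame().to_csv(
            outdir / "variant_tables" / f"{table.sample_id}.tsv",
            sep="\t", index=False)
    fates = pd.DataFrame(fate_rows)
    fates.to_csv(outdir / "read_fates.tsv", sep="\t", index=False)

    matrix = share_mod.VariantMatrix.from_tables(tables)
    sweep = share_mod.sweep_theta(matrix, config.theta_values)
    common = share_mod.flag_common_variants(matrix, sweep.selected_theta)
    reduced = [share_mod.reduce_sample(t, common) for t in tables]
    phi = [share_mod.informative_fraction(r) for r in reduced]
    mean_phi = float(np.mean(phi))
    mean_S = share_mod.mean_pairwise_sharing(reduced)
    warnings = list(sweep.warnings)
    warnings += share_mod.qc_warnings(sweep, mean_S, mean_phi,
                                      config.s_warn, config.phi_warn)
    sweep.to_frame().to_csv(outdir / "sweep.tsv", sep="\t", index=False)
    pd.Series(sorted(common.names), name="variant_name").to_csv(
        outdir / "common_variants.tsv", sep="\t", index=False)
    share_mod.pairwise_sharing_matrix(reduced).to_csv(
        outdir / "pairwise_sharing.tsv", sep="\t")
    for r in reduced:
        r.to_frame().to_csv(outdir / "reduced_tables" / f"{r.sample_id}.tsv",
                            sep="\t", index=False)

    b002 = [div_mod.count_clones(r, config.vaf_cutoff) for r in reduced]
    boot = select_mod.bootstrap_phi(list(zip(phi, b002)),
                                    n_reps=config.n_boot, seed=config.seed)
    cls = select_mod.classify_samples([t.sample_id for t in tables], phi,
                                      boot.ci_low)
    pd.DataFrame({"replicate_mean_phi": boot.replicate_mean_phi,
                  "replicate_sd_B002": boot.replicate_sd_B002}).to_csv(
        outdir / "bootstrap_replicates.tsv", sep="\t", index=False)
    class_df = pd.DataFrame({
        "sample_id": [t.sample_id for t in tables],
        "phi": phi, "B_cutoff": b002,
        "class": ["high" if s in set(cls.high) else "low"
                  for s in (t.sample_id for t in tables)],
    })
    class_df.to_csv(outdir / "classification.tsv", sep="\t", index=False)

    ks = None
    high_b = class_df.loc[class_df["class"] == "high", "B_cutoff"]
    low_b = class_df.loc[class_df["class"] == "low", "B_cutoff"]
    if len(high_b) >= 2 and len(low_b) >= 2:
        ks = select_mod.compare_distributions(high_b.tolist(), low_b.tolist())

    clone_sets = []
    clone_rows = []
    for r in reduced:
        if r.informative.sum() == 0:
            continue
        cs = div_mod.build_clone_set(r, config.vaf_cutoff)
        clone_sets.append(cs)
        for name, vaf in cs.clones:
            clone_rows.append({"sample_id": cs.sample_id, "variant_name": name,
                               "vaf": vaf})
    pd.DataFrame(clone_rows,
                 columns=["sample_id", "variant_name", "vaf"]).to_csv(
        outdir / "clone_sets.tsv", sep="\t", index=False)

    group_cmp = None
    groups = sheet.set_index("sample_id")["group"]
    uniq = sorted(groups.unique())
    if len(uniq) == 2:
        ga = class_df.loc[class_df["sample_id"].map(groups) == uniq[0], "B_cutoff"]
        gb = class_df.loc[class_df["sample_id"].map(groups) == uniq[1], "B_cutoff"]
        if len(ga) >= 3 and len(gb) >= 3 and (ga.std() > 0 or gb.std() > 0):
            group_cmp = div_mod.group_compare(ga.tolist(), gb.tolist())
            with open(outdir / "group_comparison.json", "w") as h:
                json.dump({"groups": uniq, **asdict(group_cmp)}, h, indent=2)

    qc = {
        "selected_theta": sweep.selected_theta,
        "mean_phi": mean_phi,
        "mean_sharing_factor": mean_S,
        "n_common_variants": len(common.names),
        "warnings": warnings,
        "bootstrap": {
            "estimate_mean_phi": boot.estimate_mean_phi,
            "ci_low": boot.ci_low, "ci_high": boot.ci_high,
            "pearson_r": boot.pearson_r, "n_reps": boot.n_reps,
        },
        "classification": {"n_high": len(cls.high), "n_low": len(cls.low),
                           "mean_phi_high": cls.mean_phi_high,
                           "mean_phi_low": cls.mean_phi_low},
        "ks_test": {"statistic": ks[0], "p_value": ks[1]} if ks else None,
        "read_fates": fate_rows,
        "per_sample": class_df.to_dict(orient="records"),
    }
    with open(outdir / "qc.json", "w") as h:
        json.dump(qc, h, indent=2, default=float)
    with open(outdir / "resolved_config.yaml", "w") as h:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(config).items()}, h)

    return RunReport(
        config=config, fates=fates, tables=tables, sweep=sweep, common=common,
        reduced=reduced, mean_phi=mean_phi, mean_sharing_factor=mean_S,
        bootstrap=boot, classification=cls, clone_sets=clone_sets,
        warnings=warnings, qc=qc, ks=ks, group_comparison=group_cmp)
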