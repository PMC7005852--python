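"""Shared fixtures: synthetic datasets run end-to-end once per session."""

import pytest

from saber.pipeline import RunConfig, run_pipeline
from saber.synth import (SimulationConfig, default_reference,
                         simulate_failure_modes, simulate_dataset)


def run_on(dataset, outdir, **overrides):
    cfg = RunConfig(
        sample_sheet=str(dataset.sample_sheet),
        reference_fasta=str(dataset.reference_fasta),
        output_dir=str(outdir), **overrides)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """4 samples x 500 reads under the default study conditions."""
    root = tmp_path_factory.mktemp("small_e2e")
    ds = simulate_dataset(
        SimulationConfig(n_samples=4, reads_per_sample=500, seed=11),
        root / "sim")
    report = run_on(ds, root / "out")
    return ds, report, root


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The default study conditions: 20 samples x 5,000 reads, ~4 clones
    per sample, substitution error 1e-3."""
    root = tmp_path_factory.mktemp("default_e2e")
    ds = simulate_dataset(SimulationConfig(seed=7), root / "sim")
    report = run_on(ds, root / "out")
    return ds, report


@pytest.fixture(scope="session")
def failure_runs(tmp_path_factory):
    root = tmp_path_factory.mktemp("failure_modes")
    out = {}
    for mode in ("poor_labeling", "dominant_shared_allele"):
        ds = simulate_failure_modes(mode, root / mode, seed=5)
        out[mode] = (ds, run_on(ds, root / f"{mode}_out"))
    return out


@pytest.fixture(scope="session")
def umi_run(tmp_path_factory):
    """Error-free UMI-tagged dataset processed along both paths."""
    root = tmp_path_factory.mktemp("umi")
    ds = simulate_dataset(
        SimulationConfig(n_samples=4, reads_per_sample=1500, umi_length=10,
                         substitution_rate=0.0, indel_error_rate=0.0,
                         seed=42),
        root / "sim")
    std = run_on(ds, root / "std", umi_length=0)
    umi = run_on(ds, root / "umi", umi_length=10)
    return ds, std, umi
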