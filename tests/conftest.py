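from __future__ import annotations

import json
from pathlib import Path

import pytest

from abaphos.pipeline import RunConfig, run_all
from abaphos.synthetic_data import GeneratorConfig, write_fixture_bundle


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory) -> Path:
    """The standard synthetic study bundle (seed 42, 200 families, 2000
    peptides per species)."""
    outdir = tmp_path_factory.mktemp("bundle_default")
    write_fixture_bundle(GeneratorConfig(seed=42), outdir, overwrite=True)
    return outdir


@pytest.fixture(scope="session")
def default_truth(default_bundle) -> dict:
    return json.loads((default_bundle / "truth.json").read_text())


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory) -> Path:
    """Full pipeline output over the standard bundle."""
    outdir = tmp_path_factory.mktemp("run_default")
    cfg = RunConfig.from_bundle(default_bundle, outdir)
    run_all(cfg)
    return outdir


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> Path:
    """A fast, reduced bundle for smoke and IO tests."""
    outdir = tmp_path_factory.mktemp("bundle_small")
    config = GeneratorConfig(
        seed=7,
        n_families=25,
        n_peptides=250,
        n_anchor_families=9,
        n_decoy_proteins=5,
        n_decoy_groups=3,
    )
    write_fixture_bundle(config, outdir, overwrite=True)
    return outdir
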