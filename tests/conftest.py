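"""Shared fixtures: one small synthetic three-species dataset (generated
once per session) plus one full pipeline run over it, reused by the module
and end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from ploidtrace.codon_evolution import SENSE_CODONS
from ploidtrace.pipeline import PipelineConfig, run_pipeline
from ploidtrace.synthetic_data import FixtureConfig, generate_fixture

SPECIES = ("T1", "T2", "T3")

SMALL_FIXTURE_KWARGS = dict(
    n_shared_single_copy=30,
    n_shared_multi_copy=8,
    n_species_specific=10,
    n_paralog_pairs=40,
    gene_length=200,
    seed=11,
)


def random_cds(n_codons: int, seed: int = 0) -> str:
    """Random sense-codon CDS starting with ATG, no stops."""
    rng = np.random.default_rng(seed)
    return "ATG" + "".join(rng.choice(list(SENSE_CODONS), size=n_codons - 1))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    generate_fixture(FixtureConfig(**SMALL_FIXTURE_KWARGS), out)
    return out


@pytest.fixture(scope="session")
def fixture_manifest():
    return generate_fixture(FixtureConfig(**SMALL_FIXTURE_KWARGS))


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(
        fasta_by_species={sp: str(fixture_dir / f"{sp}.fasta") for sp in SPECIES},
        annotation_tsv=str(fixture_dir / "annotations.tsv"),
        out_dir=str(out),
        seed=3,
    )
    report = run_pipeline(cfg)
    return cfg, report, out
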