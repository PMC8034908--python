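"""Session-scoped fixtures: one default synthetic study and one pipeline run
shared by the recovery and acceptance tests."""

from __future__ import annotations

import warnings

import pytest

from milncnet.pipeline import PipelineConfig, PipelineRun
from milncnet.synthdata import (SynthConfig, generate_dataset,
                                generate_external_dataset)


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def synth_data(synth_config):
    return generate_dataset(synth_config)


@pytest.fixture(scope="session")
def external_data(synth_config):
    return generate_external_dataset(synth_config)


@pytest.fixture(scope="session")
def pipeline_run(synth_data, external_data, tmp_path_factory) -> PipelineRun:
    """Full default pipeline on the default synthetic study, run once."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(outdir=str(outdir), seed=1, beta=6)
    run = PipelineRun(
        config,
        expr=synth_data.expression,
        external=external_data.expression,
        mir_mrna=synth_data.mirna_mrna_edges,
        mir_lnc=synth_data.mirna_lnc_edges,
        drug_targets=synth_data.drug_target_edges,
        ppi=synth_data.ppi_edges,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run.run()
    return run
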