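"""Shared fixtures: one generated synthetic community and its pipeline run."""

from __future__ import annotations

import pytest

from magscreen import pipeline, synthetic


@pytest.fixture(scope="session")
def community(tmp_path_factory):
    """Noise-free default community: (dataset dir, truth manifest, config)."""
    outdir = tmp_path_factory.mktemp("community")
    config = synthetic.default_community(seed=20180907)
    manifest = synthetic.generate_community(config, outdir)
    return outdir, manifest, config


@pytest.fixture(scope="session")
def pipeline_run(community, tmp_path_factory):
    """Full pipeline result over the session community."""
    dataset_dir, manifest, config = community
    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = pipeline.PipelineConfig(dataset_dir=str(dataset_dir), outdir=str(outdir))
    result = pipeline.run_pipeline(cfg)
    return result, manifest, outdir
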