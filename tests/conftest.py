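"""Shared fixtures: one synthetic study bundle and one full pipeline run.

The bundle is deterministic (exact planted counts) so pipeline output can be
compared against ground truth exactly; a second stochastic bundle covers
sampling behaviour.  Both are session-scoped: the pipeline runs once.
"""

from __future__ import annotations

import os

import pytest

from mirswim.pipeline import RunConfig, run_all
from mirswim.synth import SyntheticConfig, build_genome, write_bundle

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def det_config() -> SyntheticConfig:
    return SyntheticConfig(seed=FIXTURE_SEED, deterministic_counts=True)


@pytest.fixture(scope="session")
def det_bundle(det_config):
    return build_genome(det_config)


@pytest.fixture(scope="session")
def det_paths(det_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synth_det")
    return write_bundle(det_bundle, outdir)


@pytest.fixture(scope="session")
def pipeline_result(det_bundle, det_paths, tmp_path_factory):
    cfg = det_bundle.config
    outdir = tmp_path_factory.mktemp("pipeline_det")
    rc = RunConfig(
        fastq={"HIST": det_paths["fastq_HIST"], "NC": det_paths["fastq_NC"]},
        genome=det_paths["genome"],
        annotation=det_paths["annotation_bed"],
        reference=det_paths["reference"],
        families=det_paths["families"],
        adapter3=cfg.adapter3,
        adapter5=cfg.adapter5,
        output_dir=str(outdir),
        seed=FIXTURE_SEED,
    )
    return run_all(rc), outdir
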