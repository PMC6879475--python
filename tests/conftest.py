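"""Shared fixtures: a seeded synthetic study quantified end-to-end.

The study fixture is session-scoped because generating and quantifying
a six-animal, four-week, two-modality, two-replicate study is the
expensive part of the suite; every test that needs end-to-end results
shares one run.
"""

import numpy as np
import pytest

from cnvquant.pipeline import PipelineConfig, run_compare_modalities, run_quantify
from cnvquant.synthetic import SimulationConfig, generate_study

STUDY_SEED = 20


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """A 6-animal study (one per arm x route), generated and quantified."""
    out = tmp_path_factory.mktemp("study")
    config = SimulationConfig(seed=STUDY_SEED).scaled(
        animals_per_drug_arm=1, animals_per_control_arm=1
    )
    manifest, truth = generate_study(config, out)
    result = run_quantify(manifest, PipelineConfig(), base_dir=out, out_dir=out / "meas")
    agreement = run_compare_modalities(result.table)
    return {
        "config": config,
        "manifest": manifest,
        "truth": truth,
        "result": result,
        "agreement": agreement,
        "dir": out,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
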