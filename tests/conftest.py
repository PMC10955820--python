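"""Shared fixtures.

The expensive artifacts — the glyph corpus, the trained backbone, and the
complete scaled-down pipeline run — are session-scoped and shared across
test modules, so the whole suite performs stage 1-3 training exactly once.
"""

import numpy as np
import pytest

from hybriclass import features, pipeline

#: Study conditions of the scaled-down experiment: 10 classes x 200
#: training images, 100 queries, 20,000 balanced predictor pairs.
PIPELINE_SEED = 7


@pytest.fixture(scope="session")
def pipeline_config():
    return pipeline.PipelineConfig(seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def glyph_corpus(pipeline_config):
    return pipeline.make_corpus(pipeline_config)


@pytest.fixture(scope="session")
def trained_backbone(pipeline_config, glyph_corpus):
    model, history = pipeline.stage1_backbone(pipeline_config, glyph_corpus)
    model.history = history
    return model


@pytest.fixture(scope="session")
def full_run(pipeline_config):
    """The complete three-stage pipeline plus evaluation, run once."""
    return pipeline.run_full(pipeline_config)
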