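import numpy as np
import pytest

import organoid_profiler as op
from organoid_profiler.config import MarkerConfig, PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_scene():
    """A noise-free rendered section with 20 well-separated nuclei and a
    known GFAP-positive fraction, plus one TH and one TUJ1 tube."""
    spec = op.SyntheticSceneSpec(
        seed=7,
        n_nuclei=20,
        noise_sd=0.0,
        marker_positive_fraction={op.GFAP: 0.4},
        n_neurites={op.TH: 1, op.TUJ1: 1},
    )
    return op.render_scene(spec)


@pytest.fixture
def fixed_threshold_config():
    """Pipeline config with fixed marker thresholds midway between the
    renderer's background (100) and foreground (1000) intensities."""
    cfg = PipelineConfig()
    cfg.marker_overrides = {
        role: MarkerConfig(threshold_method="fixed", fixed_threshold=550.0)
        for role in (op.GFAP, op.S100B, op.TH, op.TUJ1)
    }
    return cfg


def make_features(organoid_id="o1", line_id="H", section_index=0, **kw):
    """SectionFeatures factory with plausible defaults for QC/stats tests."""
    defaults = dict(
        n_cells=20,
        nuclear_pixels=6000,
        gfap_percentage=40.0,
        s100b_percentage=25.0,
        tuj1_pixels=1500.0,
        th_fragmentation=0.8,
    )
    defaults.update(kw)
    return op.SectionFeatures(
        organoid_id=organoid_id,
        line_id=line_id,
        section_index=section_index,
        **defaults,
    )
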