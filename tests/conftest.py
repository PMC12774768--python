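import math

import pytest

from scst.geometry import EmbryoModelConfig, example_e75_config
from scst import synthetic


@pytest.fixture(scope="session")
def e75_config():
    return example_e75_config()


@pytest.fixture(scope="session")
def small_config():
    """Compact 3-layer model (40 positions) for replicate-heavy tests."""
    return EmbryoModelConfig.from_ratios(
        stage="TEST",
        proximal_distal_length=5.0,
        outer_diameter=5.0,
        end_mes_ratio=1.2,
        mes_ect_ratio=1.2,
        n_sections=5,
        sector_schemes={
            "ectoderm": [("P", 0.0), ("R", math.pi / 2), ("A", math.pi), ("L", -math.pi / 2)],
            "mesoderm": [("MP", 0.0), ("MA", math.pi)],
            "endoderm": [("EP", 0.0), ("EA", math.pi)],
        },
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return synthetic.make_reference(small_config, n_genes=120, n_domains=4,
                                    markers_per_domain=10, seed=11)


@pytest.fixture(scope="session")
def e75_atlas(e75_config):
    return synthetic.make_reference(e75_config, seed=11)
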