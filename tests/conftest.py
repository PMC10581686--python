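import numpy as np
import pytest

import biointerest as bi


@pytest.fixture(scope="session")
def small_cfg():
    """A compact study system: 5 phyla x 3 classes x 3 orders, 8 realms."""
    return bi.GeneratorConfig(seed=42, n_phyla=5, classes_per_phylum=3,
                              orders_per_class=3)


@pytest.fixture(scope="session")
def profiles_small(small_cfg):
    """800 species with traits, counts and known truth (shared, read-only)."""
    species = bi.gen_species_frame(small_cfg, 800)
    prof, truth = bi.gen_profiles(species, small_cfg)
    return prof, truth


@pytest.fixture(scope="session")
def backbone_small():
    cfg = bi.GeneratorConfig(seed=7, n_phyla=4, classes_per_phylum=2,
                             orders_per_class=2, order_size_law=("lognormal", 4.0, 1.0))
    return bi.gen_backbone(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
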