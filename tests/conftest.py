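import pytest

from killerkit import maturation, synthetic


@pytest.fixture(scope="session")
def k1_config():
    return maturation.load_toxin_config("K1")


@pytest.fixture(scope="session")
def planted_preprotoxin():
    """A synthetic preprotoxin with its planted ground truth (seed 7)."""
    return synthetic.gen_preprotoxin(synthetic.PreprotoxinSpec(seed=7))


@pytest.fixture(scope="session")
def ideal_helix():
    return synthetic.gen_ideal_backbone(20, -57.0, -47.0)


@pytest.fixture(scope="session")
def planted_hit_tables():
    spec = synthetic.HitTableSpec(seed=3, out_of_range_per_query=4)
    return synthetic.gen_hit_tables(spec)
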