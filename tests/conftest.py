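import pytest

from cladekey import SimConfig, extract_region, simulate_reference_set


def small_config(seed=0, **overrides):
    """A fast survey configuration for unit tests: short gene, few stations."""
    defaults = dict(
        seed=seed,
        n_clades=4,
        members_per_clade=(1, 3),
        gene_length=300,
        region_span=(150, 229),
        diagnostics_per_clade=(1, 3),
        variant_clade_prob=0.25,
        n_stations=10,
        depth_range=(1000, 3000),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def small_cfg():
    return small_config(seed=0)


@pytest.fixture
def small_reference(small_cfg):
    aln, clades, truth = simulate_reference_set(small_cfg)
    region = extract_region(aln, cols=small_cfg.region_span)
    return small_cfg, aln, clades, region, truth
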