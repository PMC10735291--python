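import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=40,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """Default five-family succession straddling both splits (500 copies)."""
    from malrkit.simulate import default_scenario, simulate_succession

    tree, families = default_scenario()
    return simulate_succession(tree, families, seed=2025)


@pytest.fixture(scope="session")
def default_entities(default_bundle):
    from malrkit.formats import group_entities

    return group_entities(default_bundle.copies[default_bundle.tree.focal])


@pytest.fixture(scope="session")
def tint_bundle():
    """Disjoint-window succession with an ancient anchor family."""
    from malrkit.simulate import simulate_succession, tint_scenario

    tree, families, focal = tint_scenario()
    bundle = simulate_succession(tree, families, seed=11, nest_prob=0.35)
    return bundle, focal
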