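import pytest

from glycotraits.synthetic_data import SynthConfig, generate_cohort, write_fixture_set
from glycotraits.trait_engine import default_rules


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (19 samples, ~20 glycans per class)."""
    return generate_cohort(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_cohort():
    return generate_cohort(
        SynthConfig(seed=2, dirichlet_concentration=None, expression_noise_sd=0.0)
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """On-disk TSV bundle written by the generator."""
    out = tmp_path_factory.mktemp("fixtures")
    paths = write_fixture_set(SynthConfig(seed=7), out)
    return paths


def random_tree(rng, max_depth=3, max_children=3):
    """Random glycan tree for round-trip properties (test-local generator)."""
    from glycotraits.glycan_model import GlycanStructure, Residue

    monos = ["Gal", "GlcNAc", "GalNAc", "Man", "Fuc", "Neu5Ac", "Glc"]

    def build(depth, linkage):
        anomer = rng.choice(["a", "b"])
        carbon = rng.choice(["1", "2"])
        residue = Residue(
            monosaccharide=str(rng.choice(monos)),
            anomericity=str(anomer) if linkage else "?",
            anomeric_carbon=str(carbon) if linkage else "?",
            linkage_position=str(rng.integers(2, 9)) if linkage else "?",
        )
        node = GlycanStructure(residue=residue)
        if depth < max_depth:
            for _ in range(rng.integers(0, max_children + 1)):
                node.children.append(build(depth + 1, linkage=True))
        return node

    return build(0, linkage=False)
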