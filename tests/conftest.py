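import pytest

from hgtscan.simulate import build_toy_taxonomy


@pytest.fixture(scope="session")
def toy_tree():
    """Small fixed taxonomy: root / 2 superkingdoms / host + 3 microbial genera."""
    tree, species = build_toy_taxonomy()
    return tree


@pytest.fixture(scope="session")
def deep_tree():
    """Hand-built chain tree 1→2→10→{11,12} for LCA/genus walk tests."""
    from hgtscan.taxonomy import TaxonomyTree

    t = TaxonomyTree()
    t.add_node(1, 1, "root", "root")
    t.add_node(2, 1, "superkingdom", "Bacteria")
    t.add_node(10, 2, "genus", "Genusia")
    t.add_node(11, 10, "species", "Genusia alpha")
    t.add_node(12, 10, "species", "Genusia beta")
    t.validate()
    return t
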