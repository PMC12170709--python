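"""Molecule representation: canonical equality, classification, codec."""

import itertools
import random

import networkx as nx
import pytest

from nogmap.molecules import (
    BIPHOSPHATE, CARBOHYDRATE, MONOPHOSPHATE, OTHER_SMALL,
    Molecule, MoleculeError, UnsupportedStructureError,
    canonical_key, chain_to_graph, classify, named, parse_molecule, registry,
)


@pytest.mark.parametrize("code,carbons,category", [
    ("F6P", 6, MONOPHOSPHATE),
    ("H2O", 0, OTHER_SMALL),
    ("FBP", 6, BIPHOSPHATE),
    ("Pi", 0, OTHER_SMALL),
    ("fructose", 6, CARBOHYDRATE),
    ("glycolaldehyde", 2, CARBOHYDRATE),
    ("formaldehyde", 1, OTHER_SMALL),
    ("AcH", 2, OTHER_SMALL),
    ("HPA", 3, OTHER_SMALL),
    ("AcP", 2, MONOPHOSPHATE),
])
def test_parse_examples(code, carbons, category):
    m = named(code)
    assert m.carbon_count == carbons
    assert m.category == category


def test_stereoisomers_share_one_graph():
    # erythrose/threose and ribulose-5P/xylulose-5P differ only in stereo
    assert parse_molecule("khhh").canonical_key == parse_molecule("hhhk").canonical_key
    ru5p = parse_molecule("hkhhp")   # ribulose-5-phosphate
    x5p = named("X5P")               # xylulose-5-phosphate
    assert ru5p.canonical_key == x5p.canonical_key


def test_relabeling_invariance():
    rng = random.Random(7)
    g = chain_to_graph(tuple("hkhhhp"))
    key = canonical_key(g)
    for _ in range(5):
        nodes = list(g.nodes)
        rng.shuffle(nodes)
        mapping = {v: i for i, v in enumerate(nodes)}
        assert canonical_key(nx.relabel_nodes(g, mapping)) == key


def _random_molecule_graph(rng, n):
    """Random connected multigraph-ish structure over C/O/P with bond orders."""
    g = nx.Graph()
    elements = [rng.choice("CCOP") for _ in range(n)]
    for i, el in enumerate(elements):
        g.add_node(i, element=el)
    for i in range(1, n):
        j = rng.randrange(i)
        g.add_edge(i, j, order=rng.choice((1, 1, 2)))
    extra = rng.randrange(2)
    for _ in range(extra):
        i, j = rng.randrange(n), rng.randrange(n)
        if i != j and not g.has_edge(i, j):
            g.add_edge(i, j, order=1)
    return g


def _isomorphic(g1, g2):
    return nx.is_isomorphic(
        g1, g2,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )


def test_canonical_key_matches_isomorphism_oracle():
    """Key equality <-> graph isomorphism on random small graphs."""
    rng = random.Random(2024)
    graphs = [_random_molecule_graph(rng, rng.randrange(2, 9))
              for _ in range(40)]
    keys = [canonical_key(g) for g in graphs]
    for (g1, k1), (g2, k2) in itertools.combinations(zip(graphs, keys), 2):
        assert (k1 == k2) == _isomorphic(g1, g2)


def test_roundtrip_every_registry_molecule():
    for name in registry():
        m = named(name)
        again = parse_molecule(m.serialize())
        assert again.canonical_key == m.canonical_key


def test_classify_partitions_molecule_set(net):
    cats = {CARBOHYDRATE, MONOPHOSPHATE, BIPHOSPHATE, OTHER_SMALL}
    counted = net.census()
    assert set(counted) == cats
    assert sum(counted.values()) == len(net.molecules)
    for m in net.molecules.values():
        assert m.category in cats


@pytest.mark.parametrize("bad", ["", "zzz", "khz", "xax"])
def test_malformed_codes_rejected(bad):
    with pytest.raises(MoleculeError):
        parse_molecule(bad)


def test_interior_acyl_state_rejected():
    with pytest.raises(MoleculeError, match="terminal"):
        parse_molecule("hah")


def test_branched_molecule_has_no_linear_code():
    g = nx.Graph()
    for i, el in enumerate("CCCC"):
        g.add_node(i, element=el)
    g.add_edge(0, 1, order=1)
    g.add_edge(1, 2, order=1)
    g.add_edge(1, 3, order=1)  # branch at atom 1
    m = Molecule.from_graph(g)
    with pytest.raises(UnsupportedStructureError):
        m.serialize()


def test_valence_violation_raises():
    g = nx.Graph()
    g.add_node(0, element="O")
    for i in (1, 2, 3):
        g.add_node(i, element="C")
        g.add_edge(0, i, order=1)  # oxygen with three bonds
    with pytest.raises(MoleculeError, match="valence"):
        Molecule.from_graph(g)


def test_smiles_roundtrip_preserves_identity():
    rdkit = pytest.importorskip("rdkit")
    from nogmap.molecules import from_smiles, to_smiles

    f6p = named("F6P")
    again = from_smiles(to_smiles(f6p))
    assert again.canonical_key == f6p.canonical_key
    assert again.formula == f6p.formula
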