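"""Enzyme rule templates: embeddings, products, balance, inverses."""

from collections import Counter

import pytest

from nogmap.molecules import named, parse_molecule
from nogmap.network import reaction_from_parts
from nogmap.rules import (
    Aldolase, AldoseKetose, KetoseAldose, Phosphohydrolase, Phosphoketolase,
    RuleConfig, Transaldolase, Transketolase, default_rules,
)


def products_of(rule, educts):
    return [Counter(p.serialize() for p in emb.products)
            for emb in rule.applicable_embeddings(educts)]


def codes(*names):
    return Counter(parse_molecule(n).serialize() for n in names)


def test_pk_reproduces_the_three_published_templates(mols):
    """Xpk/Fpk/Spk: ketose-P + Pi -> AcP + two-carbon-shorter aldose + H2O."""
    pk = Phosphoketolase(RuleConfig())
    for ketose, aldose in [("X5P", "G3P"), ("F6P", "E4P"), ("S7P", "R5P")]:
        prods = products_of(pk, (mols[ketose], mols["Pi"]))
        assert codes(aldose, "AcP", "H2O") in prods


def test_pk_far_side_cleavage_yields_hydroxypropionyl_phosphate(mols):
    pk = Phosphoketolase(RuleConfig())
    prods = products_of(pk, (mols["F6P"], mols["Pi"]))
    assert codes("HPA-P", "G3P", "H2O") in prods
    # classic-only configuration has exactly the one template embedding
    classic = Phosphoketolase(RuleConfig(pk_both_sides=False))
    assert products_of(classic, (mols["F6P"], mols["Pi"])) == [
        codes("E4P", "AcP", "H2O")
    ]


def test_pk_on_erythrulose_phosphate(mols):
    pk = Phosphoketolase(RuleConfig())
    prods = products_of(pk, (mols["Eu4P"], mols["Pi"]))
    assert codes("Gly2P", "AcP", "H2O") in prods


def test_phl_requires_a_phosphoester(mols):
    phl = Phosphohydrolase(RuleConfig())
    assert phl.applicable_embeddings((mols["H2O"], mols["H2O"])) == []
    prods = products_of(phl, (mols["FBP"], mols["H2O"]))
    assert codes("F6P", "Pi") in prods
    assert codes("AcH", "Pi") in products_of(phl, (mols["AcP"], mols["H2O"]))


def test_aldolase_addition(mols):
    al = Aldolase(RuleConfig())
    assert products_of(al, (mols["DHAP"], mols["G3P"])) == [codes("FBP")]
    assert codes("SBP") in products_of(al, (mols["E4P"], mols["DHAP"]))
    assert codes("XBP") in products_of(al, (mols["Gly2P"], mols["DHAP"]))


def test_transfer_rules(mols):
    tal = Transaldolase(RuleConfig())
    assert codes("G3P", "S7P") in products_of(tal, (mols["F6P"], mols["E4P"]))
    tkl = Transketolase(RuleConfig())
    assert codes("E4P", "X5P") in products_of(tkl, (mols["F6P"], mols["G3P"]))
    # the Gly2P acceptor variant used by the published FBP pathway
    assert codes("X5P", "G3P") in products_of(tal, (mols["Gly2P"], mols["F6P"]))


def test_isomerase_pair_are_mutual_inverses(mols):
    alke, keal = AldoseKetose(RuleConfig()), KetoseAldose(RuleConfig())
    for aldose, ketose in [("G3P", "DHAP"), ("R5P", "X5P"), ("E4P", "Eu4P")]:
        fwd = products_of(alke, (mols[aldose],))
        assert codes(ketose) in fwd
        back = products_of(keal, (mols[ketose],))
        assert codes(aldose) in back


def test_apply_produces_balanced_tagged_reaction(mols):
    pk = Phosphoketolase(RuleConfig())
    educts = (mols["S7P"], mols["Pi"])
    emb = next(e for e in pk.applicable_embeddings(educts)
               if Counter(p.serialize() for p in e.products)
               == codes("R5P", "AcP", "H2O"))
    rx = pk.apply(educts, emb)
    assert rx.rules == {"PK"}
    assert Counter(rx.educts) == Counter(
        m.canonical_key for m in educts)


def test_balance_checker_rejects_unbalanced():
    from nogmap.network import BalanceError

    with pytest.raises(BalanceError):
        reaction_from_parts([named("F6P")], [named("G3P")], "bogus")


def test_embedding_deduplication():
    """Symmetric matches collapse to one embedding per product multiset."""
    phl = Phosphohydrolase(RuleConfig())
    fbp = named("FBP")  # two phosphoesters, two distinct products
    prods = products_of(phl, (fbp, named("H2O")))
    assert len(prods) == len({frozenset(p.items()) for p in prods})


def test_default_rules_respect_enabled_set():
    cfg = RuleConfig(enabled=frozenset({"PHL", "PK"}))
    tags = {r.abbrev for r in default_rules(cfg)}
    assert tags == {"PHL", "PK"}
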