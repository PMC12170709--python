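"""Hyperflow ILP: model building, exhaustive enumeration, characterization."""

from collections import Counter

import pytest

from nogmap.molecules import named
from nogmap.network import default_network, expand
from nogmap.pathways import (
    FlowQuery, ILPModel, Pathway, QueryError, build_model, characterize,
    enumerate_pathways,
)
from nogmap.rules import RuleConfig
from nogmap.thermo import reaction_id_of


def rid_index(net):
    return {reaction_id_of(r, net): i for i, r in enumerate(net.reactions)}


NOG_QUERY = FlowQuery(inflow={"F6P": 1}, outflow={"AcP": 3}, max_total=8)


def test_nog_model_optimum_is_seven(net):
    model = build_model(net, NOG_QUERY)
    flows = model.solve(objective="total_flow")
    assert flows is not None
    assert sum(flows.values()) == 7


def test_empty_query_zero_flow_optimal(net):
    q = FlowQuery(inflow={}, outflow={}, max_total=4)
    model = build_model(net, q)
    flows = model.solve()
    assert flows == {}


def test_unknown_molecule_raises(net):
    q = FlowQuery(inflow={"hhbx": 1}, outflow={"AcP": 1})
    with pytest.raises(QueryError):
        build_model(net, q)


def test_acp_unreachable_without_pk():
    cfg = RuleConfig(enabled=frozenset({"AL", "AlKe", "KeAl", "PHL",
                                        "TAL", "TKL"}))
    net = expand([named(c) for c in ("F6P", "Pi", "H2O")], config=cfg)
    # acetylphosphate is only ever produced by phosphoketolase
    assert all(m.serialize() != "ab" for m in net.molecules.values())


def test_every_enumerated_pathway_conserves_mass(nog_pathways):
    for p in nog_pathways:
        p.check_conservation()  # raises on any nonzero residual


def test_scaled_flow_violates_unit_inflow(net, nog_pathways):
    p = nog_pathways[0]
    doubled = Pathway(
        flows={i: 2 * f for i, f in p.flows.items()},
        exchange=p.exchange,  # still claims inflow F6P = 1
        net=net,
    )
    with pytest.raises(AssertionError):
        doubled.check_conservation()


def test_enumeration_deterministic(net):
    q = FlowQuery(inflow={"F6P": 1}, outflow={"AcP": 3}, max_total=7)
    a = [p.flow_vector() for p in enumerate_pathways(net, q)]
    b = [p.flow_vector() for p in enumerate_pathways(net, q)]
    assert a == b


def test_no_good_cut_excludes_only_the_incumbent(net):
    model = ILPModel(net, NOG_QUERY)
    first = model.solve(total=7)
    model.add_no_good_cut(first)
    second = model.solve(total=7)
    assert second is not None and second != first
    model.add_no_good_cut(second)
    assert model.solve(total=7) is None  # only two length-7 solutions exist


def classic_eleven_step_pathway(net):
    """The classic 11-reaction NOG pathway, encoded as hyperflows."""
    idx = rid_index(net)
    flows = {
        idx["hkhhhp+khhp->hkhhhhp+khp"]: 1,          # TAL: F6P+E4P -> S7P+G3P
        idx["hkhhhhp+khp->hkhhp+khhhp"]: 1,       # TKL: S7P+G3P -> X5P+R5P
        idx["hkhhp+khhp->hkhhhp+khp"]: 2,            # TKL: X5P+E4P -> F6P+G3P
        idx["hkhhhp+phosphate->ab+khhp+water"]: 3,   # Fpk
        idx["khhhp->hkhhp"]: 1,                   # AlKe: R5P -> X5P
        idx["khp->hkp"]: 1,                       # AlKe: G3P -> DHAP
        idx["hkp+khp->phhhkp"]: 1,                # AL: DHAP+G3P -> FBP
        idx["phhhkp+water->hkhhhp+phosphate"]: 1,    # PHL: FBP -> F6P
    }
    p = Pathway(flows=flows, net=net, exchange={
        named("F6P").canonical_key: (1, 0),
        named("AcP").canonical_key: (0, 3),
        named("Pi").canonical_key: (2, 0),
        named("H2O").canonical_key: (0, 2),
    })
    p.check_conservation()
    return p


def triple_phosphoketolase_pathway(net):
    """The three-phosphoketolase pathway (Xpk, Fpk and Spk once each)."""
    idx = rid_index(net)
    flows = {
        idx["hkhhhp+khhp->hkhhhhp+khp"]: 1,            # TAL
        idx["hkhhhhp+phosphate->ab+khhhp+water"]: 1,  # Spk
        idx["khhhp->hkhhp"]: 1,                     # AlKe: R5P -> X5P
        idx["hkhhp+phosphate->ab+khp+water"]: 1,    # Xpk
        idx["khp->hkp"]: 1,                         # AlKe: G3P -> DHAP
        idx["hkp+khp->phhhkp"]: 1,                  # AL
        idx["phhhkp+water->hkhhhp+phosphate"]: 1,      # PHL
        idx["hkhhhp+phosphate->ab+khhp+water"]: 1,     # Fpk
    }
    p = Pathway(flows=flows, net=net, exchange={
        named("F6P").canonical_key: (1, 0),
        named("AcP").canonical_key: (0, 3),
        named("Pi").canonical_key: (2, 0),
        named("H2O").canonical_key: (0, 2),
    })
    p.check_conservation()
    return p


def test_characterize_classic_eleven_step_pathway(net):
    stats = characterize(classic_eleven_step_pathway(net), net)
    assert stats.n_reactions == 11
    assert stats.n_hyperedges == 8
    assert stats.pk_tuple == (0, 3, 0)
    assert stats.n_bimolecular == 9
    assert stats.n_two_sugar == 5


def test_characterize_three_phosphoketolase_pathway(net):
    stats = characterize(triple_phosphoketolase_pathway(net), net)
    assert stats.n_reactions == 8
    assert stats.n_hyperedges == 8
    assert stats.pk_tuple == (1, 1, 1)
    assert stats.n_bimolecular == 6
    assert stats.n_two_sugar == 2


def test_zero_pathway_all_zero_stats(net):
    p = Pathway(flows={}, exchange={}, net=net)
    stats = characterize(p, net)
    assert (stats.n_reactions, stats.n_hyperedges, stats.n_bimolecular) == (0, 0, 0)
    assert stats.pk_tuple == (0, 0, 0)


def test_phosphate_constraint_excludes_free_sugars(net):
    admissible = set()
    q = NOG_QUERY
    from nogmap.pathways import admissible_reactions

    for i in admissible_reactions(net, q):
        r = net.reactions[i]
        for k in (*r.educts, *r.products):
            admissible.add(k)
    assert all(net.molecules[k].category != "carbohydrate"
               for k in admissible)
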