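"""Free energies: fixture values, ratios, state-function invariance."""

import math
import random

import pytest

from nogmap.molecules import named
from nogmap.pathways import FlowQuery, enumerate_pathways
from nogmap.thermo import (
    CoverageError, DeltaGTable, PotentialTable, boltzmann_ratio,
    equilibrium_ratio, paper_delta_g_table, paper_product_preference,
    pathway_profile, reaction_delta_g, reaction_id, reaction_id_of,
)

PRINTED = {
    "X5P+Pi->G3P+AcP+H2O": -44.376,   # Xpk
    "F6P+Pi->E4P+AcP+H2O": -49.666,   # Fpk
    "S7P+Pi->R5P+AcP+H2O": -53.887,   # Spk
    "XBP+H2O->X5P+Pi": 7.386,
    "SBP+H2O->S7P+Pi": 0.576,
    "FBP+H2O->F6P+Pi": -0.0322,
    "Gly2P+F6P->X5P+G3P": 4.27,
    "F6P+E4P->G3P+S7P": 2.72,
}


def test_fixture_reproduces_every_printed_value(net):
    dg = paper_delta_g_table()
    by_id = {reaction_id_of(r, net): r for r in net.reactions}
    for human, value in PRINTED.items():
        lhs, rhs = human.split("->")
        rid = reaction_id(lhs.split("+"), rhs.split("+"))
        assert rid in by_id, f"{human} not a network reaction"
        assert reaction_delta_g(by_id[rid], net, dg=dg) == pytest.approx(value)


def test_potential_table_difference_and_antisymmetry(net):
    rng = random.Random(11)
    pot = PotentialTable({k: rng.uniform(-900, -100) for k in net.molecules})
    for r in net.reactions[:40]:
        g_fwd = reaction_delta_g(r, net, pot=pot)
        from nogmap.network import Reaction

        rev = Reaction(r.products, r.educts, r.rules)
        assert reaction_delta_g(rev, net, pot=pot) == pytest.approx(-g_fwd)


def test_missing_coverage_reports_molecules(net):
    pot = PotentialTable({named("F6P").canonical_key: -100.0})
    r = next(x for x in net.reactions if named("F6P").canonical_key in x.educts)
    with pytest.raises(CoverageError):
        reaction_delta_g(r, net, pot=pot)
    with pytest.raises(CoverageError):
        reaction_delta_g(r, net)


@pytest.mark.parametrize("dg,t,expected,tol", [
    (0.576, 300.0, 1.26, 0.01),
    (7.386, 300.0, 19.32, 0.02),
    (0.0, 500.0, 1.0, 1e-12),
])
def test_equilibrium_ratio_published_values(dg, t, expected, tol):
    assert equilibrium_ratio(dg, t) == pytest.approx(expected, abs=tol)


def test_boltzmann_ratio_sign_convention():
    assert boltzmann_ratio(-10.0) > 1.0       # favorable -> products likelier
    assert boltzmann_ratio(+10.0) < 1.0
    assert boltzmann_ratio(0.0) == 1.0
    assert boltzmann_ratio(3.3) * boltzmann_ratio(-3.3) == pytest.approx(1.0)


def test_equilibrium_and_boltzmann_are_reciprocal():
    for dg in (-25.0, -0.5, 0.576, 7.386):
        assert equilibrium_ratio(dg) == pytest.approx(1 / boltzmann_ratio(dg))


def test_product_preference_statistic():
    v = paper_product_preference(-236.75, -114.28)
    assert round(v) == 8
    assert paper_product_preference(3.0, 3.0) == pytest.approx(math.e)
    # high-precision cross-check with an independent evaluator
    import sympy

    exact = sympy.exp(sympy.Rational("-236.75") / sympy.Rational("-114.28"))
    assert v == pytest.approx(float(exact.evalf(20)), rel=1e-12)


def test_net_delta_g_is_a_state_function(net, nog_pathways):
    """All pathways implementing the same overall reaction share one net."""
    rng = random.Random(3)
    pot = PotentialTable({k: rng.uniform(-900, -100) for k in net.molecules})
    f6p, acp = named("F6P").canonical_key, named("AcP").canonical_key
    pi, h2o = named("Pi").canonical_key, named("H2O").canonical_key
    overall = (3 * pot.get(acp) + 2 * pot.get(h2o)
               - pot.get(f6p) - 2 * pot.get(pi))
    for p in nog_pathways:
        prof = pathway_profile(p, net, pot=pot)
        assert prof.net == pytest.approx(overall, abs=1e-9)


def test_profile_order_invariance_and_bottlenecks(net, nog_pathways):
    rng = random.Random(4)
    pot = PotentialTable({k: rng.uniform(-900, -100) for k in net.molecules})
    p = nog_pathways[0]
    base = pathway_profile(p, net, pot=pot)
    order = [i for i, f in sorted(p.flows.items()) for _ in range(f)]
    rng.shuffle(order)
    shuffled = pathway_profile(p, net, order=order, pot=pot)
    assert shuffled.net == pytest.approx(base.net)
    # bottleneck set == steps with positive DrG
    for prof in (base, shuffled):
        for j, (_, _, g) in enumerate(prof.steps):
            assert (j in prof.bottlenecks) == (g > 0)


def test_profile_rejects_inconsistent_order(net, nog_pathways):
    # a pathway with a repeated reaction: listing each reaction only once
    # (ignoring flow multiplicity) must be rejected
    p = next(q for q in nog_pathways
             if q.total_reactions != q.unique_reactions)
    with pytest.raises(ValueError):
        pathway_profile(p, net, order=list(p.flows))


def test_all_negative_profile_has_no_bottleneck(net, nog_pathways):
    dg = DeltaGTable({reaction_id_of(r, net): -1.0 for r in net.reactions})
    prof = pathway_profile(nog_pathways[0], net, dg=dg)
    assert prof.bottlenecks == []
    assert prof.net == pytest.approx(-nog_pathways[0].total_reactions)


def test_tsv_roundtrip():
    dg = paper_delta_g_table()
    again = DeltaGTable.from_tsv(dg.to_tsv())
    assert again.overrides == dg.overrides
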