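"""Thermodynamic feasibility of the phosphoketolase/hydrolysis steps.

Standard reaction free energies (kJ/mol) for the phosphoketolase reactions
and the biphosphate hydrolyses are shipped as a fixture of published
values.  A step with DrG > 0 is a bottleneck; the equilibrium ratio says
what educt/product concentration ratio would bring a slightly uphill
hydrolysis to equilibrium at 300 K.
"""

from nogmap import default_network, equilibrium_ratio, paper_delta_g_table
from nogmap.thermo import reaction_delta_g, reaction_id_of

net = default_network()
dg = paper_delta_g_table()

print("per-reaction standard free energies (fixture):")
for r in net.reactions:
    value = dg.get(reaction_id_of(r, net))
    if value is not None:
        flag = "  <- bottleneck" if value > 0 else ""
        print(f"  {reaction_id_of(r, net):42s} {value:+9.3f} kJ/mol{flag}")

print("\nconcentration ratios bringing the uphill hydrolyses to equilibrium")
print(f"  [SBP]/[S7P] at 300 K : {equilibrium_ratio(0.576, 300):.2f}")
print(f"  [XBP]/[X5P] at 300 K : {equilibrium_ratio(7.386, 300):.2f}")

from nogmap import paper_product_preference
from nogmap.thermo import NET_DELTA_G

pref = paper_product_preference(NET_DELTA_G["nog"], NET_DELTA_G["hpa"])
print(f"\nacetylphosphate vs 3-HPA product preference : {pref:.2f} (~{round(pref)}x)")
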