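"""Enumerate the shortest non-oxidative glycolysis pathways.

The search asks for integer hyperflows converting one fructose-6-phosphate
into three acetylphosphate molecules (100% carbon efficiency: no carbon is
lost as CO2), with water and phosphate freely exchangeable and every
carbohydrate intermediate required to carry a phosphate group.  Exactly two
routes of seven reactions exist: one through sedoheptulose-1,7-biphosphate,
one through xylulose-1,5-biphosphate.
"""

from collections import Counter

from nogmap import FlowQuery, default_network, enumerate_pathways, render_pathway

net = default_network()
query = FlowQuery(inflow={"F6P": 1}, outflow={"AcP": 3}, max_total=8)
pathways = enumerate_pathways(net, query)

groups = Counter((p.total_reactions, p.unique_reactions) for p in pathways)
print("pathways by (total reactions, distinct reactions):")
for (total, unique), n in sorted(groups.items()):
    print(f"  {total} total / {unique} distinct : {n} pathway(s)")

for p in pathways:
    if p.total_reactions == 7:
        bip = ", ".join(sorted(p.biphosphate_used()))
        print(f"\n7-reaction pathway via biphosphate {bip}:")
        print(render_pathway(p, net))
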