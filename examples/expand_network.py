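"""Expand the carbohydrate-phosphate reaction space and print its census.

Starting from fructose-6-phosphate, phosphoric acid and water, the seven
enzyme templates (aldolase, the two aldose/ketose isomerases,
phosphohydrolase, phosphoketolase, transaldolase, transketolase) are
applied recursively until no molecule with at most seven carbons and no
reaction can be added.  The census partitions the molecular space into
carbohydrates, their mono-/bi-phosphates, and small non-sugar species.
"""

from nogmap import default_network

net = default_network()

print(f"molecules : {len(net.molecules)}")
print(f"reactions : {len(net.reactions)}")
for category, count in sorted(net.census().items()):
    print(f"  {category:30s} {count}")

print("\nsmall non-sugar species in the space:")
for m in net.molecules.values():
    if m.category == "other-small":
        label = {"water": "water", "phosphate": "phosphoric acid",
                 "k": "methanal", "bx": "ethanoic acid",
                 "hbx": "3-hydroxypropionic acid"}[m.serialize()]
        print(f"  {m.serialize():12s} {label}")
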