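"""Closure expansion of the molecular space and the reaction hypergraph.

Starting from a seed set, the enabled rule templates are applied
recursively (breadth-first by generation) until no new molecule with at
most ``carbon_cap`` carbons and no new reaction can be added.  A reaction
any of whose products exceeds the cap is discarded entirely: it cannot be
a hyperedge of the bounded network.

Reactions are deduplicated by their (sorted educts, sorted products)
identity; the same transformation produced by two templates is stored once
carrying all contributing rule tags.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .molecules import (
    BIPHOSPHATE, CARBOHYDRATE, MONOPHOSPHATE, OTHER_SMALL,
    Molecule, MoleculeError, parse_molecule,
)
from .rules import DEFAULT_CONFIG, RuleConfig, RuleTemplate, default_rules


class BalanceError(RuntimeError):
    """A rule produced an elementally unbalanced reaction (internal bug)."""


class ExpansionBudgetError(RuntimeError):
    """Runaway growth beyond the configured molecule budget."""


def _formula_sum(mols: Sequence[Molecule]) -> Counter:
    total: Counter = Counter()
    for m in mols:
        total.update(m.formula)
    return total


@dataclass(frozen=True)
class Reaction:
    """A directed hyperedge: educt multiset -> product multiset."""

    educts: Tuple[str, ...]            # sorted canonical keys, with multiplicity
    products: Tuple[str, ...]
    rules: frozenset = frozenset()

    @property
    def key(self) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
        return (self.educts, self.products)

    @property
    def bimolecular(self) -> bool:
        return len(self.educts) == 2

    def educt_counts(self) -> Counter:
        return Counter(self.educts)

    def product_counts(self) -> Counter:
        return Counter(self.products)


def reaction_from_parts(educts: Sequence[Molecule], products: Sequence[Molecule],
                        rule: str) -> Reaction:
    """Build a Reaction and verify elemental conservation (C, O, P, H)."""
    le, rp = _formula_sum(educts), _formula_sum(products)
    if le != rp:
        raise BalanceError(
            f"rule {rule} lost atoms: {dict(le)} -> {dict(rp)} "
            f"({[m.serialize() for m in educts]} -> {[m.serialize() for m in products]})"
        )
    e = tuple(sorted(m.canonical_key for m in educts))
    p = tuple(sorted(m.canonical_key for m in products))
    return Reaction(e, p, frozenset({rule}))


@dataclass
class ReactionNetwork:
    molecules: Dict[str, Molecule]
    reactions: List[Reaction]
    seeds: List[str] = field(default_factory=list)
    carbon_cap: int = 7
    rule_config: RuleConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self):
        for r in self.reactions:
            for k in r.educts + r.products:
                if k not in self.molecules:
                    raise ValueError("reaction references unknown molecule")

    def molecule_by_code(self, code: str) -> Molecule:
        m = parse_molecule(code)
        if m.canonical_key not in self.molecules:
            raise KeyError(f"{code!r} not in network")
        return self.molecules[m.canonical_key]

    def census(self) -> Dict[str, int]:
        """Category -> count partition of the molecule set."""
        counts = {CARBOHYDRATE: 0, MONOPHOSPHATE: 0, BIPHOSPHATE: 0,
                  OTHER_SMALL: 0}
        for m in self.molecules.values():
            counts[m.category] += 1
        return counts

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        mols = {}
        for k, m in self.molecules.items():
            try:
                code = m.serialize()
            except MoleculeError:
                code = None
            mols[k] = {"code": code, "name": m.name,
                       "carbons": m.carbon_count, "category": m.category}
        data = {
            "carbon_cap": self.carbon_cap,
            "rule_config": self.rule_config.to_dict(),
            "seeds": self.seeds,
            "molecules": mols,
            "reactions": [
                {"educts": list(r.educts), "products": list(r.products),
                 "rules": sorted(r.rules)}
                for r in self.reactions
            ],
        }
        return json.dumps(data, indent=1)

    @staticmethod
    def from_json(text: str) -> "ReactionNetwork":
        data = json.loads(text)
        molecules = {}
        for k, spec in data["molecules"].items():
            if spec["code"] is None:
                # abstract token (toy worlds): identity carried by the key
                import networkx as nx

                g = nx.Graph()
                g.add_node(0, element="C")
                molecules[k] = Molecule(
                    graph=g, canonical_key=k, formula={"C": 1},
                    carbon_count=spec.get("carbons", 0),
                    category=spec.get("category", OTHER_SMALL),
                    chain=None, name=spec.get("name"),
                )
                continue
            m = parse_molecule(spec["code"])
            if spec.get("name"):
                m = Molecule(graph=m.graph, canonical_key=m.canonical_key,
                             formula=m.formula, carbon_count=m.carbon_count,
                             category=m.category, chain=m.chain,
                             name=spec["name"])
            if m.canonical_key != k:
                raise ValueError("corrupt network file: key mismatch")
            molecules[k] = m
        reactions = [
            Reaction(tuple(r["educts"]), tuple(r["products"]),
                     frozenset(r["rules"]))
            for r in data["reactions"]
        ]
        return ReactionNetwork(
            molecules, reactions, seeds=data.get("seeds", []),
            carbon_cap=data.get("carbon_cap", 7),
            rule_config=RuleConfig.from_dict(data.get("rule_config", {})),
        )

    def to_graphml(self) -> str:
        """Bipartite molecule-reaction graph for visualization."""
        import networkx as nx

        g = nx.DiGraph()
        for k, m in self.molecules.items():
            label = m.name or (m.chain and "".join(m.chain)) or k[:12]
            g.add_node(k, kind="molecule", label=label, category=m.category)
        for i, r in enumerate(self.reactions):
            rid = f"r{i}"
            g.add_node(rid, kind="reaction", label="+".join(sorted(r.rules)))
            for e in r.educts:
                g.add_edge(e, rid)
            for p in r.products:
                g.add_edge(rid, p)
        import io
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()


def expand(seeds: Iterable[Molecule], rules: Optional[List[RuleTemplate]] = None,
           carbon_cap: int = 7, config: RuleConfig = DEFAULT_CONFIG,
           molecule_budget: int = 20000) -> ReactionNetwork:
    """Compute the closure network (order-independent fixed point).

    Deterministic: molecules are processed in canonical-key order within each
    generation, and the result is a set-level fixed point, so seed order and
    rule order cannot affect the outcome.
    """
    if rules is None:
        rules = default_rules(config)
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set must be nonempty")
    if carbon_cap < 1:
        raise ValueError("carbon_cap must be >= 1")

    molecules: Dict[str, Molecule] = {}
    seed_keys = []
    for s in seeds:
        molecules[s.canonical_key] = s
        seed_keys.append(s.canonical_key)

    reactions: Dict[Tuple, Reaction] = {}
    frontier = sorted(molecules)

    while frontier:
        old = [k for k in sorted(molecules) if k not in set(frontier)]
        new_mols: Dict[str, Molecule] = {}

        def consider(educts: Tuple[Molecule, ...], rule: RuleTemplate):
            for emb in rule.applicable_embeddings(educts):
                prods = emb.products
                if any(p.carbon_count > carbon_cap for p in prods):
                    continue
                rx = rule.apply(educts, emb)
                if rx.educts == rx.products:
                    continue
                prev = reactions.get(rx.key)
                if prev is not None:
                    reactions[rx.key] = Reaction(rx.educts, rx.products,
                                                 prev.rules | rx.rules)
                    continue
                reactions[rx.key] = rx
                for p in prods:
                    if p.canonical_key not in molecules:
                        new_mols.setdefault(p.canonical_key, p)

        for rule in rules:
            if rule.arity == 1:
                for k in frontier:
                    consider((molecules[k],), rule)
            else:
                for a, b in combinations_with_replacement(frontier, 2):
                    consider((molecules[a], molecules[b]), rule)
                for a in frontier:
                    for b in old:
                        consider((molecules[a], molecules[b]), rule)

        molecules.update(new_mols)
        if len(molecules) > molecule_budget:
            raise ExpansionBudgetError(
                f"expansion exceeded {molecule_budget} molecules; "
                "check the rule configuration or raise the budget"
            )
        frontier = sorted(new_mols)

    net = ReactionNetwork(
        molecules, sorted(reactions.values(), key=lambda r: r.key),
        seeds=seed_keys, carbon_cap=carbon_cap, rule_config=config,
    )
    return net


DEFAULT_SEED_CODES = ("F6P", "Pi", "H2O")


def default_network(config: RuleConfig = DEFAULT_CONFIG, carbon_cap: int = 7,
                    seed_codes: Sequence[str] = DEFAULT_SEED_CODES) -> ReactionNetwork:
    """The headline network: default seeds, all seven templates, 7-carbon cap."""
    from .molecules import named

    return expand([named(c) for c in seed_codes], carbon_cap=carbon_cap,
                  config=config)
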