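"""Abstract toy reaction hypergraphs with planted pathways.

Toy molecules are plain tokens (no chemistry) behind the same
:class:`~nogmap.network.ReactionNetwork` interface, so the hyperflow ILP
and the thermodynamic profiler can be exercised and cross-validated against
a brute-force oracle without any molecular-graph machinery.  A planted
pathway (a conservation-valid chain from a source to a sink) is embedded in
every generated network by construction; random distractor reactions are
layered on top.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .molecules import Molecule, OTHER_SMALL
from .network import Reaction, ReactionNetwork
from .pathways import FlowQuery, Pathway


class ToyGenerationError(ValueError):
    """The toy spec cannot be satisfied."""


class OracleBudgetError(RuntimeError):
    """Brute-force enumeration would exceed its search budget."""


def _token(name: str) -> Molecule:
    import networkx as nx

    g = nx.Graph()
    g.add_node(0, element="C")
    m = Molecule(graph=g, canonical_key=f"toy:{name}", formula={"C": 1},
                 carbon_count=0, category=OTHER_SMALL, chain=None, name=name)
    return m


@dataclass(frozen=True)
class ToySpec:
    """Parameters of a generated toy world."""

    n_molecules: int = 6
    n_reactions: int = 6
    chain_length: int = 3          # planted source -> ... -> sink chain
    max_educts: int = 2
    max_products: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.chain_length + 1 > self.n_molecules:
            raise ToyGenerationError("chain does not fit in molecule budget")
        if self.n_reactions < self.chain_length:
            raise ToyGenerationError("reaction budget below planted chain")
        if not (1 <= self.max_educts <= 2 and 1 <= self.max_products <= 3):
            raise ToyGenerationError("educts <= 2 and products <= 3 required")


def toy_molecule_names(spec: ToySpec) -> List[str]:
    return [f"M{i}" for i in range(spec.n_molecules)]


def make_toy_network(spec: ToySpec) -> ReactionNetwork:
    """Reproducible toy network containing the planted chain M0 -> ... -> Mk."""
    rng = np.random.default_rng(spec.seed)
    names = toy_molecule_names(spec)
    mols = {f"toy:{n}": _token(n) for n in names}
    keys = sorted(mols)

    reactions: Dict[Tuple, Reaction] = {}
    # planted chain: M0 -> M1 -> ... -> M{chain_length}
    for i in range(spec.chain_length):
        r = Reaction((f"toy:M{i}",), (f"toy:M{i + 1}",), frozenset({"toy"}))
        reactions[r.key] = r

    attempts = 0
    while len(reactions) < spec.n_reactions and attempts < 1000:
        attempts += 1
        ne = int(rng.integers(1, spec.max_educts + 1))
        np_ = int(rng.integers(1, spec.max_products + 1))
        educts = tuple(sorted(rng.choice(keys, size=ne, replace=True)))
        products = tuple(sorted(rng.choice(keys, size=np_, replace=True)))
        if educts == products:
            continue
        r = Reaction(educts, products, frozenset({"toy"}))
        reactions.setdefault(r.key, r)
    if len(reactions) < spec.n_reactions:
        raise ToyGenerationError("could not place requested reactions")

    return ReactionNetwork(
        molecules=mols,
        reactions=sorted(reactions.values(), key=lambda r: r.key),
        seeds=[f"toy:M0"], carbon_cap=0,
    )


def planted_query(spec: ToySpec, max_total: Optional[int] = None) -> FlowQuery:
    """Query for which the planted chain is a feasible solution."""
    return FlowQuery(
        inflow={"M0": 1},
        outflow={f"M{spec.chain_length}": 1},
        free_exchange=(),
        require_phosphorylated_sugars=False,
        max_total=max_total if max_total is not None else spec.chain_length,
    )


def planted_pathway(spec: ToySpec, net: ReactionNetwork) -> Pathway:
    idx = {}
    for i, r in enumerate(net.reactions):
        idx[r.key] = i
    flows = {}
    for i in range(spec.chain_length):
        key = ((f"toy:M{i}",), (f"toy:M{i + 1}",))
        flows[idx[key]] = 1
    p = Pathway(
        flows=flows,
        exchange={f"toy:M0": (1, 0), f"toy:M{spec.chain_length}": (0, 1)},
        net=net,
    )
    p.check_conservation()
    return p


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_pathways(net: ReactionNetwork, q: FlowQuery, max_total: int,
                         budget: int = 5_000_000) -> Set[Tuple[int, ...]]:
    """Exhaustive enumeration of all feasible integer flow vectors.

    Independent of the ILP path: iterates every flow vector with
    ``sum f_e <= max_total`` (per-edge cap ``max_total``) and keeps those
    satisfying conservation and the query exactly.  Returns the set of full
    flow vectors.  Intended for small instances; raises
    :class:`OracleBudgetError` rather than truncating silently.
    """
    from .pathways import admissible_reactions, ILPModel

    idx = admissible_reactions(net, q)
    n = len(idx)
    cap = min(max_total, q.max_flow_per_reaction or max_total)
    if (cap + 1) ** n > budget:
        raise OracleBudgetError(
            f"{(cap + 1) ** n} flow vectors exceed budget {budget}"
        )

    # stoichiometric matrix over molecules appearing in admissible reactions
    mol_keys = sorted({k for i in idx
                       for k in (*net.reactions[i].educts,
                                 *net.reactions[i].products)}
                      | {m for m in _fixed_keys(net, q)})
    mpos = {k: j for j, k in enumerate(mol_keys)}
    S = np.zeros((len(mol_keys), n), dtype=int)
    for col, i in enumerate(idx):
        r = net.reactions[i]
        for k in r.products:
            S[mpos[k], col] += 1
        for k in r.educts:
            S[mpos[k], col] -= 1

    from .pathways import resolve_molecule
    free = set()
    for c in q.free_exchange:
        key = resolve_molecule(net, c, missing_ok=True)
        if key in mpos:
            free.add(mpos[key])
    rhs = np.zeros(len(mol_keys))
    for c, v in q.inflow.items():
        key = resolve_molecule(net, c)
        if key in mpos:
            rhs[mpos[key]] = -v
    for c, v in q.outflow.items():
        key = resolve_molecule(net, c)
        if key in mpos:
            rhs[mpos[key]] = v
    fixed_rows = [j for j in range(len(mol_keys)) if j not in free]

    # infeasible fixed exchanges on molecules outside the matrix
    for c, v in (*q.inflow.items(), *q.outflow.items()):
        key = resolve_molecule(net, c)
        if key not in mpos and v != 0:
            return set()

    solutions: Set[Tuple[int, ...]] = set()
    n_all = len(net.reactions)
    for vec in itertools.product(range(cap + 1), repeat=n):
        if sum(vec) > max_total:
            continue
        prod = S @ np.array(vec)
        if all(prod[j] == rhs[j] for j in fixed_rows):
            full = [0] * n_all
            for col, i in enumerate(idx):
                full[i] = vec[col]
            solutions.add(tuple(full))
    return solutions


def _fixed_keys(net: ReactionNetwork, q: FlowQuery):
    from .pathways import resolve_molecule

    out = []
    for c in (*q.inflow, *q.outflow):
        key = resolve_molecule(net, c, missing_ok=True)
        if key is not None:
            out.append(key)
    return out
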