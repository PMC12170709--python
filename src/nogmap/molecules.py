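"""Stereo-free molecule representation for carbohydrate-phosphate chemistry.

Molecules are labeled undirected graphs over heavy atoms {C, O, P} with
integer bond orders; hydrogens are implicit and recovered from standard
valences (C=4, O=2, P=5).  Because stereochemistry is not represented,
stereoisomeric sugars (erythrose/threose, ribose/xylose, ribulose/xylulose)
collapse onto a single molecule, which is exactly the identity the reaction
network is built on.

Most network species are *linear* sugars and small acyl compounds, and those
are written in a compact linear code: one letter per backbone carbon, from
C1 to Cn,

    h  hydroxyl        -CH(OH)-          (CHOH / CH2OH)
    k  carbonyl        -C(=O)-           (aldehyde or ketone)
    p  phosphoester    -CH(O-PO3H2)-
    b  bare            -CH2- / -CH3
    x  carboxyl        -C(=O)OH          (terminal only)
    a  acyl phosphate  -C(=O)O-PO3H2     (terminal only)

e.g. ``khp`` is glyceraldehyde-3-phosphate, ``hkhhhp`` fructose-6-phosphate,
``ab`` acetylphosphate.  ``water`` and ``phosphate`` are the two registered
carbon-free species.  Arbitrary (including branched) molecules can be built
through :meth:`Molecule.from_graph`; only linear-backbone molecules are
expressible in the code.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Optional, Tuple

import networkx as nx

VALENCE = {"C": 4, "O": 2, "P": 5}

CHAIN_STATES = frozenset("hkpbxa")
TERMINAL_ONLY_STATES = frozenset("xa")

#: categories used by the network census
CARBOHYDRATE = "carbohydrate"
MONOPHOSPHATE = "carbohydrate-monophosphate"
BIPHOSPHATE = "carbohydrate-biphosphate"
OTHER_SMALL = "other-small"


class MoleculeError(ValueError):
    """Malformed molecule code or graph."""


class UnsupportedStructureError(MoleculeError):
    """Molecule cannot be expressed in the linear code (e.g. branched)."""


# ---------------------------------------------------------------------------
# graph construction helpers
# ---------------------------------------------------------------------------

def _add_phospho_group(g: nx.Graph, ester_o: int) -> None:
    """Attach -PO3H2 to an existing ester oxygen node."""
    p = g.number_of_nodes()
    g.add_node(p, element="P")
    g.add_edge(ester_o, p, order=1)
    o_dbl = p + 1
    g.add_node(o_dbl, element="O")
    g.add_edge(p, o_dbl, order=2)
    for i in (2, 3):
        o = p + i
        g.add_node(o, element="O")
        g.add_edge(p, o, order=1)


def chain_to_graph(states: Tuple[str, ...]) -> nx.Graph:
    """Build the heavy-atom graph of a linear-backbone molecule."""
    g = nx.Graph()
    n = len(states)
    for i in range(n):
        g.add_node(i, element="C")
        if i:
            g.add_edge(i - 1, i, order=1)
    for i, s in enumerate(states):
        if s == "b":
            continue
        o = g.number_of_nodes()
        g.add_node(o, element="O")
        if s == "h":
            g.add_edge(i, o, order=1)
        elif s == "p":
            g.add_edge(i, o, order=1)
            _add_phospho_group(g, o)
        elif s == "k":
            g.add_edge(i, o, order=2)
        elif s == "x":
            g.add_edge(i, o, order=2)
            o2 = g.number_of_nodes()
            g.add_node(o2, element="O")
            g.add_edge(i, o2, order=1)
        elif s == "a":
            g.add_edge(i, o, order=2)
            o2 = g.number_of_nodes()
            g.add_node(o2, element="O")
            g.add_edge(i, o2, order=1)
            _add_phospho_group(g, o2)
        else:  # pragma: no cover - guarded by parse
            raise MoleculeError(f"unknown chain state {s!r}")
    return g


def water_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_node(0, element="O")
    return g


def phosphate_graph() -> nx.Graph:
    """Phosphoric acid, H3PO4, in the fixed neutral protonation state."""
    g = nx.Graph()
    g.add_node(0, element="P")
    g.add_node(1, element="O")
    g.add_edge(0, 1, order=2)
    for i in (2, 3, 4):
        g.add_node(i, element="O")
        g.add_edge(0, i, order=1)
    return g


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def _refine(g: nx.Graph, colors: Dict[int, int]) -> Dict[int, int]:
    """Iterative neighborhood color refinement to a fixed point."""
    nodes = list(g.nodes)
    while True:
        sigs = {}
        for v in nodes:
            nb = sorted((g[v][w]["order"], colors[w]) for w in g[v])
            sigs[v] = (colors[v], tuple(nb))
        ranks = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
        new = {v: ranks[sigs[v]] for v in nodes}
        if new == colors:
            return new
        colors = new


def _certificate(g: nx.Graph, order: Tuple[int, ...]) -> Tuple:
    pos = {v: i for i, v in enumerate(order)}
    edges = sorted(
        (min(pos[u], pos[v]), max(pos[u], pos[v]), d["order"])
        for u, v, d in g.edges(data=True)
    )
    return (tuple(g.nodes[v]["element"] for v in order), tuple(edges))


def _canon_order(g: nx.Graph, colors: Dict[int, int]) -> Tuple:
    """Backtracking canonical labeling; returns the minimal certificate."""
    cells: Dict[int, list] = {}
    for v, c in colors.items():
        cells.setdefault(c, []).append(v)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = cells[c]
            break
    if target is None:
        order = tuple(sorted(g.nodes, key=lambda v: colors[v]))
        return _certificate(g, order)
    n = len(g)
    best = None
    for v in sorted(target):
        branched = dict(colors)
        branched[v] = -1  # individualize
        branched = {u: c + n for u, c in branched.items()}
        cert = _canon_order(g, _refine(g, branched))
        if best is None or cert < best:
            best = cert
    return best


def canonical_key(g: nx.Graph) -> str:
    """Deterministic string, identical for isomorphic graphs.

    Element- and bond-order-preserving isomorphism; invariant under vertex
    relabeling by construction (iterative refinement with full backtracking
    over ties).
    """
    if g.number_of_nodes() == 0:
        raise MoleculeError("empty molecular graph")
    init = {v: 0 for v in g.nodes}
    elems = sorted({g.nodes[v]["element"] for v in g.nodes})
    rank = {e: i for i, e in enumerate(elems)}
    init = {v: rank[g.nodes[v]["element"]] for v in g.nodes}
    elements, edges = _canon_order(g, _refine(g, init))
    parts = ["".join(elements)]
    parts += [f"{i}-{j}:{o}" for i, j, o in edges]
    return "|".join(parts)


# ---------------------------------------------------------------------------
# classification & formula
# ---------------------------------------------------------------------------

def _implicit_h(g: nx.Graph, v: int) -> int:
    el = g.nodes[v]["element"]
    used = sum(d["order"] for _, _, d in g.edges(v, data=True))
    h = VALENCE[el] - used
    if h < 0:
        raise MoleculeError(
            f"valence of {el} exceeded ({used} > {VALENCE[el]}) at atom {v}"
        )
    return h


def formula_of(g: nx.Graph) -> Dict[str, int]:
    f: Dict[str, int] = {}
    h = 0
    for v in g.nodes:
        el = g.nodes[v]["element"]
        f[el] = f.get(el, 0) + 1
        h += _implicit_h(g, v)
    if h:
        f["H"] = h
    return f


def _carbon_features(g: nx.Graph):
    """Per-molecule structural features used by classify()."""
    n_carboxyl = n_carbonyl = n_hydroxyl = 0
    phospho_groups = 0
    for v in g.nodes:
        el = g.nodes[v]["element"]
        if el == "P":
            phospho_groups += any(
                g.nodes[w]["element"] == "O"
                and any(g.nodes[u]["element"] == "C" for u in g[w])
                for w in g[v]
            )
        if el != "C":
            continue
        dbl_o = single_o_term = 0
        for w in g[v]:
            if g.nodes[w]["element"] != "O":
                continue
            if g[v][w]["order"] == 2:
                dbl_o += 1
            elif g.degree(w) == 1:
                single_o_term += 1
        if dbl_o and single_o_term:
            n_carboxyl += 1
        elif dbl_o:
            n_carbonyl += 1
        elif single_o_term:
            n_hydroxyl += 1
    return n_carboxyl, n_carbonyl, n_hydroxyl, phospho_groups


def classify(g: nx.Graph) -> str:
    """Census category of a molecule.

    Phosphates are classified by the number of phospho groups bound through
    an oxygen to carbon (mono- vs bi-phosphates of carbohydrates); among
    phosphorus-free molecules, a carbohydrate is a polyhydroxy carbonyl
    compound -- at least one ketone/aldehyde carbonyl and one hydroxyl, and
    no carboxylic-acid group.  Everything else (water, phosphoric acid,
    formaldehyde, the free acids) is 'other-small'.
    """
    if not any(g.nodes[v]["element"] == "C" for v in g.nodes):
        return OTHER_SMALL
    n_x, n_k, n_h, n_p = _carbon_features(g)
    if n_p == 1:
        return MONOPHOSPHATE
    if n_p == 2:
        return BIPHOSPHATE
    if n_p == 0 and n_x == 0 and n_k >= 1 and n_h >= 1:
        return CARBOHYDRATE
    return OTHER_SMALL


# ---------------------------------------------------------------------------
# Molecule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Molecule:
    graph: nx.Graph = field(compare=False, repr=False)
    canonical_key: str = field(compare=True)
    formula: Dict[str, int] = field(compare=False)
    carbon_count: int = field(compare=False)
    category: str = field(compare=False)
    chain: Optional[Tuple[str, ...]] = field(compare=False, default=None)
    name: Optional[str] = field(compare=False, default=None)

    def __hash__(self) -> int:
        return hash(self.canonical_key)

    @staticmethod
    def from_graph(g: nx.Graph, name: Optional[str] = None,
                   chain: Optional[Tuple[str, ...]] = None) -> "Molecule":
        for v in g.nodes:
            el = g.nodes[v].get("element")
            if el not in VALENCE:
                raise MoleculeError(f"unsupported element {el!r} at atom {v}")
        return Molecule(
            graph=g,
            canonical_key=canonical_key(g),
            formula=formula_of(g),
            carbon_count=sum(1 for v in g.nodes if g.nodes[v]["element"] == "C"),
            category=classify(g),
            chain=chain,
            name=name,
        )

    @property
    def is_sugar_like(self) -> bool:
        """True for any carbohydrate or carbohydrate phosphate."""
        return self.category in (CARBOHYDRATE, MONOPHOSPHATE, BIPHOSPHATE)

    def serialize(self) -> str:
        """Linear MoleculeCode; raises for molecules without one."""
        if self.chain is not None:
            return canonical_chain_code(self.chain)
        if self.canonical_key == WATER.canonical_key:
            return "water"
        if self.canonical_key == PHOSPHATE.canonical_key:
            return "phosphate"
        raise UnsupportedStructureError(
            "molecule has no linear-backbone code (branched or unregistered)"
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = self.name or (self.chain and "".join(self.chain)) or "mol"
        return f"Molecule({label}, C{self.carbon_count}, {self.category})"


def canonical_chain_code(states: Iterable[str]) -> str:
    s = "".join(states)
    return min(s, s[::-1])


def _validate_chain(code: str) -> Tuple[str, ...]:
    for i, ch in enumerate(code):
        if ch not in CHAIN_STATES:
            raise MoleculeError(
                f"malformed molecule code {code!r}: bad token {ch!r} at {i}"
            )
    for i, ch in enumerate(code):
        if ch in TERMINAL_ONLY_STATES and i not in (0, len(code) - 1):
            raise MoleculeError(
                f"{code!r}: acyl state {ch!r} only allowed on a terminal carbon"
            )
    return tuple(code)


def parse_molecule(code: str) -> Molecule:
    """Parse a MoleculeCode (registered name or linear chain code)."""
    if not code:
        raise MoleculeError("empty molecule code")
    key = code.strip().lower()
    if key == "water":
        return WATER
    if key == "phosphate":
        return PHOSPHATE
    if key in _NAME_REGISTRY:
        key = _NAME_REGISTRY[key]
        if key == "water":
            return WATER
        if key == "phosphate":
            return PHOSPHATE
    states = _validate_chain(key)
    canon = canonical_chain_code(states)
    return Molecule.from_graph(chain_to_graph(tuple(canon)), chain=tuple(canon))


def _load_registry() -> Tuple[Dict[str, str], Dict[str, str]]:
    with resources.files("nogmap.fixtures").joinpath("molecules.json").open() as fh:
        reg = json.load(fh)
    lookup = {k.lower(): v for k, v in reg.items()}
    display = dict(reg)
    return lookup, display


WATER = Molecule.from_graph(water_graph(), name="H2O")
PHOSPHATE = Molecule.from_graph(phosphate_graph(), name="Pi")

_NAME_REGISTRY, _DISPLAY_REGISTRY = _load_registry()


def registry() -> Dict[str, str]:
    """Name -> MoleculeCode map shipped with the package."""
    return dict(_DISPLAY_REGISTRY)


def named(name: str) -> Molecule:
    m = parse_molecule(name)
    return Molecule(
        graph=m.graph, canonical_key=m.canonical_key, formula=m.formula,
        carbon_count=m.carbon_count, category=m.category, chain=m.chain,
        name=name,
    )


# ---------------------------------------------------------------------------
# optional SMILES interop (rdkit)
# ---------------------------------------------------------------------------

def from_smiles(smiles: str) -> Molecule:
    """Import from SMILES; stereo descriptors are dropped with a warning."""
    from rdkit import Chem  # optional dependency

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"rdkit could not parse SMILES {smiles!r}")
    if any(a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
           for a in mol.GetAtoms()):
        warnings.warn("stereo descriptors dropped on import", stacklevel=2)
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                   order=int(b.GetBondTypeAsDouble()))
    return Molecule.from_graph(g)


def to_smiles(m: Molecule) -> str:
    from rdkit import Chem

    rw = Chem.RWMol()
    idx = {}
    for v in m.graph.nodes:
        idx[v] = rw.AddAtom(Chem.Atom(m.graph.nodes[v]["element"]))
    for u, v, d in m.graph.edges(data=True):
        rw.AddBond(idx[u], idx[v],
                   Chem.BondType.DOUBLE if d["order"] == 2 else Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)
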