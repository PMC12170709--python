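"""Integer hyperflow pathway enumeration over a reaction network.

A pathway is an assignment of nonnegative integer flows ``f_e`` to reaction
hyperedges satisfying per-molecule conservation

    for all v:  sum_{e: v in products(e)} f_e * mult  +  in(v)
              = sum_{e: v in educts(e)}   f_e * mult  +  out(v)

with the query fixing the inflow of the source and the outflow of the sink
(e.g. one fructose-6-phosphate in, three acetylphosphate out) and leaving
abundant species (water, phosphate) freely exchangeable.  Fixing the source
inflow to one eliminates superfluous solutions that are integer multiples
of a base solution.

The model is solved with HiGHS (``scipy.optimize.milp``).  Flows are
encoded in unary ("thermometer") binaries ``y[e,k] = [f_e >= k]``, which
makes exact solution-exclusion (no-good) cuts linear, so the solution set
can be enumerated exhaustively in nondecreasing total-flow order.  An
optional constraint restricts pathways to phosphorylated sugars: any
reaction touching an unphosphorylated carbohydrate that is not a query
source or sink is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .molecules import CARBOHYDRATE, Molecule, parse_molecule
from .network import Reaction, ReactionNetwork

DEFAULT_FREE_EXCHANGE = ("H2O", "Pi")


class QueryError(ValueError):
    """Query references a molecule absent from the network."""


class SolverError(RuntimeError):
    """The MILP solver failed for a reason other than infeasibility."""


@dataclass(frozen=True)
class FlowQuery:
    """Source/sink specification for a pathway search.

    Molecules are referenced by MoleculeCode (registered name or chain
    code).  ``inflow`` and ``outflow`` fix exact exchange counts;
    ``free_exchange`` molecules may flow in or out without constraint.
    """

    inflow: Dict[str, int]
    outflow: Dict[str, int]
    free_exchange: Tuple[str, ...] = DEFAULT_FREE_EXCHANGE
    require_phosphorylated_sugars: bool = True
    objective: str = "total_flow"  # or "unique_reactions"
    max_total: int = 10
    max_flow_per_reaction: Optional[int] = None

    def __post_init__(self):
        if any(v < 0 for v in self.inflow.values()):
            raise ValueError("inflow values must be >= 0")
        if any(v < 0 for v in self.outflow.values()):
            raise ValueError("outflow values must be >= 0")
        overlap = set(self.inflow) & set(self.outflow)
        if overlap:
            raise ValueError(f"molecules in both inflow and outflow: {overlap}")
        if self.objective not in ("total_flow", "unique_reactions"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class Pathway:
    """An integer hyperflow: reaction -> flow, plus exchange flows."""

    flows: Dict[int, int]                 # reaction index in net -> f_e > 0
    exchange: Dict[str, Tuple[int, int]]  # molecule key -> (in, out)
    net: ReactionNetwork = field(repr=False)

    @property
    def total_reactions(self) -> int:
        return sum(self.flows.values())

    @property
    def unique_reactions(self) -> int:
        return len(self.flows)

    def flow_vector(self, n_reactions: Optional[int] = None) -> Tuple[int, ...]:
        n = n_reactions if n_reactions is not None else len(self.net.reactions)
        v = [0] * n
        for i, f in self.flows.items():
            v[i] = f
        return tuple(v)

    def reactions(self) -> List[Tuple[Reaction, int]]:
        return [(self.net.reactions[i], f) for i, f in sorted(self.flows.items())]

    def molecules_used(self) -> Set[str]:
        keys: Set[str] = set()
        for i in self.flows:
            r = self.net.reactions[i]
            keys.update(r.educts)
            keys.update(r.products)
        return keys

    def biphosphate_used(self) -> Set[str]:
        """Biphosphates with positive throughput (FBP/SBP/XBP by name,
        otherwise the serialized code)."""
        names = _registry_names()
        out = set()
        for k in self.molecules_used():
            m = self.net.molecules[k]
            if m.category == "carbohydrate-biphosphate":
                out.add(names.get(k, m.serialize()))
        return out

    def check_conservation(self) -> None:
        """Assert the flow-conservation residual is exactly zero everywhere."""
        residual: Dict[str, int] = {}
        for i, f in self.flows.items():
            r = self.net.reactions[i]
            for k in r.products:
                residual[k] = residual.get(k, 0) + f
            for k in r.educts:
                residual[k] = residual.get(k, 0) - f
        for k, (fin, fout) in self.exchange.items():
            residual[k] = residual.get(k, 0) + fin - fout
        bad = {k: v for k, v in residual.items() if v != 0}
        if bad:
            raise AssertionError(f"conservation violated at {bad}")


@dataclass(frozen=True)
class PathwayStats:
    """Per-pathway characteristics (counts include flow multiplicity)."""

    n_reactions: int
    n_hyperedges: int
    n_enzymes: int
    pk_tuple: Tuple[int, int, int]   # reactions using (Xpk, Fpk, Spk)
    n_pk_other: int                  # PK reactions on other substrates
    n_bimolecular: int
    n_two_sugar: int


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def resolve_molecule(net: ReactionNetwork, code: str,
                     missing_ok: bool = False) -> Optional[str]:
    """Canonical key of a query molecule: raw key, token/registered name,
    or MoleculeCode."""
    if code in net.molecules:
        return code
    for key, m in net.molecules.items():
        if m.name == code:
            return key
    try:
        key = parse_molecule(code).canonical_key
    except Exception:
        key = None
    if key is not None and key in net.molecules:
        return key
    if missing_ok:
        return None
    raise QueryError(f"molecule {code!r} not in network")


def _resolve(net: ReactionNetwork, code: str) -> str:
    return resolve_molecule(net, code)


def admissible_reactions(net: ReactionNetwork, q: FlowQuery) -> List[int]:
    """Indices of reactions a pathway may use under the query.

    With ``require_phosphorylated_sugars``, every reaction touching an
    unphosphorylated carbohydrate is excluded unless that molecule is a
    designated source or sink of the query.
    """
    exempt = {_resolve(net, c) for c in (*q.inflow, *q.outflow)}
    out = []
    for i, r in enumerate(net.reactions):
        if q.require_phosphorylated_sugars:
            bad = False
            for k in set(r.educts) | set(r.products):
                m = net.molecules[k]
                if m.category == CARBOHYDRATE and k not in exempt:
                    bad = True
                    break
            if bad:
                continue
        out.append(i)
    return out


class ILPModel:
    """Thermometer-encoded hyperflow MILP with no-good cut support."""

    def __init__(self, net: ReactionNetwork, q: FlowQuery):
        self.net = net
        self.query = q
        self.rxn_idx = admissible_reactions(net, q)
        self.cap = q.max_flow_per_reaction or q.max_total
        self.cap = min(self.cap, q.max_total)

        self.inflow = {_resolve(net, c): v for c, v in q.inflow.items()}
        self.outflow = {_resolve(net, c): v for c, v in q.outflow.items()}
        free = []
        for c in q.free_exchange:
            k = resolve_molecule(net, c, missing_ok=True)
            if k is not None:
                free.append(k)
        self.free = free

        # variable layout: y[e,k] for e in rxn_idx, k=1..cap, then
        # (in, out) integer pairs for each free-exchange molecule
        self.ny = len(self.rxn_idx) * self.cap
        self.nfree = len(self.free)
        self.nvar = self.ny + 2 * self.nfree
        self._build()
        self.cuts: List[Tuple[np.ndarray, float]] = []

    def _yvar(self, ei: int, k: int) -> int:
        return ei * self.cap + (k - 1)

    def _build(self):
        rows, lbs, ubs = [], [], []
        exch_bound = float(
            4 * self.query.max_total
            + sum(self.inflow.values()) + sum(self.outflow.values()) + 4
        )

        # thermometer monotonicity: y[e,k+1] - y[e,k] <= 0
        for ei in range(len(self.rxn_idx)):
            for k in range(1, self.cap):
                row = np.zeros(self.nvar)
                row[self._yvar(ei, k + 1)] = 1.0
                row[self._yvar(ei, k)] = -1.0
                rows.append(row)
                lbs.append(-np.inf)
                ubs.append(0.0)

        # conservation per molecule
        mol_rows: Dict[str, np.ndarray] = {}

        def mrow(key: str) -> np.ndarray:
            if key not in mol_rows:
                mol_rows[key] = np.zeros(self.nvar)
            return mol_rows[key]

        for ei, ri in enumerate(self.rxn_idx):
            r = self.net.reactions[ri]
            coef: Dict[str, int] = {}
            for k in r.products:
                coef[k] = coef.get(k, 0) + 1
            for k in r.educts:
                coef[k] = coef.get(k, 0) - 1
            for key, c in coef.items():
                row = mrow(key)
                for k in range(1, self.cap + 1):
                    row[self._yvar(ei, k)] += c
        for fi, key in enumerate(self.free):
            mrow(key)[self.ny + 2 * fi] += 1.0       # free in
            mrow(key)[self.ny + 2 * fi + 1] -= 1.0   # free out
        for key, row in sorted(mol_rows.items()):
            rhs = float(self.outflow.get(key, 0) - self.inflow.get(key, 0))
            rows.append(row)
            lbs.append(rhs)
            ubs.append(rhs)
        # molecules with fixed exchange but no admissible reaction: the
        # conservation row is all-zero and rhs nonzero -> infeasible, as it
        # should be; milp handles the empty row correctly.
        for key in (*self.inflow, *self.outflow):
            if key not in mol_rows:
                row = np.zeros(self.nvar)
                rhs = float(self.outflow.get(key, 0) - self.inflow.get(key, 0))
                rows.append(row)
                lbs.append(rhs)
                ubs.append(rhs)

        self.A = sparse.csr_matrix(np.array(rows)) if rows else None
        self.lb = np.array(lbs)
        self.ub = np.array(ubs)
        lo = np.zeros(self.nvar)
        hi = np.concatenate([np.ones(self.ny),
                             np.full(2 * self.nfree, exch_bound)])
        self.bounds = Bounds(lo, hi)
        self.total_row = np.concatenate([np.ones(self.ny),
                                         np.zeros(2 * self.nfree)])

    def add_no_good_cut(self, flows_on_idx: Dict[int, int]) -> None:
        """Exclude one exact flow vector (on admissible reactions).

        For the incumbent f*, feasibility of any other vector requires
        some e with f_e >= f*_e + 1 (y[e, f*+1] = 1) or f_e <= f*_e - 1
        (y[e, f*] = 0); the cut demands at least one such deviation.
        """
        row = np.zeros(self.nvar)
        const = 0.0
        for ei in range(len(self.rxn_idx)):
            fstar = flows_on_idx.get(ei, 0)
            if fstar + 1 <= self.cap:
                row[self._yvar(ei, fstar + 1)] += 1.0
            if fstar >= 1:
                row[self._yvar(ei, fstar)] -= 1.0
                const += 1.0
        # sum_dev >= 1  <=>  row >= 1 - const
        self.cuts.append((row, 1.0 - const))

    def solve(self, total: Optional[int] = None,
              objective: Optional[str] = None) -> Optional[Dict[int, int]]:
        """Solve; returns flows on admissible-reaction indices, or None."""
        cons = []
        if self.A is not None:
            cons.append(LinearConstraint(self.A, self.lb, self.ub))
        if total is not None:
            cons.append(LinearConstraint(self.total_row, float(total),
                                         float(total)))
        else:
            cons.append(LinearConstraint(self.total_row, 0.0,
                                         float(self.query.max_total)))
        if self.cuts:
            cut_rows = np.array([r for r, _ in self.cuts])
            cut_lb = np.array([b for _, b in self.cuts])
            cons.append(LinearConstraint(sparse.csr_matrix(cut_rows), cut_lb,
                                         np.full(len(self.cuts), np.inf)))

        obj = objective or self.query.objective
        c = np.zeros(self.nvar)
        if obj == "total_flow":
            c[: self.ny] = 1.0
        elif obj == "unique_reactions":
            for ei in range(len(self.rxn_idx)):
                c[self._yvar(ei, 1)] = 1.0
        res = milp(c, constraints=cons, bounds=self.bounds,
                   integrality=np.ones(self.nvar))
        if res.status == 2:  # infeasible
            return None
        if not res.success:
            raise SolverError(f"HiGHS failed: {res.message}")
        y = np.round(res.x).astype(int)
        flows: Dict[int, int] = {}
        for ei in range(len(self.rxn_idx)):
            f = int(y[self._yvar(ei, 1): self._yvar(ei, self.cap) + 1].sum())
            if f:
                flows[ei] = f
        return flows

    def pathway(self, flows_on_idx: Dict[int, int]) -> Pathway:
        """Materialize a Pathway (with derived exchange flows) and verify it."""
        flows = {self.rxn_idx[ei]: f for ei, f in flows_on_idx.items()}
        residual: Dict[str, int] = {}
        for ri, f in flows.items():
            r = self.net.reactions[ri]
            for k in r.products:
                residual[k] = residual.get(k, 0) + f
            for k in r.educts:
                residual[k] = residual.get(k, 0) - f
        exchange: Dict[str, Tuple[int, int]] = {}
        for key, v in self.inflow.items():
            exchange[key] = (v, 0)
        for key, v in self.outflow.items():
            exchange[key] = (exchange.get(key, (0, 0))[0], v)
        for key in self.free:
            net_prod = residual.get(key, 0)
            exchange[key] = (max(0, -net_prod), max(0, net_prod))
        p = Pathway(flows=flows, exchange=exchange, net=self.net)
        p.check_conservation()
        return p


def build_model(net: ReactionNetwork, q: FlowQuery) -> ILPModel:
    return ILPModel(net, q)


def enumerate_pathways(net: ReactionNetwork, q: FlowQuery,
                       limit: int = 10000) -> List[Pathway]:
    """All distinct integer hyperflows satisfying the query.

    Complete up to ``q.max_total``; returned in nondecreasing total-flow
    order, ties broken lexicographically on the flow vector, so the output
    order is deterministic regardless of solver behavior.
    """
    model = ILPModel(net, q)
    found: List[Dict[int, int]] = []
    first = model.solve(objective="total_flow")
    if first is None:
        return []
    t0 = sum(first.values())
    for total in range(t0, q.max_total + 1):
        while len(found) < limit:
            flows = model.solve(total=total)
            if flows is None:
                break
            found.append(flows)
            model.add_no_good_cut(flows)
        if len(found) >= limit:
            break
    pathways = [model.pathway(f) for f in found]
    pathways.sort(key=lambda p: (p.total_reactions,
                                 p.flow_vector()))
    return pathways


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------

def _pk_substrate_carbons(r: Reaction, net: ReactionNetwork) -> Optional[int]:
    if "PK" not in r.rules:
        return None
    return max(net.molecules[k].carbon_count for k in r.educts)


def characterize(p: Pathway, net: ReactionNetwork) -> PathwayStats:
    """Pathway statistics: totals, PK usage by substrate size, bimolecular
    and two-sugar reaction counts (the latter two with flow multiplicity)."""
    n_reactions = p.total_reactions
    n_hyperedges = p.unique_reactions
    enzymes: Set[str] = set()
    pk = [0, 0, 0]
    pk_other = 0
    n_bi = n_two = 0
    for i, f in p.flows.items():
        r = net.reactions[i]
        enzymes.update(r.rules)
        nc = _pk_substrate_carbons(r, net)
        if nc is not None:
            if nc == 5:
                pk[0] += f
            elif nc == 6:
                pk[1] += f
            elif nc == 7:
                pk[2] += f
            else:
                pk_other += f
        if len(r.educts) == 2:
            n_bi += f
            if all(net.molecules[k].is_sugar_like for k in r.educts):
                n_two += f
    return PathwayStats(
        n_reactions=n_reactions, n_hyperedges=n_hyperedges,
        n_enzymes=len(enzymes), pk_tuple=tuple(pk), n_pk_other=pk_other,
        n_bimolecular=n_bi, n_two_sugar=n_two,
    )


def _registry_names() -> Dict[str, str]:
    from .molecules import registry

    out: Dict[str, str] = {}
    for name, code in registry().items():
        key = parse_molecule(code).canonical_key
        # prefer the shortest registered alias (F6P over fructose-6-...)
        if key not in out or len(name) < len(out[key]):
            out[key] = name
    return out


def render_pathway(p: Pathway, net: ReactionNetwork) -> str:
    """Human-readable reaction table (educts -> products, enzyme over arrow)."""
    lines = []
    names = _registry_names()
    for k, m in net.molecules.items():
        if k in names:
            continue
        try:
            names[k] = m.name or m.serialize()
        except Exception:
            names[k] = k[:10]
    for r, f in p.reactions():
        lhs = " + ".join(names[k] for k in r.educts)
        rhs = " + ".join(names[k] for k in r.products)
        tag = "/".join(sorted(r.rules))
        mult = f" (x{f})" if f > 1 else ""
        lines.append(f"{lhs} --{tag}--> {rhs}{mult}")
    return "\n".join(lines)
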