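"""Gibbs free-energy assignment to reactions and pathways.

A reaction's standard free-energy difference is the difference of the
chemical potentials of its products and educts,

    DrG = sum G(products) - sum G(educts)   [kJ/mol],

either computed from a per-molecule :class:`PotentialTable` or taken from a
per-reaction :class:`DeltaGTable` of measured/printed values (overrides win).
Thermodynamics favors reactions with DrG < 0; a step with DrG > 0 is a
bottleneck.  Because G is a state function, every pathway implementing the
same overall exchange reaction has the same net DrG, whatever its
intermediate steps -- this is asserted by :func:`pathway_profile`.

Two dimensionless ratios are provided:

* ``boltzmann_ratio``: P_RHS / P_LHS = exp(-DrG / RT), the relative
  likelihood of finding the system on the product side.
* ``equilibrium_ratio``: exp(+DrG / RT), the educt/product concentration
  ratio at which a hydrolysis reaction with standard free energy DrG sits
  at equilibrium (unit activities for water and phosphate); e.g. the
  [SBP]/[S7P] ratio that makes sedoheptulose-biphosphate hydrolysis
  equilibrate at 300 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .molecules import Molecule, parse_molecule
from .network import Reaction, ReactionNetwork
from .pathways import Pathway

R_GAS = 8.314  # J / (mol K)
DEFAULT_T = 300.0  # K, the temperature the published ratios are quoted at
STANDARD_T = 273.15  # K, standard physical conditions of the potential model
STANDARD_P = 1e5  # Pa


class CoverageError(KeyError):
    """A reaction's free energy cannot be resolved from the given tables."""


def reaction_id(educt_codes: Sequence[str], product_codes: Sequence[str]) -> str:
    """Stable human-readable reaction identifier from MoleculeCodes."""
    def canon(codes):
        return "+".join(sorted(parse_molecule(c).serialize() for c in codes))
    return canon(educt_codes) + "->" + canon(product_codes)


def reaction_id_of(r: Reaction, net: ReactionNetwork) -> str:
    e = "+".join(sorted(net.molecules[k].serialize() for k in r.educts))
    p = "+".join(sorted(net.molecules[k].serialize() for k in r.products))
    return e + "->" + p


@dataclass
class PotentialTable:
    """Per-molecule standard chemical potentials G° in kJ/mol."""

    potentials: Dict[str, float]           # canonical_key -> G°
    temperature: float = STANDARD_T
    pressure: float = STANDARD_P
    source: str = "user"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @staticmethod
    def from_codes(values: Dict[str, float], **kw) -> "PotentialTable":
        return PotentialTable(
            {parse_molecule(c).canonical_key: v for c, v in values.items()}, **kw
        )

    def get(self, key: str) -> Optional[float]:
        return self.potentials.get(key)


@dataclass
class DeltaGTable:
    """Per-reaction DrG overrides in kJ/mol, keyed by reaction id."""

    overrides: Dict[str, float] = field(default_factory=dict)
    source: str = "user"

    def __post_init__(self):
        for k, v in self.overrides.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite DrG for {k}")

    def get(self, rid: str) -> Optional[float]:
        return self.overrides.get(rid)

    @staticmethod
    def from_tsv(text: str, source: str = "user") -> "DeltaGTable":
        overrides = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, val = line.split("\t")[:2]
            lhs, rhs = rid.split("->")
            rid = reaction_id(lhs.split("+"), rhs.split("+"))
            overrides[rid] = float(val)
        return DeltaGTable(overrides, source=source)

    def to_tsv(self) -> str:
        lines = ["# reaction_id\tdelta_g_kJ_per_mol\tsource"]
        for rid, v in sorted(self.overrides.items()):
            lines.append(f"{rid}\t{v}\t{self.source}")
        return "\n".join(lines) + "\n"


def paper_delta_g_table() -> DeltaGTable:
    """The shipped fixture of published per-reaction DrG values."""
    text = (resources.files("nogmap.fixtures") / "delta_g.tsv").read_text()
    return DeltaGTable.from_tsv(text, source="paper-fixture")


#: published net free energies of the three overall exchange reactions, kJ/mol
NET_DELTA_G = {
    "nog": -236.75,      # F6P + 2 Pi -> 3 AcP + 2 H2O
    "hpa": -114.428,     # F6P + H2O  -> 2 HPA + Pi
    "acetate": -286.711,  # F6P + H2O -> 3 AcH + Pi
}


# ---------------------------------------------------------------------------
# per-reaction and per-pathway energies
# ---------------------------------------------------------------------------

def reaction_delta_g(r: Reaction, net: ReactionNetwork,
                     pot: Optional[PotentialTable] = None,
                     dg: Optional[DeltaGTable] = None) -> float:
    """DrG of one reaction; a DeltaGTable override takes precedence."""
    if dg is not None:
        v = dg.get(reaction_id_of(r, net))
        if v is not None:
            return v
    if pot is not None:
        missing = [k for k in set(r.educts) | set(r.products)
                   if pot.get(k) is None]
        if not missing:
            return (sum(pot.get(k) for k in r.products)
                    - sum(pot.get(k) for k in r.educts))
        missing_names = [net.molecules[k].serialize() for k in missing]
        raise CoverageError(
            f"no potentials for {missing_names} and no DrG override for "
            f"{reaction_id_of(r, net)}"
        )
    raise CoverageError(f"no DrG source covers {reaction_id_of(r, net)}")


@dataclass
class ThermoProfile:
    """Ordered free-energy profile of a pathway."""

    steps: List[Tuple[Reaction, int, float]]   # (reaction, flow, DrG)
    cumulative: List[float]
    bottlenecks: List[int]                     # indices of steps with DrG > 0
    net: float

    def __post_init__(self):
        total = sum(f * g for _, f, g in self.steps)
        if abs(total - self.net) > 1e-9:
            raise AssertionError("net DrG inconsistent with steps")


def pathway_profile(p: Pathway, net: ReactionNetwork,
                    order: Optional[Sequence[int]] = None,
                    pot: Optional[PotentialTable] = None,
                    dg: Optional[DeltaGTable] = None) -> ThermoProfile:
    """Free-energy profile along a linearization of the pathway.

    ``order`` lists reaction indices of the network, each appearing as many
    times as its flow (one entry per occurrence); by default reactions are
    laid out in stored order, each repeated ``f_e`` times.  The net value is
    order-independent (state function) and is asserted to equal the
    flow-weighted sum of the steps.
    """
    if order is None:
        order = [i for i, f in sorted(p.flows.items()) for _ in range(f)]
    else:
        from collections import Counter
        want = Counter({i: f for i, f in p.flows.items()})
        if Counter(order) != want:
            raise ValueError("order must list each reaction exactly f_e times")
    steps = []
    cumulative = []
    run = 0.0
    for i in order:
        r = net.reactions[i]
        g = reaction_delta_g(r, net, pot, dg)
        steps.append((r, 1, g))
        run += g
        cumulative.append(run)
    bottlenecks = [j for j, (_, _, g) in enumerate(steps) if g > 0]
    return ThermoProfile(steps=steps, cumulative=cumulative,
                         bottlenecks=bottlenecks, net=run)


# ---------------------------------------------------------------------------
# dimensionless ratios
# ---------------------------------------------------------------------------

def boltzmann_ratio(delta_g: float, temperature: float = DEFAULT_T) -> float:
    """P_RHS / P_LHS = exp(-DrG/RT); > 1 for thermodynamically favored steps."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return math.exp(-delta_g * 1000.0 / (R_GAS * temperature))


def equilibrium_ratio(delta_g: float, temperature: float = DEFAULT_T) -> float:
    """Educt/product concentration ratio at equilibrium.

    For a hydrolysis  XBP + H2O -> X-P + Pi  with standard free energy
    DrG° > 0 and unit activities of water and phosphate, equilibrium
    ([educt]/[product] such that DrG = 0) requires

        ratio = exp(+DrG° / RT),

    e.g. 1.26 for [SBP]/[S7P] at 300 K from DrG° = +0.576 kJ/mol.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return math.exp(delta_g * 1000.0 / (R_GAS * temperature))


def paper_product_preference(net_a: float, net_b: float) -> float:
    """The published product-preference statistic exp(net_a / net_b).

    Reproduces the literal printed formula comparing the net free energy of
    the acetylphosphate route with the 3-hydroxypropionate route
    (exp(-236.75 / -114.28) ~ 8).  Note the exponent is a ratio of two free
    energies, not a free-energy difference over RT, so the quantity is
    dimensionally unconventional; it is provided for reproducibility, not
    as a recommended statistic.
    """
    if net_b == 0:
        raise ValueError("net_b must be nonzero")
    return math.exp(net_a / net_b)
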