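"""The seven enzymatic reaction templates as executable rewrite rules.

Each rule rewrites linear-backbone molecules (see :mod:`nogmap.molecules`)
and produces elementally balanced reactions.  The templates:

    AL    aldolase            C-C bond formation: ketose donor C1 attacks an
                              aldose's carbonyl carbon (aldol addition);
                              optionally also emitted in the retro direction.
    AlKe  aldose->ketose      carbonyl migrates one position inward
    KeAl  ketose->aldose      carbonyl migrates one position outward
    PHL   phosphohydrolase    hydrolyses one phosphoester (or acyl phosphate)
                              with water, releasing phosphoric acid
    PK    phosphoketolase     cleaves the C-C bond next to a keto group and
                              phosphorylates the acyl fragment, releasing
                              water and a shorter aldose
    TAL   transaldolase       transfers the C1-C3 dihydroxyacetone unit of a
                              ketose onto an aldose
    TKL   transketolase       transfers the C1-C2 glycolaldehyde unit of a
                              ketose onto an aldose

The structural preconditions that are not pinned down by the template
descriptions (how far a carbonyl may migrate, which ketoses phosphoketolase
accepts, the aldol donor size) are exposed on :class:`RuleConfig`; the
defaults are the configuration whose pathway-level behavior matches the
published results (see docs/methods.md for the calibration and its known
census discrepancy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Sequence, Tuple

from .molecules import (
    Molecule,
    PHOSPHATE,
    WATER,
    canonical_chain_code,
    chain_to_graph,
)

Chain = Tuple[str, ...]


from functools import lru_cache


@lru_cache(maxsize=None)
def _mol_cached(code: str) -> Molecule:
    return Molecule.from_graph(chain_to_graph(tuple(code)), chain=tuple(code))


def _mol(chain: Chain) -> Molecule:
    return _mol_cached(canonical_chain_code(chain))


def _orientations(m: Molecule) -> List[Chain]:
    if m.chain is None:
        return []
    c = tuple(m.chain)
    r = c[::-1]
    return [c] if c == r else [c, r]


@dataclass(frozen=True)
class RuleConfig:
    """Tunable structural preconditions of the rule templates.

    keto_migration: how far AlKe/KeAl may carry the carbonyl from the
        nearer chain end: ``1`` = aldose<->2-ketose only, ``2`` = also
        2-ketose<->3-ketose, ``0`` = unrestricted.
    pk_both_sides: phosphoketolase cleaves the C-C bond on either side of
        the C2-C3 enediol system of a 2-ketose.  Cleaving C2-C3 gives the
        classic acetylphosphate chemistry (Xpk/Fpk/Spk); cleaving C3-C4
        phosphorylates C3 instead and yields the 3-hydroxypropionyl
        phosphate family.
    al_donor_carbons: backbone length the aldol donor must have
        (3 = dihydroxyacetone-like donors only; 0 = any ketose).
    al_alpha_states: substitution states through which an aldol donor may
        attack: ``"h"`` = the hydroxymethyl arm only (classic class-I
        aldolase regiochemistry); add ``"p"``/``"b"`` to let the
        phosphorylated or bare alpha carbon attack as well.
    al_acyl_donors: also admit acyl phosphates/acids (e.g. acetylphosphate)
        as aldol donors through their bare alpha carbon.
    al_min_acceptor_carbons: smallest aldose accepted by aldolase
        (1 admits formaldehyde).
    retro_al: emit the retro-aldol (cleavage) direction of AL as well.
    tkl_min_donor_carbons / tal_min_donor_carbons: smallest ketose donor.
    enabled: which rule tags are active.
    """

    keto_migration: int = 1
    pk_both_sides: bool = True
    al_donor_carbons: int = 3
    al_alpha_states: str = "h"
    al_acyl_donors: bool = False
    al_min_acceptor_carbons: int = 2
    retro_al: bool = False
    tkl_min_donor_carbons: int = 4
    tal_min_donor_carbons: int = 4
    enabled: frozenset = frozenset({"AL", "AlKe", "KeAl", "PHL", "PK", "TAL", "TKL"})

    def to_dict(self) -> Dict:
        d = self.__dict__.copy()
        d["enabled"] = sorted(self.enabled)
        return d

    @staticmethod
    def from_dict(d: Dict) -> "RuleConfig":
        d = dict(d)
        if "enabled" in d:
            d["enabled"] = frozenset(d["enabled"])
        return RuleConfig(**d)


DEFAULT_CONFIG = RuleConfig()


@dataclass(frozen=True)
class Embedding:
    """One match of a rule's left-hand pattern in an educt multiset."""

    rule: str
    educts: Tuple[Molecule, ...]
    products: Tuple[Molecule, ...]

    def product_keys(self) -> Tuple[str, ...]:
        return tuple(sorted(p.canonical_key for p in self.products))


class RuleTemplate:
    """Base class: a named rewrite with arity 1 or 2."""

    abbrev: str = "?"
    name: str = "?"
    arity: int = 1

    def __init__(self, config: RuleConfig = DEFAULT_CONFIG):
        self.config = config

    # -- subclass hook -----------------------------------------------------
    def _products(self, educts: Tuple[Molecule, ...]) -> Iterator[Tuple[Molecule, ...]]:
        raise NotImplementedError

    # -----------------------------------------------------------------------
    def applicable_embeddings(self, educts: Sequence[Molecule]) -> List[Embedding]:
        """Every distinct match of the rule in the educts.

        Embeddings yielding identical product multisets are deduplicated;
        an empty list signals inapplicability.
        """
        educts = tuple(educts)
        if len(educts) != self.arity:
            raise ValueError(
                f"{self.abbrev} takes {self.arity} educt(s), got {len(educts)}"
            )
        seen = set()
        out = []
        orders = [educts]
        if self.arity == 2 and educts[0].canonical_key != educts[1].canonical_key:
            orders.append((educts[1], educts[0]))
        for ed in orders:
            for prods in self._products(ed):
                keysig = tuple(sorted(p.canonical_key for p in prods))
                if keysig in seen:
                    continue
                seen.add(keysig)
                out.append(Embedding(self.abbrev, educts, tuple(prods)))
        return out

    def apply(self, educts: Sequence[Molecule], emb: Embedding):
        """Materialize a balanced Reaction from an embedding."""
        from .network import Reaction, reaction_from_parts  # lazy: avoid cycle

        if emb.rule != self.abbrev:
            raise ValueError("embedding does not belong to this rule")
        return reaction_from_parts(tuple(educts), emb.products, self.abbrev)


# ---------------------------------------------------------------------------
# concrete rules
# ---------------------------------------------------------------------------

def _carbonyl_positions(chain: Chain) -> List[int]:
    return [i for i, s in enumerate(chain) if s == "k"]


class AldoseKetose(RuleTemplate):
    """AlKe: isomerizes aldehydes to ketones (carbonyl moves inward)."""

    abbrev, name, arity = "AlKe", "aldose-ketose isomerase", 1
    _inward = True

    def _products(self, educts):
        (m,) = educts
        span = self.config.keto_migration
        for o in _orientations(m):
            n = len(o)
            for i in _carbonyl_positions(o):
                j = i + 1
                if j >= n or o[j] != "h":
                    continue
                # carbonyl position counted from the nearer chain end (1-based);
                # both orientations are scanned, so index-increasing moves cover
                # physically inward and outward migrations.
                pos_i = min(i, n - 1 - i) + 1
                pos_j = min(j, n - 1 - j) + 1
                if self._inward != (pos_j >= pos_i):
                    continue
                if span and min(pos_i, pos_j) > span:
                    continue
                new = list(o)
                new[i], new[j] = "h", "k"
                yield (_mol(tuple(new)),)


class KetoseAldose(AldoseKetose):
    """KeAl: isomerises ketones to aldehydes (carbonyl moves outward)."""

    abbrev, name = "KeAl", "ketose-aldose isomerase"
    _inward = False


class Phosphohydrolase(RuleTemplate):
    """PHL: hydrolyses one phosphoester (any position) with one water."""

    abbrev, name, arity = "PHL", "phosphohydrolase", 2

    def _products(self, educts):
        m, w = educts
        if w.canonical_key != WATER.canonical_key:
            return
        for o in _orientations(m):
            for i, s in enumerate(o):
                if s in ("p", "a"):
                    new = list(o)
                    new[i] = "h" if s == "p" else "x"
                    yield (_mol(tuple(new)), PHOSPHATE)


class Phosphoketolase(RuleTemplate):
    """PK: breaks a C-C bond at the keto group and adds phosphate.

    On a 2-ketose, cleaving the bond between the carbonyl carbon and the
    rest of the chain gives the classic Xpk/Fpk/Spk template

        ketose-P + Pi -> acetylphosphate + aldose-P + H2O

    (the alpha hydroxyl leaves as water, C1 ends up as a methyl group).
    With ``pk_both_sides`` the bond on the far side of the carbonyl can be
    cleaved as well, phosphorylating that carbon instead; on the same
    2-ketoses this produces 3-hydroxypropionyl phosphate, e.g.

        F6P + Pi -> HPA-P + G3P + H2O.

    Both readings conserve atoms exactly; the flanking carbon of the
    released fragment must carry a hydroxyl (it becomes the new aldehyde).
    """

    abbrev, name, arity = "PK", "phosphoketolase", 2

    def _products(self, educts):
        m, pi = educts
        if pi.canonical_key != PHOSPHATE.canonical_key:
            return
        cfg = self.config
        for o in _orientations(m):
            n = len(o)
            if n < 3 or o[1] != "k":
                continue
            # classic: cleave C2-C3; C1 (terminal CH2OH) is dehydrated
            if o[0] == "h" and o[2] == "h":
                yield (_mol(("b", "a")), _mol(("k",) + o[3:]), WATER)
            # far-side: cleave C3-C4; the carbonyl carbon is dehydrated
            if cfg.pk_both_sides and n >= 4 and o[2] == "h" and o[3] == "h":
                yield (_mol((o[0], "b", "a")), _mol(("k",) + o[4:]), WATER)


class Aldolase(RuleTemplate):
    """AL: generic aldol addition (donor C1 onto an aldose carbonyl)."""

    abbrev, name, arity = "AL", "aldolase", 2

    def _donor_orients(self, m: Molecule) -> Iterator[Chain]:
        cfg = self.config
        for o in _orientations(m):
            if len(o) < 2:
                continue
            if o[1] == "k" and o[0] in cfg.al_alpha_states:
                if cfg.al_donor_carbons and len(o) != cfg.al_donor_carbons:
                    continue
                yield o
            elif cfg.al_acyl_donors and o[1] in ("a", "x") and o[0] == "b":
                # acyl phosphates/acids enolize through their bare alpha carbon
                yield o

    def _products(self, educts):
        donor, acceptor = educts
        cfg = self.config
        for d in self._donor_orients(donor):
            for a in _orientations(acceptor):
                if a[0] != "k":
                    continue
                if len(a) < cfg.al_min_acceptor_carbons:
                    continue
                product = d[::-1] + ("h",) + a[1:]
                yield (_mol(product),)


class RetroAldolase(RuleTemplate):
    """AL (retro direction): cleaves the aldol C-C bond.

    Inverse of :class:`Aldolase`; emitted under the same AL tag when
    ``retro_al`` is enabled, since aldolases are reversible.
    """

    abbrev, name, arity = "AL", "aldolase (retro)", 1

    def _products(self, educts):
        (m,) = educts
        cfg = self.config
        for o in _orientations(m):
            n = len(o)
            for i, s in enumerate(o):
                # donor part o[:i+2] (carbonyl at i, alpha carbon at i+1),
                # acceptor part from i+2, whose carbon reverts to an aldehyde
                if i + 2 >= n or o[i + 2] != "h":
                    continue
                if s == "k":
                    if o[i + 1] not in cfg.al_alpha_states:
                        continue
                    if cfg.al_donor_carbons and i + 2 != cfg.al_donor_carbons:
                        continue
                elif s in ("x", "a") and cfg.al_acyl_donors:
                    # acyl aldols cleave back to the 2-carbon acid/acyl donor
                    if i != 0 or o[i + 1] != "b":
                        continue
                else:
                    continue
                if n - (i + 2) < cfg.al_min_acceptor_carbons:
                    continue
                donor = o[: i + 2][::-1]
                acceptor = ("k",) + o[i + 3:]
                yield (_mol(donor), _mol(acceptor))


class Transaldolase(RuleTemplate):
    """TAL: transfers the C1-C3 dihydroxyacetone unit onto an aldose."""

    abbrev, name, arity = "TAL", "transaldolase", 2
    _unit = 3

    def _min_donor(self) -> int:
        return self.config.tal_min_donor_carbons

    def _unit_ok(self, o: Chain) -> bool:
        return o[0] == "h" and o[1] == "k" and o[2] == "h"

    def _products(self, educts):
        donor, acceptor = educts
        u = self._unit
        for o in _orientations(donor):
            if len(o) < max(u + 1, self._min_donor()):
                continue
            if u == 3 and not self._unit_ok(o):
                continue
            if u == 2 and not (o[0] == "h" and o[1] == "k"):
                continue
            if o[u] != "h":
                continue
            for a in _orientations(acceptor):
                if a[0] != "k":
                    continue
                new_ketose = o[:u] + ("h",) + a[1:]
                new_aldose = ("k",) + o[u + 1:]
                yield (_mol(new_aldose), _mol(new_ketose))


class Transketolase(Transaldolase):
    """TKL: transfers the C1-C2 glycolaldehyde unit onto an aldose."""

    abbrev, name = "TKL", "transketolase"
    _unit = 2

    def _min_donor(self) -> int:
        return self.config.tkl_min_donor_carbons


_RULE_CLASSES = [Aldolase, RetroAldolase, AldoseKetose, KetoseAldose,
                 Phosphohydrolase, Phosphoketolase, Transaldolase, Transketolase]


def default_rules(config: RuleConfig = DEFAULT_CONFIG) -> List[RuleTemplate]:
    """Instantiate the enabled rule set for a configuration."""
    rules: List[RuleTemplate] = []
    for cls in _RULE_CLASSES:
        if cls is RetroAldolase:
            if config.retro_al and "AL" in config.enabled:
                rules.append(cls(config))
            continue
        if cls.abbrev in config.enabled:
            rules.append(cls(config))
    return rules
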