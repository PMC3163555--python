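"""Metabolic network container, extended reaction space, and thermodynamics.

The extended metabolic reaction space (EMRS) augments a nominal reaction set
with putative reactions obtained by swapping, into each reaction role, any
compound whose hydrogen-suppressed molecular signature at the chosen height
equals that of the original participant.  Because substitution preserves the
molecular signature exactly, every putative reaction has the same reaction
signature as its parent at the generation height — the degeneracy of the
signature coding is the engine that proposes promiscuous chemistry.

Thermodynamic screening uses a group-contribution estimate: each compound's
standard Gibbs energy is the sum of contributions of its structural
subgroups (atomic signatures at a configured height), and a reaction's
Delta_G is the product-minus-substrate balance.  Putative reactions above
the threshold are dropped; reactions whose compounds contain subgroups
missing from the table stay, flagged as unscored.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .config import RunConfig
from .signatures import (
    MolecularGraph,
    SignatureVector,
    ReactionSignature,
    molecular_signature,
    reaction_signature,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "NetworkReaction",
    "MetabolicNetwork",
    "GroupContributionTable",
    "UnsupportedHeightError",
    "signature_classes",
    "enumerate_emrs",
    "compound_gibbs",
    "reaction_gibbs",
    "feasibility_filter",
    "emrs_statistics",
]


class UnsupportedHeightError(ValueError):
    """Raised for expansion heights the method does not support (h = 0)."""


@dataclass
class Compound:
    id: str
    structure: MolecularGraph
    endogenous: bool = False
    _sig_cache: Dict[int, SignatureVector] = field(default_factory=dict, repr=False)

    def signature(self, h: int) -> SignatureVector:
        if h not in self._sig_cache:
            self._sig_cache[h] = molecular_signature(self.structure, h)
        return self._sig_cache[h]

    def signature_key(self, h: int) -> Tuple[Tuple[str, int], ...]:
        return tuple(sorted(self.signature(h).entries.items()))


@dataclass
class NetworkReaction:
    """A stoichiometric reaction; putative ones carry their parent's id."""

    id: str
    ec: str = ""
    substrates: List[Tuple[int, str]] = field(default_factory=list)
    products: List[Tuple[int, str]] = field(default_factory=list)
    direction: str = "forward"          # or "reversible"
    provenance: str = "nominal"         # or "putative"
    parent_id: Optional[str] = None
    dg: Optional[float] = None          # kJ/mol, product minus substrate
    flags: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.direction not in ("forward", "reversible"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.provenance == "putative" and not self.parent_id:
            raise ValueError("putative reactions must name a parent")
        if sorted(self.substrates) == sorted(self.products):
            raise ValueError(f"{self.id}: substrate and product multisets identical")

    def participant_key(self) -> Tuple:
        return (
            tuple(sorted(self.substrates)),
            tuple(sorted(self.products)),
            self.direction,
        )


class MetabolicNetwork:
    """Compounds, reactions and the chassis metabolite set."""

    def __init__(
        self,
        compounds: Iterable[Compound] = (),
        reactions: Iterable[NetworkReaction] = (),
        chassis: Iterable[str] = (),
    ):
        self.compounds: Dict[str, Compound] = {}
        self.reactions: Dict[str, NetworkReaction] = {}
        for c in compounds:
            self.add_compound(c)
        for r in reactions:
            self.add_reaction(r)
        self.chassis: Set[str] = set(chassis)
        unknown = self.chassis - set(self.compounds)
        if unknown:
            raise ValueError(f"chassis ids not in network: {sorted(unknown)}")

    def add_compound(self, c: Compound) -> None:
        if c.id in self.compounds:
            raise ValueError(f"duplicate compound id {c.id!r}")
        self.compounds[c.id] = c

    def add_reaction(self, r: NetworkReaction) -> None:
        if r.id in self.reactions:
            raise ValueError(f"duplicate reaction id {r.id!r}")
        missing = {c for _, c in r.substrates + r.products} - set(self.compounds)
        if missing:
            raise ValueError(f"{r.id}: unknown compounds {sorted(missing)}")
        self.reactions[r.id] = r

    def nominal_reactions(self) -> List[NetworkReaction]:
        return [r for r in self.reactions.values() if r.provenance == "nominal"]

    def putative_reactions(self) -> List[NetworkReaction]:
        return [r for r in self.reactions.values() if r.provenance == "putative"]

    def sides(self, r: NetworkReaction):
        subs = [(k, self.compounds[c].structure) for k, c in r.substrates]
        prods = [(k, self.compounds[c].structure) for k, c in r.products]
        return subs, prods

    def reaction_signature_of(
        self, rid: str, h: int, representation: str = "heavy"
    ) -> ReactionSignature:
        subs, prods = self.sides(self.reactions[rid])
        return reaction_signature(subs, prods, h, representation=representation)

    def copy(self) -> "MetabolicNetwork":
        net = MetabolicNetwork()
        net.compounds = dict(self.compounds)
        net.reactions = {rid: replace(r, flags=set(r.flags)) for rid, r in self.reactions.items()}
        net.chassis = set(self.chassis)
        return net


def signature_classes(net: MetabolicNetwork, h: int) -> Dict[Tuple, List[str]]:
    """Partition compound ids by molecular signature at height ``h``."""
    classes: Dict[Tuple, List[str]] = {}
    for cid in sorted(net.compounds):
        classes.setdefault(net.compounds[cid].signature_key(h), []).append(cid)
    return classes


def enumerate_emrs(
    net: MetabolicNetwork, h: int, config: Optional[RunConfig] = None
) -> MetabolicNetwork:
    """Augment the network with putative signature-preserving reactions.

    For every nominal reaction, each participant is swapped (cross-product
    over roles) with the members of its molecular-signature class at height
    ``h``; stoichiometric coefficients are inherited.  Duplicates of any
    nominal or previously emitted reaction (by participant multisets and
    direction) are suppressed, as is the identity substitution.  Height 0
    corresponds to elemental-formula Diophantine enumeration and is
    unsupported.
    """
    if h == 0:
        raise UnsupportedHeightError(
            "height-0 expansion (elemental-formula Diophantine search) is unsupported"
        )
    if h < 0:
        raise ValueError("height must be >= 1")
    cfg = config or RunConfig()
    classes = signature_classes(net, h)
    member_of: Dict[str, List[str]] = {}
    for key, members in classes.items():
        if len(members) > cfg.max_class_size:
            logger.warning(
                "signature class truncated from %d to %d members", len(members), cfg.max_class_size
            )
            members = sorted(members)[: cfg.max_class_size]
        for cid in members:
            member_of[cid] = sorted(members)

    out = net.copy()
    seen = {r.participant_key() for r in net.reactions.values()}
    for rxn in sorted(net.nominal_reactions(), key=lambda r: r.id):
        roles = [cid for _, cid in rxn.substrates] + [cid for _, cid in rxn.products]
        options = [member_of.get(cid, [cid]) for cid in roles]
        count = 0
        n_subs = len(rxn.substrates)
        for combo in itertools.product(*options):
            if list(combo) == roles:
                continue  # identity substitution regenerates the parent
            if count >= cfg.max_substitutions:
                logger.warning("substitution cap reached for reaction %s", rxn.id)
                break
            subs = [(k, combo[i]) for i, (k, _) in enumerate(rxn.substrates)]
            prods = [
                (k, combo[n_subs + i]) for i, (k, _) in enumerate(rxn.products)
            ]
            if sorted(subs) == sorted(prods):
                continue  # degenerate null transformation
            cand = NetworkReaction(
                id=f"{rxn.id}~emrs{count}",
                ec=rxn.ec,
                substrates=subs,
                products=prods,
                direction=rxn.direction,
                provenance="putative",
                parent_id=rxn.id,
            )
            key = cand.participant_key()
            if key in seen:
                continue
            seen.add(key)
            out.add_reaction(cand)
            count += 1
    return out


@dataclass
class GroupContributionTable:
    """Structural-subgroup Gibbs contributions, keyed by atomic signature."""

    contributions: Mapping[str, float]
    height: int = 1

    def get(self, signature: str) -> Optional[float]:
        return self.contributions.get(signature)


def compound_gibbs(c: Compound, table: GroupContributionTable) -> Optional[float]:
    """Sum of subgroup contributions; None if any subgroup is missing."""
    total = 0.0
    for sig, n in c.signature(table.height).entries.items():
        g = table.get(sig)
        if g is None:
            return None
        total += n * g
    return total


def reaction_gibbs(
    rxn: NetworkReaction, net: MetabolicNetwork, table: GroupContributionTable
) -> Optional[float]:
    """Delta_G_r = sum(products) - sum(substrates), stoichiometry-weighted."""
    total = 0.0
    for sign, side in ((+1, rxn.products), (-1, rxn.substrates)):
        for coeff, cid in side:
            g = compound_gibbs(net.compounds[cid], table)
            if g is None:
                return None
            total += sign * coeff * g
    return total


def feasibility_filter(
    net: MetabolicNetwork,
    table: GroupContributionTable,
    threshold: Optional[float] = None,
    config: Optional[RunConfig] = None,
) -> MetabolicNetwork:
    """Drop putative reactions whose Delta_G_r exceeds the threshold.

    Nominal reactions are never removed.  Reversible reactions pass if
    either direction does, and the feasible direction is recorded in the
    flags.  Unscored reactions (missing subgroups) are retained and
    flagged.
    """
    cfg = config or RunConfig()
    cut = (cfg.gibbs_threshold if threshold is None else threshold) + cfg.gibbs_tolerance
    out = net.copy()
    for rid in sorted(net.reactions):
        rxn = out.reactions[rid]
        dg = reaction_gibbs(rxn, net, table)
        rxn.dg = dg
        if dg is None:
            rxn.flags.add("unscored")
            continue
        if rxn.provenance != "putative":
            continue
        if rxn.direction == "reversible":
            fwd, rev = dg <= cut, -dg <= cut
            if not (fwd or rev):
                del out.reactions[rid]
            elif fwd and not rev:
                rxn.flags.add("feasible:forward")
            elif rev and not fwd:
                rxn.flags.add("feasible:reverse")
        elif dg > cut:
            del out.reactions[rid]
    return out


def emrs_statistics(
    net: MetabolicNetwork,
    heights: Sequence[int],
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Reaction counts and % increase over nominal per expansion height."""
    nominal = len(net.nominal_reactions())
    rows = []
    for h in heights:
        count = len(enumerate_emrs(net, h, config).reactions)
        rows.append(
            {
                "height": h,
                "reactions": count,
                "pct_increase": 100.0 * (count - nominal) / nominal if nominal else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["height", "reactions", "pct_increase"])
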