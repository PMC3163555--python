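"""Canonical molecular signatures and signature-space reaction similarity.

A molecule is modelled as a heavy-atom graph; hydrogens are folded into the
atom label together with the formal charge.  The atomic signature of height
``h`` is a canonical string encoding of the subgraph within ``h`` bonds of a
root atom; a molecular signature is the multiset of atomic signatures over
all heavy atoms; a reaction signature is the stoichiometry-weighted
difference between product and substrate molecular signatures.  Reactions
with equal signatures at height ``h`` perform the same chemical
transformation at that molecular resolution, which is the basis of the
extended-reaction-space search and of the Tanimoto similarity between
reactions used throughout the package.

Canonicalisation is defined as the lexicographic minimum, over all atom
orderings of the rooted neighbourhood subgraph, of a predecessor-adjacency
serialisation.  The minimum is computed exactly by branch-and-bound with tie
branching, so the canonical string is invariant to the input atom order and
identical for isomorphic rooted neighbourhoods.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "AtomicSignature",
    "SignatureVector",
    "ReactionSignature",
    "atomic_signature",
    "molecular_signature",
    "reaction_signature",
    "tanimoto_similarity",
    "reaction_distance",
    "reaction_similarity",
    "brute_force_atomic_signature",
]

#: bond-order symbols used inside signature strings
BOND_SYMBOLS = {1: "-", 2: "=", 3: "#", "aromatic": ":"}
_BOND_RANK = {"-": 0, ":": 1, "=": 2, "#": 3}


@dataclass(frozen=True)
class Atom:
    """Heavy atom: element symbol, formal charge and attached-H count."""

    index: int
    element: str
    charge: int = 0
    h_count: int = 0

    def label(self) -> str:
        q = ""
        if self.charge > 0:
            q = "+" + (str(self.charge) if self.charge > 1 else "")
        elif self.charge < 0:
            q = "-" + (str(-self.charge) if self.charge < -1 else "")
        h = "" if self.h_count == 0 else ("H" if self.h_count == 1 else f"H{self.h_count}")
        return f"[{self.element}{q}{h}]"


@dataclass(frozen=True)
class Bond:
    """Undirected bond between two heavy atoms; order 1, 2, 3 or 'aromatic'."""

    i: int
    j: int
    order: object = 1

    def symbol(self) -> str:
        return BOND_SYMBOLS[self.order]


class MolecularGraph:
    """Undirected heavy-atom molecular graph.

    Atom indices must be unique and contiguous starting at zero; bonds must
    reference existing atoms and self-bonds are rejected.
    """

    def __init__(self, atoms: Sequence[Atom], bonds: Sequence[Bond], name: str = ""):
        atoms = list(atoms)
        idx = [a.index for a in atoms]
        if sorted(idx) != list(range(len(atoms))):
            raise ValueError("atom indices must be unique and contiguous from 0")
        self.atoms: List[Atom] = sorted(atoms, key=lambda a: a.index)
        self.name = name
        self.bonds: List[Bond] = []
        self._adj: Dict[int, Dict[int, object]] = {a.index: {} for a in self.atoms}
        for b in bonds:
            if b.i == b.j:
                raise ValueError(f"self-bond on atom {b.i}")
            if b.i not in self._adj or b.j not in self._adj:
                raise ValueError(f"bond ({b.i},{b.j}) references unknown atom")
            if b.order not in BOND_SYMBOLS:
                raise ValueError(f"unsupported bond order {b.order!r}")
            self.bonds.append(b)
            self._adj[b.i][b.j] = b.order
            self._adj[b.j][b.i] = b.order

    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> Dict[int, object]:
        return self._adj[i]

    # ---- construction -------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol, name: str = "") -> "MolecularGraph":
        from rdkit import Chem

        atoms = [
            Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        ]
        bonds = []
        for b in mol.GetBonds():
            if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
                order: object = "aromatic"
            else:
                order = int(b.GetBondTypeAsDouble())
            bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return cls(atoms, bonds, name=name)

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "MolecularGraph":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls.from_rdkit(mol, name=name or smiles)

    def permuted(self, order: Sequence[int]) -> "MolecularGraph":
        """Relabel atoms so old index ``order[k]`` becomes new index ``k``."""
        if sorted(order) != list(range(len(self))):
            raise ValueError("order must be a permutation of atom indices")
        new_of_old = {old: new for new, old in enumerate(order)}
        atoms = [
            Atom(new_of_old[a.index], a.element, a.charge, a.h_count) for a in self.atoms
        ]
        bonds = [Bond(new_of_old[b.i], new_of_old[b.j], b.order) for b in self.bonds]
        return MolecularGraph(atoms, bonds, name=self.name)

    def with_explicit_hydrogens(self) -> "MolecularGraph":
        """Expand attached hydrogens into explicit degree-1 vertices."""
        atoms = [Atom(a.index, a.element, a.charge, 0) for a in self.atoms]
        bonds = list(self.bonds)
        nxt = len(atoms)
        for a in self.atoms:
            for _ in range(a.h_count):
                atoms.append(Atom(nxt, "H", 0, 0))
                bonds.append(Bond(a.index, nxt, 1))
                nxt += 1
        return MolecularGraph(atoms, bonds, name=self.name)

    def diameter(self) -> int:
        """Longest shortest-path (in bonds) between any two atoms."""
        best = 0
        for a in self.atoms:
            dist = self._bfs_depths(a.index, len(self))
            best = max(best, max(dist.values(), default=0))
        return best

    def _bfs_depths(self, root: int, h: int) -> Dict[int, int]:
        dist = {root: 0}
        q = deque([root])
        while q:
            u = q.popleft()
            if dist[u] == h:
                continue
            for v in self._adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        return dist


@dataclass(frozen=True)
class AtomicSignature:
    root: int
    height: int
    string: str


@dataclass(frozen=True)
class SignatureVector:
    """Sparse molecular signature: canonical atomic-signature string -> count."""

    height: int
    entries: Mapping[str, int]

    def __post_init__(self):
        if any(c <= 0 for c in self.entries.values()):
            raise ValueError("signature counts must be strictly positive")

    def total(self) -> int:
        return sum(self.entries.values())


@dataclass(frozen=True)
class ReactionSignature:
    """Signed signature: products minus substrates, stoichiometry-weighted."""

    height: int
    entries: Mapping[str, int]

    def __post_init__(self):
        if any(v == 0 for v in self.entries.values()):
            raise ValueError("reaction signature entries must be nonzero")


# ---------------------------------------------------------------------------
# canonicalisation


def _rooted_subgraph(mol: MolecularGraph, root: int, h: int):
    """Atoms within ``h`` bonds of root plus all bonds among them."""
    depths = mol._bfs_depths(root, h)
    keep = sorted(depths)
    local = {g: i for i, g in enumerate(keep)}
    labels = [mol.atoms[g].label() for g in keep]
    adj: List[Dict[int, str]] = [{} for _ in keep]
    for b in mol.bonds:
        if b.i in depths and b.j in depths:
            li, lj = local[b.i], local[b.j]
            adj[li][lj] = b.symbol()
            adj[lj][li] = b.symbol()
    return labels, adj, local[root]


def _chunk(v: int, pos: Dict[int, int], labels, adj) -> tuple:
    back = sorted((pos[u], _BOND_RANK[sym]) for u, sym in adj[v].items() if u in pos)
    # more back-edges sort first so the minimum is attained on connected orders
    return (-len(back), labels[v], tuple(back))


def _serialize(order: Sequence[int], labels, adj) -> Tuple[tuple, ...]:
    pos: Dict[int, int] = {}
    chunks = []
    for v in order:
        chunks.append(_chunk(v, pos, labels, adj))
        pos[v] = len(pos)
    return tuple(chunks)


def _canonical_chunks(labels, adj, root: int) -> Tuple[tuple, ...]:
    n = len(labels)
    # frontier of equally-minimal prefixes: list of (order tuple, placed set)
    states = [((root,), frozenset([root]))]
    chunks = [_chunk(root, {}, labels, adj)]
    for _ in range(n - 1):
        best = None
        nxt = []
        for order, placed in states:
            pos = {v: i for i, v in enumerate(order)}
            for v in range(n):
                if v in placed:
                    continue
                c = _chunk(v, pos, labels, adj)
                if best is None or c < best:
                    best = c
                    nxt = [(order + (v,), placed | {v})]
                elif c == best:
                    nxt.append((order + (v,), placed | {v}))
        chunks.append(best)
        # dedupe identical orders reached through different tie branches
        states = list({o: (o, p) for o, p in nxt}.values())
    return tuple(chunks)


def _render(chunks: Iterable[tuple]) -> str:
    parts = []
    for _neg, label, back in chunks:
        rev = {v: k for k, v in _BOND_RANK.items()}
        edges = ",".join(f"{rev[r]}{p}" for p, r in back)
        parts.append(label + (f"({edges})" if edges else ""))
    return ".".join(parts)


def brute_force_atomic_signature(mol: MolecularGraph, root: int, h: int) -> str:
    """Independent oracle: minimise the serialisation over all atom orders.

    Exponential; intended for graphs with small neighbourhoods only.
    """
    from itertools import permutations

    labels, adj, lroot = _rooted_subgraph(mol, root, h)
    rest = [v for v in range(len(labels)) if v != lroot]
    best = min(_serialize((lroot,) + p, labels, adj) for p in permutations(rest)) if rest else _serialize((lroot,), labels, adj)
    return _render(best)


# ---------------------------------------------------------------------------
# public operations


def atomic_signature(mol: MolecularGraph, root: int, h: int) -> AtomicSignature:
    """Canonical signature of the subgraph within ``h`` bonds of ``root``."""
    if h < 0:
        raise ValueError("height must be non-negative")
    if not (0 <= root < len(mol)):
        raise ValueError(f"invalid root atom index {root}")
    labels, adj, lroot = _rooted_subgraph(mol, root, h)
    return AtomicSignature(root, h, _render(_canonical_chunks(labels, adj, lroot)))


def molecular_signature(mol: MolecularGraph, h: int) -> SignatureVector:
    """Count vector of atomic signatures over all heavy atoms (sums to |V|)."""
    if len(mol) == 0:
        raise ValueError("empty molecule")
    counts = Counter(atomic_signature(mol, a.index, h).string for a in mol.atoms)
    return SignatureVector(h, dict(counts))


def reaction_signature(
    substrates: Sequence[Tuple[int, MolecularGraph]],
    products: Sequence[Tuple[int, MolecularGraph]],
    h: int,
    representation: str = "heavy",
) -> ReactionSignature:
    """Products-minus-substrates signature; unchanged substructures cancel.

    ``representation`` selects the molecular coding:

    ``heavy``
        hydrogen-suppressed graph, atomic signatures at the single height
        ``h``.  This is the coding used for extended-reaction-space
        equality searches.
    ``explicit_h``
        hydrogen-explicit graph with a cumulative signature dictionary:
        all radii 0..h+1 contribute, keyed by (radius, string).  The extra
        layer carries the hydrogen envelope of the outermost heavy shell.
        This is the calibrated coding behind :func:`reaction_similarity`.
    """
    if not substrates or not products:
        raise ValueError("a reaction needs at least one substrate and one product")
    if representation == "heavy":
        heights = [h]
        prep = lambda m: m  # noqa: E731
    elif representation == "explicit_h":
        heights = list(range(h + 2))
        prep = lambda m: m.with_explicit_hydrogens()  # noqa: E731
    else:
        raise ValueError(f"unknown representation {representation!r}")
    acc: Counter = Counter()
    for sign, side in ((+1, products), (-1, substrates)):
        for coeff, mol in side:
            if coeff <= 0:
                raise ValueError("stoichiometric coefficients must be positive")
            g = prep(mol)
            for hh in heights:
                for s, c in molecular_signature(g, hh).entries.items():
                    key = s if representation == "heavy" else f"{hh}|{s}"
                    acc[key] += sign * coeff * c
    return ReactionSignature(h, {s: v for s, v in acc.items() if v != 0})


def tanimoto_similarity(
    r1: ReactionSignature, r2: ReactionSignature, convention: str = "minmax"
) -> float:
    """Tanimoto similarity between two reaction signatures, in [0, 1].

    The default ``minmax`` convention splits each signed vector into its
    positive (product-side) and negative (substrate-side) parts, keyed by
    (side, string), and computes sum(min)/sum(max) on the resulting
    non-negative vectors.  The alternative ``dot`` convention is
    <a,b>/(<a,a>+<b,b>-<a,b>) on the raw signed vectors.
    """
    if r1.height != r2.height:
        raise ValueError(f"height mismatch: {r1.height} != {r2.height}")
    if convention == "minmax":
        a = _split(r1)
        b = _split(r2)
        keys = set(a) | set(b)
        num = sum(min(a.get(k, 0), b.get(k, 0)) for k in keys)
        den = sum(max(a.get(k, 0), b.get(k, 0)) for k in keys)
        return 1.0 if den == 0 else num / den
    if convention == "dot":
        keys = set(r1.entries) | set(r2.entries)
        ab = sum(r1.entries.get(k, 0) * r2.entries.get(k, 0) for k in keys)
        if ab <= 0:  # anticorrelated signed vectors share no transformation
            return 0.0 if r1.entries or r2.entries else 1.0
        aa = sum(v * v for v in r1.entries.values())
        bb = sum(v * v for v in r2.entries.values())
        den = aa + bb - ab
        return 1.0 if den == 0 else ab / den
    raise ValueError(f"unknown Tanimoto convention {convention!r}")


def _split(r: ReactionSignature) -> Dict[Tuple[str, str], int]:
    out: Dict[Tuple[str, str], int] = {}
    for s, v in r.entries.items():
        out[("p" if v > 0 else "s", s)] = abs(v)
    return out


def reaction_similarity(
    substrates1: Sequence[Tuple[int, MolecularGraph]],
    products1: Sequence[Tuple[int, MolecularGraph]],
    substrates2: Sequence[Tuple[int, MolecularGraph]],
    products2: Sequence[Tuple[int, MolecularGraph]],
    h: int,
    representation: str = "explicit_h",
    convention: str = "minmax",
) -> float:
    """Chemical similarity between two reactions at heavy height ``h``.

    The default (calibrated) coding is the hydrogen-inclusive cumulative
    representation with the min/max Tanimoto; the hydrolase pair of
    6-aminohexanoate dimer and 4-(gamma-glutamylamino)butanoate scores 1.0
    at h=1 and 0.81 at h=2 under it.
    """
    r1 = reaction_signature(substrates1, products1, h, representation=representation)
    r2 = reaction_signature(substrates2, products2, h, representation=representation)
    return tanimoto_similarity(r1, r2, convention=convention)


def reaction_distance(
    r1: ReactionSignature, r2: ReactionSignature, convention: str = "minmax"
) -> float:
    """Chemical dissimilarity d = 1 - Tanimoto similarity."""
    return 1.0 - tanimoto_similarity(r1, r2, convention=convention)
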