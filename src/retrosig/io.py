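"""File formats: molecules, networks, sequence/kinetic tables, pathways.

All tabular outputs are TSV with a provenance header line embedding the
resolved run configuration; all readers are strict and report the file,
record or line of the first offence.
"""

from __future__ import annotations

import json
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .config import RunConfig
from .network import (
    Compound,
    GroupContributionTable,
    MetabolicNetwork,
    NetworkReaction,
)
from .retro import Pathway
from .signatures import MolecularGraph

__all__ = [
    "read_smiles_file",
    "read_sdf",
    "read_compound_tsv",
    "write_compound_tsv",
    "read_reaction_tsv",
    "write_reaction_tsv",
    "read_network_tsv",
    "network_to_json",
    "network_from_json",
    "read_group_table",
    "write_group_table",
    "read_fasta",
    "write_fasta",
    "read_kinetics_tsv",
    "read_toxicity_tsv",
    "read_taxonomy_tsv",
    "write_pathways_tsv",
    "read_pathways_tsv",
    "pathways_to_dot",
    "write_tsv",
]


def write_tsv(
    path: str,
    header: Sequence[str],
    rows: Iterable[Sequence],
    config: Optional[RunConfig] = None,
) -> None:
    with open(path, "w") as fh:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _data_lines(path: str) -> List[Tuple[int, str]]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line and not line.startswith("#"):
                out.append((i, line))
    return out


# ---------------------------------------------------------------------------
# molecules


def read_smiles_file(path: str) -> List[Tuple[str, MolecularGraph]]:
    """One SMILES per line, optional tab-separated id."""
    out = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        smiles = parts[0].strip()
        cid = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        try:
            out.append((cid, MolecularGraph.from_smiles(smiles, name=cid)))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_sdf(path: str) -> List[MolecularGraph]:
    """SDF V2000 records via RDKit; errors name the failing record index."""
    from rdkit import Chem

    out = []
    with open(path, "rb") as fh:
        supplier = Chem.ForwardSDMolSupplier(fh, sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"{path}: unparsable SDF record #{i}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{i}"
            out.append(MolecularGraph.from_rdkit(mol, name=name))
    return out


# ---------------------------------------------------------------------------
# networks


def write_compound_tsv(path: str, net: MetabolicNetwork, config: Optional[RunConfig] = None) -> None:
    from rdkit import Chem

    rows = []
    for cid in sorted(net.compounds):
        c = net.compounds[cid]
        mol = Chem.MolFromSmiles(_graph_smiles(c.structure))
        rows.append((cid, Chem.MolToSmiles(mol), int(c.endogenous)))
    write_tsv(path, ["id", "smiles", "endogenous"], rows, config)


def _graph_smiles(g: MolecularGraph) -> str:
    """Rebuild a SMILES via RDKit from the heavy-atom graph."""
    from rdkit import Chem

    em = Chem.RWMol()
    for a in g.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.charge)
        at.SetNumExplicitHs(a.h_count)
        at.SetNoImplicit(True)
        em.AddAtom(at)
    order_map = {
        1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE, "aromatic": Chem.BondType.AROMATIC,
    }
    for b in g.bonds:
        em.AddBond(b.i, b.j, order_map[b.order])
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def read_compound_tsv(path: str) -> Tuple[Dict[str, Compound], List[str]]:
    """Columns id, smiles, endogenous(0/1); returns compounds and chassis ids."""
    compounds: Dict[str, Compound] = {}
    chassis: List[str] = []
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty compound table")
    start = 1 if lines[0][1].lower().startswith("id\t") else 0
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        cid, smiles, endo = parts
        endogenous = endo.strip() == "1"
        try:
            compounds[cid] = Compound(cid, MolecularGraph.from_smiles(smiles, name=cid), endogenous)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if endogenous:
            chassis.append(cid)
    return compounds, chassis


def _format_equation(r: NetworkReaction) -> str:
    def side(terms):
        return " + ".join(f"{k} {c}" if k != 1 else c for k, c in terms)

    arrow = "<=>" if r.direction == "reversible" else "=>"
    return f"{side(r.substrates)} {arrow} {side(r.products)}"


def _parse_equation(eq: str) -> Tuple[List[Tuple[int, str]], List[Tuple[int, str]], str]:
    if "<=>" in eq:
        arrow, direction = "<=>", "reversible"
    elif "=>" in eq:
        arrow, direction = "=>", "forward"
    else:
        raise ValueError(f"no arrow ('=>' or '<=>') in equation {eq!r}")
    left, right = eq.split(arrow)

    def side(text):
        terms = []
        for part in text.split(" + "):
            toks = part.split()
            if not toks:
                raise ValueError(f"empty term in equation {eq!r}")
            if len(toks) == 2:
                terms.append((int(toks[0]), toks[1]))
            elif len(toks) == 1:
                terms.append((1, toks[0]))
            else:
                raise ValueError(f"bad term {part!r} in equation {eq!r}")
        return terms

    return side(left), side(right), direction


def write_reaction_tsv(path: str, net: MetabolicNetwork, config: Optional[RunConfig] = None) -> None:
    rows = []
    for rid in sorted(net.reactions):
        r = net.reactions[rid]
        rows.append((rid, r.ec, _format_equation(r), r.provenance, r.parent_id or ""))
    write_tsv(path, ["reaction_id", "EC", "equation", "provenance", "parent"], rows, config)


def read_reaction_tsv(path: str) -> List[NetworkReaction]:
    out = []
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty reaction table")
    start = 1 if lines[0][1].lower().startswith("reaction_id\t") else 0
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 columns")
        rid, ec, eq = parts[0], parts[1], parts[2]
        provenance = parts[3] if len(parts) > 3 and parts[3] else "nominal"
        parent = parts[4] if len(parts) > 4 and parts[4] else None
        try:
            subs, prods, direction = _parse_equation(eq)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        out.append(
            NetworkReaction(rid, ec, subs, prods, direction, provenance, parent)
        )
    return out


def read_network_tsv(compound_path: str, reaction_path: str) -> MetabolicNetwork:
    compounds, chassis = read_compound_tsv(compound_path)
    reactions = read_reaction_tsv(reaction_path)
    return MetabolicNetwork(compounds.values(), reactions, chassis)


def network_to_json(net: MetabolicNetwork) -> str:
    doc = {
        "compounds": [
            {
                "id": c.id,
                "smiles": _graph_smiles(c.structure),
                "endogenous": c.endogenous,
            }
            for c in (net.compounds[k] for k in sorted(net.compounds))
        ],
        "reactions": [
            {
                "id": r.id,
                "ec": r.ec,
                "substrates": [[k, c] for k, c in r.substrates],
                "products": [[k, c] for k, c in r.products],
                "direction": r.direction,
                "provenance": r.provenance,
                "parent_id": r.parent_id,
                "dg": r.dg,
                "flags": sorted(r.flags),
            }
            for r in (net.reactions[k] for k in sorted(net.reactions))
        ],
        "chassis": sorted(net.chassis),
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def network_from_json(text: str) -> MetabolicNetwork:
    doc = json.loads(text)
    compounds = [
        Compound(c["id"], MolecularGraph.from_smiles(c["smiles"], name=c["id"]), c["endogenous"])
        for c in doc["compounds"]
    ]
    reactions = []
    for r in doc["reactions"]:
        rxn = NetworkReaction(
            r["id"], r.get("ec", ""),
            [(int(k), c) for k, c in r["substrates"]],
            [(int(k), c) for k, c in r["products"]],
            r.get("direction", "forward"), r.get("provenance", "nominal"),
            r.get("parent_id"), r.get("dg"),
        )
        rxn.flags = set(r.get("flags", []))
        reactions.append(rxn)
    return MetabolicNetwork(compounds, reactions, doc.get("chassis", []))


# ---------------------------------------------------------------------------
# auxiliary tables


def write_group_table(path: str, table: GroupContributionTable, config: Optional[RunConfig] = None) -> None:
    rows = [(sig, f"{dg:.6g}") for sig, dg in sorted(table.contributions.items())]
    write_tsv(path, ["signature", "dG"], rows, config)


def read_group_table(path: str, height: int = 1) -> GroupContributionTable:
    contributions = {}
    lines = _data_lines(path)
    start = 1 if lines and lines[0][1].lower().startswith("signature\t") else 0
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        try:
            contributions[parts[0]] = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad dG {parts[1]!r}") from exc
    return GroupContributionTable(contributions, height)


def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    out: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(path: str, seqs: Dict[str, str]) -> None:
    with open(path, "w") as fh:
        for sid in sorted(seqs):
            fh.write(f">{sid}\n")
            s = seqs[sid]
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")


def read_kinetics_tsv(path: str):
    from .predictors import KineticRecord

    out = []
    lines = _data_lines(path)
    start = 1 if lines and lines[0][1].lower().startswith("enzyme_id\t") else 0
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected >=4 columns")
        ki = float(parts[4]) if len(parts) > 4 and parts[4] else None
        out.append(
            KineticRecord(parts[0], parts[1], float(parts[2]), float(parts[3]), ki)
        )
    return out


def read_toxicity_tsv(path: str) -> List[Tuple[str, float]]:
    """Rows of (compound_id, IC50); units column is carried but not used."""
    out = []
    lines = _data_lines(path)
    start = 1 if lines and lines[0][1].lower().startswith("compound_id\t") else 0
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected >=2 columns")
        out.append((parts[0], float(parts[1])))
    return out


def read_taxonomy_tsv(path: str) -> List[Tuple[str, str]]:
    """Parent-child organism pairs."""
    out = []
    lines = _data_lines(path)
    start = 1 if lines and lines[0][1].lower().startswith("parent\t") else 0
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        out.append((parts[0], parts[1]))
    return out


# ---------------------------------------------------------------------------
# pathways


def write_pathways_tsv(path: str, pathways: Sequence[Pathway], config: Optional[RunConfig] = None) -> None:
    rows = [
        (i + 1, p.target, ";".join(p.reactions), len(p))
        for i, p in enumerate(pathways)
    ]
    write_tsv(path, ["pathway", "target", "reactions", "length"], rows, config)


def read_pathways_tsv(path: str) -> List[Pathway]:
    out = []
    lines = _data_lines(path)
    start = 1 if lines and lines[0][1].lower().startswith("pathway\t") else 0
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        reactions = parts[2].split(";") if parts[2] else []
        out.append(Pathway(target=parts[1], reactions=reactions))
    return out


def pathways_to_dot(
    pathways: Sequence[Pathway], net: MetabolicNetwork, target: str
) -> str:
    """Retrosynthetic map in DOT: grey endogenous nodes, circles for
    reactions, the target at the bottom."""
    lines = ["digraph retrosynthesis {", "  rankdir=TB;"]
    compounds: set = set()
    edges = []
    used_edges: set = set()
    for p in pathways:
        for eid in p.reactions:
            if eid in used_edges:
                continue
            used_edges.add(eid)
            rid = eid.rstrip("<>")
            rxn = net.reactions[rid]
            subs = [c for _, c in rxn.substrates]
            prods = [c for _, c in rxn.products]
            if eid.endswith("<"):
                subs, prods = prods, subs
            node = f'"{eid}"'
            edges.append(f'  {node} [shape=circle,label="{rxn.ec or rid}"];')
            for c in subs:
                edges.append(f'  "{c}" -> {node};')
                compounds.add(c)
            for c in prods:
                edges.append(f'  {node} -> "{c}";')
                compounds.add(c)
    for c in sorted(compounds):
        endo = c in net.chassis
        style = "filled" if endo else "solid"
        fill = "gray" if endo else "white"
        shape = "box"
        extra = ",penwidth=2" if c == target else ""
        lines.append(
            f'  "{c}" [shape={shape},style={style},fillcolor={fill}{extra}];'
        )
    lines.extend(edges)
    lines.append("}")
    return "\n".join(lines)
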