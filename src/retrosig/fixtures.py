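"""Seeded synthetic fixtures: toy networks, sequences, kinetics, toxicity.

Everything the design stack consumes can be generated here without any
external database.  The generators plant known structure so that recovery
tests have ground truth:

* toy metabolic networks contain ether isomer pairs C_p-O-C_q with fixed
  p+q (p, q >= 3), which share their height-1 molecular signature but
  separate at height >= 3 — the degeneracy that drives the extended
  reaction space;
* promiscuous enzymes carry a repeated sequence motif;
* kinetic records follow a known descriptor split with additive noise;
* toxicity follows a known linear model in the package's own descriptors;
* chassis genes differ from background genes in GC content and
  hydropathy by a stated margin.

The same spec always yields byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import RunConfig
from .flux import StoichiometricModel
from .network import (
    Compound,
    GroupContributionTable,
    MetabolicNetwork,
    NetworkReaction,
)
from .predictors import (
    EnzymeSequence,
    KineticRecord,
    compound_descriptors,
    TOXICITY_FEATURES,
)
from .ranking import PathwayScore, PathwayWeights, ScoredReaction
from .signatures import MolecularGraph

__all__ = [
    "FixtureSpec",
    "ether_pair",
    "generate_toy_network",
    "generate_group_table",
    "generate_predictor_data",
    "generate_ranking_corpus",
    "toy_chain_model",
    "toy_tradeoff_model",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


@dataclass
class FixtureSpec:
    """Reproducible description of a synthetic workspace."""

    seed: int = 0
    n_pairs: int = 1               # planted signature-equivalent ether pairs
    n_enzymes: int = 24
    n_promiscuity_sequences: int = 200
    motif: str = "WWHWW"           # planted promiscuity marker
    motif_copies: int = 3          # effect size of the marker
    kinetic_noise: float = 0.15    # sd of log10(kcat/KM) around the split
    kinetic_split: float = 2.0     # planted efficiency gap across the split
    toxicity_noise: float = 0.0    # sd of log10 IC50 around the linear model
    gc_separation: float = 0.25    # chassis vs background GC-content gap
    chassis_organism: str = "ECO"


def ether_pair(total_carbons: int) -> Tuple[str, str]:
    """Two ether isomers C_p-O-C_q with p+q = total sharing their height-1
    molecular signature; requires total >= 8 so both tails keep q >= 3."""
    if total_carbons < 8:
        raise ValueError("need at least 8 carbons for a signature-equivalent pair")
    p1, q1 = total_carbons - 4, 4
    p2, q2 = total_carbons - 3, 3
    mk = lambda p, q: "C" * p + "O" + "C" * q  # noqa: E731
    return mk(p1, q1), mk(p2, q2)


def generate_toy_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Branched chassis-to-target network with planted equivalences.

    Two nominal routes reach the target (a branch point in the
    retrosynthetic map); each planted ether pair adds a compound that is
    signature-equivalent at height 1 to a pathway intermediate, so the
    extended space at low height opens extra routes that close again at
    height >= 3.
    """
    if spec.n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    compounds = {
        "CHS_ETOH": ("CCO", True),
        "CHS_GLY": ("NCC(=O)O", True),
        "CHS_ACE": ("CC(=O)O", True),
        "CHS_PROH": ("CCCO", True),
        "WATER": ("O", True),
        "INT_EA": ("OCCN", False),
        "INT_LAC": ("CC(O)C(=O)O", False),
        "TGT": ("C=CCOCC=C", False),
    }
    reactions = [
        NetworkReaction("R01", "2.3.1.-", [(1, "CHS_ETOH"), (1, "CHS_GLY")],
                        [(1, "INT_EA"), (1, "WATER")]),
        NetworkReaction("R04", "1.1.1.-", [(1, "CHS_ACE")], [(1, "INT_LAC")],
                        direction="reversible"),
        NetworkReaction("R05", "4.2.1.-", [(1, "INT_LAC")], [(1, "TGT")]),
    ]
    for i in range(spec.n_pairs):
        a, b = ether_pair(8 + i)
        xa, xb = f"ETH_A{i}", f"ETH_B{i}"
        compounds[xa] = (a, False)
        compounds[xb] = (b, False)
        # route through the A-isomer; the B-isomer is reachable from the
        # chassis so the low-height expansion can splice it in
        reactions.append(
            NetworkReaction(f"R1{i}", "2.4.1.-", [(1, "INT_EA")], [(1, xa)])
        )
        reactions.append(
            NetworkReaction(f"R2{i}", "3.2.1.-", [(1, xa)], [(1, "TGT")])
        )
        reactions.append(
            NetworkReaction(f"R3{i}", "1.1.3.-", [(1, "CHS_PROH")], [(1, xb)])
        )
    comp_objs = [
        Compound(cid, MolecularGraph.from_smiles(smi, name=cid), endo)
        for cid, (smi, endo) in compounds.items()
    ]
    chassis = [cid for cid, (_, endo) in compounds.items() if endo]
    return MetabolicNetwork(comp_objs, reactions, chassis)


def generate_group_table(net: MetabolicNetwork, seed: int, height: int = 1) -> GroupContributionTable:
    """Synthetic group contributions covering every subgroup in the network."""
    rng = np.random.default_rng(seed)
    sigs = sorted(
        {s for c in net.compounds.values() for s in c.signature(height).entries}
    )
    return GroupContributionTable(
        {s: float(rng.normal(-20.0, 10.0)) for s in sigs}, height
    )


# ---------------------------------------------------------------------------
# predictor fixtures


def _random_seq(rng, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def generate_predictor_data(
    spec: FixtureSpec, net: Optional[MetabolicNetwork] = None
) -> Dict[str, object]:
    """Enzymes, promiscuity training set, kinetics, toxicity, taxonomy.

    Returns a dict with keys: enzymes (list of EnzymeSequence),
    promiscuity_sequences, promiscuity_labels, kinetics (KineticRecord
    list), toxicity (list of (Compound, IC50)), toxicity_coefficients,
    taxonomy_edges, organisms.
    """
    rng = np.random.default_rng(spec.seed)
    net = net if net is not None else generate_toy_network(spec)
    rids = sorted(net.reactions)

    organisms = [spec.chassis_organism, "ORG1", "ORG2", "ORG3", "ORG4"]
    taxonomy_edges = [
        ("ROOT", "CLADE_A"), ("ROOT", "CLADE_B"),
        ("CLADE_A", spec.chassis_organism), ("CLADE_A", "ORG1"),
        ("CLADE_B", "ORG2"), ("CLADE_B", "ORG3"), ("CLADE_B", "ORG4"),
    ]

    enzymes: List[EnzymeSequence] = []
    for i in range(spec.n_enzymes):
        org = organisms[int(rng.integers(len(organisms)))]
        chassis_like = org == spec.chassis_organism
        length = int(rng.integers(150, 400))
        aa = _random_seq(rng, AA, length)
        gc = 0.5 + (spec.gc_separation / 2 if chassis_like else -spec.gc_separation / 2)
        nt = "".join(
            ("G" if rng.random() < 0.5 else "C") if rng.random() < gc
            else ("A" if rng.random() < 0.5 else "T")
            for _ in range(3 * length)
        )
        n_rxn = int(rng.integers(1, 3))
        cat = sorted(
            rids[j] for j in rng.choice(len(rids), size=min(n_rxn, len(rids)), replace=False)
        )
        enzymes.append(EnzymeSequence(f"ENZ{i:03d}", aa, nt, org, cat))

    # promiscuity training sequences with a planted motif
    seqs, labels = [], []
    for i in range(spec.n_promiscuity_sequences):
        promiscuous = i % 2 == 0
        s = _random_seq(rng, AA, int(rng.integers(80, 150)))
        if promiscuous:
            for _ in range(spec.motif_copies):
                pos = int(rng.integers(0, len(s) - len(spec.motif)))
                s = s[:pos] + spec.motif + s[pos + len(spec.motif):]
        seqs.append(s)
        labels.append(int(promiscuous))

    # kinetics: efficiency split on a planted sequence-length threshold
    kinetics: List[KineticRecord] = []
    for enz in enzymes:
        for rid in enz.reaction_ids:
            base = 2.0 + (spec.kinetic_split if len(enz.aa) > 270 else 0.0)
            eff = base + rng.normal(0.0, spec.kinetic_noise)
            km = 1e-4
            kinetics.append(KineticRecord(enz.id, rid, km * 10.0 ** eff, km))

    # toxicity: linear model in the package's own descriptors
    tox_smiles = [
        "CCO", "CCCO", "CCCCO", "CCN", "CCCN", "CC(=O)O", "CCC(=O)O",
        "CC(=O)N", "CCS", "OCCO", "OCCCO", "NCCN", "CC(C)O", "CC(C)N",
        "CCOC", "CCOCC", "CC=O", "CCC=O", "C1CCCCC1", "c1ccccc1",
        "c1ccncc1", "CC#N", "CCCl", "OCC(O)CO",
    ]
    coef = {"mol_weight": -0.01, "solubility_surrogate": 1.5, "logp_surrogate": -0.8}
    toxicity: List[Tuple[Compound, float]] = []
    for i, smi in enumerate(tox_smiles):
        c = Compound(f"TOX{i:02d}", MolecularGraph.from_smiles(smi, name=f"TOX{i:02d}"))
        d = compound_descriptors(c)
        log_ic50 = 1.0 + sum(coef[k] * d[k] for k in coef)
        log_ic50 += rng.normal(0.0, spec.toxicity_noise)
        toxicity.append((c, 10.0 ** log_ic50))

    return {
        "enzymes": enzymes,
        "promiscuity_sequences": seqs,
        "promiscuity_labels": labels,
        "kinetics": kinetics,
        "toxicity": toxicity,
        "toxicity_coefficients": coef,
        "taxonomy_edges": taxonomy_edges,
        "organisms": organisms,
    }


def generate_ranking_corpus(
    seed: int,
    n_compounds: int = 6,
    pathways_per_compound: int = 5,
    tox_separation: float = 1.0,
    flux_separation: float = 0.0,
) -> Dict[str, List[PathwayScore]]:
    """Per-compound pathway sets with one annotated route per compound.

    Annotated pathways carry systematically lower summed toxicity (and/or
    higher nominal flux) than predicted ones by the stated separation, on
    top of seeded noise, so weight optimisation has signal to find.
    """
    rng = np.random.default_rng(seed)
    corpus: Dict[str, List[PathwayScore]] = {}
    for ci in range(n_compounds):
        scores = []
        for pi in range(pathways_per_compound):
            annotated = pi == 0
            n_steps = int(rng.integers(2, 5))
            steps = []
            for si in range(n_steps):
                tox = float(rng.uniform(0.2, 1.0))
                if annotated:
                    tox = max(0.0, tox - tox_separation / n_steps)
                steps.append(
                    ScoredReaction(
                        reaction_id=f"C{ci}P{pi}S{si}",
                        ec="1.1.1.-",
                        enzyme_id=f"E{ci}{pi}{si}",
                        cost=float(rng.uniform(0.5, 2.0)),
                        product_tox={f"M{ci}{pi}{si}": tox},
                    )
                )
            v_c = float(rng.uniform(0.5, 3.0)) + (flux_separation if annotated else 0.0)
            scores.append(
                PathwayScore(f"C{ci}_rho{pi}", steps, v_c, PathwayWeights(), annotated)
            )
        corpus[f"C{ci}"] = scores
    return corpus


# ---------------------------------------------------------------------------
# toy stoichiometric models


def toy_chain_model(uptake: float = 10.0) -> StoichiometricModel:
    """Uptake (<= bound) -> A -> biomass with unit stoichiometry."""
    return StoichiometricModel(
        compounds=["A"],
        reactions=["UPT", "BIO"],
        stoich={("A", "UPT"): 1.0, ("A", "BIO"): -1.0},
        lower={"UPT": 0.0, "BIO": 0.0},
        upper={"UPT": uptake, "BIO": 1000.0},
        biomass="BIO",
        exchanges=["UPT"],
    )


def toy_tradeoff_model(uptake: float = 10.0) -> StoichiometricModel:
    """Growth and production compete linearly for one substrate:
    v_c = uptake - Z, so v_c * Z peaks at Z = Z_max / 2."""
    return StoichiometricModel(
        compounds=["S", "P"],
        reactions=["UPT", "BIO", "PRD"],
        stoich={
            ("S", "UPT"): 1.0,
            ("S", "BIO"): -1.0,
            ("S", "PRD"): -1.0,
            ("P", "PRD"): 1.0,
        },
        lower={"UPT": 0.0, "BIO": 0.0, "PRD": 0.0},
        upper={"UPT": uptake, "BIO": 1000.0, "PRD": 1000.0},
        biomass="BIO",
        exchanges=["UPT"],
    )
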