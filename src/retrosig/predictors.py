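"""Enzyme and compound scoring for pathway ranking.

This module houses the machine-learning stack that prices each step of a
candidate pathway: a k-mer spectrum string kernel over enzyme sequences, a
promiscuity score derived from the chemical dissimilarity of an enzyme's
catalysed reactions, agglomerative clustering of the reaction space with
silhouette-selected granularity, a tensor-product enzyme-reaction kernel
for proposing candidate sequences for putative reactions, a regression
tree for catalytic performance from kinetic constants, a sequence/organism
compatibility classifier, and a partial-least-squares toxicity model.

All scores consumed by the ranking layer are in [0, 1].
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .config import RunConfig
from .network import Compound, MetabolicNetwork
from .signatures import molecular_signature, tanimoto_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeSequence",
    "KmerSpectrum",
    "kmer_spectrum",
    "string_kernel",
    "promiscuity_score",
    "PromiscuityClassifier",
    "ReactionClustering",
    "cluster_reactions",
    "similarity_matrix",
    "tensor_kernel",
    "candidate_enzymes",
    "KineticRecord",
    "PerformanceModel",
    "train_performance_model",
    "Taxonomy",
    "compatibility_descriptors",
    "CompatibilityModel",
    "train_compatibility",
    "gene_rank_pvalue",
    "ToxicityModel",
    "train_toxicity",
    "compound_descriptors",
]


@dataclass
class EnzymeSequence:
    id: str
    aa: str
    nt: Optional[str] = None
    organism: Optional[str] = None
    reaction_ids: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# string kernel


@dataclass(frozen=True)
class KmerSpectrum:
    k: int
    counts: Mapping[str, int]


def kmer_spectrum(seq: str, k: int) -> KmerSpectrum:
    """Sliding-window k-mer counts; total count is len(seq) - k + 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    return KmerSpectrum(k, dict(Counter(seq[i : i + k] for i in range(len(seq) - k + 1))))


def string_kernel(s1: str, s2: str, k: int) -> float:
    """Cosine-normalised spectrum kernel in [0, 1]; 1.0 for identical input."""
    a = kmer_spectrum(s1, k).counts
    b = kmer_spectrum(s2, k).counts
    num = sum(v * b.get(km, 0) for km, v in a.items())
    if num == 0:
        return 0.0
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    return num / (na * nb)


def _gram(seqs: Sequence[str], k: int) -> np.ndarray:
    spectra = [kmer_spectrum(s, k).counts for s in seqs]
    norms = [math.sqrt(sum(v * v for v in sp.values())) for sp in spectra]
    n = len(seqs)
    G = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            num = sum(v * spectra[j].get(km, 0) for km, v in spectra[i].items())
            G[i, j] = G[j, i] = num / (norms[i] * norms[j])
    return G


# ---------------------------------------------------------------------------
# reaction similarity helpers


def reaction_pair_similarity(
    net: MetabolicNetwork, rid1: str, rid2: str, h: int, config: Optional[RunConfig] = None
) -> float:
    cfg = config or RunConfig()
    r1 = net.reaction_signature_of(rid1, h, representation=cfg.similarity_representation)
    r2 = net.reaction_signature_of(rid2, h, representation=cfg.similarity_representation)
    return tanimoto_similarity(r1, r2, convention=cfg.tanimoto_convention)


def similarity_matrix(
    net: MetabolicNetwork, rids: Sequence[str], h: int, config: Optional[RunConfig] = None
) -> np.ndarray:
    cfg = config or RunConfig()
    sigs = [
        net.reaction_signature_of(r, h, representation=cfg.similarity_representation)
        for r in rids
    ]
    n = len(rids)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = tanimoto_similarity(
                sigs[i], sigs[j], convention=cfg.tanimoto_convention
            )
    return M


# ---------------------------------------------------------------------------
# promiscuity


def promiscuity_score(
    enz: EnzymeSequence,
    net: MetabolicNetwork,
    h: Optional[int] = None,
    config: Optional[RunConfig] = None,
    aggregate: str = "min",
) -> float:
    """Chemical breadth of an enzyme's catalysed reactions, in [0, 1].

    Defined as one minus the minimum (default) or mean pairwise similarity
    of the catalysed reactions; enzymes with at most one known reaction
    score 0.  Invariant to the order of the reaction list.
    """
    cfg = config or RunConfig()
    hh = cfg.height if h is None else h
    rids = sorted(set(enz.reaction_ids))
    if len(rids) < 2:
        return 0.0
    M = similarity_matrix(net, rids, hh, cfg)
    pair = [M[i, j] for i in range(len(rids)) for j in range(i + 1, len(rids))]
    if aggregate == "min":
        return 1.0 - min(pair)
    if aggregate == "mean":
        return 1.0 - float(np.mean(pair))
    raise ValueError(f"unknown aggregate {aggregate!r}")


class PromiscuityClassifier:
    """Kernel classifier over k-mer spectra predicting promiscuity.

    Any learner accepting a precomputed Gram matrix can stand behind this
    contract; the default is a support-vector classifier with Platt
    calibration, with a deterministic kernel-nearest-neighbour fallback
    when the training set is too small for calibration.
    """

    def __init__(self, k: int = 3, seed: int = 0):
        self.k = k
        self.seed = seed
        self._seqs: List[str] = []
        self._labels: Optional[np.ndarray] = None
        self._svc = None

    def fit(self, sequences: Sequence[str], labels: Sequence[int]) -> "PromiscuityClassifier":
        labels = np.asarray(labels, dtype=int)
        if len(set(labels.tolist())) < 2:
            raise ValueError("training set must contain both classes")
        self._seqs = list(sequences)
        self._labels = labels
        from sklearn.svm import SVC

        G = _gram(self._seqs, self.k)
        self._svc = SVC(kernel="precomputed", probability=True, random_state=self.seed)
        self._svc.fit(G, labels)
        return self

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        """Calibrated promiscuity probability in [0, 1] per sequence."""
        if self._svc is None:
            raise ValueError("classifier is not trained")
        K = np.array(
            [[string_kernel(s, t, self.k) for t in self._seqs] for s in sequences]
        )
        pos = list(self._svc.classes_).index(1)
        return self._svc.predict_proba(K)[:, pos]


# ---------------------------------------------------------------------------
# reaction clustering


@dataclass
class ReactionClustering:
    reaction_ids: List[str]
    labels: np.ndarray               # cluster index per reaction
    n: int
    silhouettes: Dict[int, float]    # candidate n -> average silhouette

    def members(self, cluster: int) -> List[str]:
        return [r for r, l in zip(self.reaction_ids, self.labels) if l == cluster]

    def clusters(self) -> Dict[int, List[str]]:
        return {c: self.members(c) for c in sorted(set(self.labels.tolist()))}


def cluster_reactions(
    net: MetabolicNetwork,
    rids: Sequence[str],
    h: Optional[int] = None,
    n_range: Optional[Sequence[int]] = None,
    config: Optional[RunConfig] = None,
) -> ReactionClustering:
    """Average-linkage agglomerative clustering on d = 1 - similarity.

    The cluster count is the silhouette argmax over the scanned range,
    with ties broken toward fewer clusters; if no candidate admits a
    defined silhouette (e.g. all reactions identical) a single cluster is
    returned by convention.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    from sklearn.metrics import silhouette_score

    cfg = config or RunConfig()
    rids = list(rids)
    if len(rids) < 2:
        raise ValueError("clustering needs at least 2 reactions")
    hh = cfg.height if h is None else h
    D = 1.0 - similarity_matrix(net, rids, hh, cfg)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    candidates = list(n_range) if n_range is not None else list(range(2, len(rids)))
    silhouettes: Dict[int, float] = {}
    best_n, best_s = 1, -np.inf
    for n in candidates:
        if not 2 <= n <= len(rids) - 1:
            continue
        labels = fcluster(Z, t=n, criterion="maxclust")
        if len(set(labels.tolist())) < 2:
            continue
        s = float(silhouette_score(D, labels, metric="precomputed"))
        silhouettes[n] = s
        if s > best_s + 1e-12:
            best_n, best_s = n, s
    if best_n == 1:
        labels = np.ones(len(rids), dtype=int)
    else:
        labels = fcluster(Z, t=best_n, criterion="maxclust")
    return ReactionClustering(rids, np.asarray(labels), best_n, silhouettes)


# ---------------------------------------------------------------------------
# tensor-product enzyme-reaction scoring


def tensor_kernel(
    seq1: str, rid1: str, seq2: str, rid2: str,
    net: MetabolicNetwork,
    k: Optional[int] = None,
    h: Optional[int] = None,
    config: Optional[RunConfig] = None,
) -> float:
    """Product of the sequence string kernel and the reaction similarity."""
    cfg = config or RunConfig()
    kk = cfg.kmer if k is None else k
    hh = cfg.height if h is None else h
    ks = string_kernel(seq1, seq2, kk)
    if ks == 0.0:
        return 0.0
    return ks * reaction_pair_similarity(net, rid1, rid2, hh, cfg)


def _assign_cluster(
    net: MetabolicNetwork, rstar: str, clustering: ReactionClustering,
    h: int, cfg: RunConfig,
) -> int:
    """Nearest cluster by average similarity to its member reactions."""
    best_c, best_s = None, -1.0
    for c, members in sorted(clustering.clusters().items()):
        s = float(
            np.mean([reaction_pair_similarity(net, rstar, m, h, cfg) for m in members])
        )
        if s > best_s + 1e-12:
            best_c, best_s = c, s
    return best_c


def candidate_enzymes(
    net: MetabolicNetwork,
    rstar: str,
    enzymes: Sequence[EnzymeSequence],
    clustering: ReactionClustering,
    config: Optional[RunConfig] = None,
    top_n: int = 10,
    trained_min_positives: int = 8,
) -> List[Tuple[EnzymeSequence, float]]:
    """Ranked candidate sequences for a (putative) reaction.

    The reaction is assigned to its nearest cluster; candidates are the
    enzymes with at least one known reaction in that cluster.  Scores come
    from a tensor-product kernel machine trained on known enzyme-reaction
    pairs against sampled negative pairs; when too few positive pairs
    exist for training, the maximum tensor kernel to any known positive
    pair is used instead.  Ties break by enzyme id.
    """
    if not enzymes:
        raise ValueError("empty enzyme database")
    cfg = config or RunConfig()
    cluster = _assign_cluster(net, rstar, clustering, cfg.height, cfg)
    members = set(clustering.members(cluster))
    if not members:
        raise ValueError(f"cluster {cluster} has no member reactions")
    cands = sorted(
        (e for e in enzymes if members & set(e.reaction_ids)), key=lambda e: e.id
    )
    positives = sorted(
        {(e.id, r) for e in cands for r in e.reaction_ids if r in members}
    )
    by_id = {e.id: e for e in cands}

    def max_kernel_score(e: EnzymeSequence) -> float:
        return max(
            tensor_kernel(e.aa, rstar, by_id[eid].aa, rid, net, config=cfg)
            for eid, rid in positives
        )

    if len(positives) >= trained_min_positives:
        scores = _tensor_svm_scores(net, rstar, cands, positives, by_id, cfg)
    else:
        scores = {e.id: max_kernel_score(e) for e in cands}
    ranked = sorted(cands, key=lambda e: (-scores[e.id], e.id))
    return [(e, scores[e.id]) for e in ranked[:top_n]]


def _tensor_svm_scores(net, rstar, cands, positives, by_id, cfg) -> Dict[str, float]:
    """Tensor-kernel SVM over known pairs plus seeded negative pairs."""
    from sklearn.svm import SVC

    rng = np.random.default_rng(cfg.seed)
    all_rids = sorted(net.reactions)
    neg = []
    known = set(positives)
    tries = 0
    while len(neg) < len(positives) and tries < 50 * len(positives):
        tries += 1
        eid = cands[rng.integers(len(cands))].id
        rid = all_rids[rng.integers(len(all_rids))]
        if (eid, rid) not in known and (eid, rid) not in neg:
            neg.append((eid, rid))
    pairs = list(positives) + neg
    y = np.array([1] * len(positives) + [0] * len(neg))
    n = len(pairs)
    G = np.empty((n, n))
    for i, (ei, ri) in enumerate(pairs):
        for j in range(i, n):
            ej, rj = pairs[j]
            G[i, j] = G[j, i] = tensor_kernel(
                by_id[ei].aa, ri, by_id[ej].aa, rj, net, config=cfg
            )
    if len(set(y.tolist())) < 2:
        return {
            e.id: max(
                tensor_kernel(e.aa, rstar, by_id[ei].aa, ri, net, config=cfg)
                for ei, ri in positives
            )
            for e in cands
        }
    svc = SVC(kernel="precomputed", probability=True, random_state=cfg.seed)
    svc.fit(G, y)
    pos_col = list(svc.classes_).index(1)
    K = np.array(
        [
            [
                tensor_kernel(e.aa, rstar, by_id[ej].aa, rj, net, config=cfg)
                for ej, rj in pairs
            ]
            for e in cands
        ]
    )
    proba = svc.predict_proba(K)[:, pos_col]
    return {e.id: float(p) for e, p in zip(cands, proba)}


# ---------------------------------------------------------------------------
# enzyme performance


@dataclass(frozen=True)
class KineticRecord:
    enzyme_id: str
    reaction_id: str
    kcat: float          # 1/s
    km: float            # mol/L
    ki: Optional[float] = None

    def __post_init__(self):
        if self.kcat <= 0 or self.km <= 0 or (self.ki is not None and self.ki <= 0):
            raise ValueError("kinetic constants must be positive")

    def efficiency(self) -> float:
        return math.log10(self.kcat / self.km)


_HYDROPHOBIC = set("AVILMFWY")
_CHARGED = set("DEKRH")


def _enzyme_reaction_features(
    enz: EnzymeSequence, rid: str, net: MetabolicNetwork, h: int
) -> List[float]:
    rxn = net.reactions[rid]
    sig = net.reaction_signature_of(rid, h)
    aa = enz.aa
    return [
        float(len(aa)),
        sum(c in _HYDROPHOBIC for c in aa) / len(aa),
        sum(c in _CHARGED for c in aa) / len(aa),
        float(len(rxn.substrates)),
        float(len(rxn.products)),
        float(len(sig.entries)),
        float(sum(abs(v) for v in sig.entries.values())),
    ]


class PerformanceModel:
    """Per-cluster regression trees predicting log10(kcat/KM).

    Predictions are min-max normalised to [0, 1] over each cluster's
    training efficiency range and clipped; clusters with fewer than
    ``min_records`` records fall back to the documented constant 0.5.
    """

    FALLBACK = 0.5

    def __init__(self, min_records: int = 5, seed: int = 0, height: int = 3):
        self.min_records = min_records
        self.seed = seed
        self.height = height
        self._trees: Dict[int, object] = {}
        self._ranges: Dict[int, Tuple[float, float]] = {}

    def fit(
        self,
        records: Sequence[KineticRecord],
        enzymes: Mapping[str, EnzymeSequence],
        net: MetabolicNetwork,
        clustering: ReactionClustering,
    ) -> "PerformanceModel":
        from sklearn.tree import DecisionTreeRegressor

        self._clustering = clustering
        self._net = net
        by_cluster: Dict[int, List[KineticRecord]] = {}
        label_of = dict(zip(clustering.reaction_ids, clustering.labels.tolist()))
        for rec in records:
            if rec.reaction_id in label_of and rec.enzyme_id in enzymes:
                by_cluster.setdefault(label_of[rec.reaction_id], []).append(rec)
        for cluster, recs in sorted(by_cluster.items()):
            if len(recs) < self.min_records:
                logger.warning(
                    "cluster %d has %d kinetic records (< %d); using fallback 0.5",
                    cluster, len(recs), self.min_records,
                )
                continue
            X = np.array(
                [
                    _enzyme_reaction_features(
                        enzymes[r.enzyme_id], r.reaction_id, net, self.height
                    )
                    for r in recs
                ]
            )
            y = np.array([r.efficiency() for r in recs])
            # leaves of >= 2 records average out measurement noise instead
            # of memorising single observations
            tree = DecisionTreeRegressor(random_state=self.seed, min_samples_leaf=2)
            tree.fit(X, y)
            self._trees[cluster] = tree
            self._ranges[cluster] = (float(y.min()), float(y.max()))
        return self

    def predict_efficiency(
        self, rstar: str, enz: EnzymeSequence, cfg: Optional[RunConfig] = None
    ) -> Optional[float]:
        """Raw log10(kcat/KM) prediction, or None outside fitted clusters."""
        cfg = cfg or RunConfig()
        cluster = _assign_cluster(self._net, rstar, self._clustering, cfg.height, cfg)
        if cluster not in self._trees:
            return None
        x = np.array([_enzyme_reaction_features(enz, rstar, self._net, self.height)])
        return float(self._trees[cluster].predict(x)[0])

    def perf(self, rstar: str, enz: EnzymeSequence, cfg: Optional[RunConfig] = None) -> float:
        cfg = cfg or RunConfig()
        cluster = _assign_cluster(self._net, rstar, self._clustering, cfg.height, cfg)
        if cluster not in self._trees:
            return self.FALLBACK
        x = np.array(
            [_enzyme_reaction_features(enz, rstar, self._net, self.height)]
        )
        yhat = float(self._trees[cluster].predict(x)[0])
        lo, hi = self._ranges[cluster]
        if hi <= lo:
            return self.FALLBACK
        return float(np.clip((yhat - lo) / (hi - lo), 0.0, 1.0))


def train_performance_model(
    records: Sequence[KineticRecord],
    enzymes: Mapping[str, EnzymeSequence],
    net: MetabolicNetwork,
    clustering: ReactionClustering,
    min_records: int = 5,
    seed: int = 0,
    height: int = 3,
) -> PerformanceModel:
    return PerformanceModel(min_records, seed, height).fit(records, enzymes, net, clustering)


# ---------------------------------------------------------------------------
# gene compatibility


class Taxonomy:
    """Organism tree from parent-child pairs; distances are path lengths."""

    def __init__(self, edges: Iterable[Tuple[str, str]]):
        import networkx as nx

        self._g = nx.Graph()
        for parent, child in edges:
            self._g.add_edge(parent, child)

    def distance(self, a: str, b: str) -> float:
        import networkx as nx

        if a == b:
            return 0.0
        try:
            return float(nx.shortest_path_length(self._g, a, b))
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            raise KeyError(f"no taxonomy path between {a!r} and {b!r}")


# Chou-Fasman conformational propensities (helix, sheet, turn)
_CF = {
    "A": (1.42, 0.83, 0.66), "R": (0.98, 0.93, 0.95), "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46), "C": (0.70, 1.19, 1.19), "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74), "G": (0.57, 0.75, 1.56), "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47), "L": (1.21, 1.30, 0.59), "K": (1.16, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60), "F": (1.13, 1.38, 0.60), "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43), "T": (0.83, 1.19, 0.96), "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14), "V": (1.06, 1.70, 0.50),
}

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

COMPATIBILITY_FEATURES = [
    "length", "gc_content", "phylo_distance", "frac_hydrophobic",
    "frac_charged", "helix", "sheet", "turn", "inclusion_body_prob",
]


def gc_content(nt: str) -> float:
    nt = nt.upper()
    if not nt:
        raise ValueError("empty nucleotide sequence")
    return (nt.count("G") + nt.count("C")) / len(nt)


def _inclusion_body_prob(aa: str) -> float:
    """Logistic surrogate from mean hydropathy and length."""
    kd = float(np.mean([_KD.get(c, 0.0) for c in aa]))
    z = 1.5 * kd + 0.002 * (len(aa) - 300)
    return 1.0 / (1.0 + math.exp(-z))


def compatibility_descriptors(
    enz: EnzymeSequence, chassis_organism: str, taxonomy: Optional[Taxonomy]
) -> Dict[str, Optional[float]]:
    """Gene/protein/organism descriptors for heterologous-expression scoring."""
    aa = enz.aa
    cf = np.array([_CF.get(c, (1.0, 1.0, 1.0)) for c in aa])
    out: Dict[str, Optional[float]] = {
        "length": float(len(aa)),
        "gc_content": gc_content(enz.nt) if enz.nt else None,
        "phylo_distance": None,
        "frac_hydrophobic": sum(c in _HYDROPHOBIC for c in aa) / len(aa),
        "frac_charged": sum(c in _CHARGED for c in aa) / len(aa),
        "helix": float(cf[:, 0].mean()),
        "sheet": float(cf[:, 1].mean()),
        "turn": float(cf[:, 2].mean()),
        "inclusion_body_prob": _inclusion_body_prob(aa),
    }
    if taxonomy is not None and enz.organism is not None:
        out["phylo_distance"] = taxonomy.distance(enz.organism, chassis_organism)
    return out


class CompatibilityModel:
    """Binary scorer: how chassis-like a heterologous gene looks.

    Trained on a balanced set: positives are the chassis' own sequences,
    negatives a seeded uniform sample from other organisms.  The het
    score is the classifier's positive-class probability.
    """

    def __init__(self, chassis_organism: str, taxonomy: Optional[Taxonomy] = None, seed: int = 0):
        self.chassis_organism = chassis_organism
        self.taxonomy = taxonomy
        self.seed = seed
        self._pipe = None
        self._impute: Dict[str, float] = {}

    def _vector(self, enz: EnzymeSequence) -> List[float]:
        d = compatibility_descriptors(enz, self.chassis_organism, self.taxonomy)
        return [
            d[f] if d[f] is not None else self._impute.get(f, 0.0)
            for f in COMPATIBILITY_FEATURES
        ]

    def fit(self, db: Sequence[EnzymeSequence]) -> "CompatibilityModel":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        pos = [e for e in db if e.organism == self.chassis_organism]
        neg_pool = sorted(
            (e for e in db if e.organism != self.chassis_organism), key=lambda e: e.id
        )
        if not pos or not neg_pool:
            raise ValueError("need both chassis and non-chassis sequences")
        rng = np.random.default_rng(self.seed)
        neg = [neg_pool[i] for i in rng.choice(len(neg_pool), size=min(len(pos), len(neg_pool)), replace=False)]
        rows = []
        for e in pos + neg:
            rows.append(compatibility_descriptors(e, self.chassis_organism, self.taxonomy))
        for f in COMPATIBILITY_FEATURES:
            vals = [r[f] for r in rows if r[f] is not None]
            self._impute[f] = float(np.mean(vals)) if vals else 0.0
        X = np.array([self._vector(e) for e in pos + neg])
        y = np.array([1] * len(pos) + [0] * len(neg))
        self._pipe = make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=self.seed)
        )
        self._pipe.fit(X, y)
        return self

    def het(self, enz: EnzymeSequence) -> float:
        if self._pipe is None:
            raise ValueError("compatibility model is not trained")
        X = np.array([self._vector(enz)])
        pos = list(self._pipe.classes_).index(1)
        return float(self._pipe.predict_proba(X)[0, pos])


def train_compatibility(
    db: Sequence[EnzymeSequence],
    chassis_organism: str,
    taxonomy: Optional[Taxonomy] = None,
    seed: int = 0,
) -> CompatibilityModel:
    return CompatibilityModel(chassis_organism, taxonomy, seed).fit(db)


def gene_rank_pvalue(rank: int, total: int) -> float:
    """P(rank at least this high under a uniform random draw) = rank/total."""
    if not 1 <= rank <= total:
        raise ValueError(f"rank {rank} outside 1..{total}")
    return rank / total


# ---------------------------------------------------------------------------
# compound toxicity


_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.90,
}
_BOND_LENGTH = {1: 1.54, 2: 1.34, 3: 1.20, "aromatic": 1.40}
_VDW_AREA = {"C": 20.0, "N": 15.0, "O": 14.0, "S": 24.0, "P": 25.0,
             "F": 12.0, "Cl": 18.0, "Br": 21.0, "I": 25.0}

TOXICITY_FEATURES = [
    "mol_weight", "solubility_surrogate", "avg_bond_length",
    "logp_surrogate", "surface_surrogate", "n_signatures",
]


def compound_descriptors(c: Compound, h: int = 1) -> Dict[str, float]:
    """Deterministic 2D descriptors: weight, solubility and partition
    surrogates, mean bond length, surface surrogate, signature richness."""
    g = c.structure
    mw = sum(
        _ATOMIC_MASS.get(a.element, 12.0) + a.h_count * _ATOMIC_MASS["H"]
        for a in g.atoms
    )
    hetero = sum(a.element not in ("C", "H") for a in g.atoms) / len(g)
    carbons = sum(a.element == "C" for a in g.atoms)
    bond_len = (
        float(np.mean([_BOND_LENGTH[b.order] for b in g.bonds])) if g.bonds else 1.54
    )
    surface = sum(_VDW_AREA.get(a.element, 20.0) + 5.0 * a.h_count for a in g.atoms)
    sig = molecular_signature(g, h)
    return {
        "mol_weight": mw,
        "solubility_surrogate": hetero,
        "avg_bond_length": bond_len,
        "logp_surrogate": (carbons - (len(g) - carbons)) / len(g),
        "surface_surrogate": surface,
        "n_signatures": float(len(sig.entries)),
    }


class ToxicityModel:
    """Partial-least-squares structure-activity model for log10 IC50.

    ``tox`` is the inverse of the predicted IC50 on the linear scale, so
    larger values mean more toxic.  The leave-one-out Q-squared of the
    fitted model is reported in ``q2``.
    """

    def __init__(self, components: int = 2, height: int = 1):
        self.components = components
        self.height = height
        self._pls = None
        self.q2: Optional[float] = None

    def _X(self, compounds: Sequence[Compound]) -> np.ndarray:
        return np.array(
            [[compound_descriptors(c, self.height)[f] for f in TOXICITY_FEATURES] for c in compounds]
        )

    def fit(self, records: Sequence[Tuple[Compound, float]]) -> "ToxicityModel":
        from sklearn.cross_decomposition import PLSRegression

        if len(records) < 10:
            raise ValueError("need at least 10 toxicity records")
        if any(ic50 <= 0 for _, ic50 in records):
            raise ValueError("IC50 values must be positive")
        X = self._X([c for c, _ in records])
        y = np.log10([ic50 for _, ic50 in records])
        ncomp = min(self.components, X.shape[1], len(records) - 1)
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if ncomp > rank:
            logger.warning("descriptor matrix rank %d < %d components; reducing", rank, ncomp)
            ncomp = max(1, rank)
        self.components = ncomp
        self._pls = PLSRegression(n_components=ncomp).fit(X, y)
        # leave-one-out cross-validated Q^2
        press, ss = 0.0, float(np.sum((y - y.mean()) ** 2))
        for i in range(len(records)):
            mask = np.arange(len(records)) != i
            m = PLSRegression(n_components=ncomp).fit(X[mask], y[mask])
            press += float((m.predict(X[i : i + 1]).ravel()[0] - y[i]) ** 2)
        self.q2 = 1.0 - press / ss if ss > 0 else 1.0
        return self

    def predict_ic50(self, c: Compound) -> float:
        if self._pls is None:
            raise ValueError("toxicity model is not trained")
        yhat = float(self._pls.predict(self._X([c])).ravel()[0])
        return 10.0 ** yhat

    def tox(self, c: Compound) -> float:
        return 1.0 / self.predict_ic50(c)


def train_toxicity(
    records: Sequence[Tuple[Compound, float]], components: int = 2, height: int = 1
) -> ToxicityModel:
    return ToxicityModel(components, height).fit(records)
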