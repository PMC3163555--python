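"""Enzyme insertion cost, pathway cost W, ranking and weight optimisation.

The cost of inserting an enzyme S for a reaction r* combines three
normalised [0, 1] scores — promiscuity, catalytic performance and host
compatibility — each contributing negatively:

    cost(r*, S) = omega_p (1 - promis(S)) + omega_e (1 - perf(r*, S)) + (1 - het(S))

A pathway rho producing compound c is then priced by

    W(c, rho) = lambda_path * sum_r cost*(r)
              + lambda_tox  * sum_p tox(p)
              + lambda_flux * 1 / (1 + v_c(rho))

where cost*(r) is the minimum insertion cost over candidate enzymes,
tox(p) is summed over each reaction's products along the pathway, and the
bounded decreasing transform of the nominal flux v_c trades yield against
cost.  Ranking is ascending in W; the optimal pathway is the first.

Weights are tuned by ranking accuracy: an annotated (reference-database)
pathway should out-rank predicted ones.  For a pathway rho among the
|rho(c)| routes to c, y_rho = (n_TP + n_TN) / |rho(c)| where n_TP counts
annotated pathways ranked at the same or higher score than rho and n_TN
counts non-annotated pathways ranked below rho.  The optimiser grid
searches (lambda_tox, lambda_flux) with lambda_path fixed at 1 — W is
invariant under uniform positive scaling of the three weights — and
maximises the aggregate sum of y_rho over all pathways of all compounds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CostWeights",
    "PathwayWeights",
    "enzyme_cost",
    "select_enzyme",
    "ScoredReaction",
    "PathwayScore",
    "pathway_cost",
    "rank_pathways",
    "optimal_pathway",
    "ranking_accuracy",
    "aggregate_accuracy",
    "optimize_weights",
    "rank_report",
]


@dataclass(frozen=True)
class CostWeights:
    omega_p: float = 1.0
    omega_e: float = 1.0

    def __post_init__(self):
        if self.omega_p < 0 or self.omega_e < 0 or not np.isfinite(self.omega_p + self.omega_e):
            raise ValueError("weights must be finite and non-negative")

    @property
    def penalty(self) -> float:
        """Worst-case cost, charged to reactions with no enzyme candidate."""
        return self.omega_p + self.omega_e + 1.0


@dataclass(frozen=True)
class PathwayWeights:
    lambda_flux: float = 0.0
    lambda_path: float = 1.0
    lambda_tox: float = 0.0

    def __post_init__(self):
        vals = (self.lambda_flux, self.lambda_path, self.lambda_tox)
        if any(v < 0 or not np.isfinite(v) for v in vals):
            raise ValueError("lambda weights must be finite and non-negative")


def enzyme_cost(promis: float, perf: float, het: float, w: CostWeights = CostWeights()) -> float:
    """Insertion cost of one enzyme; bounded in [0, omega_p + omega_e + 1]."""
    for name, v in (("promis", promis), ("perf", perf), ("het", het)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} score {v} outside [0, 1]")
    return w.omega_p * (1.0 - promis) + w.omega_e * (1.0 - perf) + (1.0 - het)


def select_enzyme(
    candidates: Sequence[Tuple[str, Tuple[float, float, float]]],
    w: CostWeights = CostWeights(),
) -> Tuple[Optional[str], float]:
    """Minimum-cost enzyme among (id, (promis, perf, het)) candidates.

    An empty candidate list yields (None, penalty): the reaction is
    unenzymed and dominated, not excluded.  Ties break by enzyme id.
    """
    if not candidates:
        logger.warning("no enzyme candidates; applying penalty cost %.3f", w.penalty)
        return None, w.penalty
    scored = [(enzyme_cost(*scores, w=w), eid) for eid, scores in candidates]
    cost, eid = min(scored)
    return eid, cost


@dataclass
class ScoredReaction:
    """One pathway step: chosen enzyme, its cost, and product toxicities."""

    reaction_id: str
    ec: str = ""
    enzyme_id: Optional[str] = None
    cost: float = 0.0
    product_tox: Dict[str, float] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)

    @property
    def tox_sum(self) -> float:
        return sum(self.product_tox.values())


@dataclass
class PathwayScore:
    pathway_id: str
    steps: List[ScoredReaction]
    v_c: float
    weights: PathwayWeights
    annotated: bool = False

    def __post_init__(self):
        if self.v_c < 0:
            raise ValueError("nominal flux v_c must be non-negative")

    @property
    def cost_sum(self) -> float:
        return sum(s.cost for s in self.steps)

    @property
    def tox_sum(self) -> float:
        return sum(s.tox_sum for s in self.steps)

    @property
    def flux_term(self) -> float:
        return 1.0 / (1.0 + self.v_c)

    @property
    def W(self) -> float:
        w = self.weights
        return (
            w.lambda_path * self.cost_sum
            + w.lambda_tox * self.tox_sum
            + w.lambda_flux * self.flux_term
        )

    def components(self) -> Dict[str, float]:
        return {
            "cost_sum": self.cost_sum,
            "tox_sum": self.tox_sum,
            "flux_term": self.flux_term,
            "W": self.W,
        }


def pathway_cost(
    pathway_id: str,
    steps: Sequence[ScoredReaction],
    v_c: float,
    weights: PathwayWeights = PathwayWeights(),
    annotated: bool = False,
) -> PathwayScore:
    """Assemble the multi-criteria score W for one pathway."""
    return PathwayScore(pathway_id, list(steps), v_c, weights, annotated)


def rank_pathways(scores: Sequence[PathwayScore]) -> List[PathwayScore]:
    """Ascending W; ties break by length then pathway id (stable, total)."""
    if not scores:
        raise ValueError("no pathways to rank")
    return sorted(scores, key=lambda s: (s.W, len(s.steps), s.pathway_id))


def optimal_pathway(scores: Sequence[PathwayScore]) -> PathwayScore:
    return rank_pathways(scores)[0]


def _reweighted(s: PathwayScore, weights: PathwayWeights) -> PathwayScore:
    return PathwayScore(s.pathway_id, s.steps, s.v_c, weights, s.annotated)


def ranking_accuracy(score: PathwayScore, ranked: Sequence[PathwayScore]) -> float:
    """y_rho = (n_TP + n_TN) / |rho(c)| for one pathway within its ranking."""
    ids = [s.pathway_id for s in ranked]
    if score.pathway_id not in ids:
        raise ValueError(f"pathway {score.pathway_id!r} absent from ranked list")
    me = next(s for s in ranked if s.pathway_id == score.pathway_id)
    n_tp = sum(1 for s in ranked if s.annotated and s.W <= me.W)
    n_tn = sum(1 for s in ranked if not s.annotated and s.W > me.W)
    return (n_tp + n_tn) / len(ranked)


def aggregate_accuracy(
    corpus: Mapping[str, Sequence[PathwayScore]], weights: PathwayWeights
) -> float:
    """Sum of y_rho over every pathway of every compound, at given weights."""
    total = 0.0
    for _compound, scores in sorted(corpus.items()):
        ranked = rank_pathways([_reweighted(s, weights) for s in scores])
        for s in ranked:
            total += ranking_accuracy(s, ranked)
    return total


def optimize_weights(
    corpus: Mapping[str, Sequence[PathwayScore]],
    grid: Optional[Sequence[float]] = None,
    mode: str = "both",
) -> Tuple[PathwayWeights, float, pd.DataFrame]:
    """Grid-search (lambda_tox, lambda_flux) maximising aggregate accuracy.

    lambda_path is fixed at 1.0 (uniform scaling of all three weights
    leaves every ranking unchanged).  ``mode`` zeroes the excluded
    parameter: 'tox-only' fixes lambda_flux = 0, 'flux-only' fixes
    lambda_tox = 0.  Ties break toward the smallest lambda values.
    Returns the best weights, the best aggregate, and the search trace.
    """
    flat = list(itertools.chain.from_iterable(corpus.values()))
    if not flat:
        raise ValueError("empty corpus")
    n_annot = sum(s.annotated for s in flat)
    if n_annot == 0 or n_annot == len(flat):
        raise ValueError("corpus must contain both annotated and predicted pathways")
    if mode not in ("both", "tox-only", "flux-only"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = list(grid) if grid is not None else [round(0.01 * i, 2) for i in range(201)]
    tox_grid = [0.0] if mode == "flux-only" else grid
    flux_grid = [0.0] if mode == "tox-only" else grid
    rows = []
    best: Optional[Tuple[float, float, float]] = None  # (-agg, tox, flux)
    for lt in tox_grid:
        for lf in flux_grid:
            agg = aggregate_accuracy(corpus, PathwayWeights(lambda_flux=lf, lambda_tox=lt))
            rows.append({"lambda_tox": lt, "lambda_flux": lf, "aggregate": agg})
            key = (-agg, lt, lf)
            if best is None or key < best:
                best = key
    _, lt, lf = best
    trace = pd.DataFrame(rows, columns=["lambda_tox", "lambda_flux", "aggregate"])
    return PathwayWeights(lambda_flux=lf, lambda_tox=lt), -best[0], trace


def rank_report(scores: Sequence[PathwayScore]) -> pd.DataFrame:
    """Membership table: one row per (EC, product) step, X/- per pathway,
    with nominal-flux and W footer rows."""
    ranked = rank_pathways(scores) if scores else []
    cols = [s.pathway_id for s in ranked]
    steps: Dict[Tuple[str, str], Dict[str, object]] = {}
    for s in ranked:
        for st in s.steps:
            for product, tox in (st.product_tox or {"": 0.0}).items():
                key = (st.ec or st.reaction_id, product)
                row = steps.setdefault(
                    key,
                    {
                        "EC": st.ec or st.reaction_id,
                        "product": product,
                        "cost": st.cost,
                        "toxicity": tox,
                        **{c: "-" for c in cols},
                    },
                )
                row[s.pathway_id] = "X"
    rows = [steps[k] for k in sorted(steps)]
    rows.append(
        {"EC": "", "product": "v_c", "cost": np.nan, "toxicity": np.nan,
         **{s.pathway_id: s.v_c for s in ranked}}
    )
    rows.append(
        {"EC": "", "product": "W", "cost": np.nan, "toxicity": np.nan,
         **{s.pathway_id: s.W for s in ranked}}
    )
    return pd.DataFrame(rows, columns=["EC", "product", "cost", "toxicity", *cols])
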