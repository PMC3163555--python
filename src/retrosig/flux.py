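"""Constraint-based estimation of nominal product flux for a pathway.

The chassis is described by a stoichiometric model (S, bounds, biomass
objective).  Inserting a heterologous pathway adds one column per pathway
reaction plus an irreversible sink for the target; the nominal flux
``v_c`` is then chosen to maximise the bilinear trade-off f = v_c * Z
between production and growth.  The bilinear program is solved by a
deterministic growth-fraction sweep: compute the growth optimum Z_max,
then for each fraction phi on a grid over (0, 1] maximise v_c subject to
Z >= phi * Z_max, and return the grid point with the largest product
v_c * Z.  When production does not compete with growth the sweep is exact
at phi = 1.

Units are mmol per gram dry weight per hour throughout; unspecified
bounds default to +/-1000.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .retro import Pathway
from .network import MetabolicNetwork

__all__ = [
    "StoichiometricModel",
    "FluxSolution",
    "augment_model",
    "fba_growth",
    "nominal_flux",
    "read_model_json",
    "write_model_json",
    "read_model_sbml",
]

DEFAULT_BOUND = 1000.0


@dataclass
class StoichiometricModel:
    compounds: List[str]
    reactions: List[str]
    stoich: Dict[Tuple[str, str], float]      # (compound, reaction) -> coefficient
    lower: Dict[str, float]
    upper: Dict[str, float]
    biomass: str
    exchanges: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.biomass not in self.reactions:
            raise ValueError(f"biomass reaction {self.biomass!r} not in model")
        for rid in self.reactions:
            lo = self.lower.get(rid, -DEFAULT_BOUND)
            hi = self.upper.get(rid, DEFAULT_BOUND)
            if lo > hi:
                raise ValueError(f"{rid}: lower bound {lo} exceeds upper bound {hi}")
        for (cid, rid), v in self.stoich.items():
            if cid not in self.compounds or rid not in self.reactions:
                raise ValueError(f"stoichiometry references unknown ({cid}, {rid})")
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient for ({cid}, {rid})")

    def matrix(self) -> np.ndarray:
        ci = {c: i for i, c in enumerate(self.compounds)}
        ri = {r: j for j, r in enumerate(self.reactions)}
        S = np.zeros((len(self.compounds), len(self.reactions)))
        for (c, r), v in self.stoich.items():
            S[ci[c], ri[r]] = v
        return S

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.lower.get(r, -DEFAULT_BOUND) for r in self.reactions])
        hi = np.array([self.upper.get(r, DEFAULT_BOUND) for r in self.reactions])
        return lo, hi

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            list(self.compounds),
            list(self.reactions),
            dict(self.stoich),
            dict(self.lower),
            dict(self.upper),
            self.biomass,
            list(self.exchanges),
        )


@dataclass
class FluxSolution:
    fluxes: Dict[str, float]
    growth: float
    product_flux: float
    objective: float
    status: str  # "optimal", "infeasible", "unbounded", "no-growth"


def _solve_lp(
    model: StoichiometricModel,
    objective_rid: str,
    extra_ge: Optional[Tuple[str, float]] = None,
):
    """Maximise one reaction's flux subject to S v = 0 and bounds."""
    S = model.matrix()
    lo, hi = model.bounds_arrays()
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reactions.index(objective_rid)] = -1.0
    A_ub = b_ub = None
    if extra_ge is not None:
        rid, floor = extra_ge
        row = np.zeros(n)
        row[model.reactions.index(rid)] = -1.0
        A_ub, b_ub = row[None, :], np.array([-floor])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    return res


def fba_growth(model: StoichiometricModel) -> FluxSolution:
    """Maximise the biomass objective Z alone."""
    res = _solve_lp(model, model.biomass)
    if res.status == 2:
        return FluxSolution({}, 0.0, 0.0, 0.0, "infeasible")
    if res.status == 3:
        return FluxSolution({}, float("inf"), 0.0, float("inf"), "unbounded")
    fluxes = dict(zip(model.reactions, res.x))
    z = fluxes[model.biomass]
    return FluxSolution(fluxes, z, 0.0, z, "optimal")


def augment_model(
    model: StoichiometricModel,
    pathway: Pathway,
    net: MetabolicNetwork,
    target: str,
    sink_bound: float = DEFAULT_BOUND,
) -> StoichiometricModel:
    """Add pathway reaction columns and an irreversible target sink.

    Pathway compounds already present in the model (by id) reuse their
    mass-balance rows; new compounds get new rows.  The sink column is
    named ``SINK_<target>``.
    """
    out = model.copy()
    known = set(out.compounds)

    def ensure_compound(cid: str):
        if cid not in known:
            out.compounds.append(cid)
            known.add(cid)

    for eid in pathway.reactions:
        rid = eid.rstrip("<>")
        reverse = eid.endswith("<")
        rxn = net.reactions[rid]
        col = f"PWY_{eid}"
        if col in out.reactions:
            raise ValueError(f"duplicate pathway reaction id {col}")
        out.reactions.append(col)
        sign = -1.0 if reverse else 1.0
        for coeff, cid in rxn.substrates:
            ensure_compound(cid)
            out.stoich[(cid, col)] = out.stoich.get((cid, col), 0.0) - sign * coeff
        for coeff, cid in rxn.products:
            ensure_compound(cid)
            out.stoich[(cid, col)] = out.stoich.get((cid, col), 0.0) + sign * coeff
        out.lower[col] = 0.0
        out.upper[col] = DEFAULT_BOUND
    ensure_compound(target)
    sink = f"SINK_{target}"
    if sink in out.reactions:
        raise ValueError(f"duplicate sink reaction {sink}")
    out.reactions.append(sink)
    out.stoich[(target, sink)] = -1.0
    out.lower[sink] = 0.0
    out.upper[sink] = sink_bound
    out.exchanges.append(sink)
    return StoichiometricModel(
        out.compounds, out.reactions, out.stoich, out.lower, out.upper,
        out.biomass, out.exchanges,
    )


def nominal_flux(
    model: StoichiometricModel,
    pathway: Pathway,
    net: MetabolicNetwork,
    target: str,
    phi_grid_points: int = 21,
) -> Tuple[float, FluxSolution]:
    """Nominal target flux maximising v_c * Z on the augmented model."""
    aug = augment_model(model, pathway, net, target)
    sink = f"SINK_{target}"
    growth = fba_growth(aug)
    if growth.status != "optimal" or growth.growth <= 0:
        return 0.0, FluxSolution({}, 0.0, 0.0, 0.0, "no-growth")
    z_max = growth.growth
    best: Optional[FluxSolution] = None
    for phi in np.linspace(1.0 / phi_grid_points, 1.0, phi_grid_points):
        res = _solve_lp(aug, sink, extra_ge=(aug.biomass, phi * z_max))
        if res.status != 0:
            continue
        fluxes = dict(zip(aug.reactions, res.x))
        vc, z = fluxes[sink], fluxes[aug.biomass]
        sol = FluxSolution(fluxes, z, vc, vc * z, "optimal")
        if best is None or sol.objective > best.objective + 1e-12:
            best = sol
    if best is None:
        return 0.0, FluxSolution({}, 0.0, 0.0, 0.0, "infeasible")
    return best.product_flux, best


# ---------------------------------------------------------------------------
# persistence


def write_model_json(model: StoichiometricModel, path: str) -> None:
    doc = {
        "compounds": model.compounds,
        "reactions": [
            {
                "id": rid,
                "stoich": {
                    cid: v for (cid, r), v in sorted(model.stoich.items()) if r == rid
                },
                "lb": model.lower.get(rid, -DEFAULT_BOUND),
                "ub": model.upper.get(rid, DEFAULT_BOUND),
            }
            for rid in model.reactions
        ],
        "biomass": model.biomass,
        "exchanges": model.exchanges,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_model_json(path: str) -> StoichiometricModel:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("compounds", "reactions", "biomass"):
        if key not in doc:
            raise ValueError(f"{path}: missing required key {key!r}")
    stoich: Dict[Tuple[str, str], float] = {}
    lower: Dict[str, float] = {}
    upper: Dict[str, float] = {}
    rids = []
    for i, r in enumerate(doc["reactions"]):
        if "id" not in r or "stoich" not in r:
            raise ValueError(f"{path}: reaction #{i} lacks 'id' or 'stoich'")
        rids.append(r["id"])
        for cid, v in r["stoich"].items():
            stoich[(cid, r["id"])] = float(v)
        lower[r["id"]] = float(r.get("lb", -DEFAULT_BOUND))
        upper[r["id"]] = float(r.get("ub", DEFAULT_BOUND))
    return StoichiometricModel(
        list(doc["compounds"]), rids, stoich, lower, upper,
        doc["biomass"], list(doc.get("exchanges", [])),
    )


def read_model_sbml(path: str, biomass: Optional[str] = None) -> StoichiometricModel:
    """Import an SBML Level 3 core model (species, reactions, fbc bounds)."""
    import libsbml

    doc = libsbml.readSBML(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getError(0)
        raise ValueError(
            f"{path}:{err.getLine()}: {err.getMessage().strip()}"
        )
    sbml = doc.getModel()
    if sbml is None:
        raise ValueError(f"{path}: no model element")
    compounds = [sbml.getSpecies(i).getId() for i in range(sbml.getNumSpecies())]
    reactions, stoich, lower, upper = [], {}, {}, {}
    for i in range(sbml.getNumReactions()):
        rxn = sbml.getReaction(i)
        rid = rxn.getId()
        reactions.append(rid)
        for j in range(rxn.getNumReactants()):
            sr = rxn.getReactant(j)
            stoich[(sr.getSpecies(), rid)] = stoich.get((sr.getSpecies(), rid), 0.0) - sr.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            sr = rxn.getProduct(j)
            stoich[(sr.getSpecies(), rid)] = stoich.get((sr.getSpecies(), rid), 0.0) + sr.getStoichiometry()
        fbc = rxn.getPlugin("fbc")
        lo, hi = -DEFAULT_BOUND, DEFAULT_BOUND
        if fbc is not None:
            lp = sbml.getParameter(fbc.getLowerFluxBound() or "")
            up = sbml.getParameter(fbc.getUpperFluxBound() or "")
            if lp is not None:
                lo = lp.getValue()
            if up is not None:
                hi = up.getValue()
        elif not rxn.getReversible():
            lo = 0.0
        lower[rid], upper[rid] = lo, hi
    if biomass is None:
        cands = [r for r in reactions if "biomass" in r.lower()]
        if not cands:
            raise ValueError(f"{path}: no biomass reaction found; pass one explicitly")
        biomass = cands[0]
    return StoichiometricModel(compounds, reactions, stoich, lower, upper, biomass)
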