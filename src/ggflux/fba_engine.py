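"""Flux balance analysis: maximize the biomass objective subject to S·v = 0
and flux bounds, and the BOFmax-based fitness ratio.

The LP is solved with HiGHS (via ``scipy.optimize.linprog``) at primal/dual
feasibility 1e-9.  Optimal flux vectors are generally degenerate; only the
objective value (BOFmax) is contractual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicModel, build_stoichiometric_matrix

__all__ = [
    "FBAResult",
    "FBAError",
    "UndefinedRatioError",
    "solve_fba",
    "fitness_ratio",
    "FEASIBILITY_TOL",
    "SOLVER_NAME",
]

FEASIBILITY_TOL = 1e-9
SOLVER_NAME = "scipy.optimize.linprog(method='highs')"


class FBAError(RuntimeError):
    """The FBA problem could not be posed or solved."""


class UndefinedRatioError(FBAError):
    """Fitness ratio with a zero denominator BOFmax."""


@dataclass
class FBAResult:
    """Outcome of one FBA solve.

    ``objective_value`` is BOFmax (h⁻¹ for a biomass objective); ``fluxes``
    are mmol·gDW⁻¹·h⁻¹ and are one optimal vertex among possibly many.
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_fba(model: MetabolicModel,
              extra_constraints: dict[str, tuple[float, float]] | None = None,
              ) -> FBAResult:
    """Maximize the objective reaction's flux at steady state.

    ``extra_constraints`` maps reaction id -> (lb, ub) and overrides the
    stored bounds for this call only.  Infeasible/unbounded problems are
    reported via ``status``, never silently.
    """
    if not model.reactions:
        raise FBAError("cannot run FBA on a model with no reactions")
    if model.objective_reaction_id is None:
        raise FBAError("model declares no objective reaction")

    smat = build_stoichiometric_matrix(model)
    n = len(smat.cols)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    if extra_constraints:
        col = {rid: j for j, rid in enumerate(smat.cols)}
        for rid, (lo, hi) in extra_constraints.items():
            if rid not in col:
                raise FBAError(f"extra constraint on unknown reaction {rid!r}")
            if lo > hi:
                raise FBAError(f"constraint on {rid!r} has lb {lo} > ub {hi}")
            lb[col[rid]], ub[col[rid]] = lo, hi

    c = np.zeros(n)
    c[smat.cols.index(model.objective_reaction_id)] = -1.0  # linprog minimizes

    res = linprog(
        c,
        A_eq=smat.matrix,
        b_eq=np.zeros(len(smat.rows)),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FBAResult(status=status, objective_value=None)
    fluxes = {rid: float(v) for rid, v in zip(smat.cols, res.x)}
    return FBAResult(status="optimal", objective_value=float(-res.fun), fluxes=fluxes)


def _supply_constraint(model: MetabolicModel, supply_reaction_id: str,
                       qGG: float) -> dict[str, tuple[float, float]]:
    """Fix the GG supply flux to qGG as an equality.

    Exchange supply means uptake, i.e. flux −qGG under the export-positive
    sign convention; an internal supply (e.g. the synthesis flux) is +qGG.
    """
    rxn = model.reaction(supply_reaction_id)
    value = -qGG if rxn.is_exchange else qGG
    return {supply_reaction_id: (value, value)}


def fitness_ratio(model: MetabolicModel, utilization_rxn_ids: set[str] | list[str],
                  qGG: float, supply_reaction_id: str = "EX_glcglyc(e)",
                  open_upper_bound: float = 1000.0) -> float:
    """Percent fitness gain from GG utilization at a fixed supply flux.

    Returns 100 × BOFmax(utilization bounds [0, open_upper_bound]) /
    BOFmax(utilization bounds [0, 0]), with the GG supply fixed at qGG in
    both solves; the storage sink keeps the denominator feasible.
    """
    if qGG < 0:
        raise ValueError(f"qGG must be non-negative, got {qGG}")
    util = sorted(set(utilization_rxn_ids))
    for rid in util:
        model.reaction(rid)  # raises KeyError for unknown ids

    supply = _supply_constraint(model, supply_reaction_id, qGG)
    open_c = dict(supply)
    closed_c = dict(supply)
    for rid in util:
        open_c[rid] = (0.0, open_upper_bound)
        closed_c[rid] = (0.0, 0.0)

    num = solve_fba(model, extra_constraints=open_c)
    den = solve_fba(model, extra_constraints=closed_c)
    if not den.is_optimal or not num.is_optimal:
        raise FBAError(
            f"fitness ratio undefined: numerator {num.status}, denominator {den.status}"
        )
    if abs(den.objective_value) < FEASIBILITY_TOL * 10:
        raise UndefinedRatioError(
            f"denominator BOFmax is zero at qGG={qGG}; ratio undefined"
        )
    return 100.0 * num.objective_value / den.objective_value
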