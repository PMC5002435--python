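"""Brute-force LP oracle for FBA problems, independent of any LP library.

Maximizes c·v over {S·v = 0, lb ≤ v ≤ ub} by enumerating candidate vertices:
every basic solution fixes n − rank(S) variables at a bound and solves the
equality system for the rest.  All bounds must be finite (the polytope is a
box intersection, hence bounded), so the optimum, when the problem is
feasible, is attained at one of the enumerated vertices.
"""

from itertools import combinations, product

import numpy as np


def brute_force_lp_max(S, lb, ub, c, tol: float = 1e-8):
    """Return the maximum of c·v, or None if no feasible vertex exists."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
        raise ValueError("oracle requires finite bounds")
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    best = None
    for fixed in combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        fixed = list(fixed)
        if k:
            combos = np.array(list(product(*[(lb[j], ub[j]) for j in fixed]))).T
        else:
            combos = np.zeros((0, 1))
        rhs = -S[:, fixed] @ combos if k else np.zeros((m, 1))
        if free:
            sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            resid = S[:, free] @ sol - rhs
            feas = np.abs(resid).max(axis=0) <= tol
            feas &= (sol >= lb[free][:, None] - tol).all(axis=0)
            feas &= (sol <= ub[free][:, None] + tol).all(axis=0)
        else:
            sol = np.zeros((0, combos.shape[1]))
            feas = np.abs(rhs).max(axis=0) <= tol
        if not feas.any():
            continue
        obj = (c[free] @ sol if free else 0.0) + (c[fixed] @ combos if k else 0.0)
        cand = float(np.max(np.atleast_1d(obj)[feas]))
        best = cand if best is None else max(best, cand)
    return best


def random_fba_model(rng, max_reactions: int = 12):
    """A random small MetabolicModel with finite bounds, feasible at v = 0."""
    from ggflux.model_core import MetabolicModel, Metabolite, Reaction

    n = int(rng.integers(4, max_reactions + 1))
    m = int(rng.integers(2, max(3, n - 1)))
    S = rng.normal(size=(m, n)) * (rng.random((m, n)) < 0.6)
    S = np.round(S, 3)
    lb = np.where(rng.random(n) < 0.75, -np.round(rng.uniform(0.5, 10.0, n), 3), 0.0)
    ub = np.round(rng.uniform(0.5, 10.0, n), 3)
    obj = int(rng.integers(n))
    mets = [Metabolite(id=f"m{i}_c") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {f"m{i}_c": float(S[i, j]) for i in range(m) if S[i, j] != 0}
        rxns.append(Reaction(id=f"r{j}", stoichiometry=stoich,
                             lower_bound=float(lb[j]), upper_bound=float(ub[j])))
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective_reaction_id=f"r{obj}", id="random")
    return model, S, lb, ub, obj
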