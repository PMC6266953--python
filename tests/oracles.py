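"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's assembly/solver code paths: the
matrix oracle is a naive double loop, and the LP oracle enumerates the
vertices of the feasible polytope {S.v = 0 (steady rows), lb <= v <= ub}
directly.  They are only practical for tiny models, which is the point.
"""

from itertools import combinations, product

import numpy as np


def brute_force_matrix(model):
    """Dense S assembled by a naive reactions x metabolites double loop."""
    M = np.zeros((len(model.metabolites), len(model.reactions)))
    for i, met in enumerate(model.metabolites):
        for j, rxn in enumerate(model.reactions):
            for mid, coef in rxn.stoichiometry.items():
                if mid == met.id:
                    M[i, j] += coef
    return M


def vertex_enumeration_optimum(S, c, lb, ub, steady_mask, feas_tol=1e-7):
    """Max of c.v over the polytope by exhaustive vertex enumeration.

    At a vertex, (n - rank) variables sit at a bound and the rest are the
    unique solution of the steady-state equations.  All finite-bound
    problems of a handful of degrees of freedom are enumerable this way.
    Returns None if no feasible vertex exists.
    """
    A = np.asarray(S.todense() if hasattr(S, "todense") else S, dtype=float)
    A = A[np.asarray(steady_mask, dtype=bool)]
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A) if A.size else 0
    dof = n - rank
    best = None
    for fixed in combinations(range(n), dof):
        free = [j for j in range(n) if j not in fixed]
        for choice in product((0, 1), repeat=dof):
            x = np.zeros(n)
            for j, ch in zip(fixed, choice):
                x[j] = lb[j] if ch == 0 else ub[j]
            if free:
                rhs = -A[:, list(fixed)] @ x[list(fixed)] if fixed else np.zeros(A.shape[0])
                sol, _, rk, _ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
                if rk < len(free):
                    continue  # bound pattern does not define a vertex
                x[free] = sol
            if A.size and np.max(np.abs(A @ x)) > feas_tol:
                continue
            if np.all(x >= lb - feas_tol) and np.all(x <= ub + feas_tol):
                val = float(c @ x)
                if best is None or val > best:
                    best = val
    return best


def enumerate_pathway_costs(total_flux_per_route):
    """Total |v|_1 of routing one unit of growth through each candidate
    route; the parsimonious optimum must pick the argmin."""
    return min(range(len(total_flux_per_route)), key=lambda i: total_flux_per_route[i])
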