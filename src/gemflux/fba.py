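"""Flux balance analysis: LP assembly and solving.

The model is turned into the linear program

    max  c . v
    s.t. S . v = xdot,   Vmin <= v <= Vmax,
         xdot_i = 0   for internal metabolites,
         xdot_i free  for exchange metabolites,

where v is the flux vector in mmol/gDW/hr.  The optimum of the objective
(the biomass flux, for a growth objective) is the predicted growth rate.

FBA optima are typically degenerate — many flux vectors achieve the same
growth — so per-reaction reporting uses parsimonious FBA
(:func:`solve_pfba`): among (near-)optimal vectors, minimise the total
absolute flux.  Biomass-level numbers are degeneracy-invariant and use
plain :func:`solve_fba`.

Solver backends are swappable: anything implementing
:class:`SolverBackend.solve` (pure arrays in, flux vector + status out) can
be plugged in.  The default backend is HiGHS via scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Tuple

import numpy as np
import scipy.optimize as spo
import scipy.sparse as sp

from .core import MetabolicModel, build_stoichiometric_matrix, require_valid

__all__ = [
    "FBAProblem",
    "FluxDistribution",
    "SolverBackend",
    "HighsBackend",
    "assemble_problem",
    "solve_fba",
    "solve_pfba",
]

#: relative optimality tolerance shared by the LP stages
SOLVER_TOL = 1e-9
#: fluxes with magnitude below this print as zero in reports
REPORT_EPS = 1e-6


@dataclass
class FBAProblem:
    """The assembled LP: sparse S, objective c, bounds, steady-state mask."""

    S: sp.csr_matrix
    c: np.ndarray
    v_min: np.ndarray
    v_max: np.ndarray
    steady_mask: np.ndarray  # True -> row constrained to S.v = 0
    reaction_ids: List[str]
    metabolite_ids: List[str]

    def __post_init__(self) -> None:
        m, n = self.S.shape
        if not (
            len(self.c) == len(self.v_min) == len(self.v_max) == len(self.reaction_ids) == n
        ):
            raise ValueError("column-dimension mismatch in FBA problem")
        if not (len(self.steady_mask) == len(self.metabolite_ids) == m):
            raise ValueError("row-dimension mismatch in FBA problem")
        if np.any(self.v_min > self.v_max):
            raise ValueError("v_min exceeds v_max for some reaction")
        if not np.any(self.c):
            raise ValueError("objective vector c is identically zero")


@dataclass
class FluxDistribution:
    """A solved flux vector keyed by reaction id, with the LP status.

    ``status`` is one of ``optimal``, ``infeasible``, ``unbounded``.  Fluxes
    and the objective value are in mmol/gDW/hr; ``fluxes`` is empty unless
    the status is optimal.
    """

    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: float = float("nan")
    status: str = "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def to_series(self):
        import pandas as pd

        return pd.Series(self.fluxes, name="flux")


class SolverBackend(Protocol):
    """Contract for pluggable LP backends (pure data in, pure data out)."""

    def solve(
        self,
        S: sp.csr_matrix,
        c: np.ndarray,
        v_min: np.ndarray,
        v_max: np.ndarray,
        steady_mask: np.ndarray,
    ) -> Tuple[Optional[np.ndarray], str]:
        """Maximise c.v subject to the steady rows of S.v = 0 and bounds.

        Returns ``(v, status)``; v is None unless status is ``optimal``.
        """
        ...


# feasibility tighter than the optimality contract, so near-optimal growth
# constraints are honoured well inside SOLVER_TOL
_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


class HighsBackend:
    """Default LP backend: scipy.optimize.linprog with the HiGHS solver."""

    def __init__(self, tolerance: float = SOLVER_TOL) -> None:
        if tolerance <= 0:
            raise ValueError("tolerance must be positive")
        self.tolerance = tolerance

    def solve(self, S, c, v_min, v_max, steady_mask):
        A_eq = S[np.asarray(steady_mask, dtype=bool)]
        b_eq = np.zeros(A_eq.shape[0])
        res = spo.linprog(
            -np.asarray(c, dtype=float),
            A_eq=A_eq if A_eq.shape[0] else None,
            b_eq=b_eq if A_eq.shape[0] else None,
            bounds=np.column_stack([v_min, v_max]),
            method="highs",
            options=_HIGHS_OPTIONS,
        )
        if res.status == 0:
            return np.asarray(res.x), "optimal"
        if res.status == 2:
            return None, "infeasible"
        if res.status == 3:
            return None, "unbounded"
        raise RuntimeError(f"LP solver failed: {res.message}")


def assemble_problem(model: MetabolicModel) -> FBAProblem:
    """Build the FBA linear program from a validated model.

    Metabolites with ``role='exchange'`` get an unconstrained row (their
    accumulation rate is free); all others are held at steady state.
    """
    require_valid(model)
    S = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    c = np.zeros(n)
    for j, r in enumerate(model.reactions):
        w = model.objective.get(r.id, 0.0)
        if w:
            c[j] = w
    v_min = np.array([r.lower_bound for r in model.reactions], dtype=float)
    v_max = np.array([r.upper_bound for r in model.reactions], dtype=float)
    steady = np.array([m.role == "internal" for m in model.metabolites], dtype=bool)
    return FBAProblem(
        S=S,
        c=c,
        v_min=v_min,
        v_max=v_max,
        steady_mask=steady,
        reaction_ids=[r.id for r in model.reactions],
        metabolite_ids=[m.id for m in model.metabolites],
    )


def _distribution(problem: FBAProblem, v: np.ndarray) -> FluxDistribution:
    return FluxDistribution(
        fluxes=dict(zip(problem.reaction_ids, map(float, v))),
        objective_value=float(problem.c @ v),
        status="optimal",
    )


def solve_fba(problem: FBAProblem, backend: Optional[SolverBackend] = None) -> FluxDistribution:
    """Maximise the objective; returns the optimal flux distribution.

    An unbounded status signals a missing uptake limit and is reported, not
    clamped.
    """
    backend = backend or HighsBackend()
    v, status = backend.solve(
        problem.S, problem.c, problem.v_min, problem.v_max, problem.steady_mask
    )
    if status != "optimal":
        return FluxDistribution(status=status)
    return _distribution(problem, v)


def solve_pfba(
    problem: FBAProblem,
    backend: Optional[SolverBackend] = None,
    optimality_fraction: float = 1.0 - SOLVER_TOL,
) -> FluxDistribution:
    """Parsimonious FBA: the minimum-total-flux vector at (near-)optimal growth.

    Two-stage LP.  Stage one finds the FBA optimum z*; stage two minimises
    sum(|v_j|) subject to the original constraints plus
    ``c.v >= optimality_fraction * z*`` (shifted by an absolute tolerance so
    z* = 0 stays feasible).  Absolute values are linearised with auxiliary
    variables a_j >= |v_j|.  The result is the canonical distribution for
    per-reaction reporting; its objective_value is c.v of the parsimonious
    vector.
    """
    fba = solve_fba(problem, backend)
    if fba.status != "optimal":
        return fba
    z_star = fba.objective_value
    # growth floor: relative backoff on either side of zero (z* itself is
    # always attainable, so the constraint stays feasible)
    z_floor = z_star - (1.0 - optimality_fraction) * abs(z_star)

    S = problem.S
    m_steady = int(np.count_nonzero(problem.steady_mask))
    n = S.shape[1]
    # variables x = [v ; a]
    S_eq = sp.hstack([S[problem.steady_mask], sp.csr_matrix((m_steady, n))], format="csr")
    eye = sp.identity(n, format="csr")
    A_ub = sp.vstack(
        [
            sp.hstack([eye, -eye]),   # v - a <= 0
            sp.hstack([-eye, -eye]),  # -v - a <= 0
            sp.hstack([-sp.csr_matrix(problem.c), sp.csr_matrix((1, n))]),  # -c.v <= -z_floor
        ],
        format="csr",
    )
    b_ub = np.concatenate([np.zeros(2 * n), [-z_floor]])
    a_max = np.maximum(np.abs(problem.v_min), np.abs(problem.v_max))
    bounds = np.column_stack(
        [
            np.concatenate([problem.v_min, np.zeros(n)]),
            np.concatenate([problem.v_max, a_max]),
        ]
    )
    obj = np.concatenate([np.zeros(n), np.ones(n)])
    res = spo.linprog(
        obj,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S_eq if m_steady else None,
        b_eq=np.zeros(m_steady) if m_steady else None,
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    if res.status != 0:
        raise RuntimeError(f"pFBA stage-two LP failed: {res.message}")
    return _distribution(problem, np.asarray(res.x[:n]))
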