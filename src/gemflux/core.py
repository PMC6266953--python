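"""Core types for constraint-based metabolic models.

A genome-scale metabolic model (GEM) is a set of metabolites and reactions.
Its stoichiometry is summarised by the matrix ``S`` (m metabolites x n
reactions): entry ``S[i, j]`` is the signed coefficient of metabolite *i* in
reaction *j* (negative = consumed, positive = produced).  Directionality is
encoded purely through flux bounds: a reaction is reversible iff
``lower_bound < 0 < upper_bound``.  Growth is represented by a single
biomass pseudo-reaction designated by the model objective.

Reactions fall into four structural categories:

``exchange``
    single-metabolite pseudo-reactions moving mass across the system
    boundary; uptake is a negative flux by convention.
``transport``
    reactions whose metabolites span two or more compartments.
``biomass``
    the objective-designated growth reaction.
``internal``
    everything else.

Metabolites are ``internal`` (subject to the steady-state constraint
``S.v = 0``) unless explicitly marked ``exchange``, in which case their
accumulation rate is left free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import scipy.sparse as sp

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Finding",
    "CATEGORIES",
    "build_stoichiometric_matrix",
    "classify_reaction",
    "validate_model",
    "ValidationError",
]

CATEGORIES = ("internal", "transport", "exchange", "biomass")

#: default bound magnitude (mmol/gDW/hr) for otherwise unbounded reactions
DEFAULT_BOUND = 1000.0


class ValidationError(ValueError):
    """Raised when an operation requires a well-formed model and it is not."""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``role='internal'`` species obey steady state (no net accumulation);
    ``role='exchange'`` species are outside the balance and their row of S
    is unconstrained.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    role: str = "internal"

    def __post_init__(self) -> None:
        if self.role not in ("internal", "exchange"):
            raise ValueError(f"metabolite {self.id!r}: unknown role {self.role!r}")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds in mmol/gDW/hr.

    ``stoichiometry`` maps metabolite id to its signed coefficient.
    ``category`` is a cached structural label; :func:`classify_reaction`
    computes it from the network.  ``annotation`` carries an external
    database id (e.g. a KEGG reaction id such as ``R00891``).
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    category: Optional[str] = None
    annotation: Optional[str] = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """An ordered collection of metabolites and reactions plus an objective.

    ``objective`` maps reaction id to its weight in the objective vector c
    (typically weight 1 on the biomass reaction).
    """

    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    objective: Dict[str, float] = field(default_factory=dict)
    name: str = ""
    version: str = ""

    # -- lookup helpers -------------------------------------------------
    def metabolite_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> Dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if classify_reaction(r, self) == "exchange"]

    def biomass_reaction(self) -> Reaction:
        for r in self.reactions:
            if classify_reaction(r, self) == "biomass":
                return r
        raise ValidationError(f"model {self.name!r} has no biomass reaction")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
            objective=dict(self.objective),
            name=self.name,
            version=self.version,
        )

    def __deepcopy__(self, memo):  # cheap: the structure is shallow
        return self.copy()


def build_stoichiometric_matrix(model: MetabolicModel) -> sp.csr_matrix:
    """Assemble S as a sparse m x n matrix.

    Row order follows ``model.metabolites``; column order follows
    ``model.reactions``.  A reaction referencing an unknown metabolite id
    raises :class:`ValidationError` naming the reaction.
    """
    midx = model.metabolite_index()
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            try:
                rows.append(midx[mid])
            except KeyError:
                raise ValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                ) from None
            cols.append(j)
            vals.append(float(coef))
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def classify_reaction(reaction: Reaction, model: MetabolicModel) -> str:
    """Assign a structural category to *reaction*.

    Biomass designation (nonzero objective weight) takes precedence; then a
    single-metabolite reaction is an exchange (sink/source); a reaction whose
    metabolites span >= 2 compartments is a transport; anything else is
    internal.  Deterministic and total.
    """
    if model.objective.get(reaction.id, 0.0) != 0.0:
        return "biomass"
    mids = list(reaction.stoichiometry)
    if len(mids) == 1:
        return "exchange"
    midx = model.metabolite_index()
    compartments = set()
    for mid in mids:
        try:
            compartments.add(model.metabolites[midx[mid]].compartment)
        except KeyError:
            raise ValidationError(
                f"reaction {reaction.id!r} references unknown metabolite {mid!r}"
            ) from None
    if len(compartments) >= 2:
        return "transport"
    return "internal"


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is 'error' or 'warning'."""

    level: str
    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.level}] {self.code}: {self.message}"


def validate_model(model: MetabolicModel) -> List[Finding]:
    """Structural validation; returns findings (empty list = well formed).

    Errors: duplicate ids, dangling metabolite references, inverted bounds,
    empty stoichiometry, missing/multiple biomass reactions, objective
    weights on unknown reactions.  Warnings: orphan metabolites.
    """
    findings: List[Finding] = []
    err = lambda code, msg: findings.append(Finding("error", code, msg))
    warn = lambda code, msg: findings.append(Finding("warning", code, msg))

    mids = [m.id for m in model.metabolites]
    rids = [r.id for r in model.reactions]
    for label, ids in (("metabolite", mids), ("reaction", rids)):
        seen = set()
        for i in ids:
            if i in seen:
                err("duplicate-id", f"duplicate {label} id {i!r}")
            seen.add(i)

    known = set(mids)
    used: set = set()
    for r in model.reactions:
        if not r.stoichiometry:
            err("empty-stoichiometry", f"reaction {r.id!r} has no metabolites")
        if r.lower_bound > r.upper_bound:
            err(
                "inverted-bounds",
                f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                f"upper bound {r.upper_bound}",
            )
        for mid in r.stoichiometry:
            if mid not in known:
                err(
                    "dangling-metabolite",
                    f"reaction {r.id!r} references unknown metabolite {mid!r}",
                )
            used.add(mid)

    for rid in model.objective:
        if rid not in set(rids):
            err("unknown-objective", f"objective references unknown reaction {rid!r}")

    n_biomass = sum(1 for w in model.objective.values() if w != 0.0)
    if n_biomass == 0:
        err("no-biomass", "no reaction carries a nonzero objective weight")
    elif n_biomass > 1:
        err(
            "multiple-biomass",
            f"{n_biomass} reactions carry objective weight; the biomass "
            "objective must be unique",
        )

    for mid in mids:
        if mid not in used:
            warn("orphan-metabolite", f"metabolite {mid!r} occurs in no reaction")

    return findings


def require_valid(model: MetabolicModel) -> None:
    """Raise :class:`ValidationError` if *model* has any error finding."""
    errors = [f for f in validate_model(model) if f.level == "error"]
    if errors:
        raise ValidationError(
            "model failed validation: " + "; ".join(str(f) for f in errors)
        )


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 0.0) -> bool:
    """Field-by-field equality of two models (order-sensitive).

    ``tol`` allows for float round-off in bounds and coefficients (0 means
    exact).
    """
    if len(a.metabolites) != len(b.metabolites) or len(a.reactions) != len(b.reactions):
        return False
    close = lambda x, y: abs(x - y) <= tol
    for ma, mb in zip(a.metabolites, b.metabolites):
        if (ma.id, ma.name, ma.compartment, ma.role) != (
            mb.id,
            mb.name,
            mb.compartment,
            mb.role,
        ):
            return False
    for ra, rb in zip(a.reactions, b.reactions):
        if ra.id != rb.id or ra.name != rb.name:
            return False
        if not (close(ra.lower_bound, rb.lower_bound) and close(ra.upper_bound, rb.upper_bound)):
            return False
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        if any(not close(ra.stoichiometry[k], rb.stoichiometry[k]) for k in ra.stoichiometry):
            return False
    if set(a.objective) != set(b.objective):
        return False
    return all(close(a.objective[k], b.objective[k]) for k in a.objective)
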