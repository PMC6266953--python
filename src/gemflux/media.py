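"""Growth-medium simulation: medium application, carbon-source comparison,
nutrient starvation and differential-flux reporting.

A medium is the set of open uptake bounds on exchange reactions.  Applying
a medium closes the uptake of every exchange reaction it does not list
(lower bound raised to 0) while leaving secretion open, so the medium fully
determines what the cell can import.

A starvation experiment closes one nutrient's uptake and compares the new
optimum against the full-medium optimum.  The headline statistic is the
differential biomass percentage

    (G_without - G_with) / |G_with| * 100

negative values are growth reductions.  The same formula, applied to the
parsimonious (pFBA) fluxes of each reaction, gives the per-reaction
differential report; baselines below 1e-6 in magnitude are flagged
``undefined-baseline`` instead of dividing by noise.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .core import MetabolicModel, classify_reaction
from .fba import REPORT_EPS, SolverBackend, assemble_problem, solve_fba, solve_pfba

__all__ = [
    "MediumSpec",
    "ReactionChange",
    "DifferentialReport",
    "UndefinedBaselineError",
    "read_medium",
    "write_medium",
    "medium_from_model",
    "apply_medium",
    "differential_biomass",
    "starvation_experiment",
    "carbon_source_comparison",
    "preferred_carbon_source",
    "rank_differential_reactions",
]

#: |baseline| at or below this is an undefined denominator
BASELINE_EPS = 1e-6


class UndefinedBaselineError(ValueError):
    """Baseline magnitude too small for a percent-change denominator."""


@dataclass
class MediumSpec:
    """Uptake/secretion bounds (mmol/gDW/hr) keyed by exchange-reaction id."""

    entries: Dict[str, Tuple[float, float]]
    name: str = "medium"

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.entries.items():
            if lo > hi:
                raise ValueError(f"medium {self.name!r}, {rid}: lower {lo} > upper {hi}")

    def without(self, rid: str, label: Optional[str] = None) -> "MediumSpec":
        """A copy with *rid*'s uptake closed (lower bound 0, secretion kept)."""
        if rid not in self.entries:
            raise KeyError(rid)
        entries = dict(self.entries)
        lo, hi = entries[rid]
        entries[rid] = (max(lo, 0.0), hi)
        return MediumSpec(entries=entries, name=label or f"{self.name}-minus-{rid}")


def read_medium(path, name: Optional[str] = None) -> MediumSpec:
    """Read a delimited medium file: columns exchange_reaction_id,
    lower_bound, upper_bound; '#' starts a comment."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {str(c).strip().lower(): c for c in df.columns}
    try:
        rid_col = cols["exchange_reaction_id"]
        lo_col = cols["lower_bound"]
        hi_col = cols["upper_bound"]
    except KeyError as exc:
        raise ValueError(
            f"{path}: medium files need columns exchange_reaction_id, "
            f"lower_bound, upper_bound (found {list(df.columns)})"
        ) from exc
    entries = {
        str(row[rid_col]).strip(): (float(row[lo_col]), float(row[hi_col]))
        for _, row in df.iterrows()
    }
    return MediumSpec(entries=entries, name=name or path.stem)


def write_medium(medium: MediumSpec, path) -> None:
    rows = [
        {"exchange_reaction_id": rid, "lower_bound": lo, "upper_bound": hi}
        for rid, (lo, hi) in medium.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def medium_from_model(model: MetabolicModel, name: str = "native") -> MediumSpec:
    """The medium implied by a model's current exchange bounds."""
    entries = {
        r.id: (r.lower_bound, r.upper_bound)
        for r in model.reactions
        if classify_reaction(r, model) == "exchange"
    }
    return MediumSpec(entries=entries, name=name)


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of *model* with *medium*'s exchange bounds applied.

    Every exchange reaction not listed in the medium has its uptake closed
    (lower bound raised to 0); secretion stays open.  The input model is
    untouched.  Unknown or non-exchange ids raise ValueError with
    near-match suggestions.
    """
    out = model.copy()
    categories = {r.id: classify_reaction(r, out) for r in out.reactions}
    exchange_ids = [rid for rid, cat in categories.items() if cat == "exchange"]
    for rid in medium.entries:
        if rid not in categories:
            hints = difflib.get_close_matches(rid, exchange_ids, n=3)
            raise ValueError(
                f"medium {medium.name!r}: unknown reaction {rid!r}"
                + (f"; did you mean {hints}?" if hints else "")
            )
        if categories[rid] != "exchange":
            raise ValueError(
                f"medium {medium.name!r}: {rid!r} is a {categories[rid]} reaction, "
                "not an exchange reaction"
            )
    for r in out.reactions:
        if categories[r.id] != "exchange":
            continue
        if r.id in medium.entries:
            r.lower_bound, r.upper_bound = medium.entries[r.id]
        else:
            r.lower_bound = max(r.lower_bound, 0.0)
    return out


def differential_biomass(g_with: float, g_without: float) -> float:
    """Percent change of growth without a nutrient relative to with it.

    ``(g_without - g_with) / |g_with| * 100``; negative means reduction.
    Raises :class:`UndefinedBaselineError` when the baseline |g_with| is at
    or below 1e-6.
    """
    if abs(g_with) <= BASELINE_EPS:
        raise UndefinedBaselineError(
            f"baseline growth {g_with} too small for a percent change"
        )
    return (g_without - g_with) / abs(g_with) * 100.0


@dataclass
class ReactionChange:
    """Per-reaction percent flux change; ``pct`` is None when flagged."""

    pct: Optional[float]
    flags: Tuple[str, ...] = ()

    @property
    def undefined(self) -> bool:
        return "undefined-baseline" in self.flags


@dataclass
class DifferentialReport:
    """Biomass- and reaction-level changes between two media conditions.

    Biomass values come from plain FBA (degeneracy-invariant); per-reaction
    changes are computed on parsimonious fluxes.  When either condition is
    not optimal the statuses are recorded and the numbers are absent.
    """

    status_with: str
    status_without: str
    biomass_with: float = float("nan")
    biomass_without: float = float("nan")
    biomass_change_pct: Optional[float] = None
    per_reaction: Dict[str, ReactionChange] = field(default_factory=dict)
    removed_nutrient: str = ""

    @property
    def ok(self) -> bool:
        return self.status_with == self.status_without == "optimal"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reaction": rid,
                "change_pct": ch.pct,
                "flags": ",".join(ch.flags),
            }
            for rid, ch in self.per_reaction.items()
        ]
        return pd.DataFrame(rows, columns=["reaction", "change_pct", "flags"])


def starvation_experiment(
    model: MetabolicModel,
    medium: MediumSpec,
    removed_nutrient: str,
    backend: Optional[SolverBackend] = None,
) -> DifferentialReport:
    """Simulate growth on the full medium vs the medium without one nutrient.

    ``removed_nutrient`` must be an entry of *medium*; its uptake is closed
    (secretion stays open).  Deterministic given the solver backend.
    """
    if removed_nutrient not in medium.entries:
        hints = difflib.get_close_matches(removed_nutrient, list(medium.entries), n=3)
        raise ValueError(
            f"{removed_nutrient!r} is not in medium {medium.name!r}"
            + (f"; did you mean {hints}?" if hints else "")
        )
    starved = medium.without(removed_nutrient)

    prob_with = assemble_problem(apply_medium(model, medium))
    prob_without = assemble_problem(apply_medium(model, starved))
    fba_with = solve_fba(prob_with, backend)
    fba_without = solve_fba(prob_without, backend)
    report = DifferentialReport(
        status_with=fba_with.status,
        status_without=fba_without.status,
        removed_nutrient=removed_nutrient,
    )
    if not (fba_with.status == fba_without.status == "optimal"):
        return report
    report.biomass_with = fba_with.objective_value
    report.biomass_without = fba_without.objective_value
    if abs(report.biomass_with) > BASELINE_EPS:
        report.biomass_change_pct = differential_biomass(
            report.biomass_with, report.biomass_without
        )

    pfba_with = solve_pfba(prob_with, backend)
    pfba_without = solve_pfba(prob_without, backend)
    for rid in prob_with.reaction_ids:
        base = pfba_with.fluxes[rid]
        new = pfba_without.fluxes[rid]
        flags: List[str] = []
        if abs(base) <= BASELINE_EPS:
            flags.append("undefined-baseline")
            if abs(new) > REPORT_EPS:
                # a pathway switching on from zero: no finite percent exists
                flags.append("activated")
            report.per_reaction[rid] = ReactionChange(pct=None, flags=tuple(flags))
            continue
        if abs(new) > REPORT_EPS and (base > 0) != (new > 0):
            flags.append("sign-flip")
        pct = (new - base) / abs(base) * 100.0
        report.per_reaction[rid] = ReactionChange(pct=pct, flags=tuple(flags))
    return report


def carbon_source_comparison(
    model: MetabolicModel,
    media: Sequence[MediumSpec],
    backend: Optional[SolverBackend] = None,
) -> pd.DataFrame:
    """Growth and substrate uptakes for each medium, sorted by growth.

    One parsimonious-FBA run per medium; rows are independent (no shared
    state).  Growth is the positive biomass flux; uptakes are the (negative)
    fluxes of each exchange reaction named in any of the media.
    """
    if not media:
        raise ValueError("need at least one medium")
    substrate_ids = sorted({rid for m in media for rid in m.entries})
    rows = []
    for medium in media:
        prob = assemble_problem(apply_medium(model, medium))
        sol = solve_pfba(prob, backend)
        row: Dict[str, object] = {"medium": medium.name, "status": sol.status}
        if sol.status == "optimal":
            row["growth"] = sol.objective_value
            for rid in substrate_ids:
                flux = sol.fluxes.get(rid, 0.0)
                row[f"uptake:{rid}"] = 0.0 if abs(flux) < REPORT_EPS else flux
        else:
            row["growth"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("growth", ascending=False, na_position="last").reset_index(
        drop=True
    )


def preferred_carbon_source(
    model: MetabolicModel,
    single_source_media: Sequence[MediumSpec],
    backend: Optional[SolverBackend] = None,
) -> str:
    """The medium name whose single-substrate growth is maximal."""
    table = carbon_source_comparison(model, single_source_media, backend)
    return str(table.iloc[0]["medium"])


def rank_differential_reactions(
    report: DifferentialReport, k: int
) -> Tuple[List[Tuple[str, float]], List[Tuple[str, float]], List[str]]:
    """Top-k most increased and most decreased reactions of a report.

    Returns ``(increased, decreased, excluded)``: two lists of (reaction
    id, percent change) ordered by change (ties broken lexicographically by
    id), plus the undefined-baseline reactions listed separately.  A
    reaction that *activates* from a zero baseline has no finite percent
    change but is the strongest possible increase, so activated reactions
    head the increased list with an infinite change; undefined-baseline
    entries that stay silent go to the excluded list.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    activated = sorted(
        rid
        for rid, ch in report.per_reaction.items()
        if ch.undefined and "activated" in ch.flags
    )
    excluded = sorted(
        rid
        for rid, ch in report.per_reaction.items()
        if ch.undefined and "activated" not in ch.flags
    )
    defined = [
        (rid, ch.pct) for rid, ch in report.per_reaction.items() if not ch.undefined
    ]
    increased = [(rid, float("inf")) for rid in activated]
    increased += sorted(defined, key=lambda t: (-t[1], t[0]))
    increased = increased[:k]
    decreased = sorted(defined, key=lambda t: (t[1], t[0]))[:k]
    return increased, decreased, excluded
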