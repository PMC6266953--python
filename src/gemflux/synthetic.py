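"""Deterministic generators of toy metabolic models with closed-form optima.

Every generator returns ``(model, spec)`` where ``spec.ground_truth``
records the analytically known optimum (and, where relevant, pathway
labels), so the LP machinery can be tested against closed forms without any
external model file.  Generators never solve anything themselves — the test
suite is responsible for confirming that ground truth and solver agree.

The designed toys:

``make_chain``
    substrate -> linear pathway -> biomass; optimum = uptake cap.
``make_branched``
    several substrates feeding one biomass precursor through disjoint
    pathways with stoichiometric yields y_i; optimum = sum(y_i * u_i) and
    single-source growth y_i * u_i, so carbon-source ranking follows the
    constructed yields.
``make_starvation_toy``
    a preferred and an alternative substrate with a biomass cap equal to
    what the preferred substrate alone sustains; closing the preferred
    uptake reduces growth by exactly (1 - y_alt/y_primary) * 100 percent.
``make_random_model``
    a seeded composition of branches (feasible by construction) with
    shuffled orderings; ground truth is the compositional optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToySpec",
    "make_chain",
    "make_branched",
    "make_starvation_toy",
    "make_random_model",
    "DEFAULT_SUBSTRATES",
    "DEFAULT_YIELDS",
]

#: four-substrate condition used throughout the docs and defaults
DEFAULT_SUBSTRATES = ("glc", "pyr", "glyc", "glu_L")
#: relative biomass yields of the default substrates (glucose-normalised)
DEFAULT_YIELDS = (1.0, 0.49, 0.07, 0.016)


@dataclass
class ToySpec:
    """Provenance of a generated toy: its kind, parameters and ground truth."""

    kind: str
    parameters: Dict[str, object] = field(default_factory=dict)
    ground_truth: Dict[str, object] = field(default_factory=dict)


def _exchange(mid: str, cap: float) -> Reaction:
    # uptake is negative flux: bounds (-cap, 0) open uptake, close secretion
    return Reaction(
        id=f"EX_{mid}",
        name=f"{mid} exchange",
        stoichiometry={mid: -1.0},
        lower_bound=-cap,
        upper_bound=0.0,
    )


def make_chain(length: int, uptake_cap: float) -> Tuple[MetabolicModel, ToySpec]:
    """A linear pathway: exchange -> `length` 1:1 steps -> biomass.

    The single binding constraint is the uptake cap, so the optimum equals
    ``uptake_cap`` regardless of length.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if uptake_cap <= 0:
        raise ValueError("uptake_cap must be positive")
    mets = [Metabolite(id=f"M{i}", compartment="c") for i in range(length + 1)]
    rxns = [_exchange("M0", uptake_cap)]
    for i in range(length):
        rxns.append(
            Reaction(
                id=f"R{i + 1}",
                stoichiometry={f"M{i}": -1.0, f"M{i + 1}": 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            )
        )
    rxns.append(
        Reaction(
            id="BIOMASS",
            name="biomass",
            stoichiometry={f"M{length}": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        name=f"chain_{length}",
    )
    spec = ToySpec(
        kind="chain",
        parameters={"length": length, "uptake_cap": uptake_cap},
        ground_truth={"optimum": uptake_cap},
    )
    return model, spec


def _branch(
    name: str, yield_: float, cap: float, steps: int = 1
) -> Tuple[List[Metabolite], List[Reaction], List[str]]:
    """One substrate pathway: EX -> transport -> conversions -> yield_ * P.

    ``steps`` counts the reactions after the exchange; the first crosses the
    boundary compartment (a transport step), the last produces the shared
    biomass precursor P with coefficient ``yield_``.  Returns the pathway's
    metabolites, reactions and the internal (non-exchange) reaction ids.
    """
    ext = f"{name}_e"
    mets = [Metabolite(id=ext, name=name, compartment="e")]
    rxns = [_exchange(ext, cap)]
    pathway_ids: List[str] = []
    prev = ext
    for s in range(steps):
        last = s == steps - 1
        if last:
            stoich = {prev: -1.0, "P": yield_}
        else:
            nxt = f"{name}_c{s}" if s else f"{name}_c"
            mets.append(Metabolite(id=nxt, name=name, compartment="c"))
            stoich = {prev: -1.0, nxt: 1.0}
            prev = nxt
        rid = f"{'T' if s == 0 else 'R'}_{name}_{s}"
        rxns.append(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0)
        )
        pathway_ids.append(rid)
    return mets, rxns, pathway_ids


def make_branched(
    yields: Sequence[float] = DEFAULT_YIELDS,
    uptake_caps: Union[float, Sequence[float]] = 10.0,
    substrates: Sequence[str] = DEFAULT_SUBSTRATES,
    steps_per_branch: int = 2,
) -> Tuple[MetabolicModel, ToySpec]:
    """Disjoint substrate pathways converging on one biomass precursor.

    Substrate *i* converts to the precursor P with stoichiometric yield
    ``yields[i]`` under an uptake cap ``u_i``, so growth on the full medium
    is ``sum(y_i * u_i)`` and growth on substrate *i* alone is ``y_i * u_i``.
    The default substrates and yields encode the four-substrate condition
    with glucose as the highest-yield (preferred) carbon source.
    """
    if len(yields) != len(substrates) or not substrates:
        raise ValueError("need one yield per substrate")
    if isinstance(uptake_caps, (int, float)):
        caps = [float(uptake_caps)] * len(substrates)
    else:
        caps = [float(u) for u in uptake_caps]
    if len(caps) != len(substrates):
        raise ValueError("need one uptake cap per substrate")
    if any(y <= 0 for y in yields) or any(u <= 0 for u in caps):
        raise ValueError("yields and uptake caps must be positive")

    mets: List[Metabolite] = [Metabolite(id="P", name="biomass precursor", compartment="c")]
    rxns: List[Reaction] = []
    pathways: Dict[str, List[str]] = {}
    for name, y, u in zip(substrates, yields, caps):
        bm, br, ids = _branch(name, y, u, steps=steps_per_branch)
        mets.extend(bm)
        rxns.extend(br)
        pathways[name] = ids
    rxns.append(
        Reaction(
            id="BIOMASS",
            name="biomass",
            stoichiometry={"P": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        name="branched_toy",
    )
    single = {s: y * u for s, y, u in zip(substrates, yields, caps)}
    spec = ToySpec(
        kind="branched",
        parameters={
            "substrates": tuple(substrates),
            "yields": tuple(yields),
            "uptake_caps": tuple(caps),
        },
        ground_truth={
            "optimum": float(sum(single.values())),
            "single_source_growth": single,
            "pathways": pathways,
            "preferred_source": max(single, key=lambda s: single[s]),
        },
    )
    return model, spec


def make_starvation_toy(
    primary_yield: float = 1.0,
    alternative_yield: float = 0.679,
    uptake_cap: float = 10.0,
    primary: str = "glc",
    alternative: str = "aa",
) -> Tuple[MetabolicModel, ToySpec]:
    """Preferred vs alternative carbon source with a closed-form starvation
    response.

    Both substrates (default: glucose and an amino-acid pool) feed the
    biomass precursor through disjoint equal-length pathways; the biomass
    reaction is capped at what the primary substrate alone sustains
    (``primary_yield * uptake_cap``).  On the full medium the parsimonious
    optimum routes everything through the primary pathway; closing the
    primary uptake forces the alternative pathway and growth drops to
    ``alternative_yield * uptake_cap``, a reduction of exactly
    ``(1 - alternative_yield/primary_yield) * 100`` percent.  The defaults
    give a 32.1% reduction at a glucose uptake bound of -10 mmol/gDW/hr.
    """
    if not primary_yield > alternative_yield > 0:
        raise ValueError("need primary_yield > alternative_yield > 0")
    if uptake_cap <= 0:
        raise ValueError("uptake_cap must be positive")
    cap_growth = primary_yield * uptake_cap

    mets: List[Metabolite] = [Metabolite(id="P", name="biomass precursor", compartment="c")]
    rxns: List[Reaction] = []
    pathways: Dict[str, List[str]] = {}
    for name, y in ((primary, primary_yield), (alternative, alternative_yield)):
        bm, br, ids = _branch(name, y, uptake_cap, steps=2)
        mets.extend(bm)
        rxns.extend(br)
        pathways[name] = ids
    rxns.append(
        Reaction(
            id="BIOMASS",
            name="biomass",
            stoichiometry={"P": -1.0},
            lower_bound=0.0,
            upper_bound=cap_growth,
        )
    )
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        name="starvation_toy",
    )
    reduction = (1.0 - alternative_yield / primary_yield) * 100.0
    spec = ToySpec(
        kind="starvation",
        parameters={
            "primary_yield": primary_yield,
            "alternative_yield": alternative_yield,
            "uptake_cap": uptake_cap,
            "primary": primary,
            "alternative": alternative,
        },
        ground_truth={
            "full_growth": cap_growth,
            "starved_growth": alternative_yield * uptake_cap,
            "reduction_pct": reduction,
            "primary_exchange": f"EX_{primary}_e",
            "alternative_exchange": f"EX_{alternative}_e",
            "alternative_pathway": pathways[alternative],
            "primary_pathway": pathways[primary],
        },
    )
    return model, spec


def make_random_model(n_reactions: int, seed: int) -> Tuple[MetabolicModel, ToySpec]:
    """A seeded random network, feasible by construction.

    Built by composing 1-4 substrate branches of random lengths, yields and
    uptake caps onto a single biomass reaction, then shuffling metabolite
    and reaction order; the compositional optimum ``sum(y_i * u_i)`` is
    recorded as ground truth.  The same seed always produces the same model
    (no global random state is touched).
    """
    if n_reactions < 3:
        raise ValueError("n_reactions must be >= 3")
    rng = np.random.default_rng(seed)
    budget = n_reactions - 1  # biomass takes one reaction
    max_branches = max(1, min(4, budget // 2))
    k = int(rng.integers(1, max_branches + 1))
    lengths = np.ones(k, dtype=int)  # steps per branch, >= 1
    extra = budget - 2 * k  # each branch costs 1 (EX) + steps
    if extra > 0:
        lengths += rng.multinomial(extra, np.full(k, 1.0 / k))
    yields = np.round(rng.uniform(0.2, 2.0, size=k), 3)
    caps = np.round(rng.uniform(1.0, 20.0, size=k), 2)
    if n_reactions == 3:
        yields = np.ones(1)  # minimal chain: optimum is the uptake cap itself

    mets: List[Metabolite] = [Metabolite(id="P", name="precursor", compartment="c")]
    rxns: List[Reaction] = []
    substrates = [f"S{i}" for i in range(k)]
    for name, y, u, steps in zip(substrates, yields, caps, lengths):
        bm, br, _ = _branch(name, float(y), float(u), steps=int(steps))
        mets.extend(bm)
        rxns.extend(br)
    rxns.append(
        Reaction(
            id="BIOMASS",
            name="biomass",
            stoichiometry={"P": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )
    mets = [mets[i] for i in rng.permutation(len(mets))]
    rxns = [rxns[i] for i in rng.permutation(len(rxns))]
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        name=f"random_{n_reactions}_{seed}",
    )
    spec = ToySpec(
        kind="random",
        parameters={"n_reactions": n_reactions, "seed": seed},
        ground_truth={
            "optimum": float(np.dot(yields, caps)),
            "yields": tuple(map(float, yields)),
            "uptake_caps": tuple(map(float, caps)),
            "branch_steps": tuple(map(int, lengths)),
        },
    )
    return model, spec
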