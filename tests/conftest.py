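import pytest

from gemflux import MetabolicModel, Metabolite, Reaction


@pytest.fixture
def linear_chain():
    """The 3-reaction linear chain: EX_A -> R1 -> BM with S = [[1,-1,0],[0,1,-1]].

    EX_A produces A (coefficient +1), R1 converts A to B, biomass consumes B.
    """
    return MetabolicModel(
        metabolites=[Metabolite(id="A"), Metabolite(id="B")],
        reactions=[
            Reaction(id="EX_A", stoichiometry={"A": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="BM", stoichiometry={"B": -1.0}, lower_bound=0.0, upper_bound=1000.0),
        ],
        objective={"BM": 1.0},
        name="linear_chain",
    )


@pytest.fixture
def parallel_pathways():
    """One substrate, two equivalent routes of length 2 and 3 to the biomass
    precursor; parsimonious FBA must route everything through the short one."""
    mets = [Metabolite(id=m) for m in ("A", "X", "Y1", "Y2", "P")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A": -1.0}, lower_bound=-10.0, upper_bound=0.0),
        # short route: 2 steps
        Reaction(id="S1", stoichiometry={"A": -1.0, "X": 1.0}, lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="S2", stoichiometry={"X": -1.0, "P": 1.0}, lower_bound=0.0, upper_bound=1000.0),
        # long route: 3 steps
        Reaction(id="L1", stoichiometry={"A": -1.0, "Y1": 1.0}, lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="L2", stoichiometry={"Y1": -1.0, "Y2": 1.0}, lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="L3", stoichiometry={"Y2": -1.0, "P": 1.0}, lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="BM", stoichiometry={"P": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, objective={"BM": 1.0},
                          name="parallel_pathways")
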