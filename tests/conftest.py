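import cobra
import pytest

import leafdiel as ld


def tiny_model(reactions: dict[str, tuple[dict[str, float], float, float]],
               name: str = "tiny") -> cobra.Model:
    """Build a throwaway cobra model from {rid: (stoich, lb, ub)}."""
    model = cobra.Model(name)
    mets: dict[str, cobra.Metabolite] = {}
    rxns = []
    for rid, (stoich, lb, ub) in reactions.items():
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({
            mets.setdefault(m, cobra.Metabolite(m, compartment="c"))
            : c for m, c in stoich.items()})
        rxns.append(r)
    model.add_reactions(rxns)
    return model


@pytest.fixture(scope="session")
def diamond_model():
    """Source -> A; direct A->B; two-step A->C->B; B -> sink fixed at 1."""
    return tiny_model({
        "R_SRC": ({"A": 1}, 0, 10),
        "R_AB": ({"A": -1, "B": 1}, 0, 10),
        "R_AC": ({"A": -1, "C": 1}, 0, 10),
        "R_CB": ({"C": -1, "B": 1}, 0, 10),
        "R_SINK": ({"B": -1}, 1, 1),
    })


@pytest.fixture(scope="session")
def parallel_model():
    """Two identical routes of equal length sharing demand 1."""
    return tiny_model({
        "R_SRC": ({"A": 1}, 0, 10),
        "R_1": ({"A": -1, "B": 1}, 0, 10),
        "R_2": ({"A": -1, "B": 1}, 0, 10),
        "R_SINK": ({"B": -1}, 1, 1),
    })


@pytest.fixture(scope="session")
def toy_params():
    return ld.ToyLeafParams()


@pytest.fixture(scope="session")
def toy_core(toy_params):
    return ld.build_toy_leaf(toy_params)


@pytest.fixture(scope="session")
def curve():
    return ld.toy_light_curve()


@pytest.fixture(scope="session")
def scenario_results():
    """All default scenarios, run once per session."""
    return {s.name: ld.run_scenario(s) for s in ld.default_scenarios()}


def result(scenario_results, prefix: str):
    for name, res in scenario_results.items():
        if name.startswith(prefix):
            return res
    raise KeyError(prefix)
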