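"""pFBA/FVA against the vertex-enumeration oracle, light minimization and
the CO2-matching bisection."""

import numpy as np
import pytest

import leafdiel as ld
from leafdiel.model_core import stoichiometric_matrix
from leafdiel.solve import (
    BracketError,
    RELIABILITY_FRACTION,
    day_net_co2_uptake,
    fva,
    match_assimilation,
    minimize_light,
    pfba,
    steady_state_residual,
)
from leafdiel.synthetic import ToyCurveParams

from _vertex_oracle import oracle_fva, oracle_pfba
from conftest import result, tiny_model


def _arrays(model):
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub


# ---------------------------------------------------------------------------
# pFBA

def test_pfba_prefers_the_direct_route(diamond_model):
    """Diamond network: direct route (flux sum 3) beats the two-step route
    (flux sum 4)."""
    sol = pfba(diamond_model)
    assert sol.optimal
    assert sol.flux("R_AB") == pytest.approx(1.0, abs=1e-8)
    assert sol.flux("R_AC") == pytest.approx(0.0, abs=1e-8)
    assert sol.objective_value == pytest.approx(3.0, abs=1e-8)


def test_pfba_zero_when_nothing_is_demanded():
    m = tiny_model({
        "R1": ({"A": 1}, 0, 10),
        "R2": ({"A": -1, "B": 1}, -10, 10),
        "R3": ({"B": -1}, 0, 10),
    })
    sol = pfba(m)
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(sol.fluxes.to_numpy(), 0.0, atol=1e-9)


def test_pfba_matches_vertex_oracle_on_small_networks(diamond_model,
                                                      parallel_model):
    reversible = tiny_model({
        "R_SRC": ({"A": 1}, 0, 10),
        "R_F": ({"A": -1, "B": 1}, -10, 10),
        "R_G": ({"B": -1, "A": 1}, -10, 10),  # forms a 2-cycle with R_F
        "R_SINK": ({"B": -1}, 2, 2),
    })
    for model in (diamond_model, parallel_model, reversible):
        sol = pfba(model)
        opt, _ = oracle_pfba(*_arrays(model))
        assert sol.objective_value == pytest.approx(opt, abs=1e-8)


def test_pfba_agrees_with_cobrapy_reference(scenario_results):
    """Independent cross-check on the full toy scenario model."""
    import cobra.flux_analysis

    res = result(scenario_results, "S1")
    model = res.diel.model
    ours = pfba(model)
    theirs = cobra.flux_analysis.pfba(model)
    theirs_total = float(np.abs(theirs.fluxes.to_numpy()).sum())
    assert ours.objective_value == pytest.approx(theirs_total, rel=1e-6)


def test_pfba_reports_infeasibility(toy_core):
    diel = ld.build_diel(toy_core, ld.toy_diel_config())
    ld.apply_light(diel, ld.LightConstraint(0.0))  # no light, maintenance > 0
    sol = pfba(diel)
    assert sol.status == "infeasible"
    assert sol.fluxes is None


def test_steady_state_across_scenarios(scenario_results):
    for res in scenario_results.values():
        assert steady_state_residual(res.diel, res.solution) <= 1e-6


# ---------------------------------------------------------------------------
# FVA

def test_fva_parallel_routes_are_unreliable(parallel_model):
    """Two equivalent routes: each spans [0, 1] and is flagged unreliable;
    the shared src/sink reactions collapse to a point and are reliable."""
    res = fva(parallel_model)
    for rid in ("R_1", "R_2"):
        lo, hi = res.range(rid)
        assert lo == pytest.approx(0.0, abs=1e-8)
        assert hi == pytest.approx(1.0, abs=1e-8)
        assert not res.reliable(rid)
    for rid in ("R_SRC", "R_SINK"):
        lo, hi = res.range(rid)
        assert hi - lo == pytest.approx(0.0, abs=1e-8)
        assert res.reliable(rid)


def test_fva_matches_vertex_oracle(diamond_model, parallel_model):
    for model in (diamond_model, parallel_model):
        sol = pfba(model)
        res = fva(model, reference=sol)
        lo, hi = oracle_fva(*_arrays(model),
                            total_flux_cap=sol.objective_value + 1e-9)
        rids = [r.id for r in model.reactions]
        assert np.allclose(res.frame.loc[rids, "minimum"], lo, atol=1e-8)
        assert np.allclose(res.frame.loc[rids, "maximum"], hi, atol=1e-8)


def test_fva_sandwich_and_reliability_rule(scenario_results):
    """Reference flux lies inside [min, max]; the reliable flag implements
    the <10%-of-flux rule."""
    for prefix in ("S1", "S2", "S3"):
        frame = result(scenario_results, prefix).fva_result.frame
        assert (frame["minimum"] <= frame["reference"] + 1e-6).all()
        assert (frame["reference"] <= frame["maximum"] + 1e-6).all()
        nonzero = frame[frame["reference"].abs() > 1e-6]
        width = nonzero["maximum"] - nonzero["minimum"]
        expected = width < RELIABILITY_FRACTION * nonzero["reference"].abs()
        assert (nonzero["reliable"] == expected).all()


def test_fva_agrees_with_cobrapy_on_small_network(diamond_model):
    from cobra.flux_analysis import flux_variability_analysis

    res = fva(diamond_model)
    ref = flux_variability_analysis(diamond_model, fraction_of_optimum=0.0,
                                    pfba_factor=1.0, processes=1)
    assert np.allclose(res.frame["minimum"], ref["minimum"], atol=1e-6)
    assert np.allclose(res.frame["maximum"], ref["maximum"], atol=1e-6)


# ---------------------------------------------------------------------------
# light minimization

def test_minimal_light_below_equality_level(scenario_results):
    res = result(scenario_results, "S3")
    assert res.min_photon_use < 0.9 * res.scenario.ppfd


def test_light_minimum_with_and_without_mito_atp_synthase(scenario_results):
    """Knocking out mitochondrial ATP synthase strictly raises the light
    minimum (the paper-style 94.7 vs 83.9 ordering)."""
    intact = result(scenario_results, "S3").min_photon_use
    blocked = result(scenario_results, "S4").min_photon_use
    assert blocked > intact + 1.0


def test_zero_output_zero_maintenance_needs_no_light(toy_core):
    params = ld.ToyLeafParams(maintenance_atp_day=0.0,
                              maintenance_atp_night=0.0)
    core = ld.build_toy_leaf(params)
    diel = ld.build_diel(core, ld.toy_diel_config(params))
    ld.apply_light(diel, ld.LightConstraint(
        200, mode=ld.LightMode.UPPER_BOUND))
    ld.apply_output(diel, ld.OutputComposition(scale=0.0))
    sol = minimize_light(diel)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_pfba_consistent_with_fixed_light_minimum(scenario_results):
    """Fixing photon use at the light minimum and re-solving pFBA reproduces
    exactly that photon usage."""
    res = result(scenario_results, "S3")
    diel = res.diel
    minimum = res.min_photon_use
    photon_rxns = diel.tagged("photon_use", phase="day")
    model = diel.model
    with model:
        cons = model.problem.Constraint(
            sum(r.flux_expression for r in photon_rxns),
            ub=minimum + 1e-9, name="fix_light_min")
        model.add_cons_vars(cons)
        sol = pfba(model)
        assert sol.optimal
        used = sum(sol.flux(r.id) for r in photon_rxns)
    assert used == pytest.approx(minimum, abs=1e-6)


# ---------------------------------------------------------------------------
# CO2 matching

def test_match_assimilation_converges(toy_core, curve):
    diel = ld.build_diel(toy_core, ld.toy_diel_config())
    ld.apply_light(diel, ld.LightConstraint(200))
    handle = ld.apply_output(diel, ld.OutputComposition())
    m = match_assimilation(diel, handle, curve, 200.0, tol=1e-4)
    assert abs(m.achieved_assimilation - m.target_assimilation) <= 1e-4
    assert m.iterations <= 60
    assert m.scale > 0
    assert day_net_co2_uptake(diel, m.solution) == \
        pytest.approx(m.achieved_assimilation)


def test_match_unreachable_target_reports_bracket_error(toy_core):
    """A curve demanding more assimilation than the light supply allows."""
    greedy = ld.toy_light_curve(ToyCurveParams(phi=0.12, a_max=400.0,
                                               theta=0.99))
    diel = ld.build_diel(toy_core, ld.toy_diel_config())
    ld.apply_light(diel, ld.LightConstraint(200))
    handle = ld.apply_output(diel, ld.OutputComposition())
    with pytest.raises(BracketError) as err:
        match_assimilation(diel, handle, greedy, 200.0)
    assert err.value.max_achievable is not None
    assert err.value.max_achievable < greedy(200.0)


def test_assimilation_monotone_in_scale(toy_core, curve):
    diel = ld.build_diel(toy_core, ld.toy_diel_config())
    ld.apply_light(diel, ld.LightConstraint(200))
    handle = ld.apply_output(diel, ld.OutputComposition())
    values = []
    for scale in (0.0, 0.3, 0.6, 0.9):
        handle.set_scale(scale)
        sol = pfba(diel)
        assert sol.optimal
        values.append(day_net_co2_uptake(diel, sol))
    assert all(b >= a - 1e-7 for a, b in zip(values, values[1:]))
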