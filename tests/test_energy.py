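"""Energy budgets, shuttle extraction, light-use fractions and scenarios."""

import math

import pandas as pd
import pytest

import leafdiel as ld
from leafdiel.energy import (
    CAP_PPDK,
    Scenario,
    compute_budget,
    cyclic_fraction,
    extract_shuttles,
    light_use_fraction,
)
from leafdiel.model_core import ConfigurationError
from leafdiel.solve import FluxSolution

from conftest import result


def test_budget_closes_in_every_scenario(scenario_results):
    """production + imports = consumption + exports for every (phase,
    compartment, cofactor)."""
    for res in scenario_results.values():
        assert res.budget.closure_residual() <= 1e-6


def test_global_transfer_closure(scenario_results):
    """Directed carrier transfers net to zero over all compartments."""
    res = result(scenario_results, "S1")
    for cof in ("ATP", "NADH", "NADPH"):
        for phase in ("day", "night"):
            assert res.budget.net_transfer_total(cof, phase) == \
                pytest.approx(0.0, abs=1e-9)


def test_night_chloroplast_makes_no_nadph(scenario_results):
    """No photons at night: zero chloroplast NADPH production."""
    for prefix in ("S1", "S3"):
        led = result(scenario_results, prefix).budget.ledgers
        row = led.query("phase == 'night' and compartment == 'p' "
                        "and cofactor == 'NADPH'")
        assert float(row["production"].iloc[0]) == pytest.approx(0.0,
                                                                 abs=1e-9)


def test_missing_cofactor_species_is_configuration_error(scenario_results):
    res = result(scenario_results, "S1")
    bad_map = {"ATP": {"c": "atp_zz"}}
    with pytest.raises(ConfigurationError):
        compute_budget(res.diel, res.solution, bad_map)


def test_blocked_chl_atp_export_leaves_ant_as_only_atp_import(
        scenario_results):
    """With the chloroplast ATP shuttles blocked, daytime carrier imports of
    cytosolic ATP come only from the mitochondrion (ANT)."""
    res = result(scenario_results, "S6")
    tr = res.budget.transfers.query(
        "phase == 'day' and cofactor == 'ATP' and acceptor == 'c' "
        "and flux > 1e-9")
    assert set(tr["donor"]) <= {"m"}
    assert res.shuttles["ant"] > 0.5


def test_shuttle_report_under_capacity_caps(scenario_results):
    """PEP-pyruvate shuttle pinned at its 0.034 cap while mitochondrial ATP
    synthase carries substantial flux."""
    res = result(scenario_results, "S2")
    assert res.shuttles["pep_pyruvate"] <= CAP_PPDK + 1e-9
    assert res.shuttles["mito_atp_synthase"] > 0.5
    assert res.shuttles["gly_decarboxylase"] > 1.0


def test_unconstrained_chl_atp_export_via_pep_pyruvate(scenario_results):
    """Without caps the PEP-pyruvate shuttle carries the dominant chloroplast
    ATP export."""
    res = result(scenario_results, "S1")
    assert res.shuttles["pep_pyruvate"] > 1.0
    assert res.shuttles["pep_pyruvate"] > abs(res.shuttles["ntt"])


def test_all_shuttles_blocked_report_zero(toy_core):
    """Zero caps on every shuttle reaction zero every report entry (idle
    model: no output, no maintenance)."""
    params = ld.ToyLeafParams(maintenance_atp_day=0.0,
                              maintenance_atp_night=0.0)
    core = ld.build_toy_leaf(params)
    diel = ld.build_diel(core, ld.toy_diel_config(params))
    ld.apply_light(diel, ld.LightConstraint(
        200, mode=ld.LightMode.UPPER_BOUND))
    ld.apply_output(diel, ld.OutputComposition(scale=0.0))
    for tag in ld.energy.SHUTTLE_TAGS.values():
        for rxn in diel.tagged(tag):
            rxn.bounds = (0.0, 0.0)
    sol = ld.pfba(diel)
    assert sol.optimal
    report = extract_shuttles(diel, sol)
    for name in ld.energy.SHUTTLE_TAGS:
        assert report[name] == pytest.approx(0.0, abs=1e-9)


def test_ntt_day_flux_zero_in_all_default_scenarios(scenario_results):
    for res in scenario_results.values():
        assert res.shuttles["ntt"] == pytest.approx(0.0, abs=1e-12)


def test_light_use_fraction_bounds_and_errors(scenario_results):
    res = result(scenario_results, "S1")
    assert light_use_fraction(res.diel, res.solution, 200.0) == \
        pytest.approx(0.9, abs=1e-6)
    res3 = result(scenario_results, "S3")
    frac = light_use_fraction(res3.diel, res3.solution, 200.0)
    assert 0.0 < frac < 0.9
    with pytest.raises(ValueError):
        light_use_fraction(res.diel, res.solution, 0.0)


def test_cyclic_fraction_arithmetic(scenario_results):
    """4 cyclic / 100 linear -> 0.04; zero cyclic -> 0; cyclic without
    linear -> infinity sentinel."""
    res = result(scenario_results, "S1")
    fluxes = res.solution.fluxes.copy()

    def fake(cyc, lin):
        f = fluxes.copy()
        f["CYCLIC_day"], f["PSII_day"] = cyc, lin
        return FluxSolution("optimal", 0.0, f)

    assert cyclic_fraction(res.diel, fake(4.0, 100.0)) == \
        pytest.approx(0.04)
    assert cyclic_fraction(res.diel, fake(0.0, 100.0)) == 0.0
    assert math.isinf(cyclic_fraction(res.diel, fake(1.0, 0.0)))


def test_cyclic_engagement_rises_with_light(curve):
    """Under upper-bound light, the cyclic:linear fraction is near zero at
    the lowest PPFD and non-decreasing across the sweep."""
    from leafdiel.energy import build_scenario_model
    from leafdiel.solve import match_assimilation

    fractions = []
    for ppfd in (50.0, 200.0, 800.0):
        scen = Scenario("sweep", ppfd=ppfd, light_mode="upper_bound")
        diel, handle = build_scenario_model(scen)
        m = match_assimilation(diel, handle, curve, ppfd)
        fractions.append(cyclic_fraction(diel, m.solution))
    assert fractions[0] < 0.05
    assert all(b >= a - 1e-6 for a, b in zip(fractions, fractions[1:]))


def test_capacity_caps_never_decrease_mito_atp_synthase(scenario_results):
    """Scenario monotonicity: the capped scenario uses at least as much
    mitochondrial ATP synthase as the unconstrained one."""
    uncapped = result(scenario_results, "S1").shuttles["mito_atp_synthase"]
    capped = result(scenario_results, "S2").shuttles["mito_atp_synthase"]
    assert capped >= uncapped - 1e-9


def test_nadph_export_block_raises_light_use(scenario_results):
    """Blocking chloroplast NAD(P)H export lowers light-use efficiency
    (48% vs 42% style ordering) and engages nocturnal citrate storage."""
    base = result(scenario_results, "S3")
    blocked = result(scenario_results, "S7")
    assert blocked.min_photon_use > base.min_photon_use + 1.0
    cit_base = base.solution.flux("LINK_cit_c_night_to_day")
    cit_blocked = blocked.solution.flux("LINK_cit_c_night_to_day")
    assert cit_blocked > 1e-3
    assert cit_blocked > cit_base + 1e-3


def test_unknown_knockout_is_configuration_error():
    scen = Scenario("bad", knockouts=["NOT_A_REACTION"])
    with pytest.raises(ConfigurationError):
        ld.run_scenario(scen)


def test_scenario_json_round_trip(tmp_path):
    scen = ld.default_scenarios()[1]
    path = tmp_path / "s.json"
    path.write_text(scen.to_json())
    back = Scenario.from_json(path)
    assert back == scen


def test_scenario_result_tables(scenario_results, tmp_path):
    res = result(scenario_results, "S1")
    res.write(tmp_path)
    for name in ("fluxes.tsv", "fva.tsv", "budget.tsv", "shuttles.tsv",
                 "scenario.json", "summary.json"):
        assert (tmp_path / name).exists()
    fluxes = pd.read_csv(tmp_path / "fluxes.tsv", sep="\t",
                         index_col="core_reaction")
    assert {"day", "night"} <= set(fluxes.columns)
    assert len(fluxes) == len(res.diel.provenance)
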