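"""Per-compartment cofactor budgets, named shuttle fluxes, light-use and
cyclic/linear electron-transport fractions, and scenario orchestration.

The seven named inter-organelle energy shuttles are declared by tags at model
build time (graph inference of shuttle cycles is ambiguous; the routes are
known by name): (1) chloroplast malate valve, (2a/2b) TP-3PGA shuttle in its
phosphorylating and nonphosphorylating modes, (3) PEP-pyruvate shuttle, (4)
mitochondrial malate valve, (5) peroxisomal malate-OAA shuttle, (6) ANT and
(7) NTT.  Sign convention: organelle -> cytosol positive for shuttles, ANT
export positive, NTT import positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .constraints import (
    CapacityConstraint,
    IMPLIED_CHL_PER_AREA,
    LightConstraint,
    LightMode,
    OutputComposition,
    apply_capacity,
    apply_light,
    apply_output,
    convert_chl_capacity,
)
from .diel import DielModel, build_diel, map_flux_to_core
from .model_core import ConfigurationError, get_phase
from .solve import (
    FluxSolution,
    FVAResult,
    MatchResult,
    fva,
    match_assimilation,
    minimize_light,
    pfba,
)

__all__ = [
    "SHUTTLE_TAGS",
    "EnergyBudget",
    "ShuttleReport",
    "Scenario",
    "ScenarioResult",
    "compute_budget",
    "extract_shuttles",
    "light_use_fraction",
    "cyclic_fraction",
    "run_scenario",
    "default_scenarios",
    "CAP_PPDK",
    "CAP_GAPDH_PHOS",
    "CAP_GAPDH_NONPHOS",
    "CAP_MALATE_VALVE",
]

#: Fig.-1-style shuttle inventory: report name -> reaction tag.
SHUTTLE_TAGS: dict[str, str] = {
    "chl_malate_valve": "shuttle:chl_malate_valve",          # 1
    "tp3pga_phosphorylating": "shuttle:tp3pga_phos",         # 2a
    "tp3pga_nonphosphorylating": "shuttle:tp3pga_nonphos",   # 2b
    "pep_pyruvate": "shuttle:pep_pyruvate",                  # 3
    "mito_malate_valve": "shuttle:mito_malate_valve",        # 4
    "perox_malate_oaa": "shuttle:perox_malate_oaa",          # 5
    "ant": "shuttle:ant",                                    # 6
    "ntt": "shuttle:ntt",                                    # 7
}

# enzyme-capacity caps, umol m-2 s-1 (PPDK converted from 0.9 umol/mg chl/h)
CAP_PPDK = convert_chl_capacity(0.9, IMPLIED_CHL_PER_AREA)     # 0.034
CAP_GAPDH_PHOS = 93.0
CAP_GAPDH_NONPHOS = 0.33
CAP_MALATE_VALVE = 0.75

_CLOSURE_TOL = 1e-6


@dataclass
class EnergyBudget:
    """Cofactor ledgers: production/consumption per (phase, compartment,
    cofactor), and cross-compartment carrier transfers (ATP moved by
    ANT/NTT).  Reducing equivalents never cross membranes as species; their
    transfer is the business of the shuttles (see ShuttleReport)."""

    ledgers: pd.DataFrame   # phase, compartment, cofactor, production,
                            # consumption, import_flux, export_flux
    transfers: pd.DataFrame  # phase, cofactor, donor, acceptor, flux

    def closure_residual(self) -> float:
        """max |production + imports - consumption - exports|; 0 at steady
        state for every (phase, compartment, cofactor)."""
        lhs = self.ledgers["production"] + self.ledgers["import_flux"]
        rhs = self.ledgers["consumption"] + self.ledgers["export_flux"]
        return float((lhs - rhs).abs().max()) if len(self.ledgers) else 0.0

    def net_transfer_total(self, cofactor: str, phase: str) -> float:
        """Sum of per-compartment net transfers; zero when every carrier flux
        that leaves one compartment arrives in another."""
        sel = self.transfers.query("cofactor == @cofactor and phase == @phase")
        net: dict[str, float] = {}
        for _, row in sel.iterrows():
            net[row["acceptor"]] = net.get(row["acceptor"], 0.0) + row["flux"]
            net[row["donor"]] = net.get(row["donor"], 0.0) - row["flux"]
        return float(sum(net.values()))

    def to_tsv(self, path) -> None:
        self.ledgers.to_csv(path, sep="\t", index=False)


def compute_budget(diel: DielModel, solution: FluxSolution,
                   cofactor_map: dict[str, dict[str, str]]) -> EnergyBudget:
    """Build per-compartment cofactor ledgers from an optimal solution.

    Production sums max(0, s_ij v_j) and consumption max(0, -s_ij v_j) over
    reactions confined to the compartment; reactions spanning compartments
    (carrier transport such as ANT/NTT) are booked as imports/exports.
    """
    model = diel.model
    rows, transfer_rows = [], []
    for phase, suffix in (("day", diel.day_suffix),
                          ("night", diel.night_suffix)):
        for cof, comp_map in cofactor_map.items():
            for comp, core_sid in comp_map.items():
                sid = core_sid + suffix
                try:
                    met = model.metabolites.get_by_id(sid)
                except KeyError as exc:
                    raise ConfigurationError(
                        f"cofactor species {sid!r} missing") from exc
                prod = cons = imp = exp = 0.0
                for rxn in met.reactions:
                    sv = rxn.metabolites[met] * solution.flux(rxn.id)
                    comps = {m.compartment for m in rxn.metabolites}
                    if comps == {comp}:
                        if sv > 0:
                            prod += sv
                        else:
                            cons -= sv
                    else:
                        others = sorted(comps - {comp})
                        if sv > 0:
                            imp += sv
                            transfer_rows.append((phase, cof, others[0],
                                                  comp, sv))
                        elif sv < 0:
                            exp -= sv
                rows.append((phase, comp, cof, prod, cons, imp, exp))
    ledgers = pd.DataFrame(rows, columns=[
        "phase", "compartment", "cofactor", "production", "consumption",
        "import_flux", "export_flux"])
    transfers = pd.DataFrame(transfer_rows, columns=[
        "phase", "cofactor", "donor", "acceptor", "flux"])
    return EnergyBudget(ledgers=ledgers, transfers=transfers)


@dataclass
class ShuttleReport:
    """Named day-phase net shuttle fluxes plus the Gly decarboxylase and
    mitochondrial ATP synthase fluxes (umol m-2 s-1)."""

    fluxes: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.fluxes[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.fluxes.items()),
                            columns=["shuttle", "day_net_flux"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def extract_shuttles(diel: DielModel, solution: FluxSolution) -> ShuttleReport:
    fluxes: dict[str, float] = {}
    for name, tag in SHUTTLE_TAGS.items():
        rxns = diel.tagged(tag, phase="day")
        if not rxns:
            raise ConfigurationError(f"no day-phase reactions tagged {tag!r}")
        fluxes[name] = sum(solution.flux(r.id) for r in rxns)
    for name, tag in (("gly_decarboxylase", "gdc"),
                      ("mito_atp_synthase", "mito_atp_synthase")):
        rxns = diel.tagged(tag, phase="day")
        if not rxns:
            raise ConfigurationError(f"no day-phase reactions tagged {tag!r}")
        fluxes[name] = sum(solution.flux(r.id) for r in rxns)
    return ShuttleReport(fluxes=fluxes)


def light_use_fraction(diel: DielModel, solution: FluxSolution,
                       ppfd: float) -> float:
    """Fraction of incident PPFD absorbed by the photosystems, in [0, 1]."""
    if ppfd <= 0:
        raise ValueError("light_use_fraction undefined at ppfd <= 0")
    used = sum(solution.flux(r.id)
               for r in diel.tagged("photon_use", phase="day"))
    return used / ppfd


def cyclic_fraction(diel: DielModel, solution: FluxSolution) -> float:
    """Cyclic relative to linear electron transport, on an electron basis.

    One PSII photon drives one electron through the whole linear chain; one
    cyclic photon recycles one electron around PSI — so the ratio of the two
    photon fluxes is the electron-flux ratio.  Returns inf when cyclic flux
    exists without any linear flux.
    """
    cyc = sum(solution.flux(r.id)
              for r in diel.tagged("cyclic_et", phase="day"))
    lin = sum(solution.flux(r.id) for r in diel.tagged("psii", phase="day"))
    if cyc <= 0:
        return 0.0
    if lin <= 0:
        return math.inf
    return cyc / lin


# ---------------------------------------------------------------------------
# scenarios

@dataclass
class Scenario:
    """A named bundle of constraints/knockouts reproducing one experiment.

    ``knockouts`` are reaction core ids, optionally phase-qualified as
    "RID:day" or "RID:night" (bare ids knock out both copies).  The
    objective sequence is match_assimilation -> pfba -> fva, optionally
    followed by light-use minimization (upper-bound light mode only).
    """

    name: str
    leaf_kind: str = "source"           # source | growing
    ppfd: float = 200.0
    light_mode: str = "equality"        # equality | upper_bound
    capacity_caps: list[CapacityConstraint] = field(default_factory=list)
    knockouts: list[str] = field(default_factory=list)
    run_minimize_light: bool = False
    fva_reactions: list[str] | None = None
    description: str = ""

    def __post_init__(self):
        if self.leaf_kind not in {"source", "growing"}:
            raise ValueError("leaf_kind must be source or growing")
        if self.ppfd <= 0:
            raise ValueError("ppfd must be positive")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "Scenario":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        d["capacity_caps"] = [CapacityConstraint(**c)
                              for c in d.get("capacity_caps", [])]
        return cls(**d)


@dataclass
class ScenarioResult:
    scenario: Scenario
    diel: DielModel
    match: MatchResult
    solution: FluxSolution
    fva_result: FVAResult
    budget: EnergyBudget
    shuttles: ShuttleReport
    light_fraction: float
    cyclic: float
    min_light: FluxSolution | None = None

    @property
    def min_photon_use(self) -> float | None:
        return None if self.min_light is None else self.min_light.objective_value

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table, linkers = map_flux_to_core(self.diel, self.solution.fluxes)
        table.to_csv(outdir / "fluxes.tsv", sep="\t")
        linkers.rename("flux").to_csv(outdir / "linkers.tsv", sep="\t")
        self.fva_result.to_tsv(outdir / "fva.tsv")
        self.budget.to_tsv(outdir / "budget.tsv")
        self.shuttles.to_tsv(outdir / "shuttles.tsv")
        (outdir / "scenario.json").write_text(self.scenario.to_json() + "\n")
        summary = {
            "scale": self.match.scale,
            "achieved_assimilation": self.match.achieved_assimilation,
            "target_assimilation": self.match.target_assimilation,
            "light_use_fraction": self.light_fraction,
            "cyclic_fraction": self.cyclic,
            "min_photon_use": self.min_photon_use,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")


_KEY_FVA_CORE = ["ATPS_M", "GDC", "PPDK", "GAPDH_PHOS_C", "GAPDH_NONPHOS_C",
                 "T_MALOAA_PC", "T_MALOAA_MC", "T_MALOAA_XC", "ANT", "NTT"]


def _resolve_knockout(diel: DielModel, spec: str) -> list:
    if ":" in spec:
        rid, phase = spec.split(":", 1)
        if phase == "day":
            targets = [rid + diel.day_suffix]
        elif phase == "night":
            targets = [rid + diel.night_suffix]
        else:
            raise ConfigurationError(f"bad knockout phase in {spec!r}")
    else:
        rid = spec
        targets = [rid + diel.day_suffix, rid + diel.night_suffix]
    out = []
    for t in targets:
        if t not in diel.model.reactions:
            raise ConfigurationError(f"knockout target {t!r} not in model")
        out.append(diel.model.reactions.get_by_id(t))
    return out


def build_scenario_model(scenario: Scenario, params=None):
    """Toy diel model with the scenario's constraints applied (not solved)."""
    from .synthetic import ToyLeafParams, build_toy_leaf, toy_diel_config

    params = params or ToyLeafParams()
    core = build_toy_leaf(params)
    diel = build_diel(core, toy_diel_config(params))
    light = LightConstraint(scenario.ppfd, mode=LightMode(scenario.light_mode))
    apply_light(diel, light)
    comp = (OutputComposition.growing() if scenario.leaf_kind == "growing"
            else OutputComposition(components={
                "EX_SUC_PHLOEM": params.phloem_sucrose,
                "EX_AA_PHLOEM": params.phloem_aa}))
    handle = apply_output(diel, comp)
    apply_capacity(diel, scenario.capacity_caps)
    for spec in scenario.knockouts:
        for rxn in _resolve_knockout(diel, spec):
            rxn.bounds = (0.0, 0.0)
    return diel, handle


def run_scenario(scenario: Scenario, params=None, curve=None,
                 outdir: str | Path | None = None,
                 match_tol: float = 1e-4) -> ScenarioResult:
    """Execute match -> pfba -> fva -> accounting for one scenario.

    Deterministic given model, config and solver.  Any stage error is
    re-raised with the stage named.
    """
    from .synthetic import toy_cofactor_map, toy_light_curve

    curve = curve or toy_light_curve()
    diel, handle = build_scenario_model(scenario, params)

    stage = "match_assimilation"
    try:
        match = match_assimilation(diel, handle, curve, scenario.ppfd,
                                   tol=match_tol)
        stage = "pfba"
        solution = match.solution
        if not solution.optimal:
            raise RuntimeError(f"solver status {solution.status}")
        stage = "fva"
        rids = scenario.fva_reactions
        if rids is None:
            rids = [r + diel.day_suffix for r in _KEY_FVA_CORE
                    if r + diel.day_suffix in diel.model.reactions]
            rids += [l for l in diel.linker_ids]
        fva_result = fva(diel, reactions=rids, reference=solution)
        stage = "energy_accounting"
        budget = compute_budget(diel, solution, toy_cofactor_map())
        shuttles = extract_shuttles(diel, solution)
        lf = light_use_fraction(diel, solution, scenario.ppfd)
        cyc = cyclic_fraction(diel, solution)
        min_light_sol = None
        if scenario.run_minimize_light:
            stage = "minimize_light"
            if scenario.light_mode != "upper_bound":
                raise ConfigurationError(
                    "light minimization needs upper_bound light mode")
            min_light_sol = minimize_light(diel)
            if not min_light_sol.optimal:
                raise RuntimeError(f"solver status {min_light_sol.status}")
    except Exception as exc:
        raise type(exc)(f"[scenario {scenario.name}, stage {stage}] {exc}") \
            from exc

    result = ScenarioResult(
        scenario=scenario, diel=diel, match=match, solution=solution,
        fva_result=fva_result, budget=budget, shuttles=shuttles,
        light_fraction=lf, cyclic=cyc, min_light=min_light_sol)
    if outdir is not None:
        result.write(outdir)
    return result


def default_scenarios() -> list[Scenario]:
    """The scenario matrix probing the organelle energy shuttles."""
    caps_atp_export = [
        CapacityConstraint("PPDK", CAP_PPDK, "day"),
        CapacityConstraint("GAPDH_PHOS_C", CAP_GAPDH_PHOS, "day"),
        CapacityConstraint("GAPDH_NONPHOS_C", CAP_GAPDH_NONPHOS, "day"),
    ]
    return [
        Scenario("S1_unconstrained_source",
                 description="source leaf, all light used, shuttles free"),
        Scenario("S2_capacity_caps_source", capacity_caps=caps_atp_export,
                 description="chloroplast ATP-export shuttles capped at "
                             "measured enzyme capacities"),
        Scenario("S3_light_upper_source", light_mode="upper_bound",
                 run_minimize_light=True,
                 description="incident PPFD as an upper bound; parsimonious "
                             "light use"),
        Scenario("S4_no_mito_atp_source", light_mode="upper_bound",
                 knockouts=["ATPS_M:day"], run_minimize_light=True,
                 description="daytime mitochondrial ATP synthase knocked out "
                             "under parsimonious light use"),
        Scenario("S5_malate_valve_cap_source", light_mode="upper_bound",
                 capacity_caps=[CapacityConstraint(
                     "T_MALOAA_PC", CAP_MALATE_VALVE, "day")],
                 run_minimize_light=True,
                 description="chloroplast malate valve capped at the "
                             "kinetic-model limit"),
        Scenario("S6_no_chl_atp_export_source",
                 knockouts=["PPDK:day", "GAPDH_PHOS_C:day"],
                 description="all chloroplast ATP-exporting shuttles blocked "
                             "(feasibility probe)"),
        Scenario("S7_no_chl_nadph_export_source", light_mode="upper_bound",
                 knockouts=["T_MALOAA_PC:day", "GAPDH_PHOS_C:day",
                            "GAPDH_NONPHOS_C:day"],
                 run_minimize_light=True,
                 description="all chloroplast NAD(P)H-export routes blocked; "
                             "probes nocturnal citrate storage"),
        Scenario("S8_growing_leaf", leaf_kind="growing",
                 description="growing leaf: biomass output instead of phloem "
                             "export"),
    ]
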