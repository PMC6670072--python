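"""Deterministic generator of the compartmented toy leaf network and the
light-response fixture.

The toy network emulates the energetic structure of a C3 leaf core-metabolism
model at ~90 reactions: a chloroplast electron-transport chain (linear PSII/PSI
plus cyclic), the Calvin-Benson-Bassham cycle with an explicit RuBisCO
oxygenase branch and the full photorespiratory loop across chloroplast,
peroxisome and mitochondrion, a coupled mitochondrial electron-transport chain
with an uncoupled alternative oxidase, and the seven named inter-organelle
energy shuttles (chloroplast malate valve, TP-3PGA shuttle in phosphorylating
and nonphosphorylating modes, PEP-pyruvate shuttle, mitochondrial malate
valve, peroxisomal malate-OAA shuttle, ANT, NTT).

Every non-boundary reaction is elementally and charge balanced; energy
coupling across membranes is carried by massless proton-motive-force tokens
(``pmf_p``, ``pmf_m``) so that textbook H+/ATP stoichiometries (14/3 for the
chloroplast CF0F1, 4 for the mitochondrial F0F1 including transport) are
explicit, tunable parameters.  There is no randomness anywhere: "synthetic
data" here means a generated, deterministic network plus a parametric
non-rectangular-hyperbola light curve standing in for digitized gas-exchange
data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import cobra

from .model_core import (
    Compartment,
    add_tags,
    set_massless,
    validate_balance,
    write_model,
)

__all__ = [
    "ToyLeafParams",
    "ToyCurveParams",
    "LightResponseCurve",
    "build_toy_leaf",
    "toy_light_curve",
    "toy_cofactor_map",
    "make_fixtures",
    "mito_vs_linear_atp_per_photon",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class ToyLeafParams:
    """Stoichiometric knobs of the toy network (all flux-unit free).

    Defaults are canonical textbook values: 8 photons per 2 NADPH through the
    linear chain; 12 lumen protons per 2 NADPH with 14/3 H+ per ATP, giving
    9/7 ~ 1.286 ATP per NADPH; cyclic electron flow depositing 2 protons per
    photon (3/7 ~ 0.429 ATP per photon); mitochondrial P/O of 2.5 ATP per
    NADH.  These preserve the ordering that oxidising one NAD(P)H-equivalent
    in the mitochondrion yields roughly twice the ATP per photon of running
    the linear chloroplast chain.
    """

    photons_per_nadph_linear: float = 4.0
    atp_per_nadph_linear: float = 9.0 / 7.0
    atp_per_photon_cyclic: float = 3.0 / 7.0
    hplus_per_atp_chl: float = 14.0 / 3.0
    hplus_per_atp_mito: float = 4.0
    p_o_ratio_mito: float = 2.5
    vc_vo_ratio: float | None = 3.0
    maintenance_atp_day: float = 4.0
    maintenance_atp_night: float = 4.0
    phloem_sucrose: float = 0.7
    phloem_aa: float = 0.3
    bounds_scale: float = 1000.0
    storage_pools: tuple[tuple[str, str], ...] = (
        ("starch_p", "chloroplast"),
        ("suc_c", "vacuole"),
        ("mal_c", "vacuole"),
        ("cit_c", "vacuole"),
        ("glu_c", "vacuole"),
        ("no3_c", "vacuole"),
    )

    def __post_init__(self):
        for name in ("photons_per_nadph_linear", "atp_per_nadph_linear",
                     "atp_per_photon_cyclic", "hplus_per_atp_chl",
                     "hplus_per_atp_mito", "p_o_ratio_mito", "bounds_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.vc_vo_ratio is not None and self.vc_vo_ratio < 0:
            raise ValueError("vc_vo_ratio must be >= 0 (or None/inf)")


def mito_vs_linear_atp_per_photon(p: ToyLeafParams) -> float:
    """ATP-per-photon of the mitochondrial route over the linear chain.

    The mitochondrial route values a photon at the NAD(P)H it produced
    (P/O ATP per ``photons_per_nadph`` photons); the linear chain yields
    ``atp_per_nadph_linear`` ATP for the same photons.  The ratio is thus
    P/O divided by the linear ATP:NADPH stoichiometry.
    """
    return p.p_o_ratio_mito / p.atp_per_nadph_linear


@dataclass(frozen=True)
class ToyCurveParams:
    """Non-rectangular hyperbola A(I); a fixture, not digitized data."""

    phi: float = 0.06        # apparent quantum yield, mol CO2 / mol photons
    a_max: float = 18.0      # light-saturated assimilation, umol m-2 s-1
    theta: float = 0.8       # curvature, dimensionless
    day_respiration: float = 0.0  # additive offset, umol m-2 s-1

    def __post_init__(self):
        if not 0 < self.phi < 0.125:
            raise ValueError("phi must be in (0, 0.125)")
        if self.a_max <= 0:
            raise ValueError("a_max must be > 0")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")


class LightResponseCurve:
    """Evaluable net assimilation curve A(I), saturating and concave."""

    def __init__(self, params: ToyCurveParams):
        self.params = params

    def __call__(self, ppfd: float) -> float:
        p = self.params
        s = p.phi * ppfd + p.a_max
        disc = s * s - 4.0 * p.theta * p.phi * ppfd * p.a_max
        if disc < 0:
            raise ValueError("negative discriminant: invalid curve parameters")
        return (s - math.sqrt(disc)) / (2.0 * p.theta) - p.day_respiration


def toy_light_curve(params: ToyCurveParams | None = None) -> LightResponseCurve:
    return LightResponseCurve(params or ToyCurveParams())


# ---------------------------------------------------------------------------
# species table

# formula, charge.  Massless book-keeping tokens are marked with None.
_SPECIES: dict[str, tuple[str | None, int]] = {
    "photon": (None, 0),
    "pmf": (None, 0),       # proton-motive-force quantum (per H+ translocated)
    "elow": (None, -2),     # electron pair between PSII and PSI
    "ehigh": (None, -2),    # electron pair at the ferredoxin level
    "vcvo": (None, 0),      # carboxylation:oxygenation coupling token
    "h": ("H", 1),
    "h2o": ("H2O", 0),
    "o2": ("O2", 0),
    "co2": ("CO2", 0),
    "h2o2": ("H2O2", 0),
    "pi": ("HO4P", -2),
    "ppi": ("HO7P2", -3),
    "nh4": ("H4N", 1),
    "no3": ("NO3", -1),
    "no2": ("NO2", -1),
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "amp": ("C10H12N5O7P", -2),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "nadp": ("C21H25N7O17P3", -3),
    "nadph": ("C21H26N7O17P3", -4),
    "coa": ("C21H32N7O16P3S", -4),
    "accoa": ("C23H34N7O17P3S", -4),
    "gap": ("C3H5O6P", -2),          # glyceraldehyde 3-phosphate
    "pga": ("C3H4O7P", -3),          # 3-phosphoglycerate
    "rubp": ("C5H8O11P2", -4),       # ribulose 1,5-bisphosphate
    "pep": ("C3H2O6P", -3),
    "pyr": ("C3H3O3", -1),
    "g2p": ("C2H2O6P", -3),          # 2-phosphoglycolate
    "glyclt": ("C2H3O3", -1),        # glycolate
    "glx": ("C2HO3", -1),            # glyoxylate
    "gly": ("C2H5NO2", 0),
    "ser": ("C3H7NO3", 0),
    "hpyr": ("C3H3O4", -1),          # hydroxypyruvate
    "glyc": ("C3H5O4", -1),          # glycerate
    "mal": ("C4H4O5", -2),
    "oaa": ("C4H2O5", -2),
    "cit": ("C6H5O7", -3),
    "akg": ("C5H4O5", -2),           # 2-oxoglutarate
    "glu": ("C5H8NO4", -1),          # glutamate; the lumped amino-acid pool
    "suc": ("C12H22O11", 0),         # sucrose
    "starch": ("C6H10O5", 0),        # glucan unit
}

_MASSLESS = {"photon", "pmf", "elow", "ehigh", "vcvo"}


class _Builder:
    def __init__(self, scale: float):
        self.model = cobra.Model("toy_leaf")
        self.model.compartments = {c.value: c.name.lower() for c in Compartment}
        self.scale = scale
        self._mets: dict[str, cobra.Metabolite] = {}

    def met(self, species: str, comp: str) -> cobra.Metabolite:
        mid = f"{species}_{comp}"
        if mid not in self._mets:
            formula, charge = _SPECIES[species]
            m = cobra.Metabolite(mid, formula=formula or "", charge=charge,
                                 name=species, compartment=comp)
            if species in _MASSLESS:
                set_massless(m)
            self._mets[mid] = m
        return self._mets[mid]

    def rxn(self, rid: str, stoich: dict[str, float], *, lb: float | None = None,
            ub: float | None = None, rev: bool = False, tags: tuple[str, ...] = (),
            name: str = "") -> cobra.Reaction:
        r = cobra.Reaction(rid, name=name or rid)
        # rounding kills float noise from parameter arithmetic (e.g.
        # (9/7)*(14/3)) so coefficients survive an SBML round trip exactly
        r.add_metabolites({
            self.met(*mid.rsplit("_", 1)): round(coef, 12)
            for mid, coef in stoich.items()
        })
        s = self.scale
        r.bounds = ((-s if rev else 0.0) if lb is None else lb,
                    s if ub is None else ub)
        if tags:
            add_tags(r, *tags)
        self.model.add_reactions([r])
        return r


def build_toy_leaf(params: ToyLeafParams | None = None) -> cobra.Model:
    """Build the single-phase (daytime-template) toy leaf core network.

    The returned model is phase-free; :func:`leafdiel.diel.build_diel`
    duplicates it into day and night copies.  All non-boundary reactions are
    mass- and charge-consistent (checked at build time).
    """
    p = params or ToyLeafParams()
    b = _Builder(p.bounds_scale)

    P = p.photons_per_nadph_linear
    pmf_per_nadph = p.atp_per_nadph_linear * p.hplus_per_atp_chl
    a_psii = 2.0 * pmf_per_nadph / (3.0 * P)   # 1/3 of the gradient at PSII/b6f
    b_psi = 4.0 * pmf_per_nadph / (3.0 * P)    # 2/3 credited to the PSI photon
    pmf_cyc = p.atp_per_photon_cyclic * p.hplus_per_atp_chl
    pmf_per_nadh_m = p.p_o_ratio_mito * p.hplus_per_atp_mito

    # -- boundary exchanges -------------------------------------------------
    # photon supply is wider than the generic bound: at high PPFD the
    # equality light constraint must remain satisfiable
    b.rxn("EX_PHOTON", {"photon_p": 1}, ub=10 * p.bounds_scale,
          tags=("boundary", "photon_influx"))
    b.rxn("EX_CO2", {"co2_c": 1}, rev=True, tags=("boundary", "co2_exchange"))
    b.rxn("EX_O2", {"o2_c": 1}, rev=True, tags=("boundary",))
    b.rxn("EX_H2O", {"h2o_c": 1}, rev=True, tags=("boundary",))
    b.rxn("EX_H", {"h_c": 1}, rev=True, tags=("boundary",))
    b.rxn("EX_NO3", {"no3_c": 1}, tags=("boundary",))
    b.rxn("EX_SUC_PHLOEM", {"suc_c": -1},
          tags=("boundary", "output:sucrose", "phloem"))
    b.rxn("EX_AA_PHLOEM", {"glu_c": -1},
          tags=("boundary", "output:aa", "phloem"))
    # lumped cell-wall/protein growth drain; deliberately more ATP-expensive
    # per carbon than phloem loading
    b.rxn("BIOMASS", {"suc_c": -1, "glu_c": -0.3, "atp_c": -2.5, "h2o_c": -2.5,
                      "adp_c": 2.5, "pi_c": 2.5, "h_c": 2.5},
          tags=("boundary", "output:biomass"))

    # -- chloroplast light reactions ---------------------------------------
    # electron pairs (elow/ehigh) and the proton gradient (pmf) are massless
    # tokens; water oxidation chemistry is explicit so O2/H+ books close.
    q = 2.0 / P  # electron pairs moved per photon at each photosystem
    b.rxn("PSII", {"photon_p": -1, "h2o_p": -q, "o2_p": q / 2,
                   "h_p": 2 * q, "elow_p": q, "pmf_p": a_psii},
          tags=("photon_use", "psii"), name="PSII + b6f (linear)")
    b.rxn("PSI", {"photon_p": -1, "elow_p": -q, "ehigh_p": q, "pmf_p": b_psi},
          tags=("photon_use", "psi"), name="PSI (linear)")
    b.rxn("FNR", {"ehigh_p": -1, "nadp_p": -1, "h_p": -1, "nadph_p": 1},
          name="ferredoxin-NADP reductase")
    b.rxn("CYCLIC", {"photon_p": -1, "pmf_p": pmf_cyc},
          tags=("photon_use", "cyclic_et"), name="cyclic electron transport")
    b.rxn("ATPS_P", {"adp_p": -1, "pi_p": -1, "h_p": -1,
                     "pmf_p": -p.hplus_per_atp_chl, "atp_p": 1, "h2o_p": 1},
          name="chloroplast ATP synthase")
    b.rxn("MEHLER", {"nadph_p": -1, "h_p": -1, "o2_p": -0.5,
                     "nadp_p": 1, "h2o_p": 1},
          tags=("dissipation",), name="water-water cycle (lumped)")
    b.rxn("PMF_LEAK_P", {"pmf_p": -1}, tags=("dissipation",))
    b.rxn("ATP_DISS_P", {"atp_p": -1, "h2o_p": -1, "adp_p": 1, "pi_p": 1,
                         "h_p": 1}, tags=("dissipation",),
          name="chloroplast futile ATPase")

    # -- Calvin-Benson-Bassham cycle ---------------------------------------
    carb = {"rubp_p": -1, "co2_p": -1, "h2o_p": -1, "pga_p": 2, "h_p": 2}
    oxy = {"rubp_p": -1, "o2_p": -1, "pga_p": 1, "g2p_p": 1, "h_p": 2}
    ratio = p.vc_vo_ratio
    if ratio is not None and math.isfinite(ratio) and ratio > 0:
        # steady state of the token forces v_carb = ratio * v_oxy
        carb["vcvo_p"] = 1.0
        oxy["vcvo_p"] = -ratio
    b.rxn("RBC_CARB", carb, tags=("rubisco",), name="RuBisCO carboxylase")
    oxy_ub = 0.0 if (ratio is not None and math.isinf(ratio)) else None
    b.rxn("RBC_OXY", oxy, ub=oxy_ub, tags=("rubisco",),
          name="RuBisCO oxygenase")
    b.rxn("PGA_RED", {"pga_p": -1, "atp_p": -1, "nadph_p": -1, "h_p": -1,
                      "gap_p": 1, "adp_p": 1, "nadp_p": 1, "pi_p": 1},
          name="plastidial PGK + NADP-GAPDH")
    b.rxn("RUBP_REGEN", {"gap_p": -5, "atp_p": -3, "h2o_p": -2,
                         "rubp_p": 3, "adp_p": 3, "pi_p": 2, "h_p": 3},
          name="RuBP regeneration (lumped)")

    # -- photorespiratory loop ---------------------------------------------
    b.rxn("PGP", {"g2p_p": -1, "h2o_p": -1, "glyclt_p": 1, "pi_p": 1},
          name="phosphoglycolate phosphatase")
    b.rxn("T_GLYCLT_PC", {"glyclt_p": -1, "glyclt_c": 1}, rev=True)
    b.rxn("T_GLYCLT_CX", {"glyclt_c": -1, "glyclt_x": 1}, rev=True)
    b.rxn("GOX", {"glyclt_x": -1, "o2_x": -1, "glx_x": 1, "h2o2_x": 1},
          name="glycolate oxidase")
    b.rxn("CAT", {"h2o2_x": -2, "h2o_x": 2, "o2_x": 1}, name="catalase")
    b.rxn("GGT", {"glx_x": -1, "glu_x": -1, "gly_x": 1, "akg_x": 1},
          name="Glu:glyoxylate aminotransferase")
    b.rxn("SGAT", {"ser_x": -1, "glx_x": -1, "hpyr_x": 1, "gly_x": 1},
          name="Ser:glyoxylate aminotransferase")
    b.rxn("HPR", {"hpyr_x": -1, "nadh_x": -1, "h_x": -1,
                  "glyc_x": 1, "nad_x": 1},
          tags=("hpr",), name="hydroxypyruvate reductase")
    b.rxn("T_GLY_XM", {"gly_x": -1, "gly_m": 1}, rev=True)
    b.rxn("GDC", {"gly_m": -2, "nad_m": -1, "h2o_m": -1, "ser_m": 1,
                  "co2_m": 1, "nh4_m": 1, "nadh_m": 1},
          tags=("gdc",), name="Gly decarboxylase + SHMT")
    b.rxn("T_SER_MX", {"ser_m": -1, "ser_x": 1}, rev=True)
    b.rxn("T_GLYC_XC", {"glyc_x": -1, "glyc_c": 1}, rev=True)
    b.rxn("T_GLYC_CP", {"glyc_c": -1, "glyc_p": 1}, rev=True)
    b.rxn("GLYK", {"glyc_p": -1, "atp_p": -1, "pga_p": 1, "adp_p": 1,
                   "h_p": 1}, name="glycerate kinase")
    b.rxn("T_NH4_MC", {"nh4_m": -1, "nh4_c": 1}, rev=True)
    b.rxn("T_NH4_CP", {"nh4_c": -1, "nh4_p": 1}, rev=True)
    b.rxn("GSGOGAT", {"akg_p": -1, "nh4_p": -1, "atp_p": -1, "nadph_p": -1,
                      "glu_p": 1, "adp_p": 1, "pi_p": 1, "nadp_p": 1},
          name="GS/GOGAT (lumped)")

    # -- nitrogen assimilation ---------------------------------------------
    b.rxn("NR_NADH", {"no3_c": -1, "nadh_c": -1, "h_c": -1,
                      "no2_c": 1, "nad_c": 1, "h2o_c": 1},
          name="nitrate reductase (NADH)")
    b.rxn("NR_NADPH", {"no3_c": -1, "nadph_c": -1, "h_c": -1,
                       "no2_c": 1, "nadp_c": 1, "h2o_c": 1},
          name="nitrate reductase (NADPH)")
    b.rxn("T_NO2_CP", {"no2_c": -1, "no2_p": 1}, rev=True)
    b.rxn("NIR", {"no2_p": -1, "nadph_p": -3, "h_p": -5,
                  "nh4_p": 1, "nadp_p": 3, "h2o_p": 2},
          name="nitrite reductase (6e, lumped)")

    # -- carbohydrate metabolism -------------------------------------------
    b.rxn("STARCH_SYN", {"gap_p": -2, "atp_p": -1, "h2o_p": -2,
                         "starch_p": 1, "adp_p": 1, "pi_p": 3, "h_p": 1},
          name="starch synthesis (lumped)")
    b.rxn("STARCH_DEG", {"starch_p": -1, "pi_p": -1, "atp_p": -1,
                         "gap_p": 2, "adp_p": 1, "h_p": 1},
          name="starch degradation to triose-P (lumped)")
    b.rxn("SUC_SYN", {"gap_c": -4, "atp_c": -1, "h2o_c": -4,
                      "suc_c": 1, "adp_c": 1, "pi_c": 5, "h_c": 1},
          name="sucrose synthesis (lumped)")
    b.rxn("SUC_DEG", {"suc_c": -1, "atp_c": -4, "h2o_c": -1,
                      "gap_c": 4, "adp_c": 4, "h_c": 4},
          name="sucrose mobilisation to triose-P (lumped)")
    b.rxn("ENO", {"pga_c": -1, "pep_c": 1, "h2o_c": 1}, rev=True,
          name="PGA mutase + enolase")
    b.rxn("PK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
          tags=("shuttle_member:pep_pyruvate",), name="cytosolic pyruvate kinase")
    b.rxn("PEPC", {"pep_c": -1, "co2_c": -1, "h2o_c": -1,
                   "oaa_c": 1, "pi_c": 1, "h_c": 1}, name="PEP carboxylase")

    # -- TP-3PGA shuttle (cytosolic limbs) ----------------------------------
    b.rxn("TPT", {"gap_p": -1, "pi_c": -1, "gap_c": 1, "pi_p": 1}, rev=True,
          tags=("shuttle_member:tp3pga",), name="triose-P/Pi translocator")
    b.rxn("T_PGA_PC", {"pga_p": -1, "pi_c": -1, "pga_c": 1, "pi_p": 1},
          rev=True, tags=("shuttle_member:tp3pga",), name="3-PGA/Pi translocator")
    b.rxn("GAPDH_PHOS_C",
          {"gap_c": -1, "nad_c": -1, "adp_c": -1, "pi_c": -1,
           "pga_c": 1, "nadh_c": 1, "atp_c": 1, "h_c": 1}, rev=True,
          tags=("shuttle:tp3pga_phos",),
          name="cytosolic phosphorylating NAD-GAPDH + PGK")
    b.rxn("GAPDH_NONPHOS_C",
          {"gap_c": -1, "nadp_c": -1, "h2o_c": -1,
           "pga_c": 1, "nadph_c": 1, "h_c": 2},
          tags=("shuttle:tp3pga_nonphos",),
          name="cytosolic nonphosphorylating NADP-GAPDH")

    # -- PEP-pyruvate shuttle -----------------------------------------------
    b.rxn("PPDK", {"pyr_p": -1, "atp_p": -1, "pi_p": -1,
                   "pep_p": 1, "amp_p": 1, "ppi_p": 1, "h_p": 1},
          tags=("shuttle:pep_pyruvate",),
          name="plastidial pyruvate orthophosphate dikinase")
    b.rxn("T_PEP_PC", {"pep_p": -1, "pi_c": -1, "pep_c": 1, "pi_p": 1},
          rev=True, tags=("shuttle_member:pep_pyruvate",), name="PEP/Pi translocator")
    b.rxn("T_PYR_CP", {"pyr_c": -1, "pyr_p": 1}, rev=True,
          tags=("shuttle_member:pep_pyruvate",))
    b.rxn("PPIASE_P", {"ppi_p": -1, "h2o_p": -1, "pi_p": 2, "h_p": 1},
          name="plastidial pyrophosphatase")
    b.rxn("ADK_P", {"atp_p": -1, "amp_p": -1, "adp_p": 2}, rev=True,
          name="plastidial adenylate kinase")

    # -- malate valves (NAD(P)H shuttles) ------------------------------------
    b.rxn("MDH_P", {"oaa_p": -1, "nadph_p": -1, "h_p": -1,
                    "mal_p": 1, "nadp_p": 1}, rev=True,
          tags=("shuttle_member:chl_malate_valve",), name="plastidial NADP-MDH")
    b.rxn("MDH_C", {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1,
                    "h_c": 1}, rev=True, name="cytosolic MDH")
    b.rxn("MDH_M", {"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1,
                    "h_m": 1}, rev=True, name="mitochondrial MDH")
    b.rxn("MDH_X", {"mal_x": -1, "nad_x": -1, "oaa_x": 1, "nadh_x": 1,
                    "h_x": 1}, rev=True, name="peroxisomal MDH")
    b.rxn("T_MALOAA_PC", {"mal_p": -1, "oaa_c": -1, "mal_c": 1, "oaa_p": 1},
          rev=True, tags=("shuttle:chl_malate_valve",),
          name="chloroplast malate/OAA exchanger")
    # dicarboxylate carrier: net malate import into the matrix (vs the
    # malate/OAA exchanger, which conserves total C4 inside the organelle)
    b.rxn("DIC_MC", {"mal_c": -1, "pi_m": -1, "mal_m": 1, "pi_c": 1},
          rev=True, name="mitochondrial dicarboxylate (malate/Pi) carrier")
    b.rxn("T_MALOAA_MC", {"mal_m": -1, "oaa_c": -1, "mal_c": 1, "oaa_m": 1},
          rev=True, tags=("shuttle:mito_malate_valve",),
          name="mitochondrial malate/OAA exchanger")
    b.rxn("T_MALOAA_XC", {"mal_x": -1, "oaa_c": -1, "mal_c": 1, "oaa_x": 1},
          rev=True, tags=("shuttle:perox_malate_oaa",),
          name="peroxisomal malate/OAA exchanger")

    # -- adenylate transporters ----------------------------------------------
    b.rxn("ANT", {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1},
          tags=("shuttle:ant",), name="adenine nucleotide translocase")
    b.rxn("NTT", {"atp_c": -1, "adp_p": -1, "atp_p": 1, "adp_c": 1},
          tags=("shuttle:ntt",), name="plastidial nucleotide transporter")

    # -- mitochondrial oxidative metabolism ----------------------------------
    b.rxn("T_PYR_CM", {"pyr_c": -1, "pyr_m": 1}, rev=True)
    b.rxn("PDH", {"pyr_m": -1, "coa_m": -1, "nad_m": -1,
                  "accoa_m": 1, "co2_m": 1, "nadh_m": 1},
          name="pyruvate dehydrogenase complex")
    b.rxn("CS", {"accoa_m": -1, "oaa_m": -1, "h2o_m": -1,
                 "cit_m": 1, "coa_m": 1, "h_m": 1}, name="citrate synthase")
    b.rxn("IDH", {"cit_m": -1, "nad_m": -1, "akg_m": 1, "co2_m": 1,
                  "nadh_m": 1}, name="aconitase + NAD-isocitrate DH")
    b.rxn("AKGDH_LUMP",
          {"akg_m": -1, "nad_m": -2, "adp_m": -1, "pi_m": -1, "o2_m": -0.5,
           "oaa_m": 1, "co2_m": 1, "nadh_m": 2, "atp_m": 1, "h_m": 1,
           "pmf_m": 6.0},
          name="2-OG -> OAA (lower TCA, succinate oxidised at the quinone)")
    b.rxn("ETC_M", {"nadh_m": -1, "h_m": -1, "o2_m": -0.5,
                    "nad_m": 1, "h2o_m": 1, "pmf_m": pmf_per_nadh_m},
          tags=("metc",), name="mitochondrial ETC (coupled)")
    b.rxn("AOX", {"nadh_m": -1, "h_m": -1, "o2_m": -0.5, "nad_m": 1,
                  "h2o_m": 1}, tags=("dissipation",),
          name="alternative oxidase (uncoupled)")
    b.rxn("ATPS_M", {"adp_m": -1, "pi_m": -1, "h_m": -1,
                     "pmf_m": -p.hplus_per_atp_mito, "atp_m": 1, "h2o_m": 1},
          tags=("mito_atp_synthase",), name="mitochondrial ATP synthase")
    b.rxn("PMF_LEAK_M", {"pmf_m": -1}, tags=("dissipation",))
    b.rxn("T_CIT_MC", {"cit_m": -1, "cit_c": 1}, rev=True)

    # -- small-molecule transporters -----------------------------------------
    for species, comps in (("co2", "pm"), ("o2", "pmx"), ("h2o", "pmx"),
                           ("h", "pmx"), ("pi", "pm"), ("akg", "pmx"),
                           ("glu", "px")):
        for comp in comps:
            b.rxn(f"T_{species.upper()}_{comp.upper()}C",
                  {f"{species}_{comp}": -1, f"{species}_c": 1}, rev=True)

    # -- maintenance ----------------------------------------------------------
    b.rxn("NGAM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
          tags=("maintenance",), name="maintenance ATPase")

    model = b.model
    report = validate_balance(model)
    if not report.balanced:
        raise AssertionError(
            f"toy network is not balanced: {report.element_imbalance} "
            f"{report.charge_imbalance}")
    return model


def toy_diel_config(params: ToyLeafParams | None = None):
    """Day/night configuration matched to the toy network.

    Besides the NTT day-block, the toy blocks the mitochondrial pyruvate
    dehydrogenase complex in the light (the complex is phosphorylated and
    inactivated in illuminated leaves, which is what keeps daytime TCA-cycle
    flux low); nocturnal citrate then feeds daytime 2-oxoglutarate demand,
    the behaviour diel leaf models are known for.
    """
    from .diel import DielConfig

    p = params or ToyLeafParams()
    return DielConfig(
        storage_metabolites=[tuple(t) for t in p.storage_pools],
        blocked_in_day=["NTT", "PDH"],
        blocked_at_night=["EX_PHOTON"],
        maintenance_reaction="NGAM",
        maintenance_day=p.maintenance_atp_day,
        maintenance_night=p.maintenance_atp_night,
    )


def toy_cofactor_map() -> dict[str, dict[str, str]]:
    """Cofactor species per compartment for the energy ledgers."""
    return {
        "ATP": {"c": "atp_c", "p": "atp_p", "m": "atp_m"},
        "NADH": {"c": "nadh_c", "m": "nadh_m", "x": "nadh_x"},
        "NADPH": {"c": "nadph_c", "p": "nadph_p"},
    }


def make_fixtures(outdir: str | Path,
                  params: ToyLeafParams | None = None,
                  curve: ToyCurveParams | None = None) -> list[Path]:
    """Write the toy SBML, curve parameters and the default scenario configs.

    Deterministic: regenerated fixtures are byte-identical across runs.
    """
    from .energy import default_scenarios  # deferred: avoids an import cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or ToyLeafParams()
    written: list[Path] = []

    model = build_toy_leaf(params)
    written.append(write_model(model, outdir / "toy_leaf.xml"))

    curve = curve or ToyCurveParams()
    cpath = outdir / "light_curve.json"
    cpath.write_text(json.dumps(asdict(curve), indent=2, sort_keys=True) + "\n")
    written.append(cpath)

    sdir = outdir / "scenarios"
    sdir.mkdir(exist_ok=True)
    for scen in default_scenarios():
        spath = sdir / f"{scen.name}.json"
        spath.write_text(scen.to_json() + "\n")
        written.append(spath)
    return written
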