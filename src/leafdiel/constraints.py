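"""Light, output-composition and enzyme-capacity constraints, plus the
bench-unit -> flux conversions.

All fluxes are umol m-2 s-1.  Enzyme capacities measured per g fresh weight,
per mg protein or per mg chlorophyll are converted to that unit through leaf
geometry factors (specific leaf area, dry:fresh mass ratio, protein and
chlorophyll densities) before being applied as reaction upper bounds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .diel import DielModel
from .model_core import ConfigurationError

__all__ = [
    "LightMode",
    "LightConstraint",
    "OutputComposition",
    "OutputHandle",
    "CapacityConstraint",
    "ConversionFactors",
    "IMPLIED_CHL_PER_AREA",
    "apply_light",
    "apply_output",
    "apply_capacity",
    "convert_fw_capacity",
    "convert_protein_capacity",
    "convert_chl_capacity",
]


class LightMode(str, enum.Enum):
    EQUALITY = "equality"        # photosystems must use all available light
    UPPER_BOUND = "upper_bound"  # light is an upper bound; the LP may use less


@dataclass(frozen=True)
class LightConstraint:
    """Incident PPFD and how it couples to the photosystems.

    ``availability_fraction`` accounts for reflectance/transmission losses
    (default 0.90: the photosystems see 90% of the incident PPFD).  The loss
    is applied to the constraint's right-hand side rather than through a
    pseudo-reaction.
    """

    ppfd_incident: float
    availability_fraction: float = 0.90
    mode: LightMode = LightMode.EQUALITY

    def __post_init__(self):
        if not 0 < self.availability_fraction <= 1:
            raise ValueError("availability_fraction must be in (0, 1]")
        if self.ppfd_incident < 0:
            raise ValueError("ppfd_incident must be >= 0")

    @property
    def available(self) -> float:
        return self.availability_fraction * self.ppfd_incident


def apply_light(diel: DielModel, c: LightConstraint):
    """Couple summed day-phase photon use (PSII + PSI + cyclic) to the PPFD.

    Adds one linear coupling constraint sum(v_photon_use) {=|<=} available
    light to the LP and returns the constraint handle.
    """
    photon_rxns = diel.tagged("photon_use", phase="day")
    if not photon_rxns:
        raise ConfigurationError("model has no day-phase photon_use reactions")
    expr = sum(r.flux_expression for r in photon_rxns)
    model = diel.model
    lb = c.available if c.mode is LightMode.EQUALITY else 0.0
    cons = model.problem.Constraint(expr, lb=lb, ub=c.available,
                                    name="light_coupling")
    model.add_cons_vars(cons)
    return cons


@dataclass
class OutputComposition:
    """Metabolic output of the leaf: what it makes and in which proportions.

    ``components`` maps drain-reaction core ids to relative molar
    proportions; ``scale`` is the single degree of freedom tuned during
    CO2 matching.  kind 'source_phloem' is sugar/amino-acid export to the
    phloem; 'growing_biomass' is synthesis of biomass for leaf growth.
    """

    kind: str = "source_phloem"
    components: dict[str, float] = field(default_factory=lambda: {
        "EX_SUC_PHLOEM": 0.7, "EX_AA_PHLOEM": 0.3})
    scale: float = 1.0

    def __post_init__(self):
        if not self.components:
            raise ValueError("output composition needs at least one component")
        if any(v <= 0 for v in self.components.values()):
            raise ValueError("proportions must be strictly positive")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    @classmethod
    def growing(cls, scale: float = 1.0) -> "OutputComposition":
        return cls(kind="growing_biomass", components={"BIOMASS": 1.0},
                   scale=scale)


class OutputHandle:
    """Ratio-locked output drains driven by one scale variable.

    For every component the day and night drain copies sum to
    proportion * scale, so a single scalar controls the whole output while
    the LP remains free to split each drain between the phases.
    """

    def __init__(self, diel: DielModel, comp: OutputComposition):
        model = diel.model
        self.composition = comp
        self.scale_var = model.problem.Variable("output_scale", lb=comp.scale,
                                                ub=comp.scale)
        cons = []
        for rid, prop in comp.components.items():
            try:
                r_day, r_night = diel.day(rid), diel.night(rid)
            except KeyError as exc:
                raise ConfigurationError(
                    f"output component {rid!r} has no drain reaction") from exc
            cons.append(model.problem.Constraint(
                r_day.flux_expression + r_night.flux_expression
                - prop * self.scale_var,
                lb=0.0, ub=0.0, name=f"output_lock_{rid}"))
        model.add_cons_vars([self.scale_var] + cons)
        self.constraints = cons

    @property
    def scale(self) -> float:
        return self.scale_var.lb

    def set_scale(self, value: float) -> None:
        if value < 0:
            raise ValueError("scale must be >= 0")
        # widen-then-narrow so lb <= ub holds at every intermediate step
        self.scale_var.lb = min(self.scale_var.lb, value)
        self.scale_var.ub = value
        self.scale_var.lb = value


def apply_output(diel: DielModel, comp: OutputComposition) -> OutputHandle:
    """Fix the output drains to scale x proportion (diel sum per component)."""
    return OutputHandle(diel, comp)


@dataclass(frozen=True)
class CapacityConstraint:
    """A Vmax cap on a reaction, already in flux units (umol m-2 s-1)."""

    reaction_id: str
    vmax: float
    phase: str = "day"  # day | night | both

    def __post_init__(self):
        if self.vmax < 0:
            raise ValueError("vmax must be >= 0")
        if self.phase not in {"day", "night", "both"}:
            raise ValueError("phase must be day, night or both")


def apply_capacity(diel: DielModel, caps: list[CapacityConstraint]) -> None:
    """Tighten bounds to min(existing, vmax); reversible reactions are capped
    in absolute value in both directions.  Never relaxes an existing bound."""
    for cap in caps:
        targets = []
        if cap.phase in ("day", "both"):
            targets.append(diel.day(cap.reaction_id))
        if cap.phase in ("night", "both"):
            targets.append(diel.night(cap.reaction_id))
        for rxn in targets:
            lb, ub = rxn.bounds
            new_ub = min(ub, cap.vmax)
            new_lb = max(lb, -cap.vmax) if lb < 0 else lb
            rxn.bounds = (new_lb, new_ub)


# ---------------------------------------------------------------------------
# unit conversions

@dataclass(frozen=True)
class ConversionFactors:
    """Leaf geometry factors for converting bench activities to area fluxes.

    ``area_per_g_fw`` is the leaf area corresponding to one gram fresh
    weight.  The published conversion chain rounds its intermediates
    (1 g DW = 11.4 g FW, 1 g FW = 0.0043 m2), so the factor is carried
    explicitly with that value as default; pass ``area_per_g_fw=None`` to
    recompute it as sla * 1e-3 * dw_fw (= 0.0044 m2/gFW with the defaults).
    """

    sla: float = 50.0            # specific leaf area, m2 per kg dry weight
    dw_fw: float = 0.088         # dry:fresh mass ratio
    protein_per_fw: float = 5.7  # mg protein per g fresh weight
    area_per_g_fw: float | None = 0.0043  # m2 per g fresh weight

    def __post_init__(self):
        if self.sla <= 0 or self.dw_fw <= 0 or self.protein_per_fw <= 0:
            raise ValueError("conversion factors must be strictly positive")
        if self.area_per_g_fw is not None and self.area_per_g_fw <= 0:
            raise ValueError("area_per_g_fw must be strictly positive")

    @property
    def effective_area_per_g_fw(self) -> float:
        if self.area_per_g_fw is not None:
            return self.area_per_g_fw
        return self.sla * 1e-3 * self.dw_fw


#: Chlorophyll density (mg chlorophyll m-2) implied by the published pair
#: 0.9 umol mg-1 chl h-1 -> 0.034 umol m-2 s-1 (0.9 * 136 / 3600 = 0.034).
#: The source does not print its density; this is the back-computed value,
#: documented as implied rather than asserted.
IMPLIED_CHL_PER_AREA = 136.0


def convert_fw_capacity(v: float, f: ConversionFactors | None = None) -> float:
    """nmol min-1 g-1 fresh weight  ->  umol m-2 s-1."""
    if v < 0:
        raise ValueError("activity must be >= 0")
    f = f or ConversionFactors()
    # v / (m2 per gFW) -> nmol min-1 m-2; /60 -> per s; /1000 -> umol
    return v / f.effective_area_per_g_fw / 60.0 / 1000.0


def convert_protein_capacity(v: float, f: ConversionFactors | None = None) -> float:
    """nmol min-1 mg-1 protein  ->  umol m-2 s-1."""
    if v < 0:
        raise ValueError("activity must be >= 0")
    f = f or ConversionFactors()
    return convert_fw_capacity(v * f.protein_per_fw, f)


def convert_chl_capacity(v: float, chl_per_area: float | None) -> float:
    """umol mg-1 chlorophyll h-1  ->  umol m-2 s-1.

    ``chl_per_area`` (mg chlorophyll m-2) has no silent default: pass a
    measured value or the documented :data:`IMPLIED_CHL_PER_AREA`.
    """
    if v < 0:
        raise ValueError("activity must be >= 0")
    if chl_per_area is None:
        raise ConfigurationError(
            "chl_per_area is required (no silent default); "
            "IMPLIED_CHL_PER_AREA is the documented implied value")
    if chl_per_area <= 0 or not math.isfinite(chl_per_area):
        raise ValueError("chl_per_area must be positive and finite")
    return v * chl_per_area / 3600.0
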