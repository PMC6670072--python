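"""Two-phase (day/night) model construction with storage linker reactions.

A diel model is a day copy and a night copy of a core network, sharing no
metabolites, coupled exclusively through storage linkers: for every storage
pool X there is an irreversible day->night accumulation route and an
irreversible night->day route, so flux stored in one phase is released in the
other and FVA ranges are reported per direction.  Phase-specific blocks
(photon influx at night; the plastidial ATP importer NTT — and, for the toy
leaf, the pyruvate dehydrogenase complex — during the day) and per-phase
maintenance ATP hydrolysis complete the construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import cobra
import pandas as pd

from .model_core import (
    ConfigurationError,
    add_tags,
    find_by_tag,
    get_phase,
    set_phase,
)

__all__ = ["DielConfig", "DielModel", "build_diel", "map_flux_to_core"]


@dataclass
class DielConfig:
    """Configuration of the day/night split.

    ``storage_metabolites`` lists (core metabolite id, storage compartment)
    pairs; the compartment is bookkeeping (it names where the pool physically
    sits, e.g. starch in the chloroplast, sugars and organic acids in the
    vacuole) and is recorded as a tag on the linker reactions.
    ``day_night_scale`` scales stored amounts between phases (1 = the phases
    are stoichiometrically equivalent; day:night length is not modelled).
    """

    storage_metabolites: list[tuple[str, str]] = field(default_factory=lambda: [
        ("starch_p", "chloroplast"),
        ("suc_c", "vacuole"),
        ("mal_c", "vacuole"),
        ("cit_c", "vacuole"),
        ("glu_c", "vacuole"),
        ("no3_c", "vacuole"),
    ])
    day_suffix: str = "_day"
    night_suffix: str = "_night"
    blocked_in_day: list[str] = field(default_factory=lambda: ["NTT"])
    blocked_at_night: list[str] = field(default_factory=lambda: ["EX_PHOTON"])
    maintenance_reaction: str = "NGAM"
    maintenance_day: float = 4.0
    maintenance_night: float = 4.0
    day_night_scale: float = 1.0

    def __post_init__(self):
        if not self.day_suffix or not self.night_suffix:
            raise ValueError("phase suffixes must be non-empty")
        if self.day_suffix == self.night_suffix:
            raise ValueError("phase suffixes must be distinct")
        if self.day_night_scale <= 0:
            raise ValueError("day_night_scale must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "DielConfig":
        data = json.loads(Path(path).read_text())
        data["storage_metabolites"] = [tuple(x) for x in
                                       data.get("storage_metabolites", [])]
        return cls(**data)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


@dataclass
class DielModel:
    """A two-phase cobra model plus provenance back to the core network."""

    model: cobra.Model
    config: DielConfig
    #: core reaction id -> (day copy id, night copy id)
    provenance: dict[str, tuple[str, str]]
    linker_ids: list[str] = field(default_factory=list)

    @property
    def day_suffix(self) -> str:
        return self.config.day_suffix

    @property
    def night_suffix(self) -> str:
        return self.config.night_suffix

    def day(self, core_id: str) -> cobra.Reaction:
        return self.model.reactions.get_by_id(core_id + self.day_suffix)

    def night(self, core_id: str) -> cobra.Reaction:
        return self.model.reactions.get_by_id(core_id + self.night_suffix)

    def phase_reactions(self, phase: str) -> list[cobra.Reaction]:
        return [r for r in self.model.reactions if get_phase(r) == phase]

    def tagged(self, tag: str, phase: str | None = None) -> list[cobra.Reaction]:
        rxns = find_by_tag(self.model, tag)
        if phase is not None:
            rxns = [r for r in rxns if get_phase(r) == phase]
        return rxns

    def provenance_to_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            [(cid, d, n) for cid, (d, n) in self.provenance.items()],
            columns=["core_reaction", "day_reaction", "night_reaction"])
        df.to_csv(path, sep="\t", index=False)
        return Path(path)


def _copy_phase(core: cobra.Model, suffix: str, phase: str) -> cobra.Model:
    m = core.copy()
    for met in m.metabolites:
        met.id = met.id + suffix
    for rxn in m.reactions:
        rxn.id = rxn.id + suffix
        set_phase(rxn, phase)
    m.repair()
    return m


def build_diel(core: cobra.Model, config: DielConfig | None = None) -> DielModel:
    """Duplicate a core model into coupled day and night phases.

    Every core reaction appears once per phase with bounds copied; each
    storage pool gets one day->night and one night->day irreversible linker;
    reactions listed in ``blocked_in_day``/``blocked_at_night`` have the
    corresponding copy clamped to zero; the maintenance reaction is fixed at
    the configured flux in each phase.
    """
    config = config or DielConfig()

    for rid in (config.blocked_in_day + config.blocked_at_night +
                [config.maintenance_reaction]):
        if rid not in core.reactions:
            raise ConfigurationError(f"reaction {rid!r} not in core model")
    for mid, _comp in config.storage_metabolites:
        if mid not in core.metabolites:
            raise ConfigurationError(f"storage metabolite {mid!r} not in core model")
    for suffix in (config.day_suffix, config.night_suffix):
        for rxn in core.reactions:
            if rxn.id + suffix in core.reactions:
                raise ConfigurationError(
                    f"suffix {suffix!r} collides with existing id "
                    f"{rxn.id + suffix!r}")

    day = _copy_phase(core, config.day_suffix, "day")
    night = _copy_phase(core, config.night_suffix, "night")

    diel = cobra.Model(core.id + "_diel")
    diel.compartments = dict(core.compartments)
    diel.add_reactions(list(day.reactions))
    diel.add_reactions(list(night.reactions))

    provenance = {r.id: (r.id + config.day_suffix, r.id + config.night_suffix)
                  for r in core.reactions}

    # storage linkers: stored day amount s appears as s*scale at night and
    # vice versa (scale 1 = stoichiometric equivalence of the phases)
    linker_ids: list[str] = []
    s = config.day_night_scale
    for mid, comp in config.storage_metabolites:
        met_d = diel.metabolites.get_by_id(mid + config.day_suffix)
        met_n = diel.metabolites.get_by_id(mid + config.night_suffix)
        for rid, src, dst, coef in (
                (f"LINK_{mid}_day_to_night", met_d, met_n, s),
                (f"LINK_{mid}_night_to_day", met_n, met_d, 1.0 / s)):
            r = cobra.Reaction(rid, lower_bound=0.0, upper_bound=1e6)
            r.add_metabolites({src: -1.0, dst: coef})
            set_phase(r, "linker")
            add_tags(r, "linker", f"storage:{comp}", f"pool:{mid}")
            diel.add_reactions([r])
            linker_ids.append(rid)

    for rid in config.blocked_in_day:
        diel.reactions.get_by_id(rid + config.day_suffix).bounds = (0.0, 0.0)
    for rid in config.blocked_at_night:
        diel.reactions.get_by_id(rid + config.night_suffix).bounds = (0.0, 0.0)

    for suffix, value in ((config.day_suffix, config.maintenance_day),
                          (config.night_suffix, config.maintenance_night)):
        diel.reactions.get_by_id(
            config.maintenance_reaction + suffix).bounds = (value, value)

    return DielModel(model=diel, config=config, provenance=provenance,
                     linker_ids=linker_ids)


def map_flux_to_core(diel: DielModel, fluxes: pd.Series
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Project a diel flux vector back onto core reaction ids.

    Returns a (core id x {day, night}) table and a series of linker fluxes.
    Raises :class:`ConfigurationError` when the flux vector does not cover the
    diel model (e.g. a solution from a different model).
    """
    missing = [rid for pair in diel.provenance.values() for rid in pair
               if rid not in fluxes.index]
    missing += [rid for rid in diel.linker_ids if rid not in fluxes.index]
    if missing:
        raise ConfigurationError(
            f"flux vector does not cover the diel model; missing e.g. "
            f"{missing[:5]}")
    table = pd.DataFrame(
        {"day": {cid: fluxes[d] for cid, (d, n) in diel.provenance.items()},
         "night": {cid: fluxes[n] for cid, (d, n) in diel.provenance.items()}})
    table.index.name = "core_reaction"
    linkers = fluxes[diel.linker_ids].copy()
    return table, linkers
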