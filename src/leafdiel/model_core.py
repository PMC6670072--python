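"""Stoichiometric model representation, SBML I/O and structural validation.

The in-memory substrate is a :class:`cobra.Model`.  On top of cobrapy this
module fixes a compartment vocabulary (the seven subcellular localisations a
compartmented leaf model distinguishes), a tagging convention for reactions
(``photon_use``, ``shuttle:*``, ``boundary``, ``linker``, ...) carried in SBML
notes so it survives a round trip to disk, and an elemental/charge balance
checker that reports every violation instead of stopping at the first.

Flux unit is fixed at umol m-2 s-1 everywhere inside the package; unit
conversions happen at the boundary (see :mod:`leafdiel.constraints`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd
from cobra.util.array import create_stoichiometric_matrix

__all__ = [
    "Compartment",
    "COMPARTMENT_ALIASES",
    "FormatError",
    "ConfigurationError",
    "ValidationError",
    "BalanceReport",
    "read_model",
    "write_model",
    "validate_balance",
    "get_tags",
    "add_tags",
    "get_phase",
    "set_phase",
    "set_massless",
    "is_massless",
    "find_by_tag",
    "stoichiometric_matrix",
]


class Compartment(str, enum.Enum):
    """Subcellular localisations recognised by the package."""

    CYTOSOL = "c"
    CHLOROPLAST = "p"
    MITOCHONDRION = "m"
    PEROXISOME = "x"
    VACUOLE = "v"
    APOPLAST = "a"
    ENVIRONMENT = "e"


#: Default mapping from SBML compartment ids to the fixed vocabulary.  The
#: table is user-editable: pass an extended copy to :func:`read_model` when a
#: model uses other ids.
COMPARTMENT_ALIASES: dict[str, Compartment] = {
    **{c.value: c for c in Compartment},
    "cytosol": Compartment.CYTOSOL,
    "cytoplasm": Compartment.CYTOSOL,
    "chloroplast": Compartment.CHLOROPLAST,
    "plastid": Compartment.CHLOROPLAST,
    "mitochondrion": Compartment.MITOCHONDRION,
    "mitochondria": Compartment.MITOCHONDRION,
    "peroxisome": Compartment.PEROXISOME,
    "vacuole": Compartment.VACUOLE,
    "apoplast": Compartment.APOPLAST,
    "environment": Compartment.ENVIRONMENT,
    "extracellular": Compartment.ENVIRONMENT,
}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as a model."""


class ConfigurationError(ValueError):
    """Raised when a model or config references something that does not exist."""


class ValidationError(ValueError):
    """Raised when a structural validation cannot even be attempted."""


# ---------------------------------------------------------------------------
# tags / phase / massless metadata (stored in cobra notes -> SBML notes)

def get_tags(obj) -> set[str]:
    raw = obj.notes.get("tags", "")
    return {t for t in str(raw).split(";") if t}


def add_tags(obj, *tags: str) -> None:
    obj.notes["tags"] = ";".join(sorted(get_tags(obj) | set(tags)))


def get_phase(rxn) -> str | None:
    return rxn.notes.get("phase") or None


def set_phase(rxn, phase: str) -> None:
    if phase not in {"day", "night", "linker"}:
        raise ValueError(f"unknown phase {phase!r}")
    rxn.notes["phase"] = phase


def set_massless(met) -> None:
    """Mark a pseudo-species (photon, pmf quantum, electron token) as massless.

    Massless species contribute no elements to balance checks (their charge,
    if any, still counts) and are exempt from the missing-formula error.
    """
    met.notes["massless"] = "true"


def is_massless(met) -> bool:
    return str(met.notes.get("massless", "")).lower() == "true"


def find_by_tag(model: cobra.Model, tag: str) -> list[cobra.Reaction]:
    return [r for r in model.reactions if tag in get_tags(r)]


# ---------------------------------------------------------------------------
# I/O

def _check_compartments(model: cobra.Model, aliases: Mapping[str, Compartment]) -> None:
    """Map every compartment id onto the fixed vocabulary, normalising in place."""
    mapping: dict[str, str] = {}
    for cid in set(m.compartment for m in model.metabolites):
        key = (cid or "").lower()
        if key not in aliases:
            raise ConfigurationError(
                f"compartment id {cid!r} is not in the compartment mapping table; "
                f"known ids: {sorted(aliases)}"
            )
        mapping[cid] = aliases[key].value
    for met in model.metabolites:
        met.compartment = mapping[met.compartment]
    model.compartments = {c.value: c.name.lower() for c in Compartment}


def read_model(path: str | Path,
               aliases: Mapping[str, Compartment] = COMPARTMENT_ALIASES) -> cobra.Model:
    """Read an SBML model and normalise compartments to the fixed vocabulary.

    Raises :class:`FormatError` on parse failure (naming the offending file)
    and :class:`ConfigurationError` for compartments that cannot be mapped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such model file: {path}")
    try:
        model = cobra.io.read_sbml_model(str(path))
    except ConfigurationError:
        raise
    except Exception as exc:  # libsbml raises a zoo of error types
        raise FormatError(f"could not parse SBML from {path}: {exc}") from exc
    _check_compartments(model, aliases)
    return model


def write_model(model: cobra.Model, path: str | Path) -> Path:
    """Write a model to SBML Level 3 (+fbc).  Tags/phase ride in notes."""
    path = Path(path)
    try:
        cobra.io.write_sbml_model(model, str(path))
    except OSError as exc:
        raise OSError(f"cannot write SBML to {path}: {exc}") from exc
    return path


def stoichiometric_matrix(model: cobra.Model):
    """Dense S (n_metabolites x n_reactions), rows/cols in model order."""
    return create_stoichiometric_matrix(model, array_type="dense")


# ---------------------------------------------------------------------------
# balance checking

@dataclass
class BalanceReport:
    """Outcome of an elemental/charge balance sweep over a model.

    ``element_imbalance`` maps reaction id -> {element: net coefficient} for
    reactions with a nonzero elemental residual; ``charge_imbalance`` maps
    reaction id -> net charge residual; ``exempt`` lists reactions that were
    skipped (boundary/linker/otherwise tagged).
    """

    element_imbalance: dict[str, dict[str, float]] = field(default_factory=dict)
    charge_imbalance: dict[str, float] = field(default_factory=dict)
    exempt: list[str] = field(default_factory=list)
    checked: list[str] = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        return not self.element_imbalance and not self.charge_imbalance

    def is_balanced(self, reaction_id: str) -> bool:
        return (reaction_id not in self.element_imbalance
                and reaction_id not in self.charge_imbalance)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid in self.checked:
            rows.append({
                "reaction": rid,
                "balanced": self.is_balanced(rid),
                "element_imbalance": ";".join(
                    f"{e}:{v:g}" for e, v in
                    sorted(self.element_imbalance.get(rid, {}).items())),
                "charge_imbalance": self.charge_imbalance.get(rid, 0.0),
            })
        for rid in self.exempt:
            rows.append({"reaction": rid, "balanced": True,
                         "element_imbalance": "exempt", "charge_imbalance": 0.0})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


_TOL = 1e-9


def validate_balance(model: cobra.Model,
                     exempt: Iterable[str] = ("boundary", "linker", "photon_use",
                                              "photon_influx", "maintenance")) -> BalanceReport:
    """Check every non-exempt reaction for elemental and charge balance.

    A reaction is exempt when it is a cobra boundary reaction or carries one
    of the ``exempt`` tags.  A checked reaction containing a metabolite with
    no formula (and not flagged massless) raises :class:`ValidationError`
    naming the metabolite.
    """
    exempt = set(exempt)
    report = BalanceReport()
    for rxn in model.reactions:
        if rxn.boundary or (get_tags(rxn) & exempt):
            report.exempt.append(rxn.id)
            continue
        report.checked.append(rxn.id)
        elems: dict[str, float] = {}
        charge = 0.0
        for met, coef in rxn.metabolites.items():
            if is_massless(met):
                pass  # contributes no elements
            elif met.formula is None:
                raise ValidationError(
                    f"metabolite {met.id} in reaction {rxn.id} has no formula")
            else:
                for el, n in met.elements.items():
                    elems[el] = elems.get(el, 0.0) + coef * n
            charge += coef * (met.charge or 0)
        bad = {el: v for el, v in elems.items() if abs(v) > _TOL}
        if bad:
            report.element_imbalance[rxn.id] = bad
        if abs(charge) > _TOL:
            report.charge_imbalance[rxn.id] = charge
    return report
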