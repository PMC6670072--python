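"""LP solving: parsimonious FBA, flux variability analysis, light-use
minimization and the output-scaling search that matches net CO2 uptake to a
light-response curve.

pFBA minimizes the sum of absolute fluxes subject to all constraints; it is
formulated on the solver's split variables (each reaction is a forward and a
reverse non-negative variable, so sum(forward + reverse) is the total flux).
Alternative optima are not broken by tie rules: FVA ranges, with the
reliability rule that a flux is trusted only when its range is below 10% of
its value, are the published interface for ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import cobra
import numpy as np
import pandas as pd

from .diel import DielModel
from .model_core import get_phase, get_tags

__all__ = [
    "FluxSolution",
    "FVAResult",
    "MatchResult",
    "BracketError",
    "pfba",
    "fva",
    "minimize_light",
    "match_assimilation",
    "steady_state_residual",
    "RELIABILITY_FRACTION",
    "ZERO_FLUX_EPS",
]

#: FVA range below this fraction of the reference flux marks it reliable.
RELIABILITY_FRACTION = 0.10
#: Absolute epsilon standing in for the 10% rule at reference flux ~ 0.
ZERO_FLUX_EPS = 1e-6

_FEASIBILITY_TOL = 1e-9
_LOCK_SLACK = 1e-9


@dataclass
class FluxSolution:
    status: str                      # optimal | infeasible | unbounded | ...
    objective_value: float
    fluxes: pd.Series | None
    objective_kind: str = "min_total_flux"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        if self.fluxes is None:
            raise ValueError(f"no fluxes: solver status {self.status}")
        return float(self.fluxes[reaction_id])


@dataclass
class FVAResult:
    """Per-reaction flux ranges under a locked total-flux optimum."""

    frame: pd.DataFrame  # columns: minimum, maximum, reference, reliable

    def range(self, reaction_id: str) -> tuple[float, float]:
        row = self.frame.loc[reaction_id]
        return float(row["minimum"]), float(row["maximum"])

    def reliable(self, reaction_id: str) -> bool:
        return bool(self.frame.loc[reaction_id, "reliable"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


@dataclass
class MatchResult:
    scale: float
    achieved_assimilation: float
    target_assimilation: float
    iterations: int
    solution: FluxSolution


class BracketError(RuntimeError):
    """Target assimilation unreachable within the scale bounds."""

    def __init__(self, message: str, max_achievable: float | None = None):
        super().__init__(message)
        self.max_achievable = max_achievable


def _as_model(m: cobra.Model | DielModel) -> cobra.Model:
    return m.model if isinstance(m, DielModel) else m


def _configure_tolerance(model: cobra.Model) -> None:
    try:
        model.tolerance = _FEASIBILITY_TOL
    except Exception:
        pass  # backend does not expose a feasibility knob


def _total_flux_expression(model: cobra.Model, include_linkers: bool = True):
    terms = []
    for r in model.reactions:
        if not include_linkers and "linker" in get_tags(r):
            continue
        terms.append(r.forward_variable + r.reverse_variable)
    return sum(terms)


def _solve(model: cobra.Model, kind: str) -> FluxSolution:
    sol = model.optimize(raise_error=False)
    if sol.status != "optimal":
        return FluxSolution(status=sol.status, objective_value=float("nan"),
                            fluxes=None, objective_kind=kind)
    return FluxSolution(status="optimal",
                        objective_value=float(sol.objective_value),
                        fluxes=sol.fluxes, objective_kind=kind)


def pfba(model: cobra.Model | DielModel, *,
         include_linkers: bool = True) -> FluxSolution:
    """Minimize sum(|v|) over all reactions subject to all constraints.

    The objective "all fluxes" includes the storage linker pseudo-fluxes by
    default; set ``include_linkers=False`` to restrict it to chemistry.
    """
    model = _as_model(model)
    _configure_tolerance(model)
    with model:
        model.objective = model.problem.Objective(
            _total_flux_expression(model, include_linkers), direction="min")
        return _solve(model, "min_total_flux")


def fva(model: cobra.Model | DielModel,
        reactions: Iterable[str] | None = None,
        lock_objective_fraction: float = 1.0,
        reference: FluxSolution | None = None, *,
        include_linkers: bool = True) -> FVAResult:
    """Per-reaction min/max flux with total flux locked near its optimum.

    The pFBA optimum T is recomputed (or taken from ``reference``) and the
    constraint sum(|v|) <= T * lock_objective_fraction is imposed; each listed
    reaction is then minimized and maximized.  The reliability flag applies
    the <10%-of-flux rule against the pFBA reference flux (absolute epsilon
    at reference ~ 0, where a relative rule is undefined).
    """
    model = _as_model(model)
    _configure_tolerance(model)
    if reference is None or reference.objective_kind != "min_total_flux":
        reference = pfba(model, include_linkers=include_linkers)
    if not reference.optimal:
        raise RuntimeError(f"pFBA reference not optimal: {reference.status}")

    rids = list(reactions) if reactions is not None else \
        [r.id for r in model.reactions]
    rows = []
    with model:
        expr = _total_flux_expression(model, include_linkers)
        lock = model.problem.Constraint(
            expr, ub=reference.objective_value * lock_objective_fraction
            + _LOCK_SLACK, name="pfba_lock")
        model.add_cons_vars(lock)
        for rid in rids:
            rxn = model.reactions.get_by_id(rid)
            bounds = []
            for direction in ("min", "max"):
                model.objective = model.problem.Objective(
                    rxn.flux_expression, direction=direction)
                sol = model.optimize(raise_error=False)
                if sol.status != "optimal":
                    raise RuntimeError(
                        f"FVA {direction} failed for {rid}: {sol.status}")
                bounds.append(float(sol.objective_value))
            vmin, vmax = bounds
            ref = reference.flux(rid)
            width = vmax - vmin
            if abs(ref) > ZERO_FLUX_EPS:
                reliable = width < RELIABILITY_FRACTION * abs(ref)
            else:
                reliable = width < ZERO_FLUX_EPS
            rows.append((rid, vmin, vmax, ref, reliable))
    frame = pd.DataFrame(rows, columns=["reaction", "minimum", "maximum",
                                        "reference", "reliable"])
    frame = frame.set_index("reaction")
    return FVAResult(frame=frame)


def minimize_light(diel: DielModel) -> FluxSolution:
    """Minimize summed day-phase photon use (the NPQ-mimicking objective).

    Meaningful when the light constraint is in upper-bound mode and the
    output/assimilation constraints are fixed.
    """
    model = diel.model
    _configure_tolerance(model)
    photon_rxns = diel.tagged("photon_use", phase="day")
    with model:
        model.objective = model.problem.Objective(
            sum(r.flux_expression for r in photon_rxns), direction="min")
        return _solve(model, "min_photon_use")


def day_net_co2_uptake(diel: DielModel, solution: FluxSolution,
                       tag: str = "co2_exchange") -> float:
    """Net CO2 uptake of the day phase (influx minus effluxes), the quantity
    gas exchange measures."""
    rxns = diel.tagged(tag, phase="day")
    if not rxns:
        raise KeyError("no day-phase co2_exchange reactions")
    return sum(solution.flux(r.id) for r in rxns)


def match_assimilation(diel: DielModel, output,  # OutputHandle
                       curve: Callable[[float], float], ppfd: float,
                       tol: float = 1e-4,
                       scale_bounds: tuple[float, float] = (0.0, 1e3),
                       max_iterations: int = 60) -> MatchResult:
    """Bisect the output scale until net day CO2 uptake matches curve(ppfd).

    Assumes (and spot-checks at the bracket points) that assimilation is
    monotone non-decreasing in the output scale.  Raises
    :class:`BracketError`, reporting the maximum achievable assimilation,
    when the target lies above what the light supply allows.
    """
    target = float(curve(ppfd))
    lo, hi_limit = scale_bounds
    if lo < 0 or hi_limit <= lo:
        raise ValueError("invalid scale_bounds")

    evaluations = 0

    def assim(scale: float) -> tuple[float, FluxSolution] | None:
        nonlocal evaluations
        evaluations += 1
        output.set_scale(scale)
        sol = pfba(diel)
        if not sol.optimal:
            return None
        return day_net_co2_uptake(diel, sol), sol

    low = assim(lo)
    if low is None:
        raise BracketError(f"model infeasible at minimum scale {lo}")
    a_lo, sol_lo = low
    if abs(a_lo - target) <= tol:
        return MatchResult(lo, a_lo, target, evaluations, sol_lo)
    if a_lo > target:
        raise BracketError(
            f"assimilation at minimum scale ({a_lo:.4g}) already exceeds the "
            f"target ({target:.4g})", max_achievable=a_lo)

    # expand the bracket geometrically until the target is enclosed
    hi = max(lo * 2, 1.0)
    a_hi, sol_hi = a_lo, sol_lo
    best_feasible = (lo, a_lo)
    while True:
        hi = min(hi, hi_limit)
        res = assim(hi)
        if res is None:
            hi_limit = hi  # infeasible: light-limited above this scale
            hi = (best_feasible[0] + hi) / 2.0
            if hi - best_feasible[0] < 1e-9:
                raise BracketError(
                    f"target assimilation {target:.4g} unreachable; maximum "
                    f"achievable ~ {best_feasible[1]:.4g}",
                    max_achievable=best_feasible[1])
            continue
        a_hi, sol_hi = res
        if a_hi < best_feasible[1] - 1e-7:
            raise BracketError(
                "assimilation is not monotone in the output scale")
        best_feasible = (hi, a_hi)
        if a_hi >= target - tol:
            break
        if hi >= hi_limit:
            raise BracketError(
                f"target assimilation {target:.4g} unreachable at max scale "
                f"{hi_limit}; maximum achievable {a_hi:.4g}",
                max_achievable=a_hi)
        hi *= 2.0
    if abs(a_hi - target) <= tol:
        return MatchResult(hi, a_hi, target, evaluations, sol_hi)

    s_lo, s_hi = best_feasible[0] if a_hi >= target else lo, hi
    s_lo = lo if s_lo >= s_hi else s_lo
    a, sol, scale = a_hi, sol_hi, hi
    for _ in range(max_iterations):
        scale = 0.5 * (s_lo + s_hi)
        res = assim(scale)
        if res is None:
            s_hi = scale
            continue
        a, sol = res
        if abs(a - target) <= tol:
            break
        if a < target:
            s_lo = scale
        else:
            s_hi = scale
    else:
        raise BracketError(
            f"bisection did not converge in {max_iterations} iterations "
            f"(|{a:.6g} - {target:.6g}| > {tol})")
    output.set_scale(scale)
    return MatchResult(scale, a, target, evaluations, sol)


def steady_state_residual(model: cobra.Model | DielModel,
                          solution: FluxSolution) -> float:
    """max |S v| over metabolites — 0 at steady state."""
    model = _as_model(model)
    S = cobra.util.array.create_stoichiometric_matrix(model)
    v = solution.fluxes[[r.id for r in model.reactions]].to_numpy()
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0
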