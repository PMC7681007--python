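"""Competitive antibody-binding isotherm for the immunoprecipitation step.

The IP is modeled as an equilibrium competitive binding reaction between
one antibody(-bead) pool and several epitope species. Each species ``i``
has a total concentration ``S_i_t`` (uM) and a macroscopic binding
constant ``K_B,i`` (1/uM) that absorbs the unknown polyvalent complexity
of the chromatin--antibody-bead interaction. With 1:1 stoichiometry and
mass conservation, the bound concentration of species ``i`` is the
sigmoid

    S_i_b = S_i_t * y / (1 + y),   y = AB_f * K_B,i

where the free-antibody concentration ``AB_f`` is the unique root of

    g(a) = a + sum_i S_i_t * a*K_i / (1 + a*K_i) - AB_t = 0

on the bracket [0, AB_t]. ``g`` is strictly increasing, so the root is
found by bisection, which is guaranteed to converge.

Two distinct readouts matter downstream and must never be conflated:

* **capture efficiency** of a species, 100 * bound/total -- the quantity
  a spike-in calibrant reports about itself;
* **fractional composition**, 100 * bound_i / sum_j bound_j -- the share
  of sequenced fragments each species contributes, which spike-ins cannot
  report.

Depletion scans sweep the target total concentration downward under a
fixed-total-chromatin constraint, either by growing an inert pool
(case 1) or by converting target into an off-target species (case 2),
and expose the characteristic failure mode of spike-in normalization:
capture efficiencies of *all* binding species rise as target is depleted,
while the composition of the captured material shifts toward off-target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Species",
    "Reaction",
    "IsothermSolution",
    "DepletionScan",
    "SolverError",
    "ScenarioError",
    "solve_binding",
    "composition",
    "capture_efficiency",
    "selectivity",
    "depletion_scan",
    "predict_efficiency",
]


class SolverError(RuntimeError):
    """Root finding failed to converge (should be impossible: g is monotone)."""


class ScenarioError(ValueError):
    """A depletion-scan grid point implies an infeasible concentration."""


@dataclass(frozen=True)
class Species:
    """One epitope species: total concentration (uM) and binding constant (1/uM).

    ``binding_constant == 0`` encodes an inert species (never binds
    antibody). ``spike`` marks an exogenous calibrant nucleosome: it
    participates in the binding competition but is excluded from the
    chromatin composition readout and reported separately.
    """

    name: str
    total: float
    binding_constant: float
    spike: bool = False

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError(f"{self.name}: total concentration must be >= 0")
        if self.binding_constant < 0:
            raise ValueError(f"{self.name}: binding constant must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """An IP reaction: antibody load plus an ordered list of species."""

    antibody_total: float
    species: tuple

    def __init__(self, antibody_total: float, species: Iterable[Species]):
        if antibody_total < 0:
            raise ValueError("antibody_total must be >= 0")
        object.__setattr__(self, "antibody_total", float(antibody_total))
        object.__setattr__(self, "species", tuple(species))
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species names: {names}")

    def get(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"no species named {name!r}")

    def replace_total(self, name: str, total: float) -> "Reaction":
        new = [Species(s.name, total, s.binding_constant, s.spike)
               if s.name == name else s for s in self.species]
        return Reaction(self.antibody_total, new)


@dataclass
class IsothermSolution:
    """Equilibrium state: free antibody plus per-species bound/free split."""

    reaction: Reaction
    free_antibody: float
    bound: np.ndarray  # per-species bound concentration, reaction order
    residual: float    # antibody-conservation defect

    @property
    def free(self) -> np.ndarray:
        totals = np.array([s.total for s in self.reaction.species])
        return totals - self.bound

    def bound_of(self, name: str) -> float:
        for s, b in zip(self.reaction.species, self.bound):
            if s.name == name:
                return float(b)
        raise KeyError(f"no species named {name!r}")


def _excess_antibody(a: float, totals: np.ndarray, ks: np.ndarray,
                     ab_total: float) -> float:
    y = a * ks
    return a + float(np.sum(totals * y / (1.0 + y))) - ab_total


def solve_binding(reaction: Reaction, tolerance: float = 1e-12,
                  max_iter: int = 200) -> IsothermSolution:
    """Solve the mass-conservation laws for the free-antibody concentration.

    Bisection on [0, AB_t] with relative bracket tolerance ``tolerance``;
    robust by construction since g is strictly increasing and changes sign
    on the bracket.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    totals = np.array([s.total for s in reaction.species], dtype=float)
    ks = np.array([s.binding_constant for s in reaction.species], dtype=float)
    ab_total = reaction.antibody_total

    if ab_total == 0 or not np.any(totals * ks > 0):
        # no antibody, or nothing that can bind: trivially free
        a = ab_total
        bound = np.zeros_like(totals)
        return IsothermSolution(reaction, a, bound, 0.0)

    lo, hi = 0.0, ab_total
    # g(0) = -AB_t < 0, g(AB_t) = sum bound >= 0: bracket guaranteed
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _excess_antibody(mid, totals, ks, ab_total) > 0.0:
            hi = mid
        else:
            lo = mid
        if (hi - lo) <= tolerance * ab_total:
            break
    else:
        raise SolverError(
            f"bisection did not converge: bracket [{lo}, {hi}] after "
            f"{max_iter} iterations")

    a = 0.5 * (lo + hi)
    # Newton polish: g is smooth and strictly increasing, so a couple of
    # clipped steps drive the conservation defect to machine precision.
    for _ in range(5):
        g = _excess_antibody(a, totals, ks, ab_total)
        if abs(g) <= 1e-14 * max(ab_total, 1.0):
            break
        dg = 1.0 + float(np.sum(totals * ks / (1.0 + a * ks) ** 2))
        a = min(max(a - g / dg, lo), hi)
    y = a * ks
    bound = totals * y / (1.0 + y)
    residual = abs(a + float(bound.sum()) - ab_total)
    return IsothermSolution(reaction, a, bound, residual)


def composition(solution: IsothermSolution) -> dict:
    """Percent of captured (sequenced) fragments contributed by each species.

    Spike-in species never enter the chromatin composition. The
    percentages sum to 100 exactly: the last species is computed by
    complement.
    """
    names, bounds = [], []
    for s, b in zip(solution.reaction.species, solution.bound):
        if not s.spike:
            names.append(s.name)
            bounds.append(float(b))
    total = sum(bounds)
    if total <= 0:
        raise ValueError("composition undefined: no chromatin species bound")
    pct = {name: 100.0 * b / total for name, b in zip(names[:-1], bounds[:-1])}
    pct[names[-1]] = 100.0 - sum(pct.values())
    return pct


def capture_efficiency(solution: IsothermSolution, species: str) -> float:
    """Percent of one species' total that is captured: 100 * bound/total.

    Equals 100 * y/(1+y) with y = AB_f * K_B for that species.
    """
    s = solution.reaction.get(species)
    if s.total <= 0:
        raise ValueError(f"{species}: capture efficiency undefined for total = 0")
    return 100.0 * solution.bound_of(species) / s.total


def selectivity(species_a: Species, species_b: Species) -> float:
    """Antibody selectivity for a over b, as the ratio of binding constants."""
    if species_b.binding_constant == 0:
        raise ValueError(
            f"selectivity vs inert species {species_b.name!r} is undefined")
    if species_a.binding_constant <= 0:
        raise ValueError(f"{species_a.name}: binding constant must be > 0")
    return species_a.binding_constant / species_b.binding_constant


@dataclass
class DepletionScan:
    """Isotherm solutions along a grid of target total concentrations."""

    scenario: str
    grid: np.ndarray
    solutions: list = field(default_factory=list)
    target: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-grid-point table: AB_f, bound, %composition, %efficiency."""
        rows = []
        for s1t, sol in zip(self.grid, self.solutions):
            row = {"S1t": s1t, "AB_f": sol.free_antibody}
            comp = composition(sol)
            for sp, b in zip(sol.reaction.species, sol.bound):
                row[f"bound_{sp.name}"] = b
                if sp.total > 0 and sp.binding_constant > 0:
                    row[f"pct_eff_{sp.name}"] = capture_efficiency(sol, sp.name)
                if sp.name in comp:
                    row[f"pct_comp_{sp.name}"] = comp[sp.name]
            rows.append(row)
        return pd.DataFrame(rows)


def depletion_scan(base: Reaction, scenario: str, grid: Sequence[float],
                   total_constant: float = 11.0,
                   tolerance: float = 1e-12) -> DepletionScan:
    """Sweep the target total concentration under equal-chromatin loading.

    The target is the first non-spike species of ``base``. Two physically
    possible depletion scenarios are supported:

    * ``case1`` -- depleted target is replaced by inert chromatin: the
      first inert non-spike species (K = 0) absorbs the difference so the
      non-spike total stays at its base value; an inert pool is appended
      if the base reaction has none.
    * ``case2`` -- depleted target is converted into the first off-target
      species, which grows so that S1t + S2t = ``total_constant``
      (default 11 uM).

    Each grid point is an independent equilibrium solve.
    """
    if scenario not in ("case1", "case2"):
        raise ScenarioError(f"unknown scenario {scenario!r}")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ScenarioError("empty grid")
    if grid.size > 1 and not (np.all(np.diff(grid) > 0)
                              or np.all(np.diff(grid) < 0)):
        raise ScenarioError("grid must be strictly monotone")

    chromatin = [s for s in base.species if not s.spike]
    if not chromatin:
        raise ScenarioError("reaction has no chromatin species")
    target = chromatin[0].name

    if scenario == "case1":
        inert = next((s.name for s in chromatin[1:] if s.binding_constant == 0),
                     None)
        species = list(base.species)
        if inert is None:
            inert = "inert"
            species.append(Species(inert, 0.0, 0.0))
        base = Reaction(base.antibody_total, species)
        base_total = sum(s.total for s in base.species if not s.spike)
    else:
        offtargets = [s.name for s in chromatin[1:] if s.binding_constant > 0]
        if not offtargets:
            raise ScenarioError("case2 needs an off-target species to grow")
        growing = offtargets[0]

    scan = DepletionScan(scenario=scenario, grid=grid, target=target)
    for s1t in grid:
        if s1t < 0:
            raise ScenarioError(f"grid point S1t={s1t} is negative")
        rx = base.replace_total(target, float(s1t))
        if scenario == "case1":
            other = sum(s.total for s in rx.species
                        if not s.spike and s.name != inert)
            fill = base_total - other
            if fill < -1e-12:
                raise ScenarioError(
                    f"grid point S1t={s1t}: implied inert concentration "
                    f"{fill} is negative")
            rx = rx.replace_total(inert, max(fill, 0.0))
        else:
            s2t = total_constant - s1t
            if s2t < 0:
                raise ScenarioError(
                    f"grid point S1t={s1t}: implied {growing} concentration "
                    f"{s2t} is negative")
            rx = rx.replace_total(growing, s2t)
        scan.solutions.append(solve_binding(rx, tolerance=tolerance))
    return scan


def predict_efficiency(solution: IsothermSolution,
                       distributions: Mapping[str, np.ndarray],
                       atol: float = 1e-8):
    """Predicted capture-efficiency track over genomic intervals.

    Given the per-species genomic distributions ``o_i(x)`` (each summing
    to 1 over the intervals), the predicted siQ efficiency at interval x is

        e(x) = sum_i S_i_b * o_i(x) / sum_i S_i_t * o_i(x)

    Intervals where the denominator is zero (no chromatin at all) are
    evaluated to 0 and flagged, mirroring the track module's zero rule.

    Returns ``(efficiency, flags)`` as aligned arrays.
    """
    names = list(distributions)
    arrays = [np.asarray(distributions[n], dtype=float) for n in names]
    shape = arrays[0].shape
    for n, o in zip(names, arrays):
        if o.shape != shape:
            raise ValueError(f"distribution {n!r} has mismatched shape")
        if np.any(o < 0) or not np.isclose(o.sum(), 1.0, atol=atol):
            raise ValueError(f"distribution {n!r} must be a probability "
                             f"vector summing to 1 (got {o.sum()})")
    num = np.zeros(shape)
    den = np.zeros(shape)
    for n, o in zip(names, arrays):
        s = solution.reaction.get(n)
        num += solution.bound_of(n) * o
        den += s.total * o
    flags = den == 0
    eff = np.divide(num, den, out=np.zeros(shape), where=~flags)
    return eff, flags
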