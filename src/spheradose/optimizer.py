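"""Cocktail optimization: minimum decays to sterilize the spheroid.

Given one or two drugs whose cumulated-decay profiles scale linearly with
molar activity (carrier concentrations are fixed by the treatment protocol),
find the molar activities that minimize the total number of decays - either
over spheroid plus medium or over the medium alone - subject to an upper
ceiling on the expected surviving fraction and box bounds on the molar
activities.

The surviving fraction is monotone non-increasing in each activity, so the
feasible set is "up-closed": along any ray of increasing activities there is
a unique feasible threshold, found by bisection.  The optimizer sweeps the
apportionment between the two drugs with a deterministic ray scan from the
lower-bound corner, bisects each ray to the SF constraint, and refines the
best apportionment by golden-section search.  A dense grid search over the
activity box serves as the validation oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .geometry import CellLattice
from .survival import DrugSpec, KernelCache, RadiobiologicalParams, \
    assign_decays, compute_doses

__all__ = ["OptimizationProblem", "OptimizationResult", "forward_sf",
           "optimize", "decays_report"]

#: Relative slack allowed on the SF constraint at the reported optimum.
SF_CONSTRAINT_RTOL = 1e-3
#: Relative tolerance on molar activities in the bisection.
ACTIVITY_RTOL = 1e-4


@dataclass
class OptimizationProblem:
    """Constrained cocktail-design problem.

    ``drugs`` carry cumulated-decay profiles produced at the corresponding
    ``reference_molar_activities``; decays (and hence doses) scale linearly
    with molar activity around those references.
    """

    lattice: CellLattice
    kernels: KernelCache
    drugs: list[DrugSpec]
    reference_molar_activities: list[float]
    target_sf: float
    lower_bounds: list[float]
    upper_bounds: list[float]
    params: RadiobiologicalParams = field(default_factory=RadiobiologicalParams)
    objective_scope: str = "spheroid+medium"

    def __post_init__(self) -> None:
        n = len(self.drugs)
        if n not in (1, 2):
            raise ValueError("one or two drugs supported")
        if not (0 < self.target_sf <= 1):
            raise ValueError("target SF must lie in (0, 1]")
        if len(self.lower_bounds) != n or len(self.upper_bounds) != n \
                or len(self.reference_molar_activities) != n:
            raise ValueError("bounds/references must match number of drugs")
        for lo, hi in zip(self.lower_bounds, self.upper_bounds):
            if not (0 <= lo <= hi) or hi <= 0:
                raise ValueError("need 0 <= lower <= upper bounds, upper > 0")
        if self.objective_scope not in ("spheroid+medium", "medium"):
            raise ValueError("objective scope must be 'spheroid+medium' or 'medium'")
        self._prepare()

    def _prepare(self) -> None:
        """Precompute per-drug unit responses (dose field and decay totals
        per unit molar activity)."""
        lat = self.lattice
        self._unit_dose = []      # per drug: (N,) Gy per unit molar activity
        self._unit_decays = []    # per drug: {region: decays per unit M}
        for drug, m_ref in zip(self.drugs, self.reference_molar_activities):
            dm = compute_doses(lat, [drug], self.kernels)
            self._unit_dose.append(dm.total / m_ref)
            decays = assign_decays(lat, drug.profile)
            per_region = {
                reg: float(decays[lat.region == reg].sum()) / m_ref
                for reg in ("spheroid", "medium")
            }
            self._unit_decays.append(per_region)
        self._sph_mask = lat.spheroid_mask

    # -- forward model ------------------------------------------------------
    def dose_total(self, molar_activities) -> np.ndarray:
        a = np.asarray(molar_activities, dtype=float)
        return np.sum([ai * u for ai, u in zip(a, self._unit_dose)], axis=0)

    def sf(self, molar_activities) -> float:
        p = self.params.survival_probability(self.dose_total(molar_activities))
        return float(p[self._sph_mask].mean())

    def decays_by_drug_region(self, molar_activities) -> dict:
        return {
            (drug.drug_id, reg): float(ai * self._unit_decays[i][reg])
            for i, (drug, ai) in enumerate(zip(self.drugs, molar_activities))
            for reg in ("spheroid", "medium")
        }

    def objective(self, molar_activities) -> float:
        d = self.decays_by_drug_region(molar_activities)
        if self.objective_scope == "medium":
            return sum(v for (_, reg), v in d.items() if reg == "medium")
        return sum(d.values())


@dataclass
class OptimizationResult:
    """Optimal molar activities, decay bookkeeping and feasibility."""

    molar_activities: np.ndarray
    decays: dict  # (drug_id, region) -> decays
    objective_decays: float
    achieved_sf: float
    feasible: bool
    target_sf: float
    objective_scope: str
    drug_ids: list[str]

    @property
    def total_decays(self) -> float:
        return float(sum(self.decays.values()))

    def decays_per_drug(self) -> dict:
        out: dict = {}
        for (drug, _), v in self.decays.items():
            out[drug] = out.get(drug, 0.0) + v
        return out


def forward_sf(problem: OptimizationProblem, molar_activities) -> float:
    """Expected SF of the spheroid at the given molar activities (GBq/mol)."""
    return problem.sf(molar_activities)


def _bisect_ray(problem: OptimizationProblem, lo: np.ndarray,
                direction: np.ndarray, s_max: float,
                target: float) -> float | None:
    """Minimal s in [0, s_max] with SF(lo + s*direction) <= target, or None."""
    if problem.sf(lo) <= target:
        return 0.0
    if problem.sf(lo + s_max * direction) > target:
        return None
    a, b = 0.0, s_max
    while b - a > ACTIVITY_RTOL * max(s_max, b):
        m = 0.5 * (a + b)
        if problem.sf(lo + m * direction) <= target:
            b = m
        else:
            a = m
    return b


def optimize(problem: OptimizationProblem, n_ray: int = 41) -> OptimizationResult:
    """Deterministic constrained minimization of total decays.

    Returns a feasible optimum with the SF constraint active (unless a lower
    bound binds), or ``feasible=False`` with the best achievable SF at the
    upper-bound corner if the target cannot be reached.
    """
    lo = np.asarray(problem.lower_bounds, dtype=float)
    hi = np.asarray(problem.upper_bounds, dtype=float)
    target = problem.target_sf * (1.0 + SF_CONSTRAINT_RTOL)

    sf_at_hi = problem.sf(hi)
    if sf_at_hi > target:
        return OptimizationResult(
            molar_activities=hi, decays=problem.decays_by_drug_region(hi),
            objective_decays=problem.objective(hi), achieved_sf=sf_at_hi,
            feasible=False, target_sf=problem.target_sf,
            objective_scope=problem.objective_scope,
            drug_ids=[d.drug_id for d in problem.drugs])

    span = hi - lo
    if len(problem.drugs) == 1:
        s = _bisect_ray(problem, lo, span, 1.0, target)
        best = lo + s * span
    else:
        def solve_theta(theta: float):
            direction = np.array([theta * span[0], (1 - theta) * span[1]])
            if np.all(direction == 0):
                return None
            s_cap = min((1.0 / theta) if theta > 0 else np.inf,
                        (1.0 / (1 - theta)) if theta < 1 else np.inf)
            s = _bisect_ray(problem, lo, direction, s_cap, target)
            if s is None:
                return None
            return np.minimum(lo + s * direction, hi)

        thetas = np.linspace(0.0, 1.0, n_ray)
        cands = []
        for th in thetas:
            a = solve_theta(th)
            if a is not None:
                cands.append((problem.objective(a), th, a))
        if not cands:  # only the upper corner is feasible
            best = hi
        else:
            cands.sort(key=lambda c: c[0])
            _, th_best, best = cands[0]
            i = int(np.argmin(np.abs(thetas - th_best)))
            th_lo = thetas[max(i - 1, 0)]
            th_hi = thetas[min(i + 1, n_ray - 1)]

            def obj_of_theta(th: float) -> float:
                a = solve_theta(th)
                return problem.objective(a) if a is not None else np.inf

            res = minimize_scalar(obj_of_theta, bounds=(th_lo, th_hi),
                                  method="bounded",
                                  options={"xatol": 1e-4})
            if np.isfinite(res.fun) and res.fun < problem.objective(best):
                best = solve_theta(float(res.x))

    achieved = problem.sf(best)
    return OptimizationResult(
        molar_activities=np.asarray(best),
        decays=problem.decays_by_drug_region(best),
        objective_decays=problem.objective(best), achieved_sf=achieved,
        feasible=bool(achieved <= target), target_sf=problem.target_sf,
        objective_scope=problem.objective_scope,
        drug_ids=[d.drug_id for d in problem.drugs])


def decays_report(result: OptimizationResult) -> pd.DataFrame:
    """Per-drug decay totals and percentage shares for a feasible optimum."""
    if not result.feasible:
        raise ValueError("decays report requires a feasible result")
    per_drug = result.decays_per_drug()
    total = sum(per_drug.values())
    rows = []
    for drug, dec in per_drug.items():
        rows.append({
            "drug": drug,
            "molar_activity_gbq_per_mol": float(
                result.molar_activities[result.drug_ids.index(drug)]),
            "decays_spheroid": result.decays[(drug, "spheroid")],
            "decays_medium": result.decays[(drug, "medium")],
            "decays_total": dec,
            "share_percent": 100.0 * dec / total if total > 0 else 0.0,
        })
    return pd.DataFrame(rows)
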