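"""Total-energy assembly, simulated-annealing refinement, and the width sweep.

The target energy is E_total = E_base + E_stap + E_flat: a pluggable base
force field (standing in for a full molecular-mechanics energy), the
torsion-grid knowledge-based term, and the flat-bottom restraint term scaled
by 10.0.  The annealing protocol minimizes, heats 100→500 K over 1600 MD
steps, anneals at 500 K (2000 steps by default; 5000/10000 supported),
cools to 25 K over 4000 steps, and ends with a short minimization —
velocity-Verlet dynamics with a per-step velocity-rescaling thermostat.

Units: Å, kcal/mol, amu, fs; accelerations use the conversion
1 kcal/mol/Å/amu = 418.4 Å²/ps² so temperatures come out in kelvin with
k_B = 1.987204e-3 kcal/mol/K.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .flatbottom import DEFAULT_SCALE, RestraintEvaluator
from .forcefield import BaseForceField
from .structure import StructureModel
from .torsiongrid import TorsionEvaluator

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyBreakdown",
    "AnnealSchedule",
    "RefinementResult",
    "EnergySystem",
    "total_energy",
    "minimize",
    "sa_refine",
    "width_sweep",
]

KB = 1.9872041e-3        # kcal/mol/K
ACCEL_UNIT = 418.4       # (Å/ps²) per (kcal/mol/Å / amu)

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
           "S": 32.06, "P": 30.974}


@dataclass
class EnergyBreakdown:
    e_base: float
    e_stap: float
    e_flat: float

    @property
    def e_total(self) -> float:
        return self.e_base + self.e_stap + self.e_flat


@dataclass
class AnnealSchedule:
    """Stage lengths and temperatures of the annealing protocol."""

    heat_steps: int = 1600
    heat_t_start: float = 100.0
    heat_t_end: float = 500.0
    anneal_steps: int = 2000
    anneal_t: float = 500.0
    cool_steps: int = 4000
    cool_t_end: float = 25.0
    initial_min_steps: int = 200
    final_min_steps: int = 100
    timestep: float = 1.0  # fs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("heat_steps", "anneal_steps", "cool_steps",
                     "initial_min_steps", "final_min_steps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("heat_t_start", "heat_t_end", "anneal_t", "cool_t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, factor: float) -> "AnnealSchedule":
        """Schedule with every MD stage's step count divided by ``factor``.

        Minimization stages are left untouched: they are cheap and keep a
        shortened run stable.
        """
        return replace(
            self,
            heat_steps=int(round(self.heat_steps / factor)),
            anneal_steps=int(round(self.anneal_steps / factor)),
            cool_steps=int(round(self.cool_steps / factor)),
        )


@dataclass
class RefinementResult:
    refined: StructureModel
    width: float
    energy_trace: list[EnergyBreakdown] = field(default_factory=list)
    scores: dict | None = None
    total_score: float | None = None

    @property
    def initial(self) -> EnergyBreakdown:
        return self.energy_trace[0]

    @property
    def final(self) -> EnergyBreakdown:
        return self.energy_trace[-1]


class EnergySystem:
    """Bundle of the three energy providers evaluated on coordinate arrays."""

    def __init__(self, base=None, stap=None, restraints=None):
        self.base = base
        self.stap = stap
        self.restraints = restraints

    @classmethod
    def build(cls, structure: StructureModel, restraint_set=None,
              w: float = 0.0, scale: float = DEFAULT_SCALE,
              stap_tables=None, base: BaseForceField | None = None,
              pre_proline_rule: bool = True, **fb_overrides) -> "EnergySystem":
        if base is None:
            base = BaseForceField(structure)
        stap = (TorsionEvaluator(structure, stap_tables, pre_proline_rule)
                if stap_tables else None)
        rest = (RestraintEvaluator(structure, restraint_set, w, scale=scale,
                                   **fb_overrides)
                if restraint_set is not None and len(restraint_set) else None)
        return cls(base=base, stap=stap, restraints=rest)

    def __call__(self, coords: np.ndarray):
        forces = np.zeros_like(coords)
        eb = es = ef = 0.0
        if self.base is not None:
            eb, f = self.base(coords)
            forces += f
        if self.stap is not None:
            es, f = self.stap(coords)
            forces += f
        if self.restraints is not None:
            ef, f = self.restraints(coords)
            forces += f
        return EnergyBreakdown(e_base=eb, e_stap=es, e_flat=ef), forces


def total_energy(structure: StructureModel, base=None, stap_tables=None,
                 restraints=None, w: float = 0.0,
                 scale: float = DEFAULT_SCALE) -> EnergyBreakdown:
    """One-shot energy breakdown of a structure under the assembled target."""
    system = EnergySystem.build(structure, restraint_set=restraints, w=w,
                                scale=scale, stap_tables=stap_tables, base=base)
    breakdown, _ = system(structure.coords())
    return breakdown


# ---------------------------------------------------------------------------
# Optimizers / integrators

def minimize(coords: np.ndarray, system, steps: int):
    """Energy minimization with L-BFGS on the analytic gradient.

    ``steps`` bounds the number of quasi-Newton iterations.  Returns
    (coords, breakdown at the final coords).
    """
    from scipy.optimize import minimize as _scipy_minimize

    shape = np.asarray(coords).shape

    def fun(x):
        breakdown, forces = system(x.reshape(shape))
        return breakdown.e_total, -forces.ravel()

    res = _scipy_minimize(fun, np.asarray(coords, dtype=float).ravel(),
                          jac=True, method="L-BFGS-B",
                          options={"maxiter": steps})
    out = res.x.reshape(shape)
    breakdown, _ = system(out)
    return out, breakdown


def _masses(structure: StructureModel) -> np.ndarray:
    return np.array([_MASSES.get(a.element, 12.011) for a in structure.atoms])


def md_run(coords, velocities, masses, system, steps: int, dt_fs: float,
           target_t=None, trace=None, trace_every: int = 100):
    """Velocity-Verlet dynamics; optional per-step velocity rescaling.

    ``target_t`` is None (NVE), a constant, or a callable step→kelvin.
    Velocities are in Å/ps.  Raises on NaN/∞ energies with a diagnostic.
    """
    dt = dt_fs * 1e-3  # ps
    x = np.array(coords, dtype=float)
    v = np.array(velocities, dtype=float)
    m = masses[:, None]
    breakdown, forces = system(x)
    a = forces / m * ACCEL_UNIT
    ndof = 3 * len(masses)
    for step in range(steps):
        x = x + v * dt + 0.5 * a * dt**2
        breakdown, forces = system(x)
        if not np.isfinite(breakdown.e_total):
            raise RuntimeError(
                f"energy diverged at MD step {step}: {breakdown!r}")
        a_new = forces / m * ACCEL_UNIT
        v = v + 0.5 * (a + a_new) * dt
        a = a_new
        if target_t is not None:
            t_want = target_t(step) if callable(target_t) else target_t
            ke = 0.5 * float(np.sum(masses[:, None] * v**2)) / ACCEL_UNIT
            t_now = 2.0 * ke / (ndof * KB)
            if t_now > 1e-12:
                v *= np.sqrt(t_want / t_now)
        if trace is not None and (step % trace_every == 0 or step == steps - 1):
            trace.append(breakdown)
    return x, v, breakdown


def _maxwell_velocities(rng, masses, temperature: float) -> np.ndarray:
    sigma = np.sqrt(KB * temperature * ACCEL_UNIT / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def sa_refine(structure: StructureModel, schedule: AnnealSchedule,
              system: EnergySystem) -> RefinementResult:
    """Run the full annealing protocol and return the refined structure.

    Stages: initial minimization → heat (linear ramp heat_t_start→heat_t_end)
    → constant-temperature anneal → linear cool to cool_t_end → final
    minimization.  With a fixed ``schedule.seed`` the trajectory, and hence
    the output, is reproducible.
    """
    coords = structure.coords()
    trace: list[EnergyBreakdown] = []
    breakdown, _ = system(coords)
    if not np.isfinite(breakdown.e_total):
        raise RuntimeError(f"non-finite initial energy: {breakdown!r}")
    trace.append(breakdown)
    masses = _masses(structure)
    rng = np.random.default_rng(schedule.seed)

    if schedule.initial_min_steps:
        coords, breakdown = minimize(coords, system, schedule.initial_min_steps)
        trace.append(breakdown)
        logger.info("stage=min0 e_total=%.3f", breakdown.e_total)

    v = _maxwell_velocities(rng, masses, schedule.heat_t_start)

    if schedule.heat_steps:
        t0, t1, n = schedule.heat_t_start, schedule.heat_t_end, schedule.heat_steps
        ramp = lambda s: t0 + (t1 - t0) * (s + 1) / n
        coords, v, breakdown = md_run(coords, v, masses, system,
                                      schedule.heat_steps, schedule.timestep,
                                      target_t=ramp, trace=trace)
        logger.info("stage=heat e_total=%.3f", breakdown.e_total)

    if schedule.anneal_steps:
        coords, v, breakdown = md_run(coords, v, masses, system,
                                      schedule.anneal_steps, schedule.timestep,
                                      target_t=schedule.anneal_t, trace=trace)
        logger.info("stage=anneal e_total=%.3f", breakdown.e_total)

    if schedule.cool_steps:
        t0, t1, n = schedule.anneal_t, schedule.cool_t_end, schedule.cool_steps
        ramp = lambda s: t0 + (t1 - t0) * (s + 1) / n
        coords, v, breakdown = md_run(coords, v, masses, system,
                                      schedule.cool_steps, schedule.timestep,
                                      target_t=ramp, trace=trace)
        logger.info("stage=cool e_total=%.3f", breakdown.e_total)

    if schedule.final_min_steps:
        coords, breakdown = minimize(coords, system, schedule.final_min_steps)
        logger.info("stage=min e_total=%.3f", breakdown.e_total)

    trace.append(breakdown)
    refined = structure.with_coords(coords)
    width = 0.0
    if system.restraints is not None and system.restraints.params:
        width = system.restraints.params[0].w
    return RefinementResult(refined=refined, width=width, energy_trace=trace)


def width_sweep(structure: StructureModel, widths, schedule: AnnealSchedule,
                restraint_set=None, stap_tables=None,
                scale: float = DEFAULT_SCALE, scorer=None):
    """One independent refinement per flat-bottom width; pick the best.

    ``scorer(result) -> (total_score, metrics dict)`` supplies the quality
    assessment; the best result is the argmax of the total score, ties going
    to the smaller width.  Without a scorer the results are returned with
    ``best_index`` None.
    """
    widths = list(widths)
    if not widths:
        raise ValueError("widths must be non-empty")
    base = BaseForceField(structure)
    results: list[RefinementResult] = []
    for w in widths:
        system = EnergySystem.build(structure, restraint_set=restraint_set,
                                    w=w, scale=scale, stap_tables=stap_tables,
                                    base=base)
        result = sa_refine(copy.deepcopy(structure), schedule, system)
        result.width = w
        if scorer is not None:
            result.total_score, result.scores = scorer(result)
        results.append(result)
    best_index = None
    if scorer is not None:
        best_index = 0
        for i, r in enumerate(results):
            if (r.total_score > results[best_index].total_score + 1e-12 or
                    (abs(r.total_score - results[best_index].total_score) <= 1e-12
                     and r.width < results[best_index].width)):
                best_index = i
    return results, best_index
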