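"""The ten-simulation experiment matrix at desk scale.

The matrix mirrors the canonical study design: coordination-only sprint
and marathon on the generic model (sims 1-2), free body-segment
dimensions for sprint and marathon (sims 3-4), cross-evaluation of the
optimized segment dimensions on the opposite task (sims 5-6), free
muscle-volume distribution under the strength-training budgets (sims
7-8), and cross-evaluation of the trained volumes (sims 9-10).
Coordination is a decision variable in every simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .gait import GaitProblem, GaitProblemSpec, GaitSolution
from .model import Morphology, MusculoskeletalModel

__all__ = ["EXPERIMENT_MATRIX", "ExperimentRecord", "run_experiment_matrix", "report"]

# sim id -> (task, free variable, morphology source sim or None)
EXPERIMENT_MATRIX = {
    1: ("sprint", None, None),
    2: ("marathon", None, None),
    3: ("sprint", "ps", None),
    4: ("marathon", "ps", None),
    5: ("marathon", None, 3),
    6: ("sprint", None, 4),
    7: ("sprint", "pv", None),
    8: ("marathon", "pv", None),
    9: ("marathon", None, 7),
    10: ("sprint", None, 8),
}


@dataclass
class ExperimentRecord:
    sim: int
    task: str
    free: str | None
    morphology_source: int | None
    converged: bool
    speed: float | None = None
    kcal: float | None = None
    mass: float | None = None
    stature: float | None = None
    bmi: float | None = None
    step_length: float | None = None
    step_frequency: float | None = None
    objective: float | None = None
    constr_violation: float | None = None
    seed: int = 0
    config_hash: str = ""
    morphology: dict = field(default_factory=dict)
    error: str | None = None


def _record_from_solution(sim, task, free, source, sol: GaitSolution, seed, cfg_hash):
    pr = sol.problem
    morph = sol.morphology()
    mass, stature, bmi = pr.anthropometrics(sol.result.p)
    rec = ExperimentRecord(
        sim=sim, task=task, free=free, morphology_source=source,
        converged=bool(sol.converged),
        speed=float(sol.average_speed),
        kcal=float(sol.marathon_kcal()) if task == "marathon" else None,
        mass=float(np.real(mass)), stature=float(np.real(stature)),
        bmi=float(np.real(bmi)),
        step_length=float(sol.step_length),
        step_frequency=float(sol.step_frequency),
        objective=float(sol.result.objective),
        constr_violation=float(sol.result.constr_violation),
        seed=seed, config_hash=cfg_hash,
        morphology={
            "p_s": {g: [float(v) for v in vals] for g, vals in morph.p_s.items()},
            "p_v": [float(v) for v in morph.p_v],
        },
    )
    return rec


def _solve_sim(model, task, free, morphology, spec_kw, warm=None, solver=None):
    spec = GaitProblemSpec(
        task=task,
        free_ps=free == "ps",
        free_pv=free == "pv",
        fixed_morphology=morphology,
        **spec_kw,
    )
    problem = GaitProblem(model, spec)
    if solver is not None:  # injection point for tests
        return solver(problem, warm)
    return problem.solve(warm=warm)


def run_experiment_matrix(model: MusculoskeletalModel, seed: int = 0,
                          spec_kw: dict | None = None, solver=None,
                          sims=None, verbose: bool = False):
    """Run the ten-simulation analogue; failures are recorded and the
    matrix continues.  ``solver(problem, warm) -> GaitSolution`` may be
    injected (tests, custom schedules); warm starts flow from the
    coordination-only solution of the same task into the free-morphology
    solves."""
    spec_kw = dict(spec_kw or {})
    spec_kw.setdefault("seed", seed)
    cfg_hash = hashlib.sha256(
        json.dumps({"seed": seed, **{k: str(v) for k, v in spec_kw.items()}},
                   sort_keys=True).encode()).hexdigest()[:12]
    sims = sims or sorted(EXPERIMENT_MATRIX)
    records: dict[int, ExperimentRecord] = {}
    solutions: dict[int, GaitSolution] = {}
    for sim in sims:
        task, free, source = EXPERIMENT_MATRIX[sim]
        try:
            morphology = None
            if source is not None:
                if source not in solutions:
                    raise RuntimeError(f"sim{sim} requires sim{source} first")
                morphology = solutions[source].morphology()
            warm = None
            if free is not None:
                base = 1 if task == "sprint" else 2
                if base in solutions:
                    warm = solutions[base].result
            sol = _solve_sim(model, task, free, morphology, spec_kw,
                             warm=warm, solver=solver)
            solutions[sim] = sol
            records[sim] = _record_from_solution(sim, task, free, source, sol,
                                                 seed, cfg_hash)
            if verbose:
                r = records[sim]
                print(f"sim{sim}: task={task} free={free} v={r.speed:.3f} "
                      f"viol={r.constr_violation:.2e}", flush=True)
        except Exception as exc:  # record failure, continue the matrix
            records[sim] = ExperimentRecord(
                sim=sim, task=task, free=free, morphology_source=source,
                converged=False, seed=seed, config_hash=cfg_hash, error=str(exc))
            if verbose:
                print(f"sim{sim}: FAILED ({exc})", flush=True)
    return [records[s] for s in sims], solutions


def report(records, normalize_to: int = 1):
    """Comparison table of the matrix metrics as a tidy DataFrame."""
    import pandas as pd

    rows = [asdict(r) for r in records]
    for r in rows:
        r.pop("morphology", None)
    return pd.DataFrame(rows)
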