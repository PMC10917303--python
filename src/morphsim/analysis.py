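"""Post-processing analyses: joint-torque capacity, morphology
constraint audits and experiment report tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import AnalyticGeometry
from .model import Morphology, MusculoskeletalModel, build_scaled_model
from .muscle import initialize_tendon_forces

__all__ = ["torque_capacity", "morphology_constraint_check", "report_table"]


def torque_capacity(model: MusculoskeletalModel, morphology: Morphology,
                    coordinates=None, n_grid: int = 9):
    """Maximal isometric joint torque per coordinate and sign.

    For each pose on a grid spanning the coordinate's range of motion,
    all muscles are fully activated and solved to static equilibrium;
    agonists (muscles whose moment arm matches the requested sign)
    contribute moment-arm times tendon force.  Returns
    ``{coordinate: {"+": max Nm, "-": max Nm}}``; linear in the muscle
    forces, so doubling every F_max_iso doubles each capacity.
    """
    geo = AnalyticGeometry(model)
    scaled = build_scaled_model(model, morphology, geo.lmt_anatomical)
    rom = model.rom_bounds()
    if coordinates is None:
        coordinates = [c for c in model.coordinates
                       if any(c in m.spanned_coordinates for m in model.muscles)]
    out = {}
    for c in coordinates:
        j = model.coord_index(c)
        lo, hi = rom[c]
        tau_pos, tau_neg = 0.0, 0.0
        for qc in np.linspace(lo, hi, n_grid):
            q = np.zeros(model.n_coordinates)
            q[j] = qc
            lmt, R, _ = geo.eval(q, morphology)
            f_t = initialize_tendon_forces(scaled.muscles, np.ones(model.n_muscles), lmt)
            arms = R[:, j]
            tau_pos = max(tau_pos, float(np.sum(np.where(arms > 0, arms * f_t, 0.0))))
            tau_neg = max(tau_neg, float(-np.sum(np.where(arms < 0, arms * f_t, 0.0))))
        out[c] = {"+": tau_pos, "-": tau_neg}
    return out


def morphology_constraint_check(model: MusculoskeletalModel, morphology: Morphology,
                                ps_bounds=(0.8, 1.2), bmi_bounds=(17.5, 25.5),
                                pv_individual_max=1.2, pv_total_increase=0.05):
    """List of (name, value, bound, margin) tuples for every violated
    morphology constraint; empty for the generic morphology."""
    from .geometry import AnalyticGeometry
    geo = AnalyticGeometry(model)
    violations = []
    for g, v in morphology.p_s.items():
        v = np.asarray(v, float)
        if np.any(v < ps_bounds[0] - 1e-12):
            violations.append((f"p_s[{g}] lower", float(v.min()), ps_bounds[0],
                               float(ps_bounds[0] - v.min())))
        if np.any(v > ps_bounds[1] + 1e-12):
            violations.append((f"p_s[{g}] upper", float(v.max()), ps_bounds[1],
                               float(v.max() - ps_bounds[1])))
    scaled = build_scaled_model(model, morphology, geo.lmt_anatomical)
    bmi = float(np.real(scaled.bmi))
    if bmi < bmi_bounds[0] - 1e-12:
        violations.append(("BMI lower", bmi, bmi_bounds[0], bmi_bounds[0] - bmi))
    if bmi > bmi_bounds[1] + 1e-12:
        violations.append(("BMI upper", bmi, bmi_bounds[1], bmi - bmi_bounds[1]))
    pv = np.asarray(morphology.p_v, float)
    if np.any(pv > pv_individual_max + 1e-12):
        k = int(np.argmax(pv))
        violations.append((f"p_v[{model.muscles[k].name}]", float(pv.max()),
                           pv_individual_max, float(pv.max() - pv_individual_max)))
    vol = np.array([m.volume for m in model.muscles])
    rel = float(np.sum(vol * (pv - 1.0)) / np.sum(vol))
    if rel > pv_total_increase + 1e-12:
        violations.append(("total volume increase", rel, pv_total_increase,
                           rel - pv_total_increase))
    return violations


def report_table(records) -> pd.DataFrame:
    """Tabulate experiment records (list of dicts) into a tidy frame."""
    rows = []
    for r in records:
        rows.append({
            "sim": r.get("sim"),
            "task": r.get("task"),
            "free": r.get("free", "none"),
            "morphology_source": r.get("morphology_source", "generic"),
            "speed_mps": r.get("speed"),
            "marathon_kcal": r.get("kcal"),
            "mass_kg": r.get("mass"),
            "stature_m": r.get("stature"),
            "bmi": r.get("bmi"),
            "step_length_m": r.get("step_length"),
            "step_frequency_hz": r.get("step_frequency"),
            "converged": r.get("converged"),
        })
    return pd.DataFrame(rows)
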