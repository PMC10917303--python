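"""Muscle metabolic power (Bhargava-style) and marathon energy reporting.

The per-muscle metabolic rate is the sum of activation heat,
maintenance heat, shortening/lengthening heat and positive mechanical
work, with slow/fast twitch fractions weighting the heat coefficients.
All coefficients are configurable; the smooth positive-part used to
clamp the shortening and work terms keeps the rate differentiable.
The whole-marathon energy multiplies the per-meter cost (kcal/m,
computed from the unsquared metabolic energy of a gait cycle divided
by the distance travelled) by the marathon distance of 42,196 m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetabolicParams", "metabolic_power", "marathon_energy",
           "MARATHON_DISTANCE_M", "J_PER_KCAL"]

MARATHON_DISTANCE_M = 42_196.0
J_PER_KCAL = 4184.0
MUSCLE_DENSITY = 1059.7  # kg/m^3


@dataclass
class MetabolicParams:
    """Coefficients of the metabolic model (units W/kg unless noted)."""

    slow_fraction: float = 0.5  # slow-twitch fiber fraction, in [0, 1]
    act_slow: float = 40.0  # activation heat rate coefficient
    act_fast: float = 133.0
    maint_slow: float = 74.0  # maintenance heat rate coefficient
    maint_fast: float = 111.0
    shortening_coef: float = 0.25  # x F_CE, heat per unit shortening velocity
    include_work: bool = True
    basal: float = 0.0  # W/kg, default none
    smooth_eps: float = 1e-4  # m/s, positive-part smoothing of velocity terms

    def validate(self):
        if not 0.0 <= self.slow_fraction <= 1.0:
            raise ValueError("slow_fraction must lie in [0, 1]")


DEFAULT_METABOLIC = MetabolicParams()


def _smooth_pos(x, eps):
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


def metabolic_power(a_m, ln, ldot_m, f_ce, muscle_mass, fl_factor=None,
                    params: MetabolicParams = DEFAULT_METABOLIC):
    """Metabolic rate (W) of one muscle (batched over leading axes).

    Parameters
    ----------
    a_m : activation in [0, 1]
    ln : normalized fiber length (maintenance-heat length dependence)
    ldot_m : fiber lengthening velocity, m/s (negative = shortening)
    f_ce : active contractile-element force along the fiber, N
    muscle_mass : kg (volume times muscle density)
    fl_factor : optional active force-length value at ``ln``; when given
        it scales the maintenance heat (a common smooth stand-in for the
        piecewise length dependence); default 1.
    """
    fs = params.slow_fraction
    ff = 1.0 - fs
    act = muscle_mass * (fs * params.act_slow + ff * params.act_fast) * a_m
    fl = 1.0 if fl_factor is None else fl_factor
    maint = muscle_mass * (fs * params.maint_slow + ff * params.maint_fast) * a_m * fl
    shortening_speed = _smooth_pos(-ldot_m, params.smooth_eps)
    short = params.shortening_coef * f_ce * shortening_speed
    work = f_ce * shortening_speed if params.include_work else 0.0
    total = act + maint + short + work + params.basal * muscle_mass
    return total


def marathon_energy(per_meter_cost_kcal: float) -> float:
    """Whole-marathon energy (kcal) from a per-meter cost (kcal/m)."""
    if np.real(per_meter_cost_kcal) < 0:
        raise ValueError("per-meter cost must be non-negative")
    return per_meter_cost_kcal * MARATHON_DISTANCE_M
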