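"""Bundled desk-scale planar running model.

A sagittal-plane, human-scale model: 7 segments (torso incl. head,
pelvis and arms; left/right thighs, shanks, feet), 9 generalized
coordinates (planar free root x/y/pitch plus hip, knee, ankle per leg)
and 9 lumped muscle-tendon units per leg chosen to cover the functional
groups that drive running: hip flexion/extension, knee
flexion/extension, ankle plantar/dorsiflexion, with three biarticular
units (hamstrings, rectus femoris, gastrocnemius).

Generic anthropometrics: total mass 75.2 kg, stature 1.81 m.  Muscle
geometry is a closed-form via-point model; tendon slack lengths are
chosen so the anatomical pose (q = 0) puts each fiber at its optimal
length with the tendon at slack.
"""

from __future__ import annotations

import numpy as np

from .model import (
    ContactSphere,
    JointSpec,
    MusclePath,
    MuscleSpec,
    MusculoskeletalModel,
    Morphology,
    PassiveTorqueParams,
    SegmentSpec,
    TorqueActuator,
    save_model_definition,
)

__all__ = ["build_desk_model", "desk_mirror_maps", "build_full_structural_model"]

# segment longitudinal dimensions (m); stack to the 1.81 m stature
L_TORSO, L_THIGH, L_SHANK, H_FOOT = 0.86, 0.44, 0.43, 0.08
SIGMA = 6.0e5  # specific tension, N/m^2

# per-leg muscle definitions: name -> (F_max N, l_m_opt m, pennation rad,
#   path points [(segment-template, (x, y))])
_MUSCLES = {
    "hip_flexor": (2000.0, 0.14, 0.14, [("torso", (0.05, 0.08)), ("torso", (0.045, 0.01)), ("thigh", (0.03, -0.12))]),
    "glut_max": (3000.0, 0.12, 0.09, [("torso", (-0.06, 0.06)), ("thigh", (-0.02, -0.10))]),
    "adductor": (1500.0, 0.13, 0.10, [("torso", (-0.04, 0.02)), ("thigh", (0.0, -0.18))]),
    "hamstrings": (3000.0, 0.13, 0.12, [("torso", (-0.06, 0.04)), ("shank", (-0.03, -0.05))]),
    "rect_fem": (1800.0, 0.11, 0.09, [("torso", (0.04, 0.06)), ("thigh", (0.05, -0.42)), ("shank", (0.04, -0.06))]),
    "vasti": (5000.0, 0.12, 0.05, [("thigh", (0.04, -0.20)), ("thigh", (0.055, -0.42)), ("shank", (0.045, -0.06))]),
    "gastroc": (2500.0, 0.07, 0.17, [("thigh", (-0.015, -0.425)), ("foot", (-0.05, -0.04))]),
    "soleus": (4000.0, 0.06, 0.44, [("shank", (-0.02, -0.15)), ("foot", (-0.05, -0.04))]),
    "tib_ant": (1200.0, 0.08, 0.09, [("shank", (0.03, -0.20)), ("foot", (0.03, -0.03))])
}

_SPANNED = {
    "hip_flexor": ["hip"],
    "glut_max": ["hip"],
    "adductor": ["hip"],
    "hamstrings": ["hip", "knee"],
    "rect_fem": ["hip", "knee"],
    "vasti": ["knee"],
    "gastroc": ["knee", "ankle"],
    "soleus": ["ankle"],
    "tib_ant": ["ankle"],
}

# passive joint-limit parameters: coordinate template -> (theta_l, theta_u)
_PASSIVE_ROM = {"hip": (-0.5, 1.8), "knee": (-2.2, 0.02), "ankle": (-0.8, 0.5)}
# optimization range-of-motion bounds (generous, outside the passive limits)
_ROM = {"hip": (-1.0, 2.2), "knee": (-2.5, 0.3), "ankle": (-1.2, 0.9)}


def _limit_params(theta_l, theta_u):
    # ~2 Nm restoring torque at 5 degrees beyond the passive range
    k2 = 10.0
    k1 = 2.0 / np.exp(k2 * np.deg2rad(5.0))
    return PassiveTorqueParams(
        k_u1=-k1, k_u2=k2, theta_u=theta_u, k_l1=k1, k_l2=k2, theta_l=theta_l, damping=0.1
    )


def build_desk_model(seed: int = 0) -> MusculoskeletalModel:
    """Construct the generic desk model (deterministic; seed kept for
    provenance symmetry with the other fixture generators)."""
    segments = [
        SegmentSpec("torso", None, (0.35, L_TORSO, 0.25), 48.2, (0.0, 0.32), (2.0, 1.0, 2.6), "torso"),
    ]
    joints = [
        JointSpec(
            "ground_torso", "planar-free", None, "torso",
            (0.0, 0.0), ["root_x", "root_y", "root_pitch"],
            rom_bounds=[(-10.0, 100.0), (0.5, 1.6), (-1.0, 1.0)],
        )
    ]
    spheres = []
    for side in ("r", "l"):
        segments += [
            SegmentSpec(f"thigh_{side}", f"hip_{side}", (0.14, L_THIGH, 0.14), 9.3, (0.0, -0.19), (0.02, 0.005, 0.14), "thigh"),
            SegmentSpec(f"shank_{side}", f"knee_{side}", (0.10, L_SHANK, 0.10), 3.5, (0.0, -0.19), (0.005, 0.002, 0.048), "shank"),
            SegmentSpec(
                f"foot_{side}", f"ankle_{side}", (0.26, H_FOOT, 0.09), 0.7, (0.05, -0.04), (0.001, 0.002, 0.004), "foot",
                contact_sphere_ids=[f"heel_{side}", f"toe_{side}"],
            ),
        ]
        joints += [
            JointSpec(f"hip_{side}", "revolute", "torso", f"thigh_{side}", (0.0, 0.0),
                      [f"hip_{side}_q"], [_ROM["hip"]], passive=_limit_params(*_PASSIVE_ROM["hip"])),
            JointSpec(f"knee_{side}", "revolute", f"thigh_{side}", f"shank_{side}", (0.0, -L_THIGH),
                      [f"knee_{side}_q"], [_ROM["knee"]], passive=_limit_params(*_PASSIVE_ROM["knee"])),
            JointSpec(f"ankle_{side}", "revolute", f"shank_{side}", f"foot_{side}", (0.0, -L_SHANK),
                      [f"ankle_{side}_q"], [_ROM["ankle"]], passive=_limit_params(*_PASSIVE_ROM["ankle"])),
        ]
        # compliant-track contact: soft enough that a coarse mesh
        # resolves the loading and unloading of stance smoothly
        spheres += [
            ContactSphere(f"heel_{side}", f"foot_{side}", (-0.05, -0.06), 0.02,
                          stiffness=1.2e5, dissipation=1.0),
            ContactSphere(f"toe_{side}", f"foot_{side}", (0.14, -0.06), 0.02,
                          stiffness=1.2e5, dissipation=1.0),
        ]

    muscles = []
    for side in ("r", "l"):
        for name, (fmax, lopt, alpha, path_pts) in _MUSCLES.items():
            pts = [(seg if seg == "torso" else f"{seg}_{side}", xy) for seg, xy in path_pts]
            spanned = [f"{j}_{side}_q" for j in _SPANNED[name]]
            muscles.append(
                MuscleSpec(
                    name=f"{name}_{side}",
                    spanned_coordinates=spanned,
                    pcsa=fmax / SIGMA,
                    sigma=SIGMA,
                    l_t_slack=1.0,  # placeholder, set from anatomical pose below
                    l_m_opt=lopt,
                    alpha_m=alpha,
                    k_t=100.0,  # stiff tendons: the lumped desk muscles are
                                # short-tendon structures, nearly rigid
                    side={"r": "right", "l": "left"}[side],
                    path=MusclePath(kind="via", points=pts),
                )
            )

    model = MusculoskeletalModel(
        name="desk-planar-runner",
        segments=segments,
        joints=joints,
        muscles=muscles,
        contact_spheres=spheres,
        torque_actuators=[],
        stature_segments=["torso", "thigh_r", "shank_r", "foot_r"],
    )
    model.validate()

    # set tendon slack so the anatomical pose (q = 0) puts the fiber at
    # its optimal length under a light reference load (15 % of maximal
    # isometric force): enough tendon pre-strain that fibers stay in
    # their working range under stance loads, little enough that the
    # passive tension of antagonist pairs at rest stays small
    from .geometry import AnalyticGeometry
    from .muscle import DEFAULT_CURVES

    geo = AnalyticGeometry(model)
    generic = Morphology.generic(model)
    for m in model.muscles:
        l0 = float(geo.lmt_anatomical(m.name, generic))
        lt_ref = DEFAULT_CURVES.lt_norm_from_force(0.15, m.k_t)
        lts = (l0 - m.l_m_opt * np.cos(m.alpha_m)) / lt_ref
        if lts <= 0.01:
            raise RuntimeError(f"muscle {m.name}: implausible tendon slack {lts:.4f}")
        m.l_t_slack = lts
    model.validate()
    return model


def desk_mirror_maps(model: MusculoskeletalModel):
    """(muscle permutation, coordinate permutation, coordinate signs)
    realizing the left-right mirror of the desk model.  Applying the
    maps twice is the identity."""
    def mirror_name(n):
        if n.endswith("_r"):
            return n[:-2] + "_l"
        if n.endswith("_l"):
            return n[:-2] + "_r"
        return n

    mperm = np.array([model._muscle_index[mirror_name(m.name)] for m in model.muscles])
    cperm = np.zeros(model.n_coordinates, dtype=int)
    for i, c in enumerate(model.coordinates):
        if c.endswith("_r_q"):
            cperm[i] = model.coord_index(c[:-4] + "_l_q")
        elif c.endswith("_l_q"):
            cperm[i] = model.coord_index(c[:-4] + "_r_q")
        else:
            cperm[i] = i
    csign = np.ones(model.n_coordinates)  # sagittal model: no lateral sign flips
    return mperm, cperm, csign


def write_desk_model(path, seed: int = 0):
    model = build_desk_model(seed)
    save_model_definition(model, path)
    return model


# -------------------------------------------------------------------------
# Structural full-scale configuration (counts and connectivity only)
# -------------------------------------------------------------------------

_FULL_BODIES = [
    "pelvis", "trunk_head",
    "talus_r", "midhindfoot_r", "toes_r", "shank_r", "thigh_r",
    "talus_l", "midhindfoot_l", "toes_l", "shank_l", "thigh_l",
    "upperarm_r", "lowerarm_r", "hand_r", "upperarm_l", "lowerarm_l", "hand_l",
]


def build_full_structural_model() -> MusculoskeletalModel:
    """A structural 18-body / 31-coordinate / 92-muscle / 8-torque-actuator
    definition with placeholder literature-scale parameters.

    Topology mirrors the full running configuration: 6-DOF pelvis root,
    3-DOF hips, lumbar and shoulders, 1-DOF knees, ankles, subtalar and
    metatarsophalangeal joints and elbows, welded hands; the 8 arm
    coordinates carry the torque actuators.  Used for structural tests
    only (state layout, counts, validation); its dynamics are not
    exercised and parameters are placeholders.
    """
    segments = [SegmentSpec("pelvis", None, (0.25, 0.18, 0.30), 11.0, (0.0, 0.05), (0.1, 0.08, 0.1), "pelvis")]
    joints = [
        JointSpec("ground_pelvis", "free", None, "pelvis", (0.0, 0.0),
                  ["pelvis_tx", "pelvis_ty", "pelvis_tz", "pelvis_list", "pelvis_rot", "pelvis_tilt"],
                  [(-10, 100), (0.3, 1.8), (-2, 2), (-1, 1), (-1.5, 1.5), (-1, 1)])
    ]
    # name -> (parent, joint type, coordinate names)
    topo = {
        "trunk_head": ("pelvis", "ball", ["lumbar_ext", "lumbar_bend", "lumbar_rot"]),
        "thigh_r": ("pelvis", "ball", ["hip_flex_r", "hip_add_r", "hip_rot_r"]),
        "thigh_l": ("pelvis", "ball", ["hip_flex_l", "hip_add_l", "hip_rot_l"]),
        "shank_r": ("thigh_r", "revolute", ["knee_r"]),
        "shank_l": ("thigh_l", "revolute", ["knee_l"]),
        "talus_r": ("shank_r", "revolute", ["ankle_r"]),
        "talus_l": ("shank_l", "revolute", ["ankle_l"]),
        "midhindfoot_r": ("talus_r", "revolute", ["subtalar_r"]),
        "midhindfoot_l": ("talus_l", "revolute", ["subtalar_l"]),
        "toes_r": ("midhindfoot_r", "revolute", ["mtp_r"]),
        "toes_l": ("midhindfoot_l", "revolute", ["mtp_l"]),
        "upperarm_r": ("trunk_head", "ball", ["shoulder_flex_r", "shoulder_add_r", "shoulder_rot_r"]),
        "upperarm_l": ("trunk_head", "ball", ["shoulder_flex_l", "shoulder_add_l", "shoulder_rot_l"]),
        "lowerarm_r": ("upperarm_r", "revolute", ["elbow_r"]),
        "lowerarm_l": ("upperarm_l", "revolute", ["elbow_l"]),
        "hand_r": ("lowerarm_r", "weld", []),
        "hand_l": ("lowerarm_l", "weld", []),
    }
    group_of = {
        "trunk_head": "trunk_arms", "upperarm_r": "trunk_arms", "upperarm_l": "trunk_arms",
        "lowerarm_r": "trunk_arms", "hand_r": "trunk_arms", "lowerarm_l": "trunk_arms",
        "hand_l": "trunk_arms",
        "talus_r": "foot", "midhindfoot_r": "foot", "toes_r": "foot",
        "talus_l": "foot", "midhindfoot_l": "foot", "toes_l": "foot",
        "thigh_r": "thigh", "thigh_l": "thigh", "shank_r": "shank", "shank_l": "shank",
    }
    mass_of = {
        "trunk_head": 34.0, "thigh_r": 9.3, "thigh_l": 9.3, "shank_r": 3.7, "shank_l": 3.7,
        "talus_r": 0.1, "talus_l": 0.1, "midhindfoot_r": 1.0, "midhindfoot_l": 1.0,
        "toes_r": 0.2, "toes_l": 0.2, "upperarm_r": 2.0, "upperarm_l": 2.0,
        "lowerarm_r": 1.2, "lowerarm_l": 1.2, "hand_r": 0.5, "hand_l": 0.5,
    }
    spheres = []
    for name, (parent, jtype, coords) in topo.items():
        sph = []
        if name.startswith("midhindfoot"):
            side = name[-1]
            for k in range(6):
                sid = f"sph_{side}_{k}"
                spheres.append(ContactSphere(sid, name, (0.03 * k - 0.05, -0.02), 0.02))
                sph.append(sid)
        if name.startswith("toes"):
            side = name[-1]
            for k in range(6, 8):
                sid = f"sph_{side}_{k}"
                spheres.append(ContactSphere(sid, name, (0.02 * (k - 6), -0.02), 0.02))
                sph.append(sid)
        segments.append(
            SegmentSpec(name, f"j_{name}", (0.1, 0.3, 0.1), mass_of[name], (0.0, -0.1),
                        (0.02, 0.01, 0.02), group_of[name], contact_sphere_ids=sph)
        )
        joints.append(
            JointSpec(f"j_{name}", jtype, parent, name, (0.0, -0.2), coords,
                      [(-2.5, 2.5)] * len(coords), mtp_flag=name.startswith("toes"))
        )
    muscles = []
    for k in range(92):
        side = "right" if k % 2 == 0 else "left"
        seg = "thigh_r" if side == "right" else "thigh_l"
        muscles.append(
            MuscleSpec(
                name=f"m{k:02d}", spanned_coordinates=[f"hip_flex_{seg[-1]}"],
                pcsa=2e-3, sigma=SIGMA, l_t_slack=0.2, l_m_opt=0.1, alpha_m=0.1, side=side,
                path=MusclePath(kind="via", points=[("pelvis", (0.0, 0.0)), (seg, (0.0, -0.1))]),
            )
        )
    actuators = [TorqueActuator(coordinate=c) for c in
                 ["shoulder_flex_r", "shoulder_add_r", "shoulder_rot_r", "elbow_r",
                  "shoulder_flex_l", "shoulder_add_l", "shoulder_rot_l", "elbow_l"]]
    model = MusculoskeletalModel(
        name="full-structural",
        segments=segments,
        joints=joints,
        muscles=muscles,
        contact_spheres=spheres,
        torque_actuators=actuators,
        stature_segments=["pelvis", "trunk_head"],
    )
    model.validate()
    return model
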