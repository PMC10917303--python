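"""Musculoskeletal model schema, validation, and morphology scaling.

A :class:`MusculoskeletalModel` is a tree of rigid segments connected by
joints, actuated by Hill-type muscle-tendon units (and optionally ideal
torque actuators), with sphere-on-plane foot contact and passive joint
torques.  A :class:`Morphology` holds the two families of decision
variables that personalise the generic model:

* ``p_s`` — per scaling-group triplets ``(s_x, s_y, s_z)`` of segment
  dimension factors (dimensionless, 1 = generic).  Segments sharing a
  scaling group (e.g. left/right thighs) are constrained to identical
  factors by construction.
* ``p_v`` — per-muscle volume factors (dimensionless, 1 = generic),
  emulating targeted strength training.

All quantities are SI (m, kg, s, N, rad).  Scaling follows constant
density: segment mass scales with the product of the three factors,
centre of mass and joint-frame offsets scale per axis, and each
principal moment of inertia scales with the mass ratio times the mean
square of the two orthogonal axis factors (exact for a constant-density
ellipsoid with equal orthogonal semi-axes).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "PassiveTorqueParams",
    "ContactSphere",
    "TorqueActuator",
    "SegmentSpec",
    "JointSpec",
    "MuscleSpec",
    "MusculoskeletalModel",
    "Morphology",
    "ScaledModel",
    "ModelError",
    "load_model_definition",
    "save_model_definition",
    "apply_segment_scaling",
    "scale_muscle_parameters",
    "compute_anthropometrics",
    "assemble_state",
    "unpack_state",
]

SCHEMA_VERSION = 1


class ModelError(ValueError):
    """Raised when a model definition violates the schema or an invariant."""


@dataclass
class PassiveTorqueParams:
    """Exponential joint-limit torque plus viscous damping.

    tau_pas(q, qdot) = k_u1 * exp(k_u2 * (q - theta_u))
                     + k_l1 * exp(k_l2 * (theta_l - q)) - damping * qdot

    ``k_u1`` is negative and ``k_l1`` positive so the limit torques
    restore the coordinate toward mid-range; damping dissipates.
    """

    k_u1: float
    k_u2: float
    theta_u: float
    k_l1: float
    k_l2: float
    theta_l: float
    damping: float = 0.1

    def validate(self, where: str) -> None:
        if self.theta_l > self.theta_u:
            raise ModelError(f"{where}: theta_l > theta_u")
        if self.damping < 0:
            raise ModelError(f"{where}: negative damping")


@dataclass
class ContactSphere:
    """Sphere fixed in a segment frame, contacting the ground plane y=0."""

    name: str
    segment: str
    location: tuple[float, float]  # (x, y) in segment frame, m
    radius: float
    stiffness: float = 1.0e6  # N / m^exponent
    exponent: float = 1.5  # Hertzian by default; 1 = linear compliant layer
    dissipation: float = 2.0  # s/m
    friction: float = 0.8  # Coulomb coefficient (regularised)

    def validate(self, where: str) -> None:
        if self.radius <= 0:
            raise ModelError(f"{where}: sphere radius must be > 0")


@dataclass
class TorqueActuator:
    """Ideal first-order torque actuator on one coordinate.

    Activation in [-1, 1]; torque = gain * activation; first-order
    excitation-to-activation dynamics with time constant ``tau``.
    """

    coordinate: str
    gain: float = 150.0  # Nm per unit activation
    tau: float = 0.035  # s


@dataclass
class SegmentSpec:
    name: str
    parent_joint: str | None  # None for the root segment
    length_axes: tuple[float, float, float]  # reference (x, y, z) dims, m
    mass: float
    com: tuple[float, float]  # (x, y) in segment frame, m
    inertia: tuple[float, float, float]  # principal moments, kg m^2
    scaling_group: str
    contact_sphere_ids: list[str] = field(default_factory=list)

    def validate(self, where: str) -> None:
        if self.mass <= 0:
            raise ModelError(f"{where}: mass must be > 0")
        if any(i < 0 for i in self.inertia):
            raise ModelError(f"{where}: inertia components must be >= 0")


@dataclass
class JointSpec:
    name: str
    type: str  # "revolute" | "planar-free"
    parent: str | None  # parent segment, None for root joint
    child: str  # child segment
    location_in_parent: tuple[float, float] = (0.0, 0.0)
    coordinates: list[str] = field(default_factory=list)
    rom_bounds: list[tuple[float, float]] = field(default_factory=list)
    passive: PassiveTorqueParams | None = None
    mtp_flag: bool = False

    def validate(self, where: str) -> None:
        if self.type not in ("revolute", "planar-free", "free", "ball", "weld"):
            raise ModelError(f"{where}: unknown joint type {self.type!r}")
        n_expected = {"revolute": 1, "planar-free": 3, "free": 6, "ball": 3, "weld": 0}[self.type]
        if len(self.coordinates) != n_expected:
            raise ModelError(
                f"{where}: {self.type} joint needs {n_expected} coordinates, "
                f"got {len(self.coordinates)}"
            )
        for k, (lo, hi) in enumerate(self.rom_bounds):
            if lo >= hi:
                raise ModelError(f"{where}: rom bound {k} has lower >= upper")
        if self.passive is not None:
            self.passive.validate(where)


@dataclass
class MusclePath:
    """Closed-form differentiable muscle path.

    ``kind="via"``: polyline through points fixed in segment frames.
    ``kind="pulley"``: reference length minus constant moment-arm
    contributions per spanned coordinate (circular-arc wrap about the
    joint), anchored on two segments for length scaling.
    """

    kind: str  # "via" | "pulley"
    # via: list of (segment, (x, y)); pulley: endpoints only
    points: list[tuple[str, tuple[float, float]]] = field(default_factory=list)
    # pulley: coordinate -> wrap radius (m, sign = moment arm sign)
    radii: dict[str, float] = field(default_factory=dict)

    def validate(self, where: str) -> None:
        if self.kind not in ("via", "pulley"):
            raise ModelError(f"{where}: unknown path kind {self.kind!r}")
        if len(self.points) < 2:
            raise ModelError(f"{where}: path needs at least 2 points")


@dataclass
class MuscleSpec:
    name: str
    spanned_coordinates: list[str]
    pcsa: float  # m^2
    sigma: float  # specific tension, N/m^2
    l_t_slack: float  # m
    l_m_opt: float  # m
    alpha_m: float  # pennation at optimal length, rad
    k_t: float = 35.0  # dimensionless tendon stiffness
    side: str = "central"  # "left" | "right" | "central"
    path: MusclePath | None = None

    def validate(self, where: str) -> None:
        if self.pcsa <= 0:
            raise ModelError(f"{where}: PCSA must be > 0")
        if self.sigma <= 0:
            raise ModelError(f"{where}: sigma must be > 0")
        if self.l_t_slack <= 0 or self.l_m_opt <= 0:
            raise ModelError(f"{where}: lengths must be > 0")
        if not (0 <= self.alpha_m < np.pi / 2):
            raise ModelError(f"{where}: pennation must be in [0, pi/2)")
        if self.side not in ("left", "right", "central"):
            raise ModelError(f"{where}: bad side {self.side!r}")
        if self.path is not None:
            self.path.validate(where)

    @property
    def f_max_iso(self) -> float:
        return self.pcsa * self.sigma

    @property
    def volume(self) -> float:
        return self.pcsa * self.l_m_opt


@dataclass
class MusculoskeletalModel:
    """Validated generic model: the tree, muscles, contact, actuators."""

    name: str
    segments: list[SegmentSpec]
    joints: list[JointSpec]
    muscles: list[MuscleSpec]
    contact_spheres: list[ContactSphere]
    torque_actuators: list[TorqueActuator] = field(default_factory=list)
    gravity: float = 9.81
    # segments whose y-dimension stacks into stature, in order
    stature_segments: list[str] = field(default_factory=list)

    # ---- derived lookups -------------------------------------------------
    def __post_init__(self) -> None:
        self._seg_index = {s.name: i for i, s in enumerate(self.segments)}
        self._joint_index = {j.name: i for i, j in enumerate(self.joints)}
        self._muscle_index = {m.name: i for i, m in enumerate(self.muscles)}
        self.coordinates: list[str] = []
        for j in self.joints:
            self.coordinates.extend(j.coordinates)
        self._coord_index = {c: i for i, c in enumerate(self.coordinates)}

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def n_coordinates(self) -> int:
        return len(self.coordinates)

    @property
    def n_torque_actuators(self) -> int:
        return len(self.torque_actuators)

    @property
    def state_size(self) -> int:
        # layout (a_m; a_T; F_t; q; qdot)
        return 2 * self.n_muscles + self.n_torque_actuators + 2 * self.n_coordinates

    def segment(self, name: str) -> SegmentSpec:
        return self.segments[self._seg_index[name]]

    def muscle(self, name: str) -> MuscleSpec:
        return self.muscles[self._muscle_index[name]]

    def coord_index(self, name: str) -> int:
        return self._coord_index[name]

    def scaling_groups(self) -> list[str]:
        groups: list[str] = []
        for s in self.segments:
            if s.scaling_group not in groups:
                groups.append(s.scaling_group)
        return groups

    def rom_bounds(self) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for j in self.joints:
            for c, b in zip(j.coordinates, j.rom_bounds):
                out[c] = b
        return out

    # ---- validation ------------------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ModelError("duplicate segment names")
        jnames = [j.name for j in self.joints]
        if len(set(jnames)) != len(jnames):
            raise ModelError("duplicate joint names")
        mnames = [m.name for m in self.muscles]
        if len(set(mnames)) != len(mnames):
            raise ModelError("duplicate muscle names")
        coords = []
        for j in self.joints:
            coords.extend(j.coordinates)
        if len(set(coords)) != len(coords):
            raise ModelError("coordinate names must be unique across joints")

        roots = [s for s in self.segments if s.parent_joint is None]
        if len(roots) != 1:
            raise ModelError(f"model must have exactly one root segment, got {len(roots)}")

        for s in self.segments:
            s.validate(f"segment {s.name!r}")
            if s.parent_joint is not None and s.parent_joint not in self._joint_index:
                raise ModelError(f"segment {s.name!r}: dangling parent_joint {s.parent_joint!r}")
        for j in self.joints:
            j.validate(f"joint {j.name!r}")
            if j.parent is not None and j.parent not in self._seg_index:
                raise ModelError(f"joint {j.name!r}: dangling parent segment {j.parent!r}")
            if j.child not in self._seg_index:
                raise ModelError(f"joint {j.name!r}: dangling child segment {j.child!r}")
            if j.parent is not None and self.segment(j.child).parent_joint != j.name:
                raise ModelError(f"joint {j.name!r}: child segment does not reference it back")
        for m in self.muscles:
            m.validate(f"muscle {m.name!r}")
            for c in m.spanned_coordinates:
                if c not in self._coord_index:
                    raise ModelError(f"muscle {m.name!r}: dangling coordinate {c!r}")
            if m.path is not None:
                for seg, _ in m.path.points:
                    if seg not in self._seg_index:
                        raise ModelError(f"muscle {m.name!r}: dangling path segment {seg!r}")
        sphere_names = set()
        for cs in self.contact_spheres:
            cs.validate(f"contact sphere {cs.name!r}")
            if cs.segment not in self._seg_index:
                raise ModelError(f"contact sphere {cs.name!r}: dangling segment {cs.segment!r}")
            sphere_names.add(cs.name)
        for s in self.segments:
            for sid in s.contact_sphere_ids:
                if sid not in sphere_names:
                    raise ModelError(f"segment {s.name!r}: dangling contact sphere id {sid!r}")
        for t in self.torque_actuators:
            if t.coordinate not in self._coord_index:
                raise ModelError(f"torque actuator on dangling coordinate {t.coordinate!r}")
        for name in self.stature_segments:
            if name not in self._seg_index:
                raise ModelError(f"stature segment {name!r} is not a segment")


# =========================================================================
# Morphology
# =========================================================================


@dataclass
class Morphology:
    """Segment-scale factors per scaling group and per-muscle volume factors."""

    p_s: dict[str, np.ndarray]  # group -> (s_x, s_y, s_z)
    p_v: np.ndarray  # per muscle, model order

    @classmethod
    def generic(cls, model: MusculoskeletalModel) -> "Morphology":
        return cls(
            p_s={g: np.ones(3) for g in model.scaling_groups()},
            p_v=np.ones(model.n_muscles),
        )

    def copy(self) -> "Morphology":
        return Morphology(
            p_s={g: np.array(v, copy=True) for g, v in self.p_s.items()},
            p_v=np.array(self.p_v, copy=True),
        )

    def validate(self, free: bool = True) -> None:
        for g, v in self.p_s.items():
            v = np.asarray(v)
            if v.shape != (3,):
                raise ModelError(f"p_s[{g!r}] must have 3 components")
            if np.any(np.real(v) <= 0):
                raise ModelError(f"p_s[{g!r}] must be positive")
            if free and (np.any(np.real(v) < 0.8 - 1e-9) or np.any(np.real(v) > 1.2 + 1e-9)):
                raise ModelError(f"p_s[{g!r}] outside [0.8, 1.2]")
        if np.any(np.real(self.p_v) <= 0):
            raise ModelError("p_v must be positive")


def segment_scale(morph: Morphology, seg: SegmentSpec) -> np.ndarray:
    """The (s_x, s_y, s_z) triplet applying to one segment."""
    return np.asarray(morph.p_s[seg.scaling_group])


# =========================================================================
# Scaled model
# =========================================================================


@dataclass
class ScaledMuscle:
    name: str
    pcsa: float
    f_max_iso: float
    l_m_opt: float
    l_t_slack: float
    volume: float
    alpha_m: float
    k_t: float


@dataclass
class ScaledModel:
    """Concrete (simulatable) model: generic parameters + morphology applied."""

    model: MusculoskeletalModel
    morphology: Morphology
    seg_mass: np.ndarray  # per segment
    seg_com: np.ndarray  # per segment, (x, y)
    seg_inertia: np.ndarray  # per segment, Izz (planar, about COM)
    joint_offsets: np.ndarray  # per joint, scaled location_in_parent (x, y)
    muscles: list[ScaledMuscle]
    total_mass: float
    stature: float
    bmi: float


def _scale_inertial(model, morph):
    """Per-segment scaled mass/com/Izz and per-joint scaled offsets."""
    n = len(model.segments)
    any_c = any(np.iscomplexobj(np.asarray(v)) for v in morph.p_s.values())
    dtype = complex if any_c else float
    mass = np.zeros(n, dtype=dtype)
    com = np.zeros((n, 2), dtype=dtype)
    izz = np.zeros(n, dtype=dtype)
    for i, s in enumerate(model.segments):
        sx, sy, sz = segment_scale(morph, s)
        r_m = sx * sy * sz
        mass[i] = s.mass * r_m
        com[i, 0] = s.com[0] * sx
        com[i, 1] = s.com[1] * sy
        # planar: only the out-of-plane principal moment matters dynamically
        izz[i] = s.inertia[2] * r_m * (sx**2 + sy**2) / 2.0
    offsets = np.zeros((len(model.joints), 2), dtype=dtype)
    for k, j in enumerate(model.joints):
        if j.parent is None:
            offsets[k] = j.location_in_parent
        else:
            sx, sy, _ = segment_scale(morph, model.segment(j.parent))
            offsets[k, 0] = j.location_in_parent[0] * sx
            offsets[k, 1] = j.location_in_parent[1] * sy
    return mass, com, izz, offsets


def apply_segment_scaling(
    model: MusculoskeletalModel, morphology: Morphology
) -> ScaledModel:
    """Scale the inertial part of the model (constant-density rule).

    Muscle parameters are scaled too when a geometry evaluator is
    attached to the model via :func:`scale_muscle_parameters`; here we
    apply the mass-ratio part only if ``p_s`` is generic-free.  Prefer
    :func:`morphsim.deskmodel.scaled_desk_model` or
    :func:`build_scaled_model` for a fully scaled model.
    """
    for g, v in morphology.p_s.items():
        if np.any(np.real(np.asarray(v)) <= 0):
            raise ModelError(f"p_s[{g!r}] must be positive")
    mass, com, izz, offsets = _scale_inertial(model, morphology)
    total_mass = np.sum(mass)
    stature = compute_stature(model, morphology)
    muscles = [
        ScaledMuscle(
            name=m.name,
            pcsa=m.pcsa,
            f_max_iso=m.f_max_iso,
            l_m_opt=m.l_m_opt,
            l_t_slack=m.l_t_slack,
            volume=m.volume,
            alpha_m=m.alpha_m,
            k_t=m.k_t,
        )
        for m in model.muscles
    ]
    return ScaledModel(
        model=model,
        morphology=morphology,
        seg_mass=mass,
        seg_com=com,
        seg_inertia=izz,
        joint_offsets=offsets,
        muscles=muscles,
        total_mass=total_mass,
        stature=stature,
        bmi=total_mass / stature**2,
    )


def compute_stature(model: MusculoskeletalModel, morphology: Morphology):
    """Stature = stacked scaled y-dimensions of the listed longitudinal segments."""
    if not model.stature_segments:
        raise ModelError("model defines no stature segments")
    h = 0.0
    for name in model.stature_segments:
        s = model.segment(name)
        _, sy, _ = segment_scale(morphology, s)
        h = h + s.length_axes[1] * sy
    return h


def scale_muscle_parameters(
    model: MusculoskeletalModel,
    morphology: Morphology,
    lmt_anatomical,
) -> list[ScaledMuscle]:
    """Scale Hill parameters for a morphology.

    ``lmt_anatomical(muscle_name, morphology) -> l_mt`` evaluates the
    muscle-tendon length in the anatomical pose (q = 0).  Optimal fiber
    length and tendon slack length scale with the ratio of anatomical
    muscle-tendon lengths; muscle volume first scales 1:1 with the
    whole-body mass ratio (constant tissue composition), then with the
    per-muscle volume factor ``p_v`` (strength training); PCSA is
    recomputed from the scaled volume and fiber length, and maximal
    isometric force follows as PCSA * sigma.
    """
    generic = Morphology.generic(model)
    mass_gen = sum(s.mass for s in model.segments)
    mass_scaled, _, _, _ = _scale_inertial(model, morphology)
    mass_ratio = np.sum(mass_scaled) / mass_gen

    out: list[ScaledMuscle] = []
    for i, m in enumerate(model.muscles):
        l0_gen = lmt_anatomical(m.name, generic)
        l0_scaled = lmt_anatomical(m.name, morphology)
        if np.real(l0_gen) <= 0 or np.real(l0_scaled) <= 0:
            raise ModelError(f"muscle {m.name!r}: non-positive anatomical length")
        ratio = l0_scaled / l0_gen
        l_m_opt = m.l_m_opt * ratio
        l_t_slack = m.l_t_slack * ratio
        volume = m.volume * mass_ratio * morphology.p_v[i]
        pcsa = volume / l_m_opt
        out.append(
            ScaledMuscle(
                name=m.name,
                pcsa=pcsa,
                f_max_iso=pcsa * m.sigma,
                l_m_opt=l_m_opt,
                l_t_slack=l_t_slack,
                volume=volume,
                alpha_m=m.alpha_m,
                k_t=m.k_t,
            )
        )
    return out


def build_scaled_model(
    model: MusculoskeletalModel,
    morphology: Morphology,
    lmt_anatomical,
) -> ScaledModel:
    """Full scaling: inertial part plus Hill-parameter part."""
    sm = apply_segment_scaling(model, morphology)
    sm.muscles = scale_muscle_parameters(model, morphology, lmt_anatomical)
    return sm


def compute_anthropometrics(scaled: ScaledModel) -> tuple[float, float, float]:
    """(total mass kg, stature m, BMI kg/m^2) of a scaled model."""
    mass = np.sum(scaled.seg_mass)
    stature = scaled.stature
    return mass, stature, mass / stature**2


# =========================================================================
# State packing
# =========================================================================


def assemble_state(model: MusculoskeletalModel, a_m, a_t, f_t, q, qdot) -> np.ndarray:
    """Pack simulator state in the fixed layout (a_m; a_T; F_t; q; qdot)."""
    a_m = np.atleast_1d(np.asarray(a_m, dtype=float) if not np.iscomplexobj(a_m) else np.asarray(a_m))
    a_t = np.atleast_1d(np.asarray(a_t)) if np.size(a_t) else np.zeros(0)
    f_t = np.atleast_1d(np.asarray(f_t))
    q = np.atleast_1d(np.asarray(q))
    qdot = np.atleast_1d(np.asarray(qdot))
    sizes = (len(a_m), len(a_t), len(f_t), len(q), len(qdot))
    expected = (
        model.n_muscles,
        model.n_torque_actuators,
        model.n_muscles,
        model.n_coordinates,
        model.n_coordinates,
    )
    if sizes != expected:
        raise ModelError(f"state component lengths {sizes} != expected {expected}")
    return np.concatenate([a_m, a_t, f_t, q, qdot])


def unpack_state(model: MusculoskeletalModel, x):
    """Inverse of :func:`assemble_state`."""
    x = np.asarray(x)
    if x.shape[-1] != model.state_size:
        raise ModelError(f"state length {x.shape[-1]} != expected {model.state_size}")
    nm, nt, nq = model.n_muscles, model.n_torque_actuators, model.n_coordinates
    i0, i1, i2, i3 = nm, nm + nt, nm + nt + nm, nm + nt + nm + nq
    return (
        x[..., :i0],
        x[..., i0:i1],
        x[..., i1:i2],
        x[..., i2:i3],
        x[..., i3:],
    )


# =========================================================================
# YAML serialisation
# =========================================================================


def _muscle_to_dict(m: MuscleSpec) -> dict:
    d = {
        "name": m.name,
        "spanned_coordinates": list(m.spanned_coordinates),
        "pcsa": float(m.pcsa),
        "sigma": float(m.sigma),
        "l_t_slack": float(m.l_t_slack),
        "l_m_opt": float(m.l_m_opt),
        "alpha_m": float(m.alpha_m),
        "k_t": float(m.k_t),
        "side": m.side,
    }
    if m.path is not None:
        d["path"] = {
            "kind": m.path.kind,
            "points": [[seg, [float(p[0]), float(p[1])]] for seg, p in m.path.points],
            "radii": {k: float(v) for k, v in m.path.radii.items()},
        }
    return d


def save_model_definition(model: MusculoskeletalModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "gravity": float(model.gravity),
        "stature_segments": list(model.stature_segments),
        "segments": [
            {
                "name": s.name,
                "parent_joint": s.parent_joint,
                "length_axes": [float(v) for v in s.length_axes],
                "mass": float(s.mass),
                "com": [float(v) for v in s.com],
                "inertia": [float(v) for v in s.inertia],
                "scaling_group": s.scaling_group,
                "contact_sphere_ids": list(s.contact_sphere_ids),
            }
            for s in model.segments
        ],
        "joints": [
            {
                "name": j.name,
                "type": j.type,
                "parent": j.parent,
                "child": j.child,
                "location_in_parent": [float(v) for v in j.location_in_parent],
                "coordinates": list(j.coordinates),
                "rom_bounds": [[float(a), float(b)] for a, b in j.rom_bounds],
                "passive": (None if j.passive is None
                            else {k: float(v) for k, v in asdict(j.passive).items()}),
                "mtp_flag": bool(j.mtp_flag),
            }
            for j in model.joints
        ],
        "muscles": [_muscle_to_dict(m) for m in model.muscles],
        "contact_spheres": [
            {
                "name": c.name,
                "segment": c.segment,
                "location": [float(v) for v in c.location],
                "radius": float(c.radius),
                "stiffness": float(c.stiffness),
                "exponent": float(c.exponent),
                "dissipation": float(c.dissipation),
                "friction": float(c.friction),
            }
            for c in model.contact_spheres
        ],
        "torque_actuators": [
            {"coordinate": t.coordinate, "gain": float(t.gain), "tau": float(t.tau)}
            for t in model.torque_actuators
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _req(d: dict, key: str, where: str):
    if key not in d:
        raise ModelError(f"{where}: missing field {key!r}")
    return d[key]


def load_model_definition(path) -> MusculoskeletalModel:
    """Load and fully validate a YAML model definition."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ModelError(f"{path}: not a mapping")
    where = str(path)
    segments = []
    for sd in _req(doc, "segments", where):
        w = f"{where}: segment {sd.get('name', '?')!r}"
        segments.append(
            SegmentSpec(
                name=_req(sd, "name", w),
                parent_joint=sd.get("parent_joint"),
                length_axes=tuple(_req(sd, "length_axes", w)),
                mass=float(_req(sd, "mass", w)),
                com=tuple(_req(sd, "com", w)),
                inertia=tuple(_req(sd, "inertia", w)),
                scaling_group=_req(sd, "scaling_group", w),
                contact_sphere_ids=list(sd.get("contact_sphere_ids", [])),
            )
        )
    joints = []
    for jd in _req(doc, "joints", where):
        w = f"{where}: joint {jd.get('name', '?')!r}"
        pd = jd.get("passive")
        joints.append(
            JointSpec(
                name=_req(jd, "name", w),
                type=_req(jd, "type", w),
                parent=jd.get("parent"),
                child=_req(jd, "child", w),
                location_in_parent=tuple(jd.get("location_in_parent", (0.0, 0.0))),
                coordinates=list(_req(jd, "coordinates", w)),
                rom_bounds=[tuple(b) for b in jd.get("rom_bounds", [])],
                passive=(None if pd is None else PassiveTorqueParams(**pd)),
                mtp_flag=bool(jd.get("mtp_flag", False)),
            )
        )
    muscles = []
    for md in _req(doc, "muscles", where):
        w = f"{where}: muscle {md.get('name', '?')!r}"
        path_d = md.get("path")
        mpath = None
        if path_d is not None:
            mpath = MusclePath(
                kind=_req(path_d, "kind", w),
                points=[(seg, tuple(p)) for seg, p in _req(path_d, "points", w)],
                radii=dict(path_d.get("radii", {})),
            )
        muscles.append(
            MuscleSpec(
                name=_req(md, "name", w),
                spanned_coordinates=list(_req(md, "spanned_coordinates", w)),
                pcsa=float(_req(md, "pcsa", w)),
                sigma=float(_req(md, "sigma", w)),
                l_t_slack=float(_req(md, "l_t_slack", w)),
                l_m_opt=float(_req(md, "l_m_opt", w)),
                alpha_m=float(_req(md, "alpha_m", w)),
                k_t=float(md.get("k_t", 35.0)),
                side=md.get("side", "central"),
                path=mpath,
            )
        )
    spheres = [
        ContactSphere(
            name=_req(cd, "name", f"{where}: contact sphere"),
            segment=_req(cd, "segment", f"{where}: contact sphere"),
            location=tuple(_req(cd, "location", f"{where}: contact sphere")),
            radius=float(_req(cd, "radius", f"{where}: contact sphere")),
            stiffness=float(cd.get("stiffness", 1.0e6)),
            exponent=float(cd.get("exponent", 1.5)),
            dissipation=float(cd.get("dissipation", 2.0)),
            friction=float(cd.get("friction", 0.8)),
        )
        for cd in doc.get("contact_spheres", [])
    ]
    actuators = [
        TorqueActuator(
            coordinate=_req(td, "coordinate", f"{where}: torque actuator"),
            gain=float(td.get("gain", 150.0)),
            tau=float(td.get("tau", 0.035)),
        )
        for td in doc.get("torque_actuators", [])
    ]
    model = MusculoskeletalModel(
        name=doc.get("name", "model"),
        segments=segments,
        joints=joints,
        muscles=muscles,
        contact_spheres=spheres,
        torque_actuators=actuators,
        gravity=float(doc.get("gravity", 9.81)),
        stature_segments=list(doc.get("stature_segments", [])),
    )
    model.validate()
    return model
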