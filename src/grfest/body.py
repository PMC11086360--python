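"""Articulated 12-segment human model.

The model comprises 12 rigid links (pelvis, trunk, upper arms, forearms,
thighs, shanks, feet) connected by rotational joints totalling 21 DOFs
(3-DOF hips, lumbar and shoulders; 1-DOF knees, ankles and elbows), plus a
6-DOF virtual joint between the pelvis and the global frame, for 27
generalized coordinates.

Frame conventions: global X points to the subject's left, Y posterior, Z up;
gravity is (0, 0, -9.81) m/s^2.  Each segment frame originates at its
proximal joint and is aligned with the global frame in the neutral pose.
3-DOF joints rotate in the intrinsic X-Y-Z Euler sequence
(flexion-extension, adduction-abduction, axial rotation).

Segment masses, lengths, COM positions and inertias are scaled from body
height and weight through a pluggable anthropometry table; joint limits,
torque limits and passive-torque coefficients come from a joint table; the
22 foot-sole contact points per foot are generated from a foot-geometry
table.  All tables ship with documented defaults and accept overrides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

GRAVITY = 9.81

SEGMENTS = [
    "pelvis", "trunk",
    "upper_arm_l", "upper_arm_r",
    "forearm_l", "forearm_r",
    "thigh_l", "thigh_r",
    "shank_l", "shank_r",
    "foot_l", "foot_r",
]

#: joints in public order; (name, base table entry, parent segment, child segment, n_dof)
JOINTS = [
    ("lumbar", "lumbar", "pelvis", "trunk", 3),
    ("shoulder_l", "shoulder", "trunk", "upper_arm_l", 3),
    ("shoulder_r", "shoulder", "trunk", "upper_arm_r", 3),
    ("elbow_l", "elbow", "upper_arm_l", "forearm_l", 1),
    ("elbow_r", "elbow", "upper_arm_r", "forearm_r", 1),
    ("hip_l", "hip", "pelvis", "thigh_l", 3),
    ("hip_r", "hip", "pelvis", "thigh_r", 3),
    ("knee_l", "knee", "thigh_l", "shank_l", 1),
    ("knee_r", "knee", "thigh_r", "shank_r", 1),
    ("ankle_l", "ankle", "shank_l", "foot_l", 1),
    ("ankle_r", "ankle", "shank_r", "foot_r", 1),
]

_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


class ValidationError(ValueError):
    """Raised for out-of-range numeric inputs."""


class ConfigurationError(ValueError):
    """Raised for incomplete or inconsistent configuration tables."""


def load_default(name: str) -> dict:
    """Load one of the packaged default tables (``anthropometry``, ``joints``,
    ``foot``, ``mountings``)."""
    with resources.files("grfest.data").joinpath(f"{name}.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class SegmentSpec:
    name: str
    mass: float                      # kg
    length: float                    # m
    com_offset: np.ndarray           # m, in segment frame from the proximal joint
    inertia: np.ndarray              # kg m^2, 3x3 about the COM in segment frame
    parent_joint: str

    def __post_init__(self):
        if self.mass <= 0 or self.length <= 0:
            raise ValidationError(f"{self.name}: mass and length must be positive")
        sym = np.allclose(self.inertia, self.inertia.T, atol=1e-12)
        if not sym or np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ValidationError(f"{self.name}: inertia must be symmetric positive-definite")


@dataclass
class JointSpec:
    name: str
    dof_axes: list[str]              # intrinsic X-Y-Z order where 3-DOF
    q_min: np.ndarray                # rad, per DOF
    q_max: np.ndarray
    tau_plus_max: np.ndarray         # N m, > 0
    tau_minus_max: np.ndarray        # N m, stored negative
    passive_params: np.ndarray       # (n_dof, 3): a [N m], b [1/rad], c [N m s/rad]

    def __post_init__(self):
        if np.any(self.q_min >= self.q_max):
            raise ValidationError(f"{self.name}: require q_min < q_max")
        if np.any(self.tau_plus_max <= 0) or np.any(self.tau_minus_max >= 0):
            raise ValidationError(f"{self.name}: require tau_plus_max > 0 > tau_minus_max")


@dataclass
class ContactPointSet:
    """22 contact points per foot, in the foot frame (origin at the ankle)."""

    points: np.ndarray               # (22, 3), m
    sole_height: float               # sole plane z (the higher of the two point heights)

    def __post_init__(self):
        if self.points.shape != (22, 3):
            raise ValidationError("contact point set must contain exactly 22 points")
        if np.any(self.points[:, 2] > self.sole_height + 1e-12):
            raise ValidationError("all contact points must lie on/below the sole plane")


@dataclass
class IMUMounting:
    segment: str
    lever_arm: np.ndarray            # m, proximal joint -> sensor origin, segment frame
    mount_rotation: np.ndarray       # scalar-first unit quaternion, sensor -> segment

    def __post_init__(self):
        n = np.linalg.norm(self.mount_rotation)
        if abs(n - 1.0) > 1e-9:
            raise ValidationError(f"{self.segment}: mount rotation must be unit norm")


@dataclass
class ModelState:
    """Generalized state: q[:21] joint angles (rad), q[21:24] root translation
    (m), q[24:27] root X-Y-Z Euler angles (rad)."""

    q: np.ndarray
    q_dot: np.ndarray
    t: float = 0.0


@dataclass
class BodyModel:
    height: float
    total_mass: float
    segments: dict[str, SegmentSpec]
    joints: dict[str, JointSpec]
    contact_points: dict[str, ContactPointSet]     # keyed "foot_l"/"foot_r"
    mountings: list[IMUMounting]
    geometry: dict = field(default_factory=dict)   # frame-placement lengths (m)
    neutral: dict[str, float] = field(default_factory=dict)  # per-DOF-name overrides

    # ---- enumeration ----------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_joint_dofs(self) -> int:
        return sum(len(j.dof_axes) for j in self.joints.values())

    @property
    def n_coords(self) -> int:
        return self.n_joint_dofs + 6

    def dof_names(self) -> list[str]:
        names = []
        for jname, base, _p, _c, nd in JOINTS:
            for ax in self.joints[jname].dof_axes[:nd]:
                names.append(f"{jname}_{ax}")
        names += ["root_tx", "root_ty", "root_tz", "root_rx", "root_ry", "root_rz"]
        return names

    def validate(self) -> None:
        if self.n_segments != 12:
            raise ValidationError("model must have exactly 12 segments")
        if self.n_joint_dofs != 21:
            raise ValidationError("joint DOFs must total 21")
        if self.n_coords != 27:
            raise ValidationError("generalized coordinates must total 27")
        msum = sum(s.mass for s in self.segments.values())
        if abs(msum - self.total_mass) > 1e-9 * self.total_mass:
            raise ValidationError("segment masses must sum to the body mass")
        for cps in self.contact_points.values():
            if cps.points.shape[0] != 22:
                raise ValidationError("each foot needs 22 contact points")
        for m in self.mountings:
            if np.linalg.norm(m.lever_arm) > self.segments[m.segment].length + 1e-9:
                raise ValidationError(f"{m.segment}: IMU lever arm exceeds segment length")

    # ---- derived quantities --------------------------------------------
    def standing_height(self) -> float:
        """Root (hip-centre) height above the ground in the neutral stance."""
        g = self.geometry
        return g["thigh_len"] + g["shank_len"] + g["ankle_height"]

    def joint_dof_table(self) -> dict[str, np.ndarray]:
        """Per-DOF limit/torque/passive arrays in public DOF order (21)."""
        cols = {k: [] for k in ("q_min", "q_max", "tau_plus", "tau_minus", "pa", "pb", "pc")}
        for jname, *_ in JOINTS:
            j = self.joints[jname]
            for d in range(len(j.dof_axes)):
                cols["q_min"].append(j.q_min[d])
                cols["q_max"].append(j.q_max[d])
                cols["tau_plus"].append(j.tau_plus_max[d])
                cols["tau_minus"].append(j.tau_minus_max[d])
                cols["pa"].append(j.passive_params[d, 0])
                cols["pb"].append(j.passive_params[d, 1])
                cols["pc"].append(j.passive_params[d, 2])
        return {k: np.asarray(v) for k, v in cols.items()}

    def summary(self) -> dict:
        """JSON-serializable structural summary for inspection and fixtures."""
        return {
            "height": self.height,
            "total_mass": self.total_mass,
            "n_segments": self.n_segments,
            "n_joint_dofs": self.n_joint_dofs,
            "n_coords": self.n_coords,
            "dof_names": self.dof_names(),
            "segments": {
                n: {
                    "mass": s.mass,
                    "length": s.length,
                    "com_offset": s.com_offset.tolist(),
                    "inertia": s.inertia.tolist(),
                }
                for n, s in self.segments.items()
            },
            "contact_points": {
                k: v.points.tolist() for k, v in self.contact_points.items()
            },
        }

    def export_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def foot_contact_points(foot_geometry: dict, height: float = 1.70,
                        foot_length: float | None = None) -> ContactPointSet:
    """Generate the 22-point sole layout from the foot-geometry table.

    Rows of two points run from the heel to the toe tip; the half-width
    profile is piecewise linear through the heel, MTP and toe widths, and
    rows forward of the MTP line are raised to the phalanx height.
    """
    g = foot_geometry
    for key in ("heel_dist_frac", "mtp_dist_frac", "toe_dist_frac",
                "heel_width_frac", "mtp_width_frac", "toe_width_frac"):
        if g[key] < 0:
            raise ValidationError(f"foot geometry: {key} must be non-negative")
    if foot_length is None:
        foot_length = g.get("length", 0.152 * height)
    L = foot_length
    d_heel, d_mtp, d_toe = (g["heel_dist_frac"] * L, g["mtp_dist_frac"] * L,
                            g["toe_dist_frac"] * L)
    h_ankle = g["ankle_height_frac_height"] * height
    h_phal = g["phalanx_height_frac_height"] * height
    n_rows = int(g.get("n_rows", 11))
    a = np.linspace(-d_heel, d_toe, n_rows)          # anterior coordinate
    widths = np.interp(a, [-d_heel, d_mtp, d_toe],
                       [g["heel_width_frac"] * L, g["mtp_width_frac"] * L,
                        g["toe_width_frac"] * L])
    pts = []
    for ai, wi in zip(a, widths):
        z = -h_ankle if ai <= d_mtp + 1e-12 else -h_phal
        pts.append([+wi / 2, -ai, z])                # anterior is -Y
        pts.append([-wi / 2, -ai, z])
    return ContactPointSet(points=np.array(pts), sole_height=-min(h_ankle, h_phal))


def _merge(base: dict, override: dict | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _parse_lever(entry, length: float) -> np.ndarray:
    out = []
    for c in entry:
        if isinstance(c, str):
            frac, _, sym = c.partition("*")
            if sym.strip() != "L":
                raise ConfigurationError(f"bad lever component {c!r}")
            out.append(float(frac) * length)
        else:
            out.append(float(c))
    return np.array(out)


def build_model(height: float, weight: float,
                anthropometry_table: dict | None = None,
                joints_table: dict | None = None,
                foot_geometry: dict | None = None,
                mountings_table: dict | None = None) -> BodyModel:
    """Construct the articulated model from body height (m) and weight (kg).

    Segment masses are ``weight`` x table mass fraction (renormalized to sum
    to 1); lengths scale with ``height``; inertia about each COM axis is
    ``mass * (gyration_fraction * length)**2``.
    """
    if not (1.0 <= height <= 2.3):
        raise ValidationError(f"height {height} m outside [1.0, 2.3]")
    if not (20.0 <= weight <= 200.0):
        raise ValidationError(f"weight {weight} kg outside [20, 200]")

    anthro = _merge(load_default("anthropometry"), anthropometry_table)
    jtab = _merge(load_default("joints"), joints_table)
    ftab = _merge(load_default("foot"), {"foot_geometry": foot_geometry} if foot_geometry else None)
    mtab = _merge(load_default("mountings"), mountings_table)

    seg_rows = anthro["segments"]
    base_of = {s: ("foot" if s.startswith("foot") else
                   "shank" if s.startswith("shank") else
                   "thigh" if s.startswith("thigh") else
                   "forearm" if s.startswith("forearm") else
                   "upper_arm" if s.startswith("upper_arm") else s)
               for s in SEGMENTS}
    missing = {base_of[s] for s in SEGMENTS
               if not isinstance(seg_rows.get(base_of[s]), dict)}
    if missing:
        raise ConfigurationError(f"anthropometry table missing segments: {sorted(missing)}")

    # renormalize mass fractions so segment masses sum exactly to the weight
    frac_sum = sum(seg_rows[base_of[s]]["mass_frac"] for s in SEGMENTS)

    frame = anthro["frame"]
    fg = ftab["foot_geometry"]
    L_foot = seg_rows["foot"]["length_frac"] * height
    h_ankle = fg["ankle_height_frac_height"] * height

    parent_joint_of = {c: jname for jname, _b, _p, c, _n in JOINTS}
    parent_joint_of["pelvis"] = "root"

    segments: dict[str, SegmentSpec] = {}
    for s in SEGMENTS:
        row = seg_rows[base_of[s]]
        mass = weight * row["mass_frac"] / frac_sum
        length = row["length_frac"] * height
        k = np.asarray(row["gyration"], dtype=float)
        inertia = np.diag(mass * (k * length) ** 2)
        if row["axis"] == "+z":
            com = np.array([0.0, 0.0, row["com_frac"] * length])
        elif row["axis"] == "-z":
            com = np.array([0.0, 0.0, -row["com_frac"] * length])
        elif row["axis"] == "foot":
            # along the sole from the heel; anterior is -Y, sole below the ankle
            d_heel = fg["heel_dist_frac"] * L_foot
            com = np.array([0.0, d_heel - row["com_frac"] * L_foot, -0.6 * h_ankle])
        else:
            raise ConfigurationError(f"unknown segment axis {row['axis']!r}")
        segments[s] = SegmentSpec(name=s, mass=mass, length=length,
                                  com_offset=com, inertia=inertia,
                                  parent_joint=parent_joint_of[s])

    pdef = jtab.get("passive_defaults", {"a": 2.0, "b": 20.0, "c": 0.1})
    joints: dict[str, JointSpec] = {}
    for jname, base, _p, _c, nd in JOINTS:
        if base not in jtab["joints"]:
            raise ConfigurationError(f"joint table missing {base!r}")
        dofs = jtab["joints"][base]["dofs"]
        if len(dofs) != nd:
            raise ConfigurationError(f"{base}: expected {nd} DOFs, table has {len(dofs)}")
        joints[jname] = JointSpec(
            name=jname,
            dof_axes=[d["axis"] for d in dofs],
            q_min=np.array([d["q_min"] for d in dofs], dtype=float),
            q_max=np.array([d["q_max"] for d in dofs], dtype=float),
            tau_plus_max=np.array([d["tau_plus_max"] for d in dofs], dtype=float),
            tau_minus_max=np.array([d["tau_minus_max"] for d in dofs], dtype=float),
            passive_params=np.array([[d.get("a", pdef["a"]), d.get("b", pdef["b"]),
                                      d.get("c", pdef["c"])] for d in dofs]),
        )

    cps = foot_contact_points(fg, height=height, foot_length=L_foot)
    contact_points = {"foot_l": cps,
                      "foot_r": ContactPointSet(points=cps.points.copy(),
                                                sole_height=cps.sole_height)}

    mountings = []
    for seg in SEGMENTS:
        if seg not in mtab["mountings"]:
            raise ConfigurationError(f"mounting table missing segment {seg!r}")
        row = mtab["mountings"][seg]
        mountings.append(IMUMounting(
            segment=seg,
            lever_arm=_parse_lever(row["lever"], segments[seg].length),
            mount_rotation=np.asarray(row["mount_rotation"], dtype=float),
        ))

    geometry = {
        "pelvis_len": segments["pelvis"].length,
        "trunk_len": segments["trunk"].length,
        "upper_arm_len": segments["upper_arm_l"].length,
        "forearm_len": segments["forearm_l"].length,
        "thigh_len": segments["thigh_l"].length,
        "shank_len": segments["shank_l"].length,
        "foot_len": L_foot,
        "hip_half_width": frame["hip_half_width_frac"] * height,
        "shoulder_half_width": frame["shoulder_half_width_frac"] * height,
        "ankle_height": h_ankle,
    }

    model = BodyModel(height=height, total_mass=weight, segments=segments,
                      joints=joints, contact_points=contact_points,
                      mountings=mountings, geometry=geometry,
                      neutral=dict(anthro.get("neutral", {})))
    model.validate()
    return model


def neutral_pose(model: BodyModel, overrides: dict[str, float] | None = None) -> ModelState:
    """Neutral stance: joint angles at their configured neutral values
    (default 0), root upright with both soles on the ground, zero velocity."""
    q = np.zeros(27)
    q[23] = model.standing_height()
    names = model.dof_names()
    neutral = dict(model.neutral)
    if overrides:
        neutral.update(overrides)
    for name, val in neutral.items():
        if name not in names:
            raise ConfigurationError(f"unknown DOF {name!r} in neutral overrides")
        q[names.index(name)] = val
    return ModelState(q=q, q_dot=np.zeros(27), t=0.0)


# ---------------------------------------------------------------------------
# flattened numeric description used by the dynamics kernels
# ---------------------------------------------------------------------------

@dataclass
class ModelArrays:
    """Flat numeric model for the numba kernels (internal tree ordering:
    root 6 DOFs first, then joint clusters; each 1-DOF node may carry a
    segment's spatial inertia)."""

    parent: np.ndarray       # (27,) int32
    jtype: np.ndarray        # (27,) int8: 0 prismatic, 1 revolute
    axis: np.ndarray         # (27, 3)
    p_off: np.ndarray        # (27, 3) joint origin in parent frame
    mass: np.ndarray         # (27,)
    com: np.ndarray          # (27, 3)
    inertia: np.ndarray      # (27, 3, 3) about COM
    int2pub: np.ndarray      # (27,) internal DOF index -> public index
    seg_body: np.ndarray     # (12,) internal body index per public segment
    cp_body: np.ndarray      # (44,) internal body index per contact point
    cp_pos: np.ndarray       # (44, 3) contact point in body frame
    q_min: np.ndarray        # (27,) per internal DOF (inf for root)
    q_max: np.ndarray
    passive: np.ndarray      # (27, 3) a, b, c (zeros for root)
    tau_plus: np.ndarray     # (27,)
    tau_minus: np.ndarray
    total_mass: float

    @property
    def pub2int(self) -> np.ndarray:
        inv = np.empty_like(self.int2pub)
        inv[self.int2pub] = np.arange(len(self.int2pub))
        return inv


def joint_offsets(model: BodyModel) -> dict[str, np.ndarray]:
    """Position of each joint in its parent segment's frame."""
    g = model.geometry
    w_hip, w_sh = g["hip_half_width"], g["shoulder_half_width"]
    return {
        "lumbar": np.array([0.0, 0.0, g["pelvis_len"]]),
        "shoulder_l": np.array([+w_sh, 0.0, g["trunk_len"]]),
        "shoulder_r": np.array([-w_sh, 0.0, g["trunk_len"]]),
        "elbow_l": np.array([0.0, 0.0, -g["upper_arm_len"]]),
        "elbow_r": np.array([0.0, 0.0, -g["upper_arm_len"]]),
        "hip_l": np.array([+w_hip, 0.0, 0.0]),
        "hip_r": np.array([-w_hip, 0.0, 0.0]),
        "knee_l": np.array([0.0, 0.0, -g["thigh_len"]]),
        "knee_r": np.array([0.0, 0.0, -g["thigh_len"]]),
        "ankle_l": np.array([0.0, 0.0, -g["shank_len"]]),
        "ankle_r": np.array([0.0, 0.0, -g["shank_len"]]),
    }


def model_arrays(model: BodyModel) -> ModelArrays:
    g = model.geometry
    n = 27
    parent = np.full(n, -1, dtype=np.int32)
    jtype = np.zeros(n, dtype=np.int8)
    axis = np.zeros((n, 3))
    p_off = np.zeros((n, 3))
    mass = np.zeros(n)
    com = np.zeros((n, 3))
    inertia = np.zeros((n, 3, 3))
    int2pub = np.zeros(n, dtype=np.int64)

    # root: 3 prismatic + 3 revolute, pelvis inertia on node 5
    for i, ax in enumerate("xyz"):
        parent[i] = i - 1
        jtype[i] = 0
        axis[i] = _AXES[ax]
        int2pub[i] = 21 + i
    for i, ax in enumerate("xyz"):
        parent[3 + i] = 2 + i
        jtype[3 + i] = 1
        axis[3 + i] = _AXES[ax]
        int2pub[3 + i] = 24 + i

    seg_body = {}

    def put_body(idx, seg):
        s = model.segments[seg]
        mass[idx] = s.mass
        com[idx] = s.com_offset
        inertia[idx] = s.inertia
        seg_body[seg] = idx

    put_body(5, "pelvis")

    offsets = joint_offsets(model)

    names = model.dof_names()
    idx = 6
    # internal joint layout order (keeps each kinematic chain contiguous)
    chain_order = ["lumbar", "shoulder_l", "elbow_l", "shoulder_r", "elbow_r",
                   "hip_l", "knee_l", "ankle_l", "hip_r", "knee_r", "ankle_r"]
    parent_body_of = {"lumbar": 5, "hip_l": 5, "hip_r": 5}
    for jname in chain_order:
        jspec = model.joints[jname]
        _, _, pseg, cseg, nd = next(j for j in JOINTS if j[0] == jname)
        pbody = parent_body_of.get(jname, seg_body.get(pseg, 5))
        for d, ax in enumerate(jspec.dof_axes):
            parent[idx] = pbody if d == 0 else idx - 1
            jtype[idx] = 1
            axis[idx] = _AXES[ax]
            if d == 0:
                p_off[idx] = offsets[jname]
            int2pub[idx] = names.index(f"{jname}_{ax}") if nd > 1 else \
                names.index(f"{jname}_{jspec.dof_axes[0]}")
            idx += 1
        put_body(idx - 1, cseg)
    assert idx == 27

    # contact points on the feet
    cp_body, cp_pos = [], []
    for foot in ("foot_l", "foot_r"):
        b = seg_body[foot]
        for p in model.contact_points[foot].points:
            cp_body.append(b)
            cp_pos.append(p)

    # per-internal-DOF joint parameters
    q_min = np.full(n, -np.inf)
    q_max = np.full(n, np.inf)
    passive = np.zeros((n, 3))
    tau_plus = np.zeros(n)
    tau_minus = np.zeros(n)
    dof_table = model.joint_dof_table()
    for i in range(n):
        p = int2pub[i]
        if p < 21:
            q_min[i] = dof_table["q_min"][p]
            q_max[i] = dof_table["q_max"][p]
            passive[i] = (dof_table["pa"][p], dof_table["pb"][p], dof_table["pc"][p])
            tau_plus[i] = dof_table["tau_plus"][p]
            tau_minus[i] = dof_table["tau_minus"][p]

    return ModelArrays(
        parent=parent, jtype=jtype, axis=axis, p_off=p_off,
        mass=mass, com=com, inertia=inertia, int2pub=int2pub,
        seg_body=np.array([seg_body[s] for s in SEGMENTS], dtype=np.int64),
        cp_body=np.array(cp_body, dtype=np.int64), cp_pos=np.array(cp_pos),
        q_min=q_min, q_max=q_max, passive=passive,
        tau_plus=tau_plus, tau_minus=tau_minus,
        total_mass=model.total_mass,
    )
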