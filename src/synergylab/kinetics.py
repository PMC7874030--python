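"""Sagittal-plane joint angles and link-segment inverse dynamics.

The limb is modelled as a planar three-segment chain (foot, shank, thigh)
in the sagittal (x-z) plane, x pointing anteriorly and z up. Joint centers
are taken at the lateral malleolus (ankle), lateral femoral epicondyle
(knee) and greater trochanter (hip). Segment masses, center-of-mass
locations and radii of gyration are expressed as fractions of body mass and
segment length (Winter's anthropometric tables by default, shipped as an
editable config). Resultant joint moments follow a bottom-up Newton-Euler
recursion: ground reaction force applied at the center of pressure, segment
weights at the segment CoM, linear/angular accelerations from zero-phase
low-pass filtered marker data differentiated by central differences.

Sign conventions (right limb, viewed from the right): internal moments are
reported with ankle plantarflexion, knee extension and hip extension
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import LungeCycle, fill_marker_gaps
from .filters import butter_zero_phase, derivative

GRAVITY = 9.81  # m s^-2

#: Winter's anthropometric fractions (literature constants, editable).
#: mass: fraction of body mass; com: CoM distance from the proximal end as a
#: fraction of segment length; gyration: radius of gyration about the CoM as
#: a fraction of segment length.
WINTER_SEGMENTS: dict[str, dict[str, float]] = {
    "foot": {"mass": 0.0145, "com": 0.50, "gyration": 0.475},
    "shank": {"mass": 0.0465, "com": 0.433, "gyration": 0.302},
    "thigh": {"mass": 0.100, "com": 0.433, "gyration": 0.323},
}


@dataclass(frozen=True)
class SegmentParameters:
    """Per-segment inertial fractions for the three-link sagittal model."""

    segments: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in WINTER_SEGMENTS.items()})

    def __post_init__(self) -> None:
        for name in ("foot", "shank", "thigh"):
            if name not in self.segments:
                raise ValueError(f"missing segment {name!r}")
            seg = self.segments[name]
            for key in ("mass", "com", "gyration"):
                if not 0 < seg[key] < 1:
                    raise ValueError(
                        f"{name}.{key} must lie in (0, 1), got {seg[key]}")
        total = sum(s["mass"] for s in self.segments.values())
        if total >= 1:
            raise ValueError("limb segment mass fractions must sum below 1")

    def __getitem__(self, name: str) -> dict[str, float]:
        return self.segments[name]


def _sagittal(points_mm: np.ndarray) -> np.ndarray:
    """(n, 3) mm marker trace -> (n, 2) m sagittal (x, z) coordinates."""
    p = np.asarray(points_mm, dtype=float)
    return p[:, [0, 2]] / 1000.0


def _vec_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pointwise angle (deg) between 2-D vector traces, in [0, 180]."""
    dot = np.sum(u * v, axis=-1)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    c = np.clip(dot / np.maximum(nu * nv, 1e-12), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def joint_angles(markers: dict[str, np.ndarray], max_gap: int = 10
                 ) -> dict[str, np.ndarray]:
    """Sagittal hip, knee and ankle angles (deg) from marker trajectories.

    Conventions: knee = angle at the lateral epicondyle between the
    epicondyle->trochanter and epicondyle->malleolus vectors (180 deg = full
    extension); ankle = angle between the malleolus->epicondyle shank vector
    and the calcaneus->fifth-metatarsal foot axis (90 deg = anatomical
    neutral); hip = inclination of the trochanter->epicondyle thigh vector
    from the downward vertical (0 deg = thigh vertical, positive anterior).
    """
    need = ("greater_trochanter", "lateral_epicondyle", "lateral_malleolus",
            "calcaneus", "fifth_metatarsal")
    missing = [m for m in need if m not in markers]
    if missing:
        raise ValueError(f"missing markers: {missing}")
    pts = {}
    for name in need:
        filled = fill_marker_gaps(markers[name], max_gap=max_gap)
        if np.isnan(filled).any():
            raise ValueError(
                f"marker {name!r} has gaps longer than {max_gap} samples")
        pts[name] = _sagittal(filled)
    troch, epi = pts["greater_trochanter"], pts["lateral_epicondyle"]
    mall, calc = pts["lateral_malleolus"], pts["calcaneus"]
    met5 = pts["fifth_metatarsal"]

    knee = _vec_angle(troch - epi, mall - epi)
    ankle = _vec_angle(epi - mall, met5 - calc)
    thigh_vec = epi - troch  # points distally
    hip = np.degrees(np.arctan2(thigh_vec[:, 0], -thigh_vec[:, 1]))
    return {"hip": hip, "knee": knee, "ankle": ankle}


def knee_flexion_angle(markers: dict[str, np.ndarray], max_gap: int = 10
                       ) -> np.ndarray:
    """Knee flexion (deg): 0 at full extension, growing with flexion."""
    return 180.0 - joint_angles(markers, max_gap=max_gap)["knee"]


def _cross2(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Out-of-plane (about +y) component of r x f for (…, 2) (x, z) vectors."""
    return r[..., 1] * f[..., 0] - r[..., 0] * f[..., 1]


def _segment_inverse(m_seg: float, i_seg: float, com: np.ndarray,
                     a_com: np.ndarray, alpha: np.ndarray,
                     r_prox: np.ndarray, f_dist: np.ndarray,
                     m_dist: np.ndarray, r_dist: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Planar Newton-Euler for one segment.

    f_dist / m_dist: force and free moment applied TO this segment at the
    distal point r_dist (external load or minus the reaction passed up the
    chain). Returns (f_prox, m_prox): force and moment applied to the segment
    at its proximal joint, about +y.
    """
    g = np.array([0.0, -GRAVITY])
    f_prox = m_seg * a_com - m_seg * g - f_dist
    m_prox = (i_seg * alpha - m_dist
              - _cross2(r_dist - com, f_dist)
              - _cross2(r_prox - com, f_prox))
    return f_prox, m_prox


def inverse_dynamics(markers: dict[str, np.ndarray], marker_rate: float,
                     grf: np.ndarray, grf_rate: float,
                     cop: np.ndarray, body_mass: float,
                     cycle: LungeCycle | None = None,
                     params: SegmentParameters | None = None,
                     lpf_cutoff: float | None = 50.0,
                     max_gap: int = 10) -> dict[str, np.ndarray]:
    """Resultant ankle, knee and hip moments (N m) on the kinematic timebase.

    markers in mm; grf (n, 3) in N on the analog timebase with cop (n, 2)
    its sagittal (x, z) application point in m. GRF/CoP are resampled to the
    kinematic rate by index mapping. During unloaded samples (zero GRF) the
    external load is zero (swing). ``cycle`` restricts loading to stance:
    samples before touchdown are treated as unloaded.

    Returns {"ankle", "knee", "hip"} with plantarflexion / extension /
    extension positive, plus the joint angles under key "angles".
    """
    params = params or SegmentParameters()
    need = ("greater_trochanter", "lateral_epicondyle", "lateral_malleolus",
            "calcaneus", "fifth_metatarsal")
    pts = {}
    n = None
    for name in need:
        filled = fill_marker_gaps(markers[name], max_gap=max_gap)
        if np.isnan(filled).any():
            raise ValueError(f"marker {name!r} has unfillable gaps")
        p = _sagittal(filled)
        if lpf_cutoff is not None and p.shape[0] > 15:
            p = butter_zero_phase(p.T, lpf_cutoff, marker_rate).T
        pts[name] = p
        n = p.shape[0]

    grf = np.asarray(grf, dtype=float)
    cop = np.asarray(cop, dtype=float)
    if cop.shape[0] != grf.shape[0]:
        raise ValueError("CoP and GRF must share the analog timebase")
    # analog -> kinematic index mapping (round half up)
    idx = np.minimum(np.floor(np.arange(n) * grf_rate / marker_rate + 0.5
                              ).astype(int), grf.shape[0] - 1)
    f_ext = grf[idx][:, [0, 2]]  # sagittal external force
    cop_k = cop[idx]
    loaded = np.linalg.norm(grf[idx], axis=1) > 0
    if cycle is not None:
        td_kin = cycle.to_rate(marker_rate).touchdown
        loaded &= np.arange(n) >= td_kin
    f_ext = np.where(loaded[:, None], f_ext, 0.0)
    if np.any(loaded & np.isnan(cop_k).any(axis=1)):
        raise ValueError("CoP undefined during loaded samples")
    cop_k = np.where(loaded[:, None], np.nan_to_num(cop_k), 0.0)

    joints = {"ankle": pts["lateral_malleolus"],
              "knee": pts["lateral_epicondyle"],
              "hip": pts["greater_trochanter"]}
    seg_ends = {"foot": (pts["calcaneus"], pts["fifth_metatarsal"],
                         joints["ankle"]),
                "shank": (joints["ankle"], joints["knee"], joints["knee"]),
                "thigh": (joints["knee"], joints["hip"], joints["hip"])}

    moments = {}
    f_dist = f_ext
    m_dist = np.zeros(n)
    r_dist = cop_k
    # foot: proximal end = ankle; CoM on the calcaneus->metatarsal axis
    chain = (("foot", "ankle"), ("shank", "knee"), ("thigh", "hip"))
    for seg_name, joint_name in chain:
        a_end, b_end, prox_joint = seg_ends[seg_name]
        p = params[seg_name]
        length = np.linalg.norm(b_end - a_end, axis=1)
        if np.any(length < 1e-6):
            raise ValueError(f"degenerate (zero-length) segment {seg_name!r}")
        com = a_end + p["com"] * (b_end - a_end)
        m_seg = p["mass"] * body_mass
        i_seg = m_seg * (p["gyration"] * float(np.mean(length))) ** 2
        a_com = derivative(com.T, marker_rate, n=2).T if n > 4 else np.zeros_like(com)
        seg_vec = b_end - a_end
        # atan2 in the (x, z) plane grows about -y; negate for +y convention
        theta = np.unwrap(np.arctan2(seg_vec[:, 1], seg_vec[:, 0]))
        alpha = -derivative(theta, marker_rate, n=2) if n > 4 else np.zeros(n)
        f_prox, m_prox = _segment_inverse(
            m_seg, i_seg, com, a_com, alpha, joints[joint_name],
            f_dist, m_dist, r_dist)
        moments[joint_name] = m_prox
        # action-reaction onto the next segment up
        f_dist = -f_prox
        m_dist = -m_prox
        r_dist = joints[joint_name]

    # sign conventions: plantarflexion (+y) positive at the ankle,
    # extension positive at knee (-y) and hip (+y)
    out = {"ankle": moments["ankle"],
           "knee": -moments["knee"],
           "hip": moments["hip"]}
    out["angles"] = joint_angles(markers, max_gap=max_gap)
    return out


def static_equilibrium_moments(markers: dict[str, np.ndarray],
                               grf_vec: np.ndarray, cop_xz: np.ndarray,
                               body_mass: float,
                               params: SegmentParameters | None = None
                               ) -> dict[str, float]:
    """Static-posture oracle: joint moments by summed force-times-lever.

    Independent of the Newton-Euler recursion: for each joint the internal
    moment balances the external moments of the GRF (at the CoP) and the
    weights of all distal segments. Markers are single-frame (1, 3) or (3,)
    mm positions; grf_vec is the sagittal (x, z) force in N.
    """
    params = params or SegmentParameters()

    def pt(name):
        p = np.asarray(markers[name], dtype=float).reshape(-1, 3)[0]
        return np.array([p[0], p[2]]) / 1000.0

    ankle, knee, hip = (pt("lateral_malleolus"), pt("lateral_epicondyle"),
                        pt("greater_trochanter"))
    calc, met5 = pt("calcaneus"), pt("fifth_metatarsal")
    f = np.asarray(grf_vec, dtype=float)
    cop = np.asarray(cop_xz, dtype=float)
    g = np.array([0.0, -GRAVITY])
    coms = {
        "foot": (calc + params["foot"]["com"] * (met5 - calc),
                 params["foot"]["mass"] * body_mass),
        "shank": (ankle + params["shank"]["com"] * (knee - ankle),
                  params["shank"]["mass"] * body_mass),
        "thigh": (knee + params["thigh"]["com"] * (hip - knee),
                  params["thigh"]["mass"] * body_mass),
    }
    distal = {"ankle": ("foot",), "knee": ("foot", "shank"),
              "hip": ("foot", "shank", "thigh")}
    joints = {"ankle": ankle, "knee": knee, "hip": hip}
    signs = {"ankle": 1.0, "knee": -1.0, "hip": 1.0}
    out = {}
    for joint, segs in distal.items():
        rj = joints[joint]
        ext = _cross2(cop - rj, f)
        for s in segs:
            com, m = coms[s]
            ext += _cross2(com - rj, m * g)
        out[joint] = signs[joint] * (-ext)
    return out
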