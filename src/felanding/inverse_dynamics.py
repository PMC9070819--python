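"""Planar three-link Newton-Euler inverse dynamics of the cat forelimb.

The forelimb is modelled as a chain of three rigid links pinned at the ground
contact point: segment 1 is the distal carpal link that receives the ground
reaction force, segment 2 the forearm and segment 3 the arm.  Given the
measured GRF (anterior/posterior ``F_y`` and vertical ``F_z``) and the segment
angles versus the horizontal, the recursion proceeds distal to proximal:
each segment's proximal reaction force follows from its centre-of-mass (COM)
acceleration, and the moment balance about the COM yields the net joint
moment.  The three proximal moments map to the wrist (segment 1), elbow
(segment 2) and shoulder (segment 3).

With the COM of segment ``i`` at a fraction ``c_i`` of its length from the
distal end (midpoint by default) the pinned-chain COM accelerations expand to

    a_iy = -sum_{k<i} L_k (ad_k^2 cos a_k + add_k sin a_k)
           - c_i L_i (ad_i^2 cos a_i + add_i sin a_i)
    a_iz = +sum_{k<i} L_k (add_k cos a_k - ad_k^2 sin a_k)
           + c_i L_i (add_i cos a_i - ad_i^2 sin a_i)

(``ad`` = angular velocity, ``add`` = angular acceleration), and the force and
moment balances are

    F_iy = F_(i-1)y + m_i a_iy
    F_iz = F_(i-1)z + m_i g + m_i a_iz
    M_i  = M_(i-1) - I_i add_i
           - (1-c_i) L_i sin a_i F_iy + (1-c_i) L_i cos a_i F_iz
           -     c_i L_i sin a_i F_(i-1)y + c_i L_i cos a_i F_(i-1)z

with ``(F_0y, F_0z) = (F_y, F_z)`` the ground force and ``M_0 = 0``.  Moments
are positive in the convention in which gravity on a horizontal static limb
produces a positive wrist moment.

Default segment parameters: masses 0.30 / 1.30 / 2.37 % of body mass and COM
moments of inertia 7.51 / 233.34 / 391.81 g*cm^2 (converted to kg*m^2) for the
carpal link, forearm and arm respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, SignalError
from .signal_prep import time_normalize, N_PHASE_POINTS
from .synthetic import LandingTrial, G

#: body-mass fractions, distal (carpal link) to proximal (arm)
MASS_FRACTIONS = (0.0030, 0.0130, 0.0237)
#: COM moments of inertia in kg*m^2 (7.51, 233.34, 391.81 g*cm^2 * 1e-7)
INERTIAS_KGM2 = (7.51e-7, 233.34e-7, 391.81e-7)


@dataclass(frozen=True)
class SegmentParams:
    """Per-segment mass (kg), length (m), COM inertia (kg*m^2) and COM
    position as a fraction of length from the distal end."""

    masses: tuple[float, float, float]
    lengths: tuple[float, float, float]
    inertias: tuple[float, float, float] = INERTIAS_KGM2
    com_fractions: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self):
        for name in ("masses", "lengths", "inertias"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ConfigurationError(f"{name} must all be positive")
        if any(not 0 < c < 1 for c in self.com_fractions):
            raise ConfigurationError("com_fractions must lie in (0, 1)")

    @classmethod
    def from_body_mass(cls, body_mass: float,
                       lengths: tuple[float, float, float]) -> "SegmentParams":
        if body_mass <= 0:
            raise ConfigurationError("body_mass must be positive")
        return cls(masses=tuple(f * body_mass for f in MASS_FRACTIONS), lengths=tuple(lengths))


@dataclass
class LinkKinematics:
    """Segment angles (rad) with angular velocity and acceleration series."""

    alpha: np.ndarray      # (3, n) segment angles vs horizontal, radians
    alpha_dot: np.ndarray  # (3, n) rad/s
    alpha_ddot: np.ndarray  # (3, n) rad/s^2
    alpha4: np.ndarray | None = None  # shoulder joint angle, radians

    def __post_init__(self):
        if not (self.alpha.shape == self.alpha_dot.shape == self.alpha_ddot.shape):
            raise ConfigurationError("kinematic series must share one shape")
        if self.alpha.shape[0] != 3:
            raise ConfigurationError("expected three segment-angle series")


@dataclass
class JointLoads:
    """Per-sample proximal reaction forces (N) and joint moments (N*m)."""

    reactions_y: np.ndarray  # (3, n): F_1y, F_2y, F_3y
    reactions_z: np.ndarray  # (3, n): F_1z, F_2z, F_3z
    moments: np.ndarray      # (3, n): wrist, elbow, shoulder

    @property
    def wrist(self) -> np.ndarray:
        return self.moments[0]

    @property
    def elbow(self) -> np.ndarray:
        return self.moments[1]

    @property
    def shoulder(self) -> np.ndarray:
        return self.moments[2]


def differentiate_kinematics(angles_rad: np.ndarray, rate: float) -> LinkKinematics:
    """Angular velocity/acceleration by central finite differences
    (second-order one-sided at the boundaries); exact for polynomials of
    degree <= 2 at interior points."""
    angles_rad = np.atleast_2d(np.asarray(angles_rad, dtype=float))
    if angles_rad.shape[1] < 5:
        raise SignalError("differentiation needs at least 5 samples")
    dt = 1.0 / rate
    dot = np.gradient(angles_rad, dt, axis=1, edge_order=2)
    ddot = np.gradient(dot, dt, axis=1, edge_order=2)
    return LinkKinematics(alpha=angles_rad, alpha_dot=dot, alpha_ddot=ddot)


def compute_joint_loads(grf_y: np.ndarray, grf_z: np.ndarray,
                        kin: LinkKinematics, params: SegmentParams,
                        g: float = G) -> JointLoads:
    """Distal-to-proximal Newton-Euler recursion over the three-link chain.

    Returns all intermediate proximal reactions and the wrist, elbow and
    shoulder moments.  Raises :class:`SignalError` naming the first offending
    sample/channel if any input is non-finite.
    """
    grf_y = np.asarray(grf_y, dtype=float)
    grf_z = np.asarray(grf_z, dtype=float)
    n = kin.alpha.shape[1]
    if grf_y.shape != (n,) or grf_z.shape != (n,):
        raise ConfigurationError("GRF series must align with the kinematic series")
    for name, arr in (("grf_y", grf_y), ("grf_z", grf_z),
                      ("alpha", kin.alpha), ("alpha_dot", kin.alpha_dot),
                      ("alpha_ddot", kin.alpha_ddot)):
        bad = ~np.isfinite(arr)
        if bad.any():
            idx = np.argwhere(bad)[0]
            raise SignalError(f"non-finite value in {name} at sample {tuple(idx)}")

    c = np.cos(kin.alpha)
    s = np.sin(kin.alpha)
    w2 = kin.alpha_dot ** 2
    add = kin.alpha_ddot
    L = params.lengths
    cf = params.com_fractions

    # centripetal/tangential building blocks per segment
    ky = w2 * c + add * s          # appears negated in a_y
    kz = add * c - w2 * s          # appears as-is in a_z

    Fy_prev = grf_y
    Fz_prev = grf_z
    M_prev = np.zeros(n)
    Ry = np.empty((3, n))
    Rz = np.empty((3, n))
    M = np.empty((3, n))
    # accumulated full-length terms of the links below the current one
    acc_y = np.zeros(n)
    acc_z = np.zeros(n)
    for i in range(3):
        a_y = -(acc_y + cf[i] * L[i] * ky[i])
        a_z = acc_z + cf[i] * L[i] * kz[i]
        Fy = Fy_prev + params.masses[i] * a_y
        Fz = Fz_prev + params.masses[i] * g + params.masses[i] * a_z
        Mi = (M_prev - params.inertias[i] * add[i]
              - (1 - cf[i]) * L[i] * s[i] * Fy + (1 - cf[i]) * L[i] * c[i] * Fz
              - cf[i] * L[i] * s[i] * Fy_prev + cf[i] * L[i] * c[i] * Fz_prev)
        Ry[i], Rz[i], M[i] = Fy, Fz, Mi
        acc_y = acc_y + L[i] * ky[i]
        acc_z = acc_z + L[i] * kz[i]
        Fy_prev, Fz_prev, M_prev = Fy, Fz, Mi
    return JointLoads(reactions_y=Ry, reactions_z=Rz, moments=M)


def moments_to_trajectories(loads: JointLoads,
                            n_points: int = N_PHASE_POINTS) -> dict[str, np.ndarray]:
    """Time-normalize the three moment series over the landing-phase window;
    order wrist, elbow, shoulder."""
    if loads.moments.shape[1] < 2:
        raise SignalError("landing-phase window shorter than 2 samples")
    return {
        "wrist_moment": time_normalize(loads.wrist, n_points),
        "elbow_moment": time_normalize(loads.elbow, n_points),
        "shoulder_moment": time_normalize(loads.shoulder, n_points),
    }


def trial_joint_loads(trial: LandingTrial, params: SegmentParams | None = None) -> JointLoads:
    """Inverse dynamics of one segmented (landing-phase) trial.

    Angles arrive in degrees at the trial boundary and are converted once
    here.  Segment parameters default to the trial's body mass and lengths.
    """
    if params is None:
        if trial.segment_lengths is None or not np.isfinite(trial.body_mass):
            raise ConfigurationError(
                "trial carries no anthropometry; pass SegmentParams explicitly")
        params = SegmentParams.from_body_mass(trial.body_mass, trial.segment_lengths)
    angles = np.deg2rad(np.vstack([trial.alpha1, trial.alpha2, trial.alpha3]))
    kin = differentiate_kinematics(angles, trial.sample_rate)
    return compute_joint_loads(trial.grf_y, trial.grf_z, kin, params)
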