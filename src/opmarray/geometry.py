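"""Sensor-array data types, rigid poses and geometry-perturbation operators.

Magnetometers are modelled as point sensors: a position, a sensitive axis
(unit vector normal to the sensor base) and a scalar gain.  All positions are
in metres in a common head frame; file formats use millimetres and conversion
happens only at the I/O boundary (:mod:`opmarray.io`).

The perturbation operators implement the geometric-error manipulations used
to probe how sensitive a source-reconstruction model is to mis-specified
sensor geometry:

* :func:`perturb_orientations` -- independent per-sensor rotation errors
  (roll/pitch/yaw about a randomly chosen frame axis),
* :func:`displace_arc` -- rigid displacement of the whole array along an arc
  around the head,
* :func:`apply_gain_error` -- per-channel multiplicative calibration error,
* :func:`apply_pose` -- a rigid transform of the whole array, the
  parameterisation searched by :mod:`opmarray.search`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Sensor",
    "SensorArray",
    "RigidTransform",
    "perturb_orientations",
    "displace_arc",
    "apply_pose",
    "apply_gain_error",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class Sensor:
    """A point magnetometer: position (m), unit sensitive axis, scalar gain."""

    position: np.ndarray
    orientation: np.ndarray
    gain: float = 1.0
    label: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        ori = np.asarray(self.orientation, dtype=float).reshape(3)
        nrm = np.linalg.norm(ori)
        if not np.isfinite(pos).all() or not np.isfinite(ori).all():
            raise ValueError("sensor position/orientation must be finite")
        if abs(nrm - 1.0) > 1e-6:
            if nrm == 0:
                raise ValueError("sensor orientation must be non-zero")
            ori = ori / nrm
        if not self.gain > 0:
            raise ValueError(f"sensor gain must be positive, got {self.gain}")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", ori / np.linalg.norm(ori))
        object.__setattr__(self, "gain", float(self.gain))


@dataclass(frozen=True)
class SensorArray:
    """Ordered collection of :class:`Sensor` sharing a coordinate frame."""

    sensors: tuple[Sensor, ...]
    frame: str = "head"

    def __post_init__(self):
        sensors = tuple(self.sensors)
        if len(sensors) < 1:
            raise ValueError("array must contain at least one sensor")
        labels = [s.label for s in sensors]
        if len(set(labels)) != len(labels):
            raise ValueError("sensor labels must be unique")
        object.__setattr__(self, "sensors", sensors)

    def __len__(self) -> int:
        return len(self.sensors)

    @property
    def n_channels(self) -> int:
        return len(self.sensors)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sensors]

    @property
    def positions(self) -> np.ndarray:
        """(Nc, 3) sensor positions in metres."""
        return np.array([s.position for s in self.sensors])

    @property
    def orientations(self) -> np.ndarray:
        """(Nc, 3) unit sensitive axes."""
        return np.array([s.orientation for s in self.sensors])

    @property
    def gains(self) -> np.ndarray:
        return np.array([s.gain for s in self.sensors])

    def replace_geometry(
        self,
        positions: np.ndarray | None = None,
        orientations: np.ndarray | None = None,
        gains: np.ndarray | None = None,
    ) -> "SensorArray":
        """Return a copy with fields swapped, preserving labels and order."""
        pos = self.positions if positions is None else np.asarray(positions, float)
        ori = self.orientations if orientations is None else np.asarray(orientations, float)
        g = self.gains if gains is None else np.asarray(gains, float)
        sensors = tuple(
            Sensor(p, o, gi, s.label)
            for p, o, gi, s in zip(pos, ori, g, self.sensors)
        )
        return SensorArray(sensors, self.frame)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid body transform: axis-angle rotation (radians) + translation (m)."""

    rotvec: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotvec", np.asarray(self.rotvec, float).reshape(3))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, float).reshape(3)
        )

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_rotvec(self.rotvec)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        r_self, r_other = self.rotation, other.rotation
        r = r_self * r_other
        t = r_self.apply(other.translation) + self.translation
        return RigidTransform(r.as_rotvec(), t)

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.inv()
        return RigidTransform(r_inv.as_rotvec(), -r_inv.apply(self.translation))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def params(self) -> np.ndarray:
        """6-vector (rotvec, translation) used by the pose search."""
        return np.concatenate([self.rotvec, self.translation])

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform":
        params = np.asarray(params, float).reshape(6)
        return cls(params[:3], params[3:])


def perturb_orientations(
    array: SensorArray, angle: float, rng_seed: int
) -> SensorArray:
    """Rotate every sensor's sensitive axis by ``angle`` degrees.

    Each sensor is rotated independently about one of the three head-frame
    axes (x, y or z, i.e. roll, pitch or yaw) chosen uniformly at random; the
    magnitude of the rotation is exactly ``|angle|`` and its sign follows the
    sign of ``angle``.  Positions and gains are untouched.
    """
    if not np.isfinite(angle):
        raise ValueError("perturbation angle must be finite")
    if angle == 0:
        return array
    rng = np.random.default_rng(rng_seed)
    axes_idx = rng.integers(0, 3, size=len(array))
    theta = np.deg2rad(angle)
    ori = array.orientations.copy()
    for i, k in enumerate(axes_idx):
        axis = np.zeros(3)
        axis[k] = 1.0
        ori[i] = Rotation.from_rotvec(theta * axis).apply(ori[i])
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    return array.replace_geometry(orientations=ori)


def displace_arc(
    array: SensorArray,
    arc_mm: float,
    centre: np.ndarray,
    axis: np.ndarray = (1.0, 0.0, 0.0),
) -> SensorArray:
    """Rigidly displace the whole array along an arc about the head centre.

    The array is rotated about the line (``centre``, ``axis``) by the angle
    ``theta = arc / r_mean`` where ``r_mean`` is the mean sensor distance from
    ``centre``, so that ``arc_mm`` is the mean arc length travelled by the
    sensors (in mm).  Orientations co-rotate; relative geometry is preserved.
    """
    centre = np.asarray(centre, float).reshape(3)
    axis = np.asarray(axis, float).reshape(3)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("arc axis must be non-zero")
    if not np.isfinite(centre).all():
        raise ValueError("arc centre must be finite")
    if arc_mm == 0:
        return array
    axis = axis / nrm
    radii = np.linalg.norm(array.positions - centre, axis=1)
    r_mean = float(radii.mean())
    theta = (arc_mm * 1e-3) / r_mean
    rot = Rotation.from_rotvec(theta * axis)
    pos = rot.apply(array.positions - centre) + centre
    ori = rot.apply(array.orientations)
    return array.replace_geometry(positions=pos, orientations=ori)


def apply_pose(
    array: SensorArray, pose: RigidTransform, pivot: np.ndarray = (0.0, 0.0, 0.0)
) -> SensorArray:
    """Apply a rigid transform about ``pivot``: p -> R(p - pivot) + pivot + t."""
    pivot = np.asarray(pivot, float).reshape(3)
    rot = pose.rotation
    pos = rot.apply(array.positions - pivot) + pivot + pose.translation
    ori = rot.apply(array.orientations)
    return array.replace_geometry(positions=pos, orientations=ori)


def apply_gain_error(
    array: SensorArray, fraction: float, rng_seed: int
) -> SensorArray:
    """Multiply each gain by an independent draw from Normal(1, fraction^2).

    ``fraction`` is the standard deviation of the multiplicative calibration
    error (0.05 for 5% gain error).  Draws are fixed by ``rng_seed``.
    """
    if not 0 <= fraction < 1:
        raise ValueError("gain-error fraction must lie in [0, 1)")
    if fraction == 0:
        return array
    rng = np.random.default_rng(rng_seed)
    mult = rng.normal(1.0, fraction, size=len(array))
    # sign flips are not modelled; with fraction < 1 they are vanishingly
    # rare but would violate the positive-gain invariant, so clip.
    mult = np.clip(mult, 1e-6, None)
    return array.replace_geometry(gains=array.gains * mult)
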