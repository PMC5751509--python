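"""Georeferencing and pose utilities.

RTK-GNSS fixes arrive as WGS84 latitude/longitude; all spatial processing
happens in a Cartesian UTM frame, so this module provides the forward
transverse Mercator projection, the meridian-convergence correction needed
to express a true-north compass heading as a UTM grid heading, pose
interpolation along the recorded stream, and the rigid scan-to-global
transform.

The projection is the Karney/Krueger series (6th order in the third
flattening), accurate to well below a millimetre anywhere within a UTM
zone, on the WGS84 ellipsoid with the standard UTM scale factor and false
easting/northing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "GeoCoordinate",
    "UtmCoordinate",
    "Pose",
    "ScanFrame",
    "RigidTransform",
    "wgs84_to_utm",
    "utm_zone",
    "meridian_convergence",
    "correct_heading",
    "interpolate_pose",
    "transform_scan",
]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_SOUTH = 10000000.0

# third flattening and rectifying radius
_N = _F / (2.0 - _F)
_A1 = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

# Krueger alpha coefficients, 6th order in n
_ALPHA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 5.0 * _N**3 / 16.0 + 41.0 * _N**4 / 180.0
    - 127.0 * _N**5 / 288.0 + 7891.0 * _N**6 / 37800.0,
    13.0 * _N**2 / 48.0 - 3.0 * _N**3 / 5.0 + 557.0 * _N**4 / 1440.0
    + 281.0 * _N**5 / 630.0 - 1983433.0 * _N**6 / 1935360.0,
    61.0 * _N**3 / 240.0 - 103.0 * _N**4 / 140.0 + 15061.0 * _N**5 / 26880.0
    + 167603.0 * _N**6 / 181440.0,
    49561.0 * _N**4 / 161280.0 - 179.0 * _N**5 / 168.0
    + 6601661.0 * _N**6 / 7257600.0,
    34729.0 * _N**5 / 80640.0 - 3418889.0 * _N**6 / 1995840.0,
    212378941.0 * _N**6 / 319334400.0,
)


class GeodesyError(ValueError):
    """Raised for coordinates outside the projection's domain."""


@dataclass(frozen=True)
class GeoCoordinate:
    """WGS84 geodetic coordinate; latitude and longitude in radians."""

    lat: float
    lon: float
    altitude: float = 0.0

    def __post_init__(self) -> None:
        if not (abs(self.lat) <= math.pi / 2.0):
            raise GeodesyError(f"latitude {self.lat} rad outside [-pi/2, pi/2]")
        if not (abs(self.lon) <= math.pi):
            raise GeodesyError(f"longitude {self.lon} rad outside [-pi, pi]")

    @classmethod
    def from_degrees(cls, lat_deg: float, lon_deg: float, altitude: float = 0.0) -> "GeoCoordinate":
        return cls(math.radians(lat_deg), math.radians(lon_deg), altitude)


@dataclass(frozen=True)
class UtmCoordinate:
    """Projected UTM coordinate (metres) with zone bookkeeping.

    ``lon_med`` is the zone's central-meridian longitude in radians; for
    zone ``z`` it equals ``(6 z - 183)`` degrees.
    """

    easting: float
    northing: float
    zone: int
    north: bool = True
    altitude: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.zone <= 60):
            raise GeodesyError(f"UTM zone {self.zone} outside 1..60")

    @property
    def lon_med(self) -> float:
        return math.radians(self.zone * 6.0 - 183.0)


def utm_zone(lon: float) -> int:
    """UTM zone number for a longitude in radians (no polar/Norway exceptions)."""
    zone = int(math.floor((math.degrees(lon) + 180.0) / 6.0)) + 1
    return min(max(zone, 1), 60)


def wgs84_to_utm(geo: GeoCoordinate, zone: int | None = None) -> UtmCoordinate:
    """Project a WGS84 coordinate to UTM.

    The zone is derived from the longitude unless ``zone`` overrides it
    (useful to keep a survey spanning a zone boundary in one frame).

    Raises
    ------
    GeodesyError
        For latitudes beyond the UTM domain (|lat| > 84 deg).
    """
    if abs(geo.lat) > math.radians(84.0):
        raise GeodesyError("UTM is undefined for |latitude| > 84 deg; use UPS")
    if zone is None:
        zone = utm_zone(geo.lon)
    lon0 = math.radians(zone * 6.0 - 183.0)
    dlon = geo.lon - lon0

    sphi = math.sin(geo.lat)
    # conformal latitude via the Gauss-Schreiber intermediate
    e = math.sqrt(_F * (2.0 - _F))
    t = math.sinh(math.atanh(sphi) - e * math.atanh(e * sphi))
    xi_p = math.atan2(t, math.cos(dlon))
    eta_p = math.asinh(math.sin(dlon) / math.hypot(t, math.cos(dlon)))

    xi = xi_p
    eta = eta_p
    for j, a in enumerate(_ALPHA, start=1):
        xi += a * math.sin(2.0 * j * xi_p) * math.cosh(2.0 * j * eta_p)
        eta += a * math.cos(2.0 * j * xi_p) * math.sinh(2.0 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _A1 * eta
    northing = _K0 * _A1 * xi
    north = geo.lat >= 0.0
    if not north:
        northing += _FALSE_NORTHING_SOUTH
    return UtmCoordinate(easting, northing, zone, north, geo.altitude)


def meridian_convergence(geo: GeoCoordinate, lon_med: float) -> float:
    """Angle from true north to grid north at ``geo``, in radians.

    gamma = arctan(tan(lon - lon_med) * sin(lat)); positive east of the
    central meridian in the northern hemisphere, where grid north leans
    east of true north.
    """
    dlon = geo.lon - lon_med
    if abs(dlon) >= math.radians(6.0):
        raise GeodesyError("longitude offset from central meridian exceeds 6 deg")
    return math.atan(math.tan(dlon) * math.sin(geo.lat))


def correct_heading(true_north_heading: float, geo: GeoCoordinate, lon_med: float) -> float:
    """Convert a true-north compass heading to a UTM grid heading.

    Grid heading = true heading - meridian convergence, wrapped to
    [0, 2*pi).  East of the central meridian (northern hemisphere) grid
    north lies east of true north, so the grid heading decreases.
    """
    gamma = meridian_convergence(geo, lon_med)
    return (true_north_heading - gamma) % (2.0 * math.pi)


@dataclass
class Pose:
    """Timestamped rigid body pose: position in (relative) UTM metres plus
    an orientation quaternion mapping sensor/base axes into the grid frame."""

    timestamp: float
    position: np.ndarray  # (3,) easting, northing, altitude
    quaternion: np.ndarray  # (4,) scalar-last (x, y, z, w)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.quaternion.shape != (4,):
            raise ValueError("quaternion must be a 4-vector (x, y, z, w)")
        if not math.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")
        norm = float(np.linalg.norm(self.quaternion))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm {norm} != 1")

    @classmethod
    def from_yaw(cls, timestamp: float, position, yaw: float) -> "Pose":
        q = Rotation.from_euler("z", yaw).as_quat()
        return cls(timestamp, np.asarray(position, dtype=float), q)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    @property
    def heading(self) -> float:
        """Grid heading (yaw about +z), wrapped to [0, 2*pi)."""
        yaw = self.rotation.as_euler("zyx")[0]
        return yaw % (2.0 * math.pi)


@dataclass
class ScanFrame:
    """A single LiDAR sweep in the sensor frame."""

    timestamp: float
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("scan contains non-finite points")


@dataclass
class RigidTransform:
    """Sensor-to-base extrinsic calibration (rotation then translation)."""

    rotation: Rotation = field(default_factory=Rotation.identity)
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.rotation.apply(points) + np.asarray(self.translation, dtype=float)


def interpolate_pose(t: float, stream: list[Pose]) -> Pose:
    """Interpolate the pose stream at time ``t``.

    Position is interpolated linearly and orientation spherically (slerp)
    between the bracketing samples; a ``t`` equal to a sample's timestamp
    returns that sample exactly.

    Raises
    ------
    ValueError
        If the stream has fewer than two poses or ``t`` falls outside its
        time span (no extrapolation).
    """
    if len(stream) < 2:
        raise ValueError("pose stream needs at least two samples")
    times = np.array([p.timestamp for p in stream])
    if np.any(np.diff(times) <= 0):
        raise ValueError("pose stream timestamps must be strictly increasing")
    if t < times[0] or t > times[-1]:
        raise ValueError(f"t={t} outside pose stream span [{times[0]}, {times[-1]}]")
    idx = int(np.searchsorted(times, t))
    if times[idx] == t:
        return stream[idx]
    lo, hi = stream[idx - 1], stream[idx]
    w = (t - lo.timestamp) / (hi.timestamp - lo.timestamp)
    pos = (1.0 - w) * lo.position + w * hi.position
    rots = Rotation.from_quat(np.vstack([lo.quaternion, hi.quaternion]))
    q = Slerp([lo.timestamp, hi.timestamp], rots)(t).as_quat()
    return Pose(t, pos, q)


def transform_scan(scan: ScanFrame, pose: Pose, extrinsics: RigidTransform | None = None) -> np.ndarray:
    """Map sensor-frame scan points into the global frame.

    p_global = R_pose (R_ext p + t_ext) + t_pose for every point.  Rigid,
    hence length-preserving.  Returns an (n, 3) array in the pose's frame.
    """
    pts = scan.points
    if extrinsics is not None:
        pts = extrinsics.apply(pts)
    return pose.rotation.apply(pts) + pose.position
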