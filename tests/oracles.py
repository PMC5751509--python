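"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, textbook series,
O(n^2) scans) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np

# -- geodesy: Snyder (1987) transverse Mercator series -----------------------

_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996


def snyder_utm(lat: float, lon: float, zone: int) -> tuple[float, float]:
    """Forward UTM by the classic Snyder series (lat/lon in radians)."""
    lon0 = math.radians(zone * 6.0 - 183.0)
    sin_lat = math.sin(lat)
    cos_lat = math.cos(lat)
    n = _A / math.sqrt(1.0 - _E2 * sin_lat**2)
    t = math.tan(lat) ** 2
    c = _EP2 * cos_lat**2
    a = (lon - lon0) * cos_lat
    m = _A * (
        (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256) * lat
        - (3 * _E2 / 8 + 3 * _E2**2 / 32 + 45 * _E2**3 / 1024) * math.sin(2 * lat)
        + (15 * _E2**2 / 256 + 45 * _E2**3 / 1024) * math.sin(4 * lat)
        - (35 * _E2**3 / 3072) * math.sin(6 * lat)
    )
    x = _K0 * n * (
        a
        + (1 - t + c) * a**3 / 6
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a**5 / 120
    ) + 500000.0
    y = _K0 * (
        m
        + n * math.tan(lat)
        * (
            a**2 / 2
            + (5 - t + 9 * c + 4 * c**2) * a**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a**6 / 720
        )
    )
    return x, y


def convergence_by_finite_difference(lat: float, lon: float, zone: int, dlat: float = 1e-6) -> float:
    """Meridian convergence from the projected meridian's grid bearing.

    Projects two points a small latitude step apart on the same meridian;
    the northward meridian direction (true north) has grid bearing -gamma,
    i.e. east of the central meridian it tilts west of grid north, so the
    convergence (true north -> grid north, positive eastward) is the
    negated bearing.
    """
    x0, y0 = snyder_utm(lat - dlat, lon, zone)
    x1, y1 = snyder_utm(lat + dlat, lon, zone)
    return -math.atan2(x1 - x0, y1 - y0)


# -- point in polygon: winding number ----------------------------------------


def winding_number_contains(point, vertices) -> bool:
    """Winding-number inside test; points on the boundary count as inside."""
    x, y = float(point[0]), float(point[1])
    v = np.asarray(vertices, dtype=float)
    wn = 0
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1)
        # on-segment check
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if y1 <= y:
            if y2 > y and cross > 0:
                wn += 1
        else:
            if y2 <= y and cross < 0:
                wn -= 1
    return wn != 0


# -- statistical outlier removal: exhaustive pairwise ------------------------


def brute_force_outlier_mask(points: np.ndarray, k: int, alpha: float) -> np.ndarray:
    """Keep-mask from the full O(n^2) distance table."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    mean_d = np.sort(d, axis=1)[:, :k].mean(axis=1)
    thresh = mean_d.mean() + alpha * mean_d.std()
    return mean_d <= thresh


# -- hole interpolation: exhaustive synchronous re-scan -----------------------


def fill_oracle(values: np.ndarray, min_valid: int = 6) -> np.ndarray:
    """Iterate the 6-of-8 fill rule with explicit loops until no change.

    Decisions and neighbour means are taken on a snapshot of the grid at
    the start of each sweep (iteration-synchronous semantics).
    """
    vals = np.asarray(values, dtype=float).copy()
    nx, ny = vals.shape
    while True:
        snap = vals.copy()
        changed = False
        for i in range(nx):
            for j in range(ny):
                if not np.isnan(snap[i, j]):
                    continue
                neigh = []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        a, b = i + di, j + dj
                        if 0 <= a < nx and 0 <= b < ny and not np.isnan(snap[a, b]):
                            neigh.append(snap[a, b])
                if len(neigh) >= min_valid:
                    vals[i, j] = sum(neigh) / len(neigh)
                    changed = True
        if not changed:
            return vals


# -- region growing: set-based simulation -------------------------------------


def region_growing_oracle(values: np.ndarray, threshold: float) -> np.ndarray:
    """Simulate the growth rule with plain sets.

    Seed at the global maximum (first in row-major order); repeatedly pick
    the highest undecided frontier candidate (row-major tie-break), join it
    iff within ``threshold`` of the running region mean, else discard it
    permanently; stop when no candidates remain.
    """
    vals = np.asarray(values, dtype=float)
    nx, ny = vals.shape
    valid = ~np.isnan(vals)
    best = None
    for i in range(nx):
        for j in range(ny):
            if valid[i, j] and (best is None or vals[i, j] > vals[best]):
                best = (i, j)
    region = {best}
    total = vals[best]
    candidates: set[tuple[int, int]] = set()
    decided = {best}

    def discover(i, j):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and valid[a, b] and (a, b) not in decided:
                    candidates.add((a, b))

    discover(*best)
    while candidates:
        pick = max(candidates, key=lambda ij: (vals[ij], (-ij[0], -ij[1])))
        candidates.discard(pick)
        decided.add(pick)
        if abs(vals[pick] - total / len(region)) <= threshold:
            region.add(pick)
            total += vals[pick]
            discover(*pick)
    mask = np.zeros(vals.shape, dtype=bool)
    for i, j in region:
        mask[i, j] = True
    return mask


# -- helpers -------------------------------------------------------------------


def random_simple_polygon(rng: np.random.Generator, n_min: int = 4, n_max: int = 9) -> np.ndarray:
    """Random star-shaped polygon around a random centre.

    Angles are jittered from an even spacing so every angular gap stays
    below pi, which (with the centre in the kernel) guarantees a simple
    ring for any radii.
    """
    n = int(rng.integers(n_min, n_max + 1))
    spacing = 2.0 * np.pi / n
    angles = np.arange(n) * spacing + rng.uniform(-0.45, 0.45, size=n) * spacing
    radii = rng.uniform(0.3, 2.0, size=n)
    centre = rng.uniform(-1.0, 1.0, size=2)
    return centre + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
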