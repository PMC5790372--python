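"""Spherical-conductor MEG forward model.

Sensors are ideal point magnetometers on a hemisphere above a
homogeneous conducting sphere; sources are current dipoles on a regular
3-D grid inside it. The field of a dipole in a homogeneous sphere has a
closed form (the classic spherically symmetric conductor solution):
volume currents cancel the field of any radial dipole component, a
dipole at the center is silent, and the measured radial field component
equals that of the primary current dipole alone. These exact properties
make the model its own test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU0_OVER_4PI = 1e-7  # T·m/(A·m)


@dataclass
class SensorArray:
    """Point magnetometers: positions (n x 3, meters) and unit orientations."""

    positions: np.ndarray
    orientations: np.ndarray
    kind: str = "magnetometer"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError("sensor orientations must be unit vectors")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class SourceGrid:
    """Axis-aligned source lattice; ``inside_mask`` marks points inside
    the conductor (strictly, within 0.9 x its radius)."""

    points: np.ndarray
    spacing: float
    inside_mask: np.ndarray

    @property
    def masked_points(self) -> np.ndarray:
        return self.points[self.inside_mask]

    @property
    def n_inside(self) -> int:
        return int(self.inside_mask.sum())

    def shape3d(self) -> tuple[tuple[int, int, int], np.ndarray]:
        """3-D lattice shape and the (i,j,k) index of every point."""
        idx = np.round((self.points - self.points.min(axis=0)) / self.spacing).astype(int)
        return tuple(idx.max(axis=0) + 1), idx

    def nearest_inside(self, pos) -> int:
        """Index (into masked points) of the grid point nearest ``pos``."""
        d = np.linalg.norm(self.masked_points - np.asarray(pos), axis=1)
        return int(np.argmin(d))


@dataclass
class Leadfield:
    """Per-source 3-column field maps: L[s] is n_sensors x 3, the measured
    field of unit dipoles along x/y/z at masked grid point s."""

    L: np.ndarray  # n_sources x n_sensors x 3
    grid: SourceGrid
    sensors: SensorArray
    conductor_center: np.ndarray = None
    conductor_radius: float = 0.09

    @property
    def n_sources(self) -> int:
        return self.L.shape[0]


def make_sensor_array(n: int = 102, radius: float = 0.12) -> SensorArray:
    """~Uniform sensors on the upper hemisphere, radially oriented.

    Uses a Fibonacci lattice restricted to z >= 0; all positions have
    norm ``radius``.
    """
    if n < 3:
        raise ValueError("need at least 3 sensors")
    # Fibonacci sphere over the upper hemisphere: z in (0, 1]
    i = np.arange(n)
    z = 1.0 - i / n  # strictly positive
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(1 - z**2)
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    return SensorArray(positions=radius * pts, orientations=pts.copy())


def make_grid(spacing: float = 0.008, conductor_radius: float = 0.09) -> SourceGrid:
    """Axis-aligned lattice covering the conductor sphere."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    half = int(np.floor(conductor_radius / spacing))
    axis = np.arange(-half, half + 1) * spacing
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    inside = np.linalg.norm(points, axis=1) < 0.9 * conductor_radius
    return SourceGrid(points=points, spacing=spacing, inside_mask=inside)


def dipole_field(r0: np.ndarray, Q: np.ndarray, sensors: SensorArray,
                 center: np.ndarray | None = None) -> np.ndarray:
    """Measured field (T) at each sensor of a current dipole Q (A·m) at r0.

    Closed-form homogeneous-sphere solution, projected onto each
    sensor's orientation.
    """
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    r = sensors.positions - c           # n x 3
    r0 = np.asarray(r0, dtype=float) - c
    Q = np.asarray(Q, dtype=float)

    a_vec = r - r0                      # n x 3
    a = np.linalg.norm(a_vec, axis=1)   # n
    R = np.linalg.norm(r, axis=1)
    if np.any(a == 0):
        raise ValueError("dipole coincides with a sensor")
    Qxr0 = np.cross(Q, r0)              # 3
    if np.allclose(Qxr0, 0):
        return np.zeros(sensors.n_sensors)
    ar = np.einsum("ni,ni->n", a_vec, r)
    r0r = r @ r0
    F = a * (R * a + R**2 - r0r)
    gradF = ((a**2 / R + ar / a + 2 * a + 2 * R)[:, None] * r
             - (a + 2 * R + ar / a)[:, None] * r0[None, :])
    B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * Qxr0[None, :]
                                          - (r @ Qxr0)[:, None] * gradF)
    return np.einsum("ni,ni->n", B, sensors.orientations)


def sphere_leadfield(grid: SourceGrid, sensors: SensorArray,
                     conductor_radius: float = 0.09,
                     center: np.ndarray | None = None) -> Leadfield:
    """Leadfield of unit x/y/z dipoles at every masked grid point.

    A grid point at the sphere center is silent (zero columns) by the
    physics of the model and is returned as zeros.
    """
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    r = sensors.positions - c                       # N x 3
    o = sensors.orientations                        # N x 3
    r0 = grid.masked_points - c                     # S x 3

    a_vec = r[None, :, :] - r0[:, None, :]          # S x N x 3
    a = np.linalg.norm(a_vec, axis=2)               # S x N
    R = np.linalg.norm(r, axis=1)[None, :]          # 1 x N
    ar = np.einsum("sni,ni->sn", a_vec, r)
    r0r = r0 @ r.T                                  # S x N
    F = a * (R * a + R**2 - r0r)
    coef_r = a**2 / R + ar / a + 2 * a + 2 * R
    coef_r0 = a + 2 * R + ar / a
    # gradF · o and r stay per (source, sensor)
    gradF = coef_r[:, :, None] * r[None, :, :] - coef_r0[:, :, None] * r0[:, None, :]
    gFo = np.einsum("sni,ni->sn", gradF, o)

    # C[s, k, :] = e_k x r0[s]: field direction term for unit dipoles
    C = np.cross(np.broadcast_to(np.eye(3), (len(r0), 3, 3)),
                 r0[:, None, :])                    # S x 3 x 3
    Co = np.einsum("ski,ni->snk", C, o)             # S x N x 3
    rC = np.einsum("ski,ni->snk", C, r)             # S x N x 3

    with np.errstate(divide="ignore", invalid="ignore"):
        L = MU0_OVER_4PI / F[:, :, None] ** 2 * (F[:, :, None] * Co
                                                 - rC * gFo[:, :, None])
    # a dipole at the exact center is silent: F -> 0 but C -> 0 too
    L[~np.isfinite(L)] = 0.0
    return Leadfield(L=L, grid=grid, sensors=sensors,
                     conductor_center=np.zeros(3) if center is None else np.asarray(center),
                     conductor_radius=conductor_radius)
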