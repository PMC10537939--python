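"""Sensor arrays, source grids, and the spherical-conductor forward model.

The forward model is the analytic Sarvas solution for a current dipole in a
homogeneous conducting sphere.  Magnetometers measure the field component
along their coil normal; planar gradiometers are modeled as a two-point
finite difference of the normal field at two virtual coils separated by the
gradiometer baseline along the stored orientation, divided by the baseline
length (output in T/m).

Units are SI throughout: meters, Tesla, A·m.  The head frame is right-handed
with the conductor-sphere center at the origin.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import h5py
import numpy as np

logger = logging.getLogger(__name__)

MU0_OVER_4PI = 1e-7  # T·m/(A·m)

#: Baseline separation of the two virtual coils of a planar gradiometer, in
#: meters (Triux-like geometry approximation).
GRADIOMETER_BASELINE = 0.0168

MAGNETOMETER = "magnetometer"
PLANAR_GRADIOMETER = "planar_gradiometer"

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SensorArray:
    """An MEG sensor array.

    Parameters
    ----------
    channel_id : list of str
    position : (M, 3) float array, meters
        Channel locations in the head frame (sphere center at origin).
    orientation : (M, 3) float array
        Unit vectors: the coil normal for magnetometers, the baseline
        direction for planar gradiometers.
    kind : list of str
        Per-channel, ``"magnetometer"`` or ``"planar_gradiometer"``.
    """

    channel_id: list
    position: np.ndarray
    orientation: np.ndarray
    kind: list

    def __post_init__(self):
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        self.orientation = np.atleast_2d(np.asarray(self.orientation, dtype=float))
        M = self.position.shape[0]
        if M < 2:
            raise ValueError("a sensor array needs at least 2 channels")
        if self.orientation.shape != (M, 3) or self.position.shape != (M, 3):
            raise ValueError("position and orientation must both be (M, 3)")
        if len(self.channel_id) != M or len(self.kind) != M:
            raise ValueError("channel_id/kind length must match position rows")
        norms = np.linalg.norm(self.orientation, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("orientation vectors must be unit-norm within 1e-9")
        bad = set(self.kind) - {MAGNETOMETER, PLANAR_GRADIOMETER}
        if bad:
            raise ValueError(f"unknown channel kind(s): {sorted(bad)}")

    @property
    def M(self) -> int:
        return self.position.shape[0]

    def _virtual_coils(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Decompose channels into point-field evaluations.

        Returns (eval_positions, eval_normals, weights, channel_index): the
        channel output is ``sum_j w_j * B(pos_j)·n_j`` over its rows.
        Gradiometer coil normals are taken radial (positions are assumed off
        the origin).
        """
        pos, nrm, wts, idx = [], [], [], []
        for m in range(self.M):
            p = self.position[m]
            o = self.orientation[m]
            if self.kind[m] == MAGNETOMETER:
                pos.append(p)
                nrm.append(o)
                wts.append(1.0)
                idx.append(m)
            else:
                n = p / np.linalg.norm(p)
                half = 0.5 * GRADIOMETER_BASELINE * o
                pos.extend([p + half, p - half])
                nrm.extend([n, n])
                wts.extend([1.0 / GRADIOMETER_BASELINE, -1.0 / GRADIOMETER_BASELINE])
                idx.extend([m, m])
        return (np.asarray(pos), np.asarray(nrm), np.asarray(wts), np.asarray(idx))


@dataclass
class SourceGrid:
    """A set of candidate dipole locations inside the conductor sphere."""

    points: np.ndarray
    spacing: float
    role: str  # "simulation" | "reconstruction"
    conductor_radius: float

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] == 0:
            raise ValueError("empty source grid")
        r = np.linalg.norm(self.points, axis=1)
        if np.any(r >= self.conductor_radius):
            raise ValueError("grid points must lie strictly inside the conductor")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class LeadFieldSet:
    """Per-grid-point lead fields L(p) and optional fixed topographies.

    ``matrix`` has shape (P, M, 3) in Tesla (or T/m for gradiometer rows) per
    A·m of dipole moment.  ``fixed_topographies`` (P, M), when present, holds
    l(p) = L(p) o for the stored per-point ``orientations``.
    """

    grid: SourceGrid
    matrix: np.ndarray
    fixed_topographies: Optional[np.ndarray] = None
    orientations: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 3 or self.matrix.shape[2] != 3:
            raise ValueError("lead-field matrix must be (P, M, 3)")
        if self.matrix.shape[0] != self.grid.n_points:
            raise ValueError("one M×3 block per grid point required")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead-field entries must be finite")

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    @property
    def M(self) -> int:
        return self.matrix.shape[1]

    def save(self, path, units: str = "T per A·m") -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("grid")
            g.create_dataset("points", data=self.grid.points)
            f.create_dataset("leadfield", data=self.matrix)
            f.attrs["units"] = units
            f.attrs["conductor_radius"] = self.grid.conductor_radius
            f.attrs["spacing"] = self.grid.spacing
            f.attrs["role"] = self.grid.role
            if self.fixed_topographies is not None:
                f.create_dataset("fixed_topographies", data=self.fixed_topographies)
                f.create_dataset("orientations", data=self.orientations)

    @classmethod
    def load(cls, path) -> "LeadFieldSet":
        with h5py.File(path, "r") as f:
            grid = SourceGrid(
                points=f["grid/points"][()],
                spacing=float(f.attrs["spacing"]),
                role=str(f.attrs.get("role", "reconstruction")),
                conductor_radius=float(f.attrs["conductor_radius"]),
            )
            lf = cls(grid=grid, matrix=f["leadfield"][()])
            if "fixed_topographies" in f:
                lf.fixed_topographies = f["fixed_topographies"][()]
                lf.orientations = f["orientations"][()]
        return lf


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _sarvas_b(dipoles: np.ndarray, eval_pos: np.ndarray) -> np.ndarray:
    """Magnetic field map of unit dipole moments in a conducting sphere.

    Returns B with shape (P, S, 3, 3): ``B[p, s, i, c]`` is field component
    ``c`` at ``eval_pos[s]`` produced by a unit dipole along axis ``i`` at
    ``dipoles[p]``.  Sphere centered at the origin.
    """
    r0 = np.asarray(dipoles, float)[:, None, :]  # (P,1,3)
    r = np.asarray(eval_pos, float)[None, :, :]  # (1,S,3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)  # (P,S)
    rn = np.linalg.norm(r, axis=-1)  # (1,S)
    r0_dot_r = np.sum(r0 * r, axis=-1)  # (P,S)
    a_dot_r = np.sum(a_vec * r, axis=-1)  # (P,S)
    F = a * (rn * a + rn**2 - r0_dot_r)  # (P,S)
    # gradient of F with respect to the observation point
    c1 = a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + a_dot_r / a
    gradF = c1[..., None] * r - c2[..., None] * r0  # (P,S,3)
    # Q x r0 for unit moments e_i: rows of cross(e_i, r0)
    eye = np.eye(3)
    C = np.cross(eye[None, None, :, :], r0[:, :, None, :])  # (P,1,3,3) -> broadcasts
    C = np.broadcast_to(C, (r0.shape[0], r.shape[1], 3, 3))
    C_dot_r = np.sum(C * r[:, :, None, :], axis=-1)  # (P,S,3)
    B = (
        MU0_OVER_4PI
        / (F**2)[..., None, None]
        * (F[..., None, None] * C - C_dot_r[..., None] * gradF[:, :, None, :])
    )
    return B


def sphere_leadfield(
    point: np.ndarray, array: SensorArray, center: np.ndarray | None = None
) -> np.ndarray:
    """Lead field L(p) of one dipole location: an (M, 3) matrix.

    ``center`` is the conductor-sphere center (defaults to the origin).
    Raises if any sensor lies closer to the center than the dipole (sensors
    must be outside the conductor, the dipole inside).
    """
    return compute_leadfields_points(np.atleast_2d(point), array, center)[0]


def compute_leadfields_points(
    points: np.ndarray, array: SensorArray, center: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized lead fields for many dipole locations: (P, M, 3)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if center is not None:
        points = points - np.asarray(center, float)
        array = replace(
            array, position=array.position - np.asarray(center, float)
        )
    eval_pos, eval_nrm, wts, idx = array._virtual_coils()
    sensor_r = np.linalg.norm(array.position, axis=1)
    dip_r = np.linalg.norm(points, axis=1)
    if np.any(dip_r[:, None] >= sensor_r[None, :]):
        raise ValueError("dipole outside the sensor sphere / conductor")
    B = _sarvas_b(points, eval_pos)  # (P,S,3,3)
    bn = np.einsum("psic,sc->psi", B, eval_nrm)  # normal components
    P = points.shape[0]
    L = np.zeros((P, array.M, 3))
    np.add.at(L, (slice(None), idx), wts[None, :, None] * bn)
    return L


def compute_leadfields(
    grid: SourceGrid, array: SensorArray, center: np.ndarray | None = None
) -> LeadFieldSet:
    """Lead fields for every grid point, as a :class:`LeadFieldSet`."""
    if np.any(np.linalg.norm(array.position, axis=1) <= grid.conductor_radius):
        raise ValueError("sensors must lie strictly outside the conductor sphere")
    return LeadFieldSet(grid=grid, matrix=compute_leadfields_points(grid.points, array, center))


def topographies(lf: LeadFieldSet, orientations: np.ndarray) -> LeadFieldSet:
    """Store fixed topographies l(p) = L(p) o on the lead-field set.

    ``orientations`` is (P, 3), unit-norm per row.
    """
    orientations = np.atleast_2d(np.asarray(orientations, float))
    if orientations.shape != (lf.n_points, 3):
        raise ValueError("need one orientation per grid point")
    norms = np.linalg.norm(orientations, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise ValueError("orientations must be unit-norm")
    lf.fixed_topographies = np.einsum("pmi,pi->pm", lf.matrix, orientations)
    lf.orientations = orientations.copy()
    return lf


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------


def build_grid_pair(
    radius: float, spacing: float, conductor_radius: float | None = None
) -> Tuple[SourceGrid, SourceGrid]:
    """Disjoint simulation/reconstruction grid pair inside a sphere.

    The reconstruction grid is a regular cubic lattice at ``spacing``; the
    simulation grid is the same lattice shifted by half the spacing along
    each axis, so the grids share no point (the nearest cross-grid neighbor
    sits at sqrt(3)/2 of the spacing).  Returns ``(simulation,
    reconstruction)``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if radius <= spacing:
        raise ValueError("radius must exceed spacing")
    if conductor_radius is None:
        conductor_radius = radius * (1 + 1e-9)

    def _lattice(offset: float) -> np.ndarray:
        n = int(np.floor(radius / spacing)) + 1
        coords = spacing * (np.arange(-n, n + 1) + offset)
        X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        keep = np.linalg.norm(pts, axis=1) < radius
        return pts[keep]

    recon_pts = _lattice(0.0)
    sim_pts = _lattice(0.5)
    if recon_pts.shape[0] == 0 or sim_pts.shape[0] == 0:
        raise ValueError("radius too small: empty grid")
    sim = SourceGrid(sim_pts, spacing, "simulation", conductor_radius)
    recon = SourceGrid(recon_pts, spacing, "reconstruction", conductor_radius)
    return sim, recon


def translate_grid(grid: SourceGrid, offset: np.ndarray) -> SourceGrid:
    """Shift all grid points by ``offset`` (meters), dropping any point the
    translation pushes outside the conductor (with a logged warning).

    Used on the reconstruction grid, before lead-field computation, to
    emulate head-registration error.
    """
    offset = np.asarray(offset, dtype=float)
    pts = grid.points + offset[None, :]
    keep = np.linalg.norm(pts, axis=1) < grid.conductor_radius
    n_drop = int(np.sum(~keep))
    if n_drop:
        logger.warning(
            "translate_grid: %d point(s) pushed outside the conductor were dropped",
            n_drop,
        )
    if not np.any(keep):
        raise ValueError("translation left no points inside the conductor")
    return SourceGrid(pts[keep], grid.spacing, grid.role, grid.conductor_radius)


# ---------------------------------------------------------------------------
# synthetic arrays and CSV I/O
# ---------------------------------------------------------------------------


def synthetic_array(
    n_positions: int = 102,
    include_gradiometers: bool = True,
    radius: float = 0.12,
    cap_cos_min: float = -0.15,
) -> SensorArray:
    """Triux-like synthetic array on a spherical cap.

    ``n_positions`` magnetometer sites are laid out with a regular Fibonacci
    spiral on the cap ``{z/r > cap_cos_min}`` of a sphere of ``radius``
    meters.  With ``include_gradiometers`` each site also carries two
    orthogonal planar gradiometers (M = 3 * n_positions, e.g. 306); without,
    M = n_positions (decimated variants, e.g. 32 or 64 magnetometers).
    """
    i = np.arange(n_positions)
    z = cap_cos_min + (1.0 - cap_cos_min) * (i + 0.5) / n_positions
    phi = _GOLDEN_ANGLE * i
    s = np.sqrt(1.0 - z**2)
    unit = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    pos = radius * unit

    # tangent frame per site (for gradiometer baselines)
    ref = np.where(np.abs(unit[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(ref, unit)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(unit, e1)

    ids, p, o, kind = [], [], [], []
    for j in range(n_positions):
        ids.append(f"MAG{j:04d}")
        p.append(pos[j])
        o.append(unit[j])
        kind.append(MAGNETOMETER)
        if include_gradiometers:
            for axis, tang in (("A", e1[j]), ("B", e2[j])):
                ids.append(f"GRD{j:04d}{axis}")
                p.append(pos[j])
                o.append(tang)
                kind.append(PLANAR_GRADIOMETER)
    return SensorArray(ids, np.asarray(p), np.asarray(o), kind)


def save_sensor_csv(array: SensorArray, path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["channel_id", "x", "y", "z", "ox", "oy", "oz", "kind"])
        for m in range(array.M):
            w.writerow(
                [array.channel_id[m], *array.position[m], *array.orientation[m], array.kind[m]]
            )


def load_sensor_csv(path) -> SensorArray:
    ids, pos, ori, kind = [], [], [], []
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            ids.append(row["channel_id"])
            pos.append([float(row[c]) for c in ("x", "y", "z")])
            ori.append([float(row[c]) for c in ("ox", "oy", "oz")])
            kind.append(row["kind"])
    return SensorArray(ids, np.asarray(pos), np.asarray(ori), kind)
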