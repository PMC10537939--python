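"""Forward model and grid machinery.

The spherical-conductor forward solution is validated against an independent
numeric oracle: the Geselowitz surface integral evaluated on a densely
triangulated sphere, with the surface potential obtained by a spherical-
harmonic Neumann solve of the volume-conduction problem.
"""

import numpy as np
import pytest
import trimesh
from numpy.polynomial.legendre import leggauss

import megenum as mg
from megenum.geometry import GRADIOMETER_BASELINE, MAGNETOMETER

MU0_4PI = 1e-7


# ---------------------------------------------------------------------------
# Geselowitz oracle (test-only, independent of the Sarvas implementation)
# ---------------------------------------------------------------------------


def _v_inf(x, r0, q):
    d = x - r0
    dn = np.linalg.norm(d, axis=-1)
    return np.sum(q * d, axis=-1) / (4 * np.pi * dn**3)


def _grad_v_inf(x, r0, q):
    d = x - r0
    dn = np.linalg.norm(d, axis=-1, keepdims=True)
    return q / (4 * np.pi * dn**3) - 3 * np.sum(q * d, axis=-1, keepdims=True) * d / (
        4 * np.pi * dn**5
    )


def _surface_potential(face_centers, R, r0, q, nmax=50, n_gl=80, n_phi=160):
    """Potential on the sphere surface: infinite-medium term plus the interior
    harmonic correction enforcing the insulating (Neumann) boundary."""
    mu, glw = leggauss(n_gl)
    phi = 2 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    st = np.sqrt(1 - mu**2)
    yhat = np.stack(
        np.broadcast_arrays(
            st[:, None] * np.cos(phi)[None, :],
            st[:, None] * np.sin(phi)[None, :],
            np.broadcast_to(mu[:, None], (n_gl, n_phi)),
        ),
        axis=-1,
    ).reshape(-1, 3)
    w = np.repeat(glw, n_phi) * (2 * np.pi / n_phi)
    g = np.sum(_grad_v_inf(R * yhat, r0, q) * yhat, axis=-1)  # dV_inf/dr at R
    fc_hat = face_centers / np.linalg.norm(face_centers, axis=1, keepdims=True)
    Vc = np.zeros(len(fc_hat))
    for a in range(0, len(fc_hat), 1024):
        t = fc_hat[a : a + 1024] @ yhat.T
        Pnm1 = np.ones_like(t)
        Pn = t
        kern = -R * 3 / (4 * np.pi) * Pn
        for n in range(2, nmax + 1):
            Pnp = ((2 * n - 1) * t * Pn - (n - 1) * Pnm1) / n
            Pnm1, Pn = Pn, Pnp
            kern += -R * (2 * n + 1) / (4 * np.pi * n) * Pn
        Vc[a : a + 1024] = kern @ (w * g)
    return _v_inf(face_centers, r0, q) + Vc


def _geselowitz_b(sensors, mesh, V_faces, r0, q):
    fc = mesh.triangles_center
    fn = mesh.face_normals
    fa = mesh.area_faces
    out = []
    for r in sensors:
        B0 = MU0_4PI * np.cross(q, r - r0) / np.linalg.norm(r - r0) ** 3
        d = r - fc
        integ = np.sum(
            (V_faces * fa)[:, None] * np.cross(fn, d) / np.linalg.norm(d, axis=1, keepdims=True) ** 3,
            axis=0,
        )
        out.append(B0 - MU0_4PI * integ)
    return np.asarray(out)


def test_sarvas_against_geselowitz_surface_integral():
    """Tangential dipole at 4 cm: analytic field matches the boundary-integral
    oracle to better than 1%."""
    R = 0.07
    r0 = np.array([0.04, 0.0, 0.0])
    q = np.array([0.0, 1e-8, 0.0])  # tangential moment, A·m
    rng = np.random.default_rng(0)
    sens_pos = rng.standard_normal((16, 3))
    sens_pos = 0.12 * sens_pos / np.linalg.norm(sens_pos, axis=1, keepdims=True)
    normals = sens_pos / 0.12
    array = mg.SensorArray(
        [f"m{i}" for i in range(16)], sens_pos, normals, [MAGNETOMETER] * 16
    )
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=R)
    V = _surface_potential(mesh.triangles_center, R, r0, q)
    B_oracle = np.sum(_geselowitz_b(sens_pos, mesh, V, r0, q) * normals, axis=1)
    B_sarvas = mg.sphere_leadfield(r0, array) @ q
    assert np.linalg.norm(B_sarvas - B_oracle) < 0.01 * np.linalg.norm(B_oracle)


# ---------------------------------------------------------------------------
# forward-model properties
# ---------------------------------------------------------------------------


def test_radial_dipole_is_silent(small_array):
    p = np.array([0.02, -0.01, 0.03])
    L = mg.sphere_leadfield(p, small_array)
    radial = p / np.linalg.norm(p)
    assert np.linalg.norm(L @ radial) < 1e-12 * np.linalg.norm(L)


def test_leadfield_rotation_invariance(small_array):
    """Rotating sensors, source, and moment jointly leaves measurements
    unchanged (magnetometer sub-array)."""
    theta = 0.7
    Rz = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    p = np.array([0.01, 0.025, 0.02])
    o = np.array([0.3, -0.5, 0.2])
    o = o - (o @ p) * p / (p @ p)
    o /= np.linalg.norm(o)
    rotated = mg.SensorArray(
        small_array.channel_id,
        small_array.position @ Rz.T,
        small_array.orientation @ Rz.T,
        small_array.kind,
    )
    b1 = mg.sphere_leadfield(p, small_array) @ o
    b2 = mg.sphere_leadfield(Rz @ p, rotated) @ (Rz @ o)
    np.testing.assert_allclose(b2, b1, rtol=1e-8)


def test_gradiometer_is_finite_difference_of_field():
    arr = mg.synthetic_array(8, include_gradiometers=True)
    grad_rows = [i for i, k in enumerate(arr.kind) if k != MAGNETOMETER]
    i = grad_rows[0]
    p_dip = np.array([0.0, 0.02, 0.03])
    L = mg.sphere_leadfield(p_dip, arr)
    # reconstruct the same channel from two virtual magnetometers
    pos, d = arr.position[i], arr.orientation[i]
    n = pos / np.linalg.norm(pos)
    half = 0.5 * GRADIOMETER_BASELINE * d
    va = mg.SensorArray(
        ["a", "b"], np.array([pos + half, pos - half]), np.array([n, n]), [MAGNETOMETER] * 2
    )
    Lv = mg.compute_leadfields_points(p_dip[None], va)[0]
    np.testing.assert_allclose(L[i], (Lv[0] - Lv[1]) / GRADIOMETER_BASELINE, rtol=1e-12)


def test_dipole_outside_conductor_errors(small_array):
    with pytest.raises(ValueError):
        mg.sphere_leadfield(np.array([0.2, 0.0, 0.0]), small_array)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------


def test_grid_pair_disjoint_and_lattice_distance(grid_pair):
    sim, recon = grid_pair
    d = np.linalg.norm(sim.points[:, None] - recon.points[None, :], axis=-1)
    nearest = d.min(axis=1)
    lattice = np.sqrt(3) / 2 * sim.spacing
    assert nearest.min() > 0
    assert np.all(nearest >= lattice - 1e-12)
    assert np.isclose(nearest.min(), lattice)


def test_grid_pair_count_matches_bruteforce():
    """Paper-scale lattice (64.5 mm sphere, 2.5 mm spacing) against an
    independent integer-triple enumeration."""
    sim, recon = mg.build_grid_pair(0.0645, 0.0025)
    n = int(np.floor(0.0645 / 0.0025)) + 1
    count = 0
    r2 = (0.0645 / 0.0025) ** 2
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            # count k with i^2+j^2+k^2 < r^2 directly
            rem = r2 - i * i - j * j
            if rem > 0:
                count += 2 * int(np.ceil(np.sqrt(rem)) - 1) + 1
    assert recon.n_points == count


def test_grid_pair_deterministic():
    a = mg.build_grid_pair(0.05, 0.01)
    b = mg.build_grid_pair(0.05, 0.01)
    np.testing.assert_array_equal(a[0].points, b[0].points)
    np.testing.assert_array_equal(a[1].points, b[1].points)


def test_translate_grid_identity_inverse_and_drop(grid_pair, caplog):
    sim, _ = grid_pair
    same = mg.translate_grid(sim, np.zeros(3))
    np.testing.assert_array_equal(same.points, sim.points)
    there = mg.translate_grid(sim, np.array([1e-3, 0, 0]))
    back = mg.translate_grid(there, np.array([-1e-3, 0, 0]))
    # points that survived both shifts recover their original coordinates
    assert back.n_points <= sim.n_points
    d = np.linalg.norm(back.points[:, None] - sim.points[None, :], axis=-1).min(axis=1)
    assert d.max() < 1e-12
    # a large shift drops points with a logged warning
    import logging

    with caplog.at_level(logging.WARNING, logger="megenum.geometry"):
        shifted = mg.translate_grid(sim, np.array([0.01, 0, 0]))
    assert shifted.n_points < sim.n_points
    assert any("dropped" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# topographies and I/O
# ---------------------------------------------------------------------------


def test_topographies_match_direct_product(leadfields):
    _, lf = leadfields
    rng = np.random.default_rng(5)
    o = rng.standard_normal((lf.n_points, 3))
    o /= np.linalg.norm(o, axis=1, keepdims=True)
    mg.topographies(lf, o)
    expected = np.stack([lf.matrix[p] @ o[p] for p in range(lf.n_points)])
    np.testing.assert_allclose(lf.fixed_topographies, expected, atol=0)
    # axis-aligned orientation selects a column; sign flip negates
    e0 = np.tile([1.0, 0.0, 0.0], (lf.n_points, 1))
    mg.topographies(lf, e0)
    np.testing.assert_array_equal(lf.fixed_topographies, lf.matrix[:, :, 0])
    mg.topographies(lf, -e0)
    np.testing.assert_array_equal(lf.fixed_topographies, -lf.matrix[:, :, 0])
    with pytest.raises(ValueError):
        mg.topographies(lf, 2.0 * e0)


def test_sensor_csv_roundtrip(tmp_path, small_array):
    path = tmp_path / "sensors.csv"
    mg.geometry.save_sensor_csv(small_array, path)
    back = mg.geometry.load_sensor_csv(path)
    np.testing.assert_allclose(back.position, small_array.position)
    np.testing.assert_allclose(back.orientation, small_array.orientation)
    assert back.kind == small_array.kind


def test_leadfield_hdf5_roundtrip(tmp_path, leadfields):
    _, lf = leadfields
    path = tmp_path / "lf.h5"
    lf.save(path)
    back = mg.LeadFieldSet.load(path)
    np.testing.assert_array_equal(back.matrix, lf.matrix)
    np.testing.assert_array_equal(back.grid.points, lf.grid.points)
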