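"""Encoding operators: trajectories, NUFFT accuracy, adjoint identities."""

import numpy as np
import pytest

from mcgre import (
    EncodingOperator,
    cartesian_full_trajectory,
    density_compensation,
    golden_angle_radial_trajectory,
    make_coil_maps,
    nufft_adjoint,
    nufft_forward,
)

from conftest import direct_ndft


def test_golden_angle_azimuths():
    traj = golden_angle_radial_trajectory(3, 8)
    ends = traj.coords[:, -1, :]
    az = np.degrees(np.arctan2(ends[:, 1], ends[:, 0])) % 360
    np.testing.assert_allclose(az, [0.0, 111.24611797, 222.49223595], atol=1e-6)


def test_radial_profile_ramp_and_linear():
    traj = golden_angle_radial_trajectory(1, 64, ramp_fraction=0.0)
    r = np.linalg.norm(traj.coords[0], axis=-1)
    np.testing.assert_allclose(np.diff(r), np.diff(r)[0], atol=1e-12)  # equal spacing
    assert r[0] == 0 and r[-1] == pytest.approx(0.5)

    frac = 0.4
    traj = golden_angle_radial_trajectory(1, 101, ramp_fraction=frac)
    r = np.linalg.norm(traj.coords[0], axis=-1)
    s = np.arange(101) / 100
    ramp = s <= frac
    # quadratic on the ramp: r/s^2 constant
    quad = r[ramp][1:] / s[ramp][1:] ** 2
    np.testing.assert_allclose(quad, quad[0], rtol=1e-9)
    # slope continuous at the junction and linear afterwards
    slopes = np.diff(r) / np.diff(s)
    after = slopes[np.nonzero(~ramp[1:])[0]]
    np.testing.assert_allclose(after, after[0], rtol=1e-9)
    assert r[-1] == pytest.approx(0.5)


@pytest.mark.parametrize("ndim", [2, 3])
def test_golden_angle_nesting(ndim):
    small = golden_angle_radial_trajectory(10, 16, 0.2, ndim=ndim)
    large = golden_angle_radial_trajectory(40, 16, 0.2, ndim=ndim)
    assert np.array_equal(large.coords[:10], small.coords)


def test_3d_directions_unit_norm():
    traj = golden_angle_radial_trajectory(100, 8, ndim=3)
    ends = traj.coords[:, -1, :]
    np.testing.assert_allclose(np.linalg.norm(ends, axis=1), 0.5, atol=1e-12)


def test_cartesian_forward_matches_direct_dft():
    rng = np.random.default_rng(0)
    img = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
    traj = cartesian_full_trajectory((32, 32))
    coils = make_coil_maps((32, 32), 1, uniform=True)
    y = EncodingOperator(coils, traj).forward(img)[0]
    oracle = direct_ndft(img, traj.flat)
    assert np.max(np.abs(y - oracle)) / np.max(np.abs(oracle)) < 1e-10


@pytest.mark.parametrize("ndim,shape", [(2, (32, 32)), (3, (16, 16, 16))])
def test_nufft_matches_direct_ndft(ndim, shape):
    rng = np.random.default_rng(1)
    img = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    traj = golden_angle_radial_trajectory(30, shape[0], 0.3, ndim=ndim)
    y = nufft_forward(img, traj.flat)
    oracle = direct_ndft(img, traj.flat)
    assert np.linalg.norm(y - oracle) / np.linalg.norm(oracle) < 1e-6


def test_delta_image_gives_flat_spectrum():
    img = np.zeros((32, 32), dtype=complex)
    img[16, 16] = 1.0  # FOV-center voxel
    traj = golden_angle_radial_trajectory(10, 32, 0.2)
    y = nufft_forward(img, traj.flat) * np.sqrt(img.size)
    np.testing.assert_allclose(y, 1.0, atol=1e-6)


def test_zero_image_zero_samples():
    traj = golden_angle_radial_trajectory(4, 16)
    assert not nufft_forward(np.zeros((16, 16)), traj.flat).any()


@pytest.mark.parametrize(
    "mode,ndim,n_coils",
    [
        ("cartesian_full", 2, 1),
        ("cartesian_full", 2, 4),
        ("radial_golden", 2, 1),
        ("radial_golden", 2, 4),
        ("radial_golden", 3, 2),
    ],
)
def test_adjoint_identity_matrix(mode, ndim, n_coils):
    shape = (24,) * ndim
    if mode == "cartesian_full":
        traj = cartesian_full_trajectory(shape)
    else:
        traj = golden_angle_radial_trajectory(20, 24, 0.25, ndim=ndim)
    coils = make_coil_maps(shape, n_coils, seed=3)
    A = EncodingOperator(coils, traj)
    rng = np.random.default_rng(4)
    u = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    y = rng.normal(size=A.out_shape) + 1j * rng.normal(size=A.out_shape)
    lhs = np.vdot(y, A.forward(u))
    rhs = np.vdot(A.adjoint(y), u)
    assert abs(lhs - rhs) / abs(lhs) < 1e-6
    # normal operator positive semidefinite
    assert np.vdot(u, A.normal(u)).real >= 0


def test_cartesian_roundtrip_identity():
    shape = (32, 32)
    coils = make_coil_maps(shape, 1, uniform=True)
    A = EncodingOperator(coils, cartesian_full_trajectory(shape))
    rng = np.random.default_rng(5)
    u = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    np.testing.assert_allclose(A.adjoint(A.forward(u)), u, atol=1e-10)


def test_density_compensated_adjoint_recovers_disk():
    shape = (48, 48)
    xs = np.linspace(-1, 1, 48)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    disk = ((X**2 + Y**2) < 0.4).astype(complex)
    traj = golden_angle_radial_trajectory(160, 48, 0.25)  # ~2x angular oversampling
    coils = make_coil_maps(shape, 1, uniform=True)
    A = EncodingOperator(coils, traj)
    y = A.forward(disk)
    recon = A.adjoint(y, density_weights=density_compensation(traj))
    corr = np.abs(np.vdot(recon, disk)) / (np.linalg.norm(recon) * np.linalg.norm(disk))
    assert corr > 0.95


def test_shape_mismatch_rejected():
    coils = make_coil_maps((32, 32), 2, seed=0)
    traj = golden_angle_radial_trajectory(4, 16)
    A = EncodingOperator(coils, traj)
    with pytest.raises(ValueError):
        A.forward(np.zeros((16, 16)))
    with pytest.raises(ValueError):
        EncodingOperator(coils, golden_angle_radial_trajectory(4, 16, ndim=3))


def test_trajectory_bounds_enforced():
    from mcgre import Trajectory

    with pytest.raises(ValueError):
        Trajectory(coords=np.array([[0.7, 0.0]]), mode="radial_golden")
    with pytest.raises(ValueError):
        Trajectory(coords=np.zeros((1, 2)), mode="spiral")
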