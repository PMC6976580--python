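"""Trajectory data model, PAS extraction, decomposition, correlations."""

import numpy as np
import pytest

from cwesr import quat
from cwesr.synthetic_motion import IsotropicDiffusion, brownian_rotation
from cwesr.trajectory_ops import (
    AngleSeries,
    DecomposedTrajectory,
    OrientationTrajectory,
    compose,
    decompose,
    dihedral_gamma,
    estimate_tau_rot,
    extract_pas,
    order_parameter,
    p2_axis_correlation,
    p2_correlation,
    rescale_tumbling,
    superposition_rotation,
)

from conftest import random_unit_quaternions


# ----------------------------------------------------------------------
# quaternion primitives
# ----------------------------------------------------------------------
def test_quaternion_roundtrips(rng):
    v = rng.normal(size=(500, 3)) * 2.0
    q = quat.from_rotvec(v)
    assert np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-12)
    m = quat.to_matrix(q)
    q2 = quat.from_matrix(m)
    # double cover: q and -q are the same rotation
    same = np.minimum(np.abs(q - q2).max(axis=1), np.abs(q + q2).max(axis=1))
    assert same.max() < 1e-12
    back = quat.to_rotvec(q)
    angles = np.linalg.norm(v, axis=1)
    wrapped = angles <= np.pi
    assert np.allclose(back[wrapped], v[wrapped], atol=1e-10)


def test_quaternion_composition_matches_matrices(rng):
    a = random_unit_quaternions(rng, 20)
    b = random_unit_quaternions(rng, 20)
    lhs = quat.to_matrix(quat.qmul(a, b))
    rhs = quat.to_matrix(a) @ quat.to_matrix(b)
    assert np.abs(lhs - rhs).max() < 1e-13


def test_cumulative_product_matches_sequential(rng):
    steps = quat.from_rotvec(rng.normal(size=(257, 3)) * 0.1)
    scan = quat.cumulative_product(steps)
    ref = steps[0]
    for k in range(1, len(steps)):
        ref = quat.qmul(ref, steps[k])
    assert np.abs(scan[-1] - ref).max() < 1e-12


# ----------------------------------------------------------------------
# data model
# ----------------------------------------------------------------------
def test_trajectory_validation(rng):
    with pytest.raises(ValueError):
        OrientationTrajectory(np.ones((1, 4)))
    with pytest.raises(ValueError, match="unit"):
        OrientationTrajectory(np.full((5, 4), 0.7))
    q = random_unit_quaternions(rng, 10)
    q[3] *= -1.0  # sign flip must be healed on load
    traj = OrientationTrajectory(q)
    dots = np.sum(traj.quats[:-1] * traj.quats[1:], axis=1)
    assert (dots >= 0).all()


def test_angle_series_wrapping():
    s = AngleSeries(values_deg=[190.0, -181.0, 180.0, 540.0])
    assert np.allclose(s.values_deg, [-170.0, 179.0, 180.0, 180.0])


# ----------------------------------------------------------------------
# PAS extraction
# ----------------------------------------------------------------------
def _ring_coords(n_frames=1):
    # N at origin, O along +x, ring carbons in the xy-plane
    n = np.zeros((n_frames, 3))
    o = np.tile([1.3, 0.0, 0.0], (n_frames, 1))
    c1 = np.tile([-0.7, 1.2, 0.0], (n_frames, 1))
    c2 = np.tile([-0.7, -1.2, 0.0], (n_frames, 1))
    return n, o, c1, c2


def test_extract_pas_identity():
    """NO along lab x, ring in the xy-plane -> identity rotation."""
    traj = extract_pas(*_ring_coords(3))
    # orientation equality up to double cover
    assert min(np.abs(traj.quats[0] - quat.identity()).max(),
               np.abs(traj.quats[0] + quat.identity()).max()) < 1e-12


def test_extract_pas_known_rotation(rng):
    n, o, c1, c2 = _ring_coords(4)
    qstar = quat.qnormalize(rng.normal(size=4))
    rot = lambda x: quat.qrotate(qstar[None, :], x)
    traj = extract_pas(rot(n), rot(o), rot(c1), rot(c2))
    assert min(np.abs(traj.quats[0] - qstar).max(),
               np.abs(traj.quats[0] + qstar).max()) < 1e-10


def test_extract_pas_colinear_error():
    n = np.zeros((2, 3))
    o = np.tile([1.0, 0.0, 0.0], (2, 1))
    c1 = np.tile([0.5, 0.0, 0.0], (2, 1))
    c2 = np.tile([2.0, 0.0, 0.0], (2, 1))
    with pytest.raises(ValueError, match="frame 0"):
        extract_pas(n, o, c1, c2)


# ----------------------------------------------------------------------
# decomposition and rescaling
# ----------------------------------------------------------------------
def test_decompose_rigid_body(rng):
    """Pure rigid-body motion -> constant internal part."""
    ref = rng.normal(size=(6, 3))
    glob = brownian_rotation(IsotropicDiffusion(0.5), 200, 1.0, seed=3)
    refc = ref - ref.mean(axis=0)
    coords = quat.qrotate(glob.quats[:, None, :], refc[None, :, :])
    full = OrientationTrajectory(glob.quats.copy())
    dec = decompose(full, coords, ref)
    spread = np.abs(dec.internal_part.quats - dec.internal_part.quats[0]).max()
    assert spread < 1e-9
    # recovered global matches the generator ground truth (up to sign)
    dq = quat.qmul(quat.qconj(dec.global_part.quats), glob.quats)
    assert np.abs(np.abs(dq[:, 0]) - 1.0).max() < 1e-9


def test_superposition_needs_noncolinear_atoms():
    ref = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    with pytest.raises(ValueError, match="colinear"):
        superposition_rotation(np.tile(ref, (3, 1, 1)), ref)


def test_compose_decompose_roundtrip(rng):
    g = brownian_rotation(IsotropicDiffusion(1.0), 300, 1.0, seed=5)
    r = brownian_rotation(IsotropicDiffusion(0.3), 300, 1.0, seed=6)
    dec = compose(g, r)
    full = dec.full()
    back = quat.qmul(dec.global_part.quats, dec.internal_part.quats)
    assert np.abs(np.abs(np.sum(back * full.quats, axis=1)) - 1.0).max() < 1e-9


def test_rescale_identity_is_bitstable():
    g = brownian_rotation(IsotropicDiffusion(1.0), 2000, 1.0, seed=7)
    ident = OrientationTrajectory(np.tile(quat.identity(), (2000, 1)))
    dec = DecomposedTrajectory(g, ident)
    out = rescale_tumbling(dec, 1.0)
    dots = np.abs(np.sum(out.global_part.quats * g.quats, axis=1))
    assert np.abs(dots - 1.0).max() < 1e-9


def test_rescale_zero_freezes():
    g = brownian_rotation(IsotropicDiffusion(1.0), 500, 1.0, seed=8)
    ident = OrientationTrajectory(np.tile(quat.identity(), (500, 1)))
    out = rescale_tumbling(DecomposedTrajectory(g, ident), 0.0)
    spread = np.abs(out.global_part.quats - out.global_part.quats[0]).max()
    assert spread < 1e-12


def test_rescale_rejects_negative():
    g = brownian_rotation(IsotropicDiffusion(1.0), 10, 1.0, seed=9)
    ident = OrientationTrajectory(np.tile(quat.identity(), (10, 1)))
    with pytest.raises(ValueError):
        rescale_tumbling(DecomposedTrajectory(g, ident), -0.5)


# ----------------------------------------------------------------------
# correlation functions
# ----------------------------------------------------------------------
def test_p2_static_vector():
    v = np.tile([0.0, 0.0, 1.0], (100, 1))
    c = p2_correlation(v, 50)
    assert np.allclose(c.values, 1.0, atol=1e-12)


def test_p2_memoryless_limit(rng):
    v = rng.normal(size=(20000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    c = p2_correlation(v, 10)
    assert c.values[0] == pytest.approx(1.0)
    assert np.abs(c.values[1:]).max() < 0.05


def test_p2_brownian_matches_exponential():
    """Isotropic diffusion: C(tau) = exp(-6 D tau) = exp(-tau/tau_rot)."""
    tau_ns = 0.4
    traj = brownian_rotation(IsotropicDiffusion(tau_ns), 200_000, 1.0, seed=11)
    u = quat.qrotate(traj.quats, np.array([0.0, 0.0, 1.0]))
    c = p2_correlation(u, 1200)
    expected = np.exp(-c.lags_ps / (tau_ns * 1e3))
    assert np.abs(c.values - expected).max() < 0.05


def test_estimate_tau_rot_recovery():
    tau_ns = 0.5
    traj = brownian_rotation(IsotropicDiffusion(tau_ns), 150_000, 1.0, seed=12)
    tau_fit, info = estimate_tau_rot(traj)
    assert tau_fit == pytest.approx(tau_ns, rel=0.10)
    assert info["rms_residual"] < 0.05


def test_estimate_tau_rot_static_raises():
    q = np.tile(quat.identity(), (5000, 1))
    with pytest.raises(ValueError, match="decay"):
        estimate_tau_rot(OrientationTrajectory(q))


def test_dihedral_gamma_limits(rng):
    const = AngleSeries(np.full(500, 37.0))
    g = dihedral_gamma(const, 100)
    assert np.allclose(g.values, 1.0, atol=1e-12)
    uni = AngleSeries(rng.uniform(-180, 180, size=20000))
    g2 = dihedral_gamma(uni, 10)
    assert g2.values[0] == pytest.approx(1.0)
    assert np.abs(g2.values[1:]).max() < 0.05


def test_dihedral_gamma_two_site(rng):
    """Symmetric two-site exchange: gamma(inf) = cos^2(delta/2)."""
    delta = 70.0
    k = 0.02  # per step
    n = 200_000
    jumps = rng.random(n) < k
    state = np.cumsum(jumps) % 2
    series = AngleSeries(np.where(state, delta, 0.0))
    g = dihedral_gamma(series, 1000)
    plateau = g.values[-200:].mean()
    expected = np.cos(np.deg2rad(delta) / 2.0) ** 2
    assert plateau == pytest.approx(expected, abs=0.03)


def test_order_parameter_plateau():
    lags = np.arange(1000.0)
    vals = 0.3 + 0.7 * np.exp(-lags / 20.0)
    from cwesr.trajectory_ops import CorrelationFunction

    c = CorrelationFunction(lags, vals)
    assert order_parameter(c) == pytest.approx(0.3, abs=1e-3)


def test_p2_axis_correlation_matches_single_axis():
    traj = brownian_rotation(IsotropicDiffusion(0.3), 50_000, 1.0, seed=13)
    c_axis = p2_axis_correlation(traj, 500)
    u = quat.qrotate(traj.quats, np.array([1.0, 0.0, 0.0]))
    c_x = p2_correlation(u, 500)
    # same decay law; axis average is smoother but equal in expectation
    assert np.abs(c_axis.values - c_x.values).max() < 0.1
    assert c_axis.values[0] == pytest.approx(1.0)
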