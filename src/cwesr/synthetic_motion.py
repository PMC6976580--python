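"""Seeded generators of orientational trajectories.

These generators emulate the motional regimes a spin-labeled globular
protein exhibits: overall Brownian tumbling (isotropic or axially
anisotropic, correlation times of a few ns), fast internal label dynamics
(diffusion in a cone, discrete rotameric jumps, 0.1-10 ns), and slow
multi-state environment exchange (microsecond lifetimes).  They serve as
ground-truth fixtures for the trajectory analyses and as motional input
for both lineshape engines.

All generators draw from ``numpy.random.default_rng(seed)`` (a
counter-based PCG64 stream), so trajectories are exactly reproducible
from ``(seed, parameters)`` across platforms.

Validity bound: per-step Gaussian axis-angle increments approximate
rotational diffusion only when the step is small, delta * 6 D < 0.01;
this is asserted at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import quat
from .trajectory_ops import DecomposedTrajectory, OrientationTrajectory, compose

__all__ = [
    "IsotropicDiffusion",
    "AxialDiffusion",
    "ConeDiffusion",
    "DiscreteJump",
    "MultistateExchange",
    "brownian_rotation",
    "internal_motion",
    "compose_motion",
    "cone_order_parameter",
]


# ----------------------------------------------------------------------
# motion models
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class IsotropicDiffusion:
    """Isotropic rotational diffusion; rank-2 correlation time 1/(6D)."""

    tau_rot_ns: float

    def __post_init__(self):
        if self.tau_rot_ns <= 0:
            raise ValueError("tau_rot must be positive (inf disables motion)")

    @property
    def diffusion_per_ps(self) -> np.ndarray:
        d = 0.0 if np.isinf(self.tau_rot_ns) else 1.0 / (6.0 * self.tau_rot_ns * 1e3)
        return np.array([d, d, d])


@dataclass(frozen=True)
class AxialDiffusion:
    """Axially anisotropic diffusion about the molecular z axis.

    ``tau_perp_ns`` sets D_perp = 1/(6 tau_perp); ``ratio`` = D_par/D_perp
    (~1.4 for a modestly prolate globular domain).
    """

    tau_perp_ns: float
    ratio: float = 1.4

    def __post_init__(self):
        if self.tau_perp_ns <= 0 or self.ratio <= 0:
            raise ValueError("tau_perp and D_par/D_perp ratio must be positive")

    @property
    def diffusion_per_ps(self) -> np.ndarray:
        d_perp = 1.0 / (6.0 * self.tau_perp_ns * 1e3)
        return np.array([d_perp, d_perp, d_perp * self.ratio])


@dataclass(frozen=True)
class ConeDiffusion:
    """Wobbling-in-a-cone: the PAS z axis diffuses inside a cone of given
    half-angle about the molecular z axis, plus free spinning about the
    PAS z axis."""

    half_angle_deg: float
    tau_internal_ns: float = 0.5  # sets the diffusion step size

    def __post_init__(self):
        if not 0.0 < self.half_angle_deg <= 180.0:
            raise ValueError("cone half-angle must lie in (0, 180] degrees")
        if self.tau_internal_ns <= 0:
            raise ValueError("tau_internal must be positive")


@dataclass(frozen=True)
class DiscreteJump:
    """Continuous-time Markov chain over discrete orientations.

    ``site_quats`` holds one quaternion per site; ``rates_per_us`` is the
    generator matrix K (off-diagonal K[i, j] = rate i -> j in 1/us,
    rows summing to zero).
    """

    site_quats: np.ndarray
    rates_per_us: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.site_quats, float)
        k = np.asarray(self.rates_per_us, float)
        if q.ndim != 2 or q.shape[1] != 4:
            raise ValueError("site_quats must have shape (n_sites, 4)")
        n = q.shape[0]
        if k.shape != (n, n):
            raise ValueError("rate matrix shape must match the site count")
        off = k - np.diag(np.diag(k))
        if np.any(off < 0):
            raise ValueError("off-diagonal jump rates must be non-negative")
        if np.any(np.abs(k.sum(axis=1)) > 1e-9 * max(1.0, np.abs(k).max())):
            raise ValueError("rate-matrix rows must sum to zero (non-stochastic)")
        object.__setattr__(self, "site_quats", quat.qnormalize(q))
        object.__setattr__(self, "rates_per_us", k)

    @classmethod
    def two_site(cls, angle_deg: float, rate_per_us: float,
                 axis=(0.0, 0.0, 1.0)) -> "DiscreteJump":
        """Symmetric two-site jump by ``angle_deg`` about ``axis``."""
        ax = np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)
        q2 = quat.from_rotvec(np.deg2rad(angle_deg) * ax)
        sites = np.stack([quat.identity(), q2])
        k = rate_per_us * np.array([[-1.0, 1.0], [1.0, -1.0]])
        return cls(sites, k)


@dataclass(frozen=True)
class MultistateExchange:
    """Slow Markov switching between orientational sub-models.

    Emulates microsecond-lifetime environment states (e.g. a label that is
    freely moving in one state and immobilized in another).
    """

    submodels: Sequence[object]
    rates_per_us: np.ndarray
    populations_start: np.ndarray | None = None

    def __post_init__(self):
        k = np.asarray(self.rates_per_us, float)
        n = len(self.submodels)
        if k.shape != (n, n):
            raise ValueError("rate matrix shape must match the sub-model count")
        if np.any(k - np.diag(np.diag(k)) < 0):
            raise ValueError("off-diagonal exchange rates must be non-negative")
        if np.any(np.abs(k.sum(axis=1)) > 1e-9 * max(1.0, np.abs(k).max())):
            raise ValueError("rate-matrix rows must sum to zero (non-stochastic)")
        object.__setattr__(self, "rates_per_us", k)


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------
def _diffusion_steps(d_per_ps: np.ndarray, n_steps: int, dt_ps: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian molecular-frame axis-angle increments, shape (n-1, 3)."""
    if float(np.max(d_per_ps)) * 6.0 * dt_ps >= 0.01:
        raise ValueError(
            "step too coarse for the diffusion constant: require 6 D dt < 0.01"
        )
    sigma = np.sqrt(2.0 * d_per_ps * dt_ps)
    return rng.normal(0.0, 1.0, size=(n_steps - 1, 3)) * sigma


def brownian_rotation(model, n_steps: int, dt_ps: float = 1.0,
                      seed: int = 0, q0: np.ndarray | None = None
                      ) -> OrientationTrajectory:
    """Brownian rotational diffusion trajectory.

    Per step a small random rotation with per-axis angular variance
    2 D_axis dt is composed in the molecular (body) frame.  For isotropic
    models the rank-2 orientational correlation time is 1/(6D).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not isinstance(model, (IsotropicDiffusion, AxialDiffusion)):
        raise TypeError("model must be IsotropicDiffusion or AxialDiffusion")
    rng = np.random.default_rng(seed)
    incr = _diffusion_steps(model.diffusion_per_ps, n_steps, dt_ps, rng)
    steps = quat.from_rotvec(incr)
    start = quat.identity()[None] if q0 is None else np.asarray(q0, float)[None]
    seq = np.concatenate([start, steps], axis=0)
    return OrientationTrajectory(quat.cumulative_product(seq), dt_ps)


def _cone_trajectory(model: ConeDiffusion, n_steps: int, dt_ps: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Rejection-sampled diffusion of the z axis inside a cone.

    Symmetric Gaussian proposals with rejection outside the cone give a
    reflecting boundary whose equilibrium is uniform within the cone cap,
    so the P2 plateau approaches the closed-form cone order parameter
    S = cos(beta) (1 + cos(beta)) / 2.
    """
    beta = np.deg2rad(model.half_angle_deg)
    d = 1.0 / (6.0 * model.tau_internal_ns * 1e3)
    sigma = np.sqrt(2.0 * d * dt_ps)
    if 6.0 * d * dt_ps >= 0.01:
        raise ValueError("step too coarse for the cone diffusion constant")
    incr = rng.normal(0.0, 1.0, size=(n_steps - 1, 3)) * sigma
    quats = np.empty((n_steps, 4))
    quats[0] = quat.identity()
    q = quats[0]
    zhat = np.array([0.0, 0.0, 1.0])
    cos_beta = np.cos(beta)
    for k in range(1, n_steps):
        prop = quat.qmul(q, quat.from_rotvec(incr[k - 1]))
        # reject moves whose z axis tilts beyond the cone half-angle
        if quat.qrotate(prop, zhat)[2] >= cos_beta:
            q = prop
        quats[k] = q
    return quats


def _ctmc_states(k_per_us: np.ndarray, n_steps: int, dt_ps: float,
                 rng: np.random.Generator, p0: np.ndarray | None) -> np.ndarray:
    """Per-frame state indices for a continuous-time Markov chain."""
    n_sites = k_per_us.shape[0]
    if p0 is None:
        p0 = np.full(n_sites, 1.0 / n_sites)
    else:
        p0 = np.asarray(p0, float)
        if not np.isclose(p0.sum(), 1.0):
            raise ValueError("start populations must sum to 1")
    states = np.empty(n_steps, dtype=np.intp)
    t_total_us = n_steps * dt_ps * 1e-6
    state = rng.choice(n_sites, p=p0)
    t = 0.0
    frame = 0
    while frame < n_steps:
        out_rate = -k_per_us[state, state]
        if out_rate <= 0:
            states[frame:] = state
            break
        dwell = rng.exponential(1.0 / out_rate)
        end_frame = min(n_steps, int(np.ceil((t + dwell) / (dt_ps * 1e-6))))
        end_frame = max(end_frame, frame + 1)
        states[frame:end_frame] = state
        frame = end_frame
        t += dwell
        if t >= t_total_us:
            break
        probs = k_per_us[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = rng.choice(n_sites, p=probs)
    if frame < n_steps:
        states[frame:] = state
    return states


def internal_motion(model, n_steps: int, dt_ps: float = 1.0,
                    seed: int = 0) -> OrientationTrajectory:
    """Internal (PAS -> molecule) motion trajectory for the given model."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)

    if isinstance(model, ConeDiffusion):
        return OrientationTrajectory(
            _cone_trajectory(model, n_steps, dt_ps, rng), dt_ps
        )

    if isinstance(model, DiscreteJump):
        states = _ctmc_states(model.rates_per_us, n_steps, dt_ps, rng, None)
        return OrientationTrajectory(model.site_quats[states], dt_ps)

    if isinstance(model, MultistateExchange):
        states = _ctmc_states(model.rates_per_us, n_steps, dt_ps, rng,
                              model.populations_start)
        quats = np.empty((n_steps, 4))
        q_current = quat.identity()
        # run each dwell segment with its sub-model, continuing from the
        # current orientation so the trajectory is continuous
        boundaries = np.flatnonzero(np.diff(states)) + 1
        segments = np.split(np.arange(n_steps), boundaries)
        for seg in segments:
            sub = model.submodels[states[seg[0]]]
            if sub is None or len(seg) < 2:  # immobilized state
                quats[seg] = q_current
                continue
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if isinstance(sub, (IsotropicDiffusion, AxialDiffusion)):
                part = brownian_rotation(sub, len(seg), dt_ps, seed=sub_seed,
                                         q0=q_current)
            else:
                part_rel = internal_motion(sub, len(seg), dt_ps, seed=sub_seed)
                part = OrientationTrajectory(
                    quat.qmul(q_current[None], part_rel.quats), dt_ps
                )
            quats[seg] = part.quats
            q_current = quats[seg[-1]]
        return OrientationTrajectory(quats, dt_ps)

    raise TypeError(f"unsupported internal-motion model: {type(model).__name__}")


def compose_motion(global_traj: OrientationTrajectory,
                   internal_traj: OrientationTrajectory) -> DecomposedTrajectory:
    """R(t) = Q(t) o r(t), keeping the ground-truth decomposition."""
    if global_traj.n_frames != internal_traj.n_frames:
        raise ValueError("global and internal trajectories differ in length")
    if global_traj.dt_ps != internal_traj.dt_ps:
        raise ValueError("global and internal trajectories differ in dt")
    return compose(global_traj, internal_traj)


def cone_order_parameter(half_angle_deg: float) -> float:
    """Closed-form order parameter of uniform wobbling in a cone:
    S = cos(beta) (1 + cos(beta)) / 2; the P2 correlation plateau is S^2."""
    c = np.cos(np.deg2rad(half_angle_deg))
    return float(0.5 * c * (1.0 + c))
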