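"""Saccadic eye-rotation kinematics.

The saccade is a single horizontal rotation about the vertical (+y) axis
described by a quintic polynomial

    theta(t) = c0 + c1 t + c2 t^2 + c3 t^3 + c4 t^4 + c5 t^5,

nominally a 50-degree excursion completed in T = 0.137 s, observed for a
further T while the fluid decelerates.

Two coefficient modes are provided:

* ``boundary_condition`` (default): c0 = c1 = 0; the published initial
  acceleration coefficient c2 = 2.01e4 deg/s^2 is retained and c3, c4, c5
  solve theta(T) = A, theta'(T) = 0, theta''(T) = 0 exactly, so the wave is
  amplitude-exact and comes smoothly to rest.
* ``table2_verbatim``: the published coefficient set (c0..c4, c5 = 0) taken
  at face value.  Evaluated at T it yields ~341 deg rather than 50 deg —
  the printed table is not consistent with the stated amplitude — so this
  mode is diagnostic only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: published coefficient set (deg, deg/s, ... deg/s^4); c5 absent
TABLE2_COEFFS = (0.0, 0.0, 2.01e4, -3.29e5, 2.30e6)

DEFAULT_AMPLITUDE_DEG = 50.0
DEFAULT_DURATION_S = 0.137


@dataclass(frozen=True)
class SaccadeParams:
    amplitude_deg: float
    duration_s: float
    coeffs: tuple[float, float, float, float, float, float]  # c0..c5
    mode: str  # "boundary_condition" | "table2_verbatim"

    @property
    def observation_s(self) -> float:
        """Total simulated span: the saccade plus an equal deceleration window."""
        return 2.0 * self.duration_s


@dataclass
class SaccadeTrajectory:
    """Sampled angular displacement / velocity / acceleration."""

    t: np.ndarray          # s
    theta_deg: np.ndarray
    omega_deg_s: np.ndarray
    alpha_deg_s2: np.ndarray

    def __post_init__(self) -> None:
        dt = np.diff(self.t)
        if len(dt) and dt.max() > 1e-3 + 1e-12:
            raise ValueError("trajectory sampling step must be <= 1 ms")


def fit_saccade(amplitude_deg: float = DEFAULT_AMPLITUDE_DEG,
                duration_s: float = DEFAULT_DURATION_S,
                mode: str = "boundary_condition") -> SaccadeParams:
    """Construct the quintic coefficients for a saccadic wave."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if mode == "table2_verbatim":
        return SaccadeParams(amplitude_deg, duration_s,
                             TABLE2_COEFFS + (0.0,), mode)
    if mode != "boundary_condition":
        raise ValueError(f"unknown mode {mode!r}")
    T = duration_s
    c2 = TABLE2_COEFFS[2]
    # theta(T) = A, theta'(T) = 0, theta''(T) = 0 with c0 = c1 = 0, c2 fixed
    M = np.array([[T ** 3, T ** 4, T ** 5],
                  [3 * T ** 2, 4 * T ** 3, 5 * T ** 4],
                  [6 * T, 12 * T ** 2, 20 * T ** 3]])
    rhs = np.array([amplitude_deg - c2 * T ** 2, -2 * c2 * T, -2 * c2])
    if amplitude_deg == 0.0:
        c2 = 0.0
        rhs = np.zeros(3)
    c3, c4, c5 = np.linalg.solve(M, rhs)
    return SaccadeParams(amplitude_deg, duration_s,
                         (0.0, 0.0, c2, float(c3), float(c4), float(c5)), mode)


def eval_saccade(params: SaccadeParams, t: float | np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angle, angular velocity and acceleration at time(s) ``t``.

    In ``boundary_condition`` mode the state is clamped to rest at the
    amplitude for t > T; verbatim mode evaluates the raw polynomial
    throughout.  Times outside [0, 2T] are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > params.observation_s + 1e-12):
        raise ValueError("t outside [0, 2T]")
    c = params.coeffs
    p = np.polynomial.Polynomial(c)
    dp = p.deriv()
    ddp = dp.deriv()
    theta, omega, alpha = p(t), dp(t), ddp(t)
    if params.mode == "boundary_condition":
        after = t > params.duration_s
        theta = np.where(after, params.amplitude_deg, theta)
        omega = np.where(after, 0.0, omega)
        alpha = np.where(after, 0.0, alpha)
    return theta, omega, alpha


def sample_trajectory(params: SaccadeParams,
                      dt: float = 1e-3) -> SaccadeTrajectory:
    """Dense trajectory over [0, 2T] at step ``dt`` (<= 1 ms)."""
    n = int(np.ceil(params.observation_s / dt)) + 1
    t = np.linspace(0.0, params.observation_s, n)
    theta, omega, alpha = eval_saccade(params, t)
    return SaccadeTrajectory(t, theta, omega, alpha)
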