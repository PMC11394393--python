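"""Extended Kalman filter (EKF) on the 4-state nonlinear blood-volume model.

States: x1 (BV change, L), x2 (target BV change, L), x3 (hemorrhage rate,
L/min, modeled as a random walk), x4 (red-blood-cell volume, L).  The output is
hematocrit h(x) = x4 / (x1 + VB0).  Process noise is not tuned: it is derived
from the population parametric uncertainty as Qw = J_theta Q_theta J_theta^T,
where J_theta is the Jacobian of the dynamics with respect to the parameters
theta = (VB0, alpha_u, alpha_h, k).  x3_hat is read directly as the hemorrhage
rate estimate and detection signature.

All operations broadcast over leading batch axes: ``xhat`` may be (..., 4) and
``P`` (..., 4, 4), which is how the batch evaluation engine runs thousands of
filters in lock-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateVolumeError, DivergenceError, InvalidInputError
from .plant import PatientParams

__all__ = [
    "EKFConfig",
    "EKFState",
    "ekf_dynamics",
    "jacobian_F",
    "jacobian_Jtheta",
    "jacobian_H",
    "ekf_predict",
    "ekf_correct",
    "ekf_rate_estimate",
    "run_ekf",
]

# initialization: position/volume states at 0 with 0.1 L std; hemorrhage state at
# 0 with 0.02 L/min std; RBC state seeded from the first HCT measurement.
DEFAULT_P0_DIAG = (0.1**2, 0.1**2, 0.02**2, 0.1**2)


@dataclass(frozen=True)
class EKFConfig:
    """Nominal plant, parametric-uncertainty covariance, and noise settings.

    ``q_floor`` is a small diagonal process-noise floor: the parametric process
    noise J Q J^T vanishes identically at the origin with zero input (J = 0),
    and the hemorrhage random-walk row of J is always zero, so a strictly
    positive floor keeps the covariance from collapsing.  ``qv_floor`` keeps the
    Kalman gain defined when the simulated measurement noise level is 0.
    """

    params_nominal: PatientParams
    q_theta: np.ndarray
    q_v: float
    p0: np.ndarray = field(default_factory=lambda: np.diag(DEFAULT_P0_DIAG))
    q_floor: float = 1e-10
    qv_floor: float = 1e-8

    def __post_init__(self) -> None:
        q = np.asarray(self.q_theta, dtype=float)
        p0 = np.asarray(self.p0, dtype=float)
        if q.shape != (4, 4) or p0.shape != (4, 4):
            raise InvalidInputError("q_theta and p0 must be 4x4")
        for name, m in (("q_theta", q), ("p0", p0)):
            if not np.allclose(m, m.T, atol=1e-12):
                raise InvalidInputError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(m)) < -1e-10:
                raise InvalidInputError(f"{name} must be positive semidefinite")
        object.__setattr__(self, "q_theta", q)
        object.__setattr__(self, "p0", p0)

    @property
    def qv_eff(self) -> float:
        """Measurement-noise variance with the floor applied."""
        return max(float(self.q_v), float(self.qv_floor))


@dataclass
class EKFState:
    """Filter mean (..., 4), covariance (..., 4, 4), and time."""

    xhat: np.ndarray
    p: np.ndarray
    t: float = 0.0


def _volume(xhat: np.ndarray, params: PatientParams) -> np.ndarray:
    bv = xhat[..., 0] + params.vb0
    if np.any(bv <= 0):
        raise DegenerateVolumeError("blood volume x1 + VB0 must stay positive")
    return bv


def ekf_dynamics(xhat: np.ndarray, u, params: PatientParams) -> np.ndarray:
    """Model derivative f(x, u); the hemorrhage state is a pure random walk."""
    xhat = np.asarray(xhat, dtype=float)
    bv = _volume(xhat, params)
    u = np.asarray(u, dtype=float)
    out = np.empty_like(xhat)
    out[..., 0] = -params.k * xhat[..., 0] + params.k * xhat[..., 1] - xhat[..., 2] + u
    out[..., 1] = -xhat[..., 2] / (1.0 + params.alpha_h) + u / (1.0 + params.alpha_u)
    out[..., 2] = 0.0
    out[..., 3] = -xhat[..., 2] * xhat[..., 3] / bv
    return out


def jacobian_F(xhat: np.ndarray, u, params: PatientParams) -> np.ndarray:
    """State Jacobian dF/dx, shape (..., 4, 4); row 3 is zero (random walk)."""
    xhat = np.asarray(xhat, dtype=float)
    bv = _volume(xhat, params)
    f = np.zeros(xhat.shape[:-1] + (4, 4))
    f[..., 0, 0] = -params.k
    f[..., 0, 1] = params.k
    f[..., 0, 2] = -1.0
    f[..., 1, 2] = -1.0 / (1.0 + params.alpha_h)
    f[..., 3, 0] = xhat[..., 2] * xhat[..., 3] / bv**2
    f[..., 3, 2] = -xhat[..., 3] / bv
    f[..., 3, 3] = -xhat[..., 2] / bv
    return f


def jacobian_Jtheta(xhat: np.ndarray, u, params: PatientParams) -> np.ndarray:
    """Parameter Jacobian df/d(theta), theta = (VB0, alpha_u, alpha_h, k)."""
    xhat = np.asarray(xhat, dtype=float)
    bv = _volume(xhat, params)
    u = np.asarray(u, dtype=float)
    j = np.zeros(np.broadcast_shapes(xhat.shape[:-1], u.shape) + (4, 4))
    j[..., 0, 3] = -xhat[..., 0] + xhat[..., 1]
    j[..., 1, 1] = -u / (1.0 + params.alpha_u) ** 2
    j[..., 1, 2] = xhat[..., 2] / (1.0 + params.alpha_h) ** 2
    j[..., 3, 0] = xhat[..., 2] * xhat[..., 3] / bv**2
    return j


def jacobian_H(xhat: np.ndarray, params: PatientParams) -> np.ndarray:
    """Output Jacobian dh/dx of h(x) = x4 / (x1 + VB0), shape (..., 4)."""
    xhat = np.asarray(xhat, dtype=float)
    bv = _volume(xhat, params)
    h = np.zeros_like(xhat)
    h[..., 0] = -xhat[..., 3] / bv**2
    h[..., 3] = 1.0 / bv
    return h


def _predict_deriv(xhat, p, u, cfg: EKFConfig):
    """Joint derivative of (mean, covariance) for the prediction ODE."""
    params = cfg.params_nominal
    dx = ekf_dynamics(xhat, u, params)
    f = jacobian_F(xhat, u, params)
    j = jacobian_Jtheta(xhat, u, params)
    qw = np.einsum("...ij,jk,...lk->...il", j, cfg.q_theta, j)
    qw = qw + cfg.q_floor * np.eye(4)
    dp = np.einsum("...ij,...jk->...ik", f, p)
    dp = dp + np.swapaxes(dp, -1, -2) + qw
    return dx, dp


def ekf_predict(
    state: EKFState, u, dt: float, cfg: EKFConfig, n_sub: int = 4
) -> EKFState:
    """Propagate mean and covariance over one measurement interval.

    The mean follows the model ODE and the covariance the Lyapunov differential
    equation dP/dt = F P + P F^T + Qw, jointly integrated with ``n_sub`` RK4
    sub-steps (input held constant).  The covariance is re-symmetrized after
    the step.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    h = dt / n_sub
    xhat = np.asarray(state.xhat, dtype=float)
    p = np.asarray(state.p, dtype=float)
    for _ in range(n_sub):
        k1x, k1p = _predict_deriv(xhat, p, u, cfg)
        k2x, k2p = _predict_deriv(xhat + 0.5 * h * k1x, p + 0.5 * h * k1p, u, cfg)
        k3x, k3p = _predict_deriv(xhat + 0.5 * h * k2x, p + 0.5 * h * k2p, u, cfg)
        k4x, k4p = _predict_deriv(xhat + h * k3x, p + h * k3p, u, cfg)
        xhat = xhat + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        p = p + (h / 6.0) * (k1p + 2 * k2p + 2 * k3p + k4p)
    p = 0.5 * (p + np.swapaxes(p, -1, -2))
    if np.max(np.abs(p)) > 1e12:
        raise DivergenceError("covariance norm exceeded 1e12")
    return EKFState(xhat=xhat, p=p, t=state.t + dt)


def ekf_correct(state: EKFState, y, cfg: EKFConfig) -> EKFState:
    """Measurement update with the Joseph-form covariance update (PSD-safe)."""
    if not np.all(np.isfinite(np.asarray(y, dtype=float))):
        raise InvalidInputError("non-finite measurement")
    params = cfg.params_nominal
    xhat = np.asarray(state.xhat, dtype=float)
    p = np.asarray(state.p, dtype=float)
    hvec = jacobian_H(xhat, params)  # (..., 4)
    yhat = xhat[..., 3] / (xhat[..., 0] + params.vb0)
    ph = np.einsum("...ij,...j->...i", p, hvec)
    s = np.einsum("...i,...i->...", hvec, ph) + cfg.qv_eff
    gain = ph / s[..., None]
    xnew = xhat + gain * (np.asarray(y, dtype=float) - yhat)[..., None]
    ikh = np.eye(4) - gain[..., :, None] * hvec[..., None, :]
    pnew = np.einsum("...ij,...jk,...lk->...il", ikh, p, ikh)
    pnew = pnew + cfg.qv_eff * np.einsum("...i,...j->...ij", gain, gain)
    pnew = 0.5 * (pnew + np.swapaxes(pnew, -1, -2))
    return EKFState(xhat=xnew, p=pnew, t=state.t)


def ekf_rate_estimate(state: EKFState) -> np.ndarray:
    """Hemorrhage-rate estimate: x3_hat, reported raw (may be negative)."""
    return np.asarray(state.xhat)[..., 2]


def run_ekf(
    sigma_meas: np.ndarray,
    u_series: np.ndarray,
    cfg: EKFConfig,
    dt_meas: float = 1.0,
    n_sub: int = 4,
    store_p33: bool = False,
):
    """Run the filter along a sampled hematocrit series.

    The filter is initialized at x_hat = (0, 0, 0, sigma_meas[0] * VB0_nominal)
    with covariance P0, then alternates predict (over each 1-min interval,
    input held) and correct (with the new HCT sample).  Returns the x3_hat
    signature series with shape (..., T+1); with ``store_p33`` also the
    P[3,3] variance series.
    """
    sigma_meas = np.asarray(sigma_meas, dtype=float)
    batch = sigma_meas.shape[:-1]
    n_t = sigma_meas.shape[-1]
    params = cfg.params_nominal
    xhat0 = np.zeros(batch + (4,))
    xhat0[..., 3] = sigma_meas[..., 0] * params.vb0
    p0 = np.broadcast_to(cfg.p0, batch + (4, 4)).copy()
    state = EKFState(xhat=xhat0, p=p0)
    sig = np.zeros(batch + (n_t,))
    p33 = np.zeros(batch + (n_t,)) if store_p33 else None
    if store_p33:
        p33[..., 0] = cfg.p0[2, 2]
    for k in range(1, n_t):
        state = ekf_predict(state, u_series[..., k - 1], dt_meas, cfg, n_sub)
        state = ekf_correct(state, sigma_meas[..., k], cfg)
        sig[..., k] = state.xhat[..., 2]
        if store_p33:
            p33[..., k] = state.p[..., 2, 2]
    if store_p33:
        return sig, p33
    return sig
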