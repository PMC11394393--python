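"""Lumped-parameter blood-volume kinetics under hemorrhage and fluid resuscitation.

The plant tracks three continuous states:

* ``x1`` — change in blood volume (BV) from its pre-insult value ``VB0`` [L],
* ``x2`` — target change in BV toward which interstitial fluid exchange drives
  ``x1`` at rate ``k`` [L],
* ``VR`` — red-blood-cell (RBC) volume [L].

Resuscitation at rate ``u`` expands the target volume by ``1/(1+alpha_u)`` of the
infused volume (the rest shifts to the interstitium); hemorrhage at rate ``h``
removes whole blood, of which the interstitium eventually replaces the
``alpha_h/(1+alpha_h)`` fraction.  Hematocrit (HCT) is the derived output
``sigma = VR / (VB0 + x1)`` and is the only measured signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateVolumeError, InvalidInputError, SimulationDomainError

__all__ = [
    "PatientParams",
    "PlantState",
    "InputSignal",
    "Trajectory",
    "plant_derivatives",
    "hematocrit",
    "simulate",
    "output_lo",
    "eta_h",
    "add_measurement_noise",
]


@dataclass(frozen=True)
class PatientParams:
    """One virtual patient's plant parameters.

    Attributes
    ----------
    vb0 : float
        Initial (pre-hemorrhage) blood volume [L].
    alpha_u : float
        Resuscitation interstitial-shift ratio (dimensionless, >= 0).
    alpha_h : float
        Hemorrhage interstitial-compensation ratio (dimensionless, >= 0).
    k : float
        Interstitial fluid-exchange rate [1/min].
    sigma0 : float
        Initial hematocrit, fraction in (0, 1).
    """

    vb0: float
    alpha_u: float
    alpha_h: float
    k: float
    sigma0: float

    def __post_init__(self) -> None:
        if not (self.vb0 > 0 and np.isfinite(self.vb0)):
            raise InvalidInputError(f"vb0 must be positive, got {self.vb0}")
        if self.alpha_u < 0 or self.alpha_h < 0:
            raise InvalidInputError("alpha_u and alpha_h must be non-negative")
        if not (self.k > 0):
            raise InvalidInputError(f"k must be positive, got {self.k}")
        if not (0.0 < self.sigma0 < 1.0):
            raise InvalidInputError(f"sigma0 must lie in (0,1), got {self.sigma0}")

    @property
    def theta(self) -> np.ndarray:
        """Parameter vector (VB0, alpha_u, alpha_h, k) in that fixed order."""
        return np.array([self.vb0, self.alpha_u, self.alpha_h, self.k])


@dataclass(frozen=True)
class PlantState:
    """Continuous plant state (x1, x2, VR); all in liters."""

    x1: float
    x2: float
    vr: float


def _derivs(x1, x2, vr, u, h, vb0, alpha_u, alpha_h, k):
    """Raw derivative kernel; broadcasts over array arguments."""
    sigma = vr / (vb0 + x1)
    dx1 = -k * x1 + k * x2 - h + u
    dx2 = -h / (1.0 + alpha_h) + u / (1.0 + alpha_u)
    dvr = -h * sigma
    return dx1, dx2, dvr


def plant_derivatives(
    state: PlantState, params: PatientParams, u: float, h: float
) -> tuple[float, float, float]:
    """Time derivatives (dx1/dt, dx2/dt, dVR/dt) in L/min.

    ``dVR/dt = -h * sigma <= 0`` always: hemorrhage removes RBCs in proportion
    to the current hematocrit and nothing replaces them.
    """
    vals = np.array([state.x1, state.x2, state.vr, u, h], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InvalidInputError("non-finite state or input")
    if u < 0 or h < 0:
        raise InvalidInputError("rates u and h must be non-negative")
    if params.vb0 + state.x1 <= 0:
        raise DegenerateVolumeError("blood volume VB0 + x1 must be positive")
    return _derivs(
        state.x1, state.x2, state.vr, u, h,
        params.vb0, params.alpha_u, params.alpha_h, params.k,
    )


def hematocrit(state: PlantState, params: PatientParams) -> float:
    """Hematocrit sigma = VR / (VB0 + x1)."""
    bv = params.vb0 + state.x1
    if bv <= 0:
        raise DegenerateVolumeError(f"degenerate blood volume {bv:.4g} L")
    return state.vr / bv


def _step_eval(times: np.ndarray, values: np.ndarray, t) -> np.ndarray:
    """Left-continuous step-function lookup: value[i] holds on [times[i], times[i+1])."""
    idx = np.searchsorted(times, t, side="right") - 1
    return values[np.clip(idx, 0, len(values) - 1)]


@dataclass(frozen=True)
class InputSignal:
    """Piecewise-constant resuscitation and hemorrhage rate profiles [L/min].

    ``u_values[i]`` applies on ``[u_times[i], u_times[i+1])`` (and the last value
    thereafter); likewise for ``h``.  Both must be zero during the settling
    period ``[0, t_settle)``.
    """

    u_times: np.ndarray
    u_values: np.ndarray
    h_times: np.ndarray
    h_values: np.ndarray
    t_settle: float = 10.0

    def __post_init__(self) -> None:
        for name in ("u", "h"):
            t = np.asarray(getattr(self, f"{name}_times"), dtype=float)
            v = np.asarray(getattr(self, f"{name}_values"), dtype=float)
            if t.shape != v.shape or t.ndim != 1 or len(t) == 0:
                raise InvalidInputError(f"{name} breakpoints/values must be equal-length 1-D")
            if np.any(np.diff(t) <= 0):
                raise InvalidInputError(f"{name} breakpoint times must be strictly increasing")
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise InvalidInputError(f"{name} rates must be finite and non-negative")
            object.__setattr__(self, f"{name}_times", t)
            object.__setattr__(self, f"{name}_values", v)
        if self.u(self.t_settle / 2.0) != 0.0 or self.h(self.t_settle / 2.0) != 0.0:
            raise InvalidInputError("inputs must be zero during the settling period")

    @classmethod
    def step(cls, u: float, h: float, t_settle: float = 10.0) -> "InputSignal":
        """Zero inputs during settling, then constant rates ``u`` and ``h``."""
        return cls(
            u_times=np.array([0.0, t_settle]),
            u_values=np.array([0.0, u]),
            h_times=np.array([0.0, t_settle]),
            h_values=np.array([0.0, h]),
            t_settle=t_settle,
        )

    def u(self, t) -> np.ndarray:
        return _step_eval(self.u_times, self.u_values, t)

    def h(self, t) -> np.ndarray:
        return _step_eval(self.h_times, self.h_values, t)


@dataclass
class Trajectory:
    """Uniformly sampled plant trajectory with the derived hematocrit series."""

    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    vr: np.ndarray
    sigma: np.ndarray
    u: np.ndarray
    h: np.ndarray
    sigma0: float
    stop_reason: str = "cap"
    sigma_meas: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("x1", "x2", "vr", "sigma", "u", "h"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"series {name} length mismatch")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9)):
            raise InvalidInputError("times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def with_noise(self, noise_level: float, seed: int) -> "Trajectory":
        """Attach a noisy hematocrit series (see :func:`add_measurement_noise`)."""
        return replace(
            self, sigma_meas=add_measurement_noise(self.sigma, noise_level, seed)
        )

    def to_frame(self):
        """Export as a pandas DataFrame (column layout used by the CSV writers)."""
        import pandas as pd

        meas = self.sigma_meas if self.sigma_meas is not None else self.sigma
        return pd.DataFrame(
            {
                "time_min": self.times,
                "x1_L": self.x1,
                "x2_L": self.x2,
                "VR_L": self.vr,
                "sigma": self.sigma,
                "sigma_meas": meas,
                "u_lpm": self.u,
                "h_lpm": self.h,
            }
        )


def simulate(
    params: PatientParams,
    inputs: InputSignal,
    dt_int: float = 0.05,
    t_max: float = 480.0,
    dt_record: float = 1.0,
    stop_rules: bool = True,
) -> Trajectory:
    """Integrate the plant with fixed-step RK4 and sample it at ``dt_record``.

    The trajectory is truncated at the first recorded sample where a stop rule
    fires (>25% BV loss or HCT < 10%), mirroring the evaluation protocol, or at
    ``t_max``.  Raises :class:`SimulationDomainError` if the state leaves the
    physiological domain (sigma <= 0 or BV <= 0) before any stop rule.
    """
    if dt_int <= 0 or dt_record <= 0:
        raise InvalidInputError("dt_int and dt_record must be positive")
    if t_max < inputs.t_settle:
        raise InvalidInputError("t_max must cover the settling period")
    n_sub = int(round(dt_record / dt_int))
    if n_sub < 1 or abs(n_sub * dt_int - dt_record) > 1e-9:
        raise InvalidInputError("dt_record must be an integer multiple of dt_int")

    p = (params.vb0, params.alpha_u, params.alpha_h, params.k)
    n_rec = int(round(t_max / dt_record))
    x1, x2, vr = 0.0, 0.0, params.sigma0 * params.vb0

    rec = np.empty((n_rec + 1, 5))
    rec[0] = (0.0, x1, x2, vr, params.sigma0)
    stop_reason = "cap"
    end = n_rec
    for i in range(1, n_rec + 1):
        t0 = (i - 1) * dt_record
        for s in range(n_sub):
            t = t0 + s * dt_int
            u, h = float(inputs.u(t)), float(inputs.h(t))
            k1 = _derivs(x1, x2, vr, u, h, *p)
            k2 = _derivs(x1 + 0.5 * dt_int * k1[0], x2 + 0.5 * dt_int * k1[1],
                         vr + 0.5 * dt_int * k1[2], u, h, *p)
            k3 = _derivs(x1 + 0.5 * dt_int * k2[0], x2 + 0.5 * dt_int * k2[1],
                         vr + 0.5 * dt_int * k2[2], u, h, *p)
            k4 = _derivs(x1 + dt_int * k3[0], x2 + dt_int * k3[1],
                         vr + dt_int * k3[2], u, h, *p)
            x1 += dt_int / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            x2 += dt_int / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            vr += dt_int / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        t1 = i * dt_record
        bv = params.vb0 + x1
        sigma = vr / bv if bv > 0 else -1.0
        rec[i] = (t1, x1, x2, vr, sigma)
        if stop_rules and bv < 0.75 * params.vb0:
            stop_reason, end = "bv25", i
            break
        if stop_rules and 0 < sigma < 0.10:
            stop_reason, end = "hct10", i
            break
        if sigma <= 0 or bv <= 0:
            raise SimulationDomainError(
                f"state left physiological domain at t={t1:.2f} min", time=t1
            )

    times = rec[: end + 1, 0]
    return Trajectory(
        times=times,
        x1=rec[: end + 1, 1],
        x2=rec[: end + 1, 2],
        vr=rec[: end + 1, 3],
        sigma=rec[: end + 1, 4],
        u=np.asarray(inputs.u(times), dtype=float),
        h=np.asarray(inputs.h(times), dtype=float),
        sigma0=params.sigma0,
        stop_reason=stop_reason,
    )


def output_lo(traj: Trajectory) -> np.ndarray:
    """Observer output series y = (sigma0 - sigma) / sigma.

    Computed from the measured (noisy) hematocrit when present.  When ``h == 0``
    and the measurement is noise-free, y equals the fractional BV change
    ``x1 / VB0`` exactly.
    """
    sigma = traj.sigma_meas if traj.sigma_meas is not None else traj.sigma
    if np.any(sigma <= 0):
        raise DegenerateVolumeError("hematocrit must be positive to form the output")
    return (traj.sigma0 - sigma) / sigma


def eta_h(traj: Trajectory, params: PatientParams) -> np.ndarray:
    """Hemorrhage-driven output disturbance (integral of h/sigma over VB0*sigma).

    Diagnostic used by the observer error-dynamics property tests:
    non-negative, non-decreasing while h > 0, and bounded below by the
    fractional hemorrhaged volume integral(h)/VB0.  Requires a noise-free
    trajectory.
    """
    from scipy.integrate import cumulative_trapezoid

    if np.any(traj.sigma <= 0):
        raise DegenerateVolumeError("hematocrit must be positive")
    integ = cumulative_trapezoid(traj.h / traj.sigma, traj.times, initial=0.0)
    return integ / (params.vb0 * traj.sigma)


def add_measurement_noise(
    sigma: np.ndarray, noise_level: float, seed: int, relative: bool = False
) -> np.ndarray:
    """Add i.i.d. Gaussian noise to a hematocrit series.

    ``noise_level`` is the noise standard deviation in absolute hematocrit
    fraction (a "1% HCT" noise level is 0.01); with ``relative=True`` it is
    instead a fraction of the instantaneous hematocrit.  Samples are clipped
    to (0.001, 0.999) so downstream ratios stay defined.
    """
    if noise_level < 0:
        raise InvalidInputError("noise level must be non-negative")
    sigma = np.asarray(sigma, dtype=float)
    if noise_level == 0:
        return sigma.copy()
    rng = np.random.default_rng(seed)
    sd = noise_level * sigma if relative else noise_level
    noisy = sigma + sd * rng.standard_normal(sigma.shape)
    return np.clip(noisy, 0.001, 0.999)
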