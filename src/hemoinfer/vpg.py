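"""Synthetic virtual-patient generator (VPG).

Samples plant parameter sets from a configurable population distribution and
exposes the population mean and covariance that the estimators consume.  The
positive parameters (VB0, alpha_u, alpha_h, k) are drawn from a moment-matched
multivariate lognormal: the exponential of a Gaussian whose mean and covariance
are chosen so that the samples reproduce the requested arithmetic mean
``theta_bar`` and covariance ``Q_theta``.  This guarantees positivity without
rejection loops.  The initial hematocrit sigma0 is drawn uniformly from
``sigma0_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .plant import PatientParams

__all__ = ["PopulationModel", "Cohort", "sample_patients", "nominal_patient", "derive_seed"]

_THETA_NAMES = ("vb0", "alpha_u", "alpha_h", "k")


def derive_seed(master_seed: int, *tags: int) -> int:
    """Deterministic sub-seed from a master seed and integer tags.

    Counter-based so every (cohort, patient, scenario) gets an independent
    stream regardless of execution order.
    """
    ss = np.random.SeedSequence([int(master_seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass(frozen=True)
class PopulationModel:
    """Population distribution over plant parameters.

    Attributes
    ----------
    theta_bar : np.ndarray
        Population-mean parameter vector (VB0, alpha_u, alpha_h, k).
    q_theta : np.ndarray
        4x4 covariance of the parameter vector (parameter units squared).
        Also the default parametric-uncertainty covariance handed to the EKF.
    sigma0_range : tuple[float, float]
        Uniform sampling interval for the initial hematocrit.
    """

    theta_bar: np.ndarray
    q_theta: np.ndarray
    sigma0_range: tuple[float, float] = (0.35, 0.45)

    def __post_init__(self) -> None:
        tb = np.asarray(self.theta_bar, dtype=float)
        q = np.asarray(self.q_theta, dtype=float)
        if tb.shape != (4,) or q.shape != (4, 4):
            raise ConfigurationError("theta_bar must be length 4 and q_theta 4x4")
        if not np.allclose(q, q.T, atol=1e-12):
            raise ConfigurationError("q_theta must be symmetric")
        if np.min(np.linalg.eigvalsh(q)) < -1e-10:
            raise ConfigurationError("q_theta must be positive semidefinite")
        lo, hi = self.sigma0_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("sigma0_range must lie inside (0,1)")
        try:
            nominal = PatientParams(tb[0], tb[1], tb[2], tb[3], 0.5 * (lo + hi))
        except InvalidInputError as exc:
            raise ConfigurationError(f"infeasible population mean: {exc}") from exc
        object.__setattr__(self, "theta_bar", tb)
        object.__setattr__(self, "q_theta", q)
        object.__setattr__(self, "_nominal", nominal)

    @classmethod
    def from_cv(
        cls,
        vb0: float = 5.0,
        alpha_u: float = 0.5,
        alpha_h: float = 2.0,
        k: float = 0.1,
        cv: float = 0.15,
        sigma0_range: tuple[float, float] = (0.35, 0.45),
    ) -> "PopulationModel":
        """Population with independent parameters at a common coefficient of variation."""
        theta = np.array([vb0, alpha_u, alpha_h, k])
        return cls(theta, np.diag((cv * theta) ** 2), sigma0_range)


@dataclass
class Cohort:
    """Struct-of-arrays view of a sampled cohort (one entry per virtual patient)."""

    vb0: np.ndarray
    alpha_u: np.ndarray
    alpha_h: np.ndarray
    k: np.ndarray
    sigma0: np.ndarray

    def __len__(self) -> int:
        return len(self.vb0)

    def __getitem__(self, i: int) -> PatientParams:
        return PatientParams(
            float(self.vb0[i]), float(self.alpha_u[i]), float(self.alpha_h[i]),
            float(self.k[i]), float(self.sigma0[i]),
        )

    @classmethod
    def from_params(cls, patients: list[PatientParams]) -> "Cohort":
        return cls(
            vb0=np.array([p.vb0 for p in patients]),
            alpha_u=np.array([p.alpha_u for p in patients]),
            alpha_h=np.array([p.alpha_h for p in patients]),
            k=np.array([p.k for p in patients]),
            sigma0=np.array([p.sigma0 for p in patients]),
        )

    @property
    def theta(self) -> np.ndarray:
        """(n, 4) parameter matrix in (VB0, alpha_u, alpha_h, k) order."""
        return np.column_stack([self.vb0, self.alpha_u, self.alpha_h, self.k])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {name: getattr(self, name) for name in (*_THETA_NAMES, "sigma0")}
        )


def _lognormal_moments(mean: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian (mu, Sigma) in log space matching arithmetic (mean, cov)."""
    outer = np.outer(mean, mean)
    sigma_ln = np.log1p(cov / outer)
    mu_ln = np.log(mean) - 0.5 * np.diag(sigma_ln)
    return mu_ln, sigma_ln


def sample_cohort(pop: PopulationModel, n: int, seed: int) -> Cohort:
    """Sample ``n`` virtual patients as a :class:`Cohort` (vectorized)."""
    if n < 0:
        raise InvalidInputError("cohort size must be non-negative")
    rng = np.random.default_rng(seed)
    if n == 0:
        empty = np.empty(0)
        return Cohort(empty, empty, empty, empty, empty)
    if np.all(pop.q_theta == 0):
        theta = np.tile(pop.theta_bar, (n, 1))
    else:
        mu_ln, sigma_ln = _lognormal_moments(pop.theta_bar, pop.q_theta)
        # eigen-based sampling tolerates exactly-zero marginal variances
        w, v = np.linalg.eigh(sigma_ln)
        root = v * np.sqrt(np.clip(w, 0.0, None))
        z = rng.standard_normal((n, 4))
        theta = np.exp(mu_ln + z @ root.T)
    lo, hi = pop.sigma0_range
    sigma0 = rng.uniform(lo, hi, size=n)
    return Cohort(theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3], sigma0)


def sample_patients(pop: PopulationModel, n: int, seed: int) -> list[PatientParams]:
    """Sample ``n`` virtual patients, reproducibly under ``seed``."""
    cohort = sample_cohort(pop, n, seed)
    return [cohort[i] for i in range(n)]


def nominal_patient(pop: PopulationModel) -> PatientParams:
    """Population-average patient (midpoint sigma0); the estimators' plant model."""
    return pop._nominal  # constructed and validated in __post_init__
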