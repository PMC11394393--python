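"""Vectorized batch execution of plant + observer + filter across many runs.

A "run" is one virtual patient under one constant-rate hemorrhage/resuscitation
scenario.  All runs share the sampling grid, so the plant, the Luenberger
observer and the EKF are advanced in lock-step across the whole batch using the
broadcastable kernels from :mod:`hemoinfer.plant`, :mod:`hemoinfer.lo` and
:mod:`hemoinfer.ekf` — the batch path and the single-run path execute the same
arithmetic.

Runs that trip a stop rule (>25% blood-volume loss or HCT < 10%) have their
plant state frozen from the stop sample on; ``stop_idx`` records where each
run's evaluation ends and downstream scoring ignores later samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lo as lo_mod
from .ekf import EKFConfig
from .errors import InvalidInputError
from .lo import LOConfig
from .plant import _derivs
from .vpg import Cohort

__all__ = ["SimSettings", "BatchResult", "simulate_plant_batch", "run_batch"]

STOP_CAP, STOP_BV25, STOP_HCT10 = 0, 1, 2
STOP_NAMES = {STOP_CAP: "cap", STOP_BV25: "bv25", STOP_HCT10: "hct10"}


@dataclass(frozen=True)
class SimSettings:
    """Timing and integration constants shared by a batch.

    All times in minutes.  ``dt_plant`` is the plant RK4 step, ``dt_meas`` the
    HCT sampling interval, ``n_substeps`` the estimator RK4 sub-steps per
    measurement interval.
    """

    t_settle: float = 10.0
    t_max: float = 480.0
    dt_plant: float = 0.05
    dt_meas: float = 1.0
    n_substeps: int = 4

    def __post_init__(self) -> None:
        if self.dt_plant <= 0 or self.dt_meas <= 0 or self.n_substeps < 1:
            raise InvalidInputError("integration steps must be positive")
        if self.t_max < self.t_settle:
            raise InvalidInputError("t_max must cover the settling period")
        sub = self.dt_meas / self.dt_plant
        if abs(sub - round(sub)) > 1e-9:
            raise InvalidInputError("dt_meas must be an integer multiple of dt_plant")

    @property
    def n_samples(self) -> int:
        """Number of measurement intervals (samples are 0..n_samples)."""
        return int(round(self.t_max / self.dt_meas))

    @property
    def settle_idx(self) -> int:
        return int(round(self.t_settle / self.dt_meas))


@dataclass
class BatchResult:
    """Per-run trajectories and estimator signatures for a batch of N runs."""

    times: np.ndarray          # (T+1,)
    sigma_true: np.ndarray     # (N, T+1)
    sigma_meas: np.ndarray     # (N, T+1)
    x1: np.ndarray             # (N, T+1)
    x2: np.ndarray             # (N, T+1)
    vr: np.ndarray             # (N, T+1)
    sig_lo: np.ndarray         # (N, T+1) observer x3_hat
    sig_ekf: np.ndarray        # (N, T+1) filter x3_hat
    stop_idx: np.ndarray       # (N,) last valid sample index
    stop_reason: np.ndarray    # (N,) codes, see STOP_NAMES
    t_bv25: np.ndarray         # (N,) first sample time with >25% BV loss (nan if never)
    t_hct10: np.ndarray        # (N,) first sample time with HCT < 10% (nan if never)
    settings: SimSettings


def simulate_plant_batch(
    cohort: Cohort, u: np.ndarray, h: np.ndarray, settings: SimSettings
):
    """Integrate N plants with settle-then-constant inputs; freeze after stop.

    Returns (times, sigma_true, x1, stop_idx, stop_reason, t_bv25, t_hct10).
    """
    n = len(cohort)
    u = np.broadcast_to(np.asarray(u, dtype=float), (n,))
    h = np.broadcast_to(np.asarray(h, dtype=float), (n,))
    if np.any(u < 0) or np.any(h < 0):
        raise InvalidInputError("rates must be non-negative")
    p = (cohort.vb0, cohort.alpha_u, cohort.alpha_h, cohort.k)
    n_t = settings.n_samples
    sub = int(round(settings.dt_meas / settings.dt_plant))
    dt = settings.dt_plant

    x1 = np.zeros(n)
    x2 = np.zeros(n)
    vr = cohort.sigma0 * cohort.vb0
    active = np.ones(n, dtype=bool)

    times = np.arange(n_t + 1) * settings.dt_meas
    sigma_rec = np.empty((n, n_t + 1))
    x1_rec = np.empty((n, n_t + 1))
    x2_rec = np.empty((n, n_t + 1))
    vr_rec = np.empty((n, n_t + 1))
    sigma_rec[:, 0] = cohort.sigma0
    x1_rec[:, 0] = 0.0
    x2_rec[:, 0] = 0.0
    vr_rec[:, 0] = vr
    stop_idx = np.full(n, n_t, dtype=np.int64)
    stop_reason = np.full(n, STOP_CAP, dtype=np.int64)
    t_bv25 = np.full(n, np.nan)
    t_hct10 = np.full(n, np.nan)

    for i in range(1, n_t + 1):
        t0 = (i - 1) * settings.dt_meas
        on = 1.0 if t0 >= settings.t_settle else 0.0
        ui, hi = u * on, h * on
        for _ in range(sub):
            k1 = _derivs(x1, x2, vr, ui, hi, *p)
            k2 = _derivs(x1 + 0.5 * dt * k1[0], x2 + 0.5 * dt * k1[1],
                         vr + 0.5 * dt * k1[2], ui, hi, *p)
            k3 = _derivs(x1 + 0.5 * dt * k2[0], x2 + 0.5 * dt * k2[1],
                         vr + 0.5 * dt * k2[2], ui, hi, *p)
            k4 = _derivs(x1 + dt * k3[0], x2 + dt * k3[1], vr + dt * k3[2], ui, hi, *p)
            nx1 = x1 + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            nx2 = x2 + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            nvr = vr + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            x1 = np.where(active, nx1, x1)
            x2 = np.where(active, nx2, x2)
            vr = np.where(active, nvr, vr)
        bv = cohort.vb0 + x1
        sigma = vr / bv
        sigma_rec[:, i] = sigma
        x1_rec[:, i] = x1
        x2_rec[:, i] = x2
        vr_rec[:, i] = vr
        hit_bv = active & (bv < 0.75 * cohort.vb0)
        hit_hct = active & (sigma < 0.10)
        t_bv25[hit_bv & np.isnan(t_bv25)] = times[i]
        t_hct10[hit_hct & np.isnan(t_hct10)] = times[i]
        newly = hit_bv | hit_hct
        if np.any(newly):
            stop_idx[newly] = i
            # BV rule takes precedence when both fire at the same sample
            stop_reason[newly] = np.where(hit_bv[newly], STOP_BV25, STOP_HCT10)
            active &= ~newly
        if not np.any(active):
            sigma_rec[:, i + 1 :] = sigma_rec[:, i : i + 1]
            x1_rec[:, i + 1 :] = x1_rec[:, i : i + 1]
            x2_rec[:, i + 1 :] = x2_rec[:, i : i + 1]
            vr_rec[:, i + 1 :] = vr_rec[:, i : i + 1]
            break
    return times, sigma_rec, x1_rec, x2_rec, vr_rec, stop_idx, stop_reason, t_bv25, t_hct10


def _noise_batch(sigma_true: np.ndarray, noise_sd: np.ndarray, seeds: np.ndarray):
    """Per-run independent Gaussian HCT noise with per-run seeds."""
    n, m = sigma_true.shape
    out = np.empty_like(sigma_true)
    for i in range(n):
        if noise_sd[i] == 0:
            out[i] = sigma_true[i]
        else:
            rng = np.random.default_rng(int(seeds[i]))
            out[i] = np.clip(
                sigma_true[i] + noise_sd[i] * rng.standard_normal(m), 0.001, 0.999
            )
    return out


def run_batch(
    cohort: Cohort,
    u: np.ndarray,
    h: np.ndarray,
    noise_sd: np.ndarray,
    seeds: np.ndarray,
    lo_cfg: LOConfig,
    ekf_cfg_base: EKFConfig,
    settings: SimSettings | None = None,
) -> BatchResult:
    """Simulate N runs and both estimators; one entry per run.

    ``cohort`` carries one patient per run (repeat patients across scenarios to
    build a grid).  ``noise_sd`` may be scalar or per-run; ``seeds`` are per-run
    noise seeds.  The EKF measurement-noise variance is set per run to the
    squared noise level (with the configured floor), mirroring the protocol of
    matching Qv to the known sensor noise; runs are grouped by noise level
    internally so each group runs one vectorized filter.
    """
    settings = settings or SimSettings()
    n = len(cohort)
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n,)).copy()
    seeds = np.broadcast_to(np.asarray(seeds), (n,))
    times, sigma_true, x1_rec, x2_rec, vr_rec, stop_idx, stop_reason, t_bv25, t_hct10 = (
        simulate_plant_batch(cohort, u, h, settings)
    )
    sigma_meas = _noise_batch(sigma_true, noise_sd, seeds)

    # Estimators start at hemorrhage/resuscitation onset: the settling period
    # exists to settle plant transients, and starting the filters there keeps
    # the hemorrhage-state covariance (which receives no parametric process
    # noise) from collapsing on the uninformative pre-onset samples.
    settle = settings.settle_idx
    u = np.broadcast_to(np.asarray(u, dtype=float), (n,))
    sm_est = sigma_meas[:, settle:]
    u_series = np.broadcast_to(u[:, None], sm_est.shape)

    sig_lo = np.zeros_like(sigma_meas)
    sig_lo[:, settle:] = lo_mod.run_lo(
        sm_est, cohort.sigma0, u_series, lo_cfg,
        dt_meas=settings.dt_meas, n_sub=settings.n_substeps,
    )

    sig_ekf = np.zeros_like(sigma_meas)
    from .ekf import run_ekf
    from dataclasses import replace as dc_replace

    for level in np.unique(noise_sd):
        mask = noise_sd == level
        cfg = dc_replace(ekf_cfg_base, q_v=float(level) ** 2)
        sig_ekf[mask, settle:] = run_ekf(
            sm_est[mask], u_series[mask], cfg,
            dt_meas=settings.dt_meas, n_sub=settings.n_substeps,
        )

    return BatchResult(
        times=times,
        sigma_true=sigma_true,
        sigma_meas=sigma_meas,
        x1=x1_rec,
        x2=x2_rec,
        vr=vr_rec,
        sig_lo=sig_lo,
        sig_ekf=sig_ekf,
        stop_idx=stop_idx,
        stop_reason=stop_reason,
        t_bv25=t_bv25,
        t_hct10=t_hct10,
        settings=settings,
    )
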