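"""Turning estimator signatures into hemorrhage detection declarations.

Thresholds are calibrated on hemorrhage-free simulations: the observer
threshold is the minimum x3_hat ever inferred by the LO across the calibration
runs (a negative bound), the filter threshold the maximum x3_hat inferred by
the EKF (a positive bound).  At evaluation time a detector declares hemorrhage
at a sample when its instantaneous condition (x3_hat <= threshold for the LO,
x3_hat >= threshold for the EKF) held in more than half of the samples of the
trailing 10-minute window.  A naive comparator declares when measured HCT has
dropped more than 10% below baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .plant import PatientParams, Trajectory

__all__ = [
    "DetectionConfig",
    "DetectionOutcome",
    "RunResult",
    "find_stop_time",
    "windowed_detector",
    "naive_hct_detector",
    "classify_run",
    "calibrate_thresholds",
    "calibrate_all",
    "CalibrationResult",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detector thresholds and declaration rules.

    ``x3_lo_threshold`` (L/min, <= 0 in noisy conditions) and
    ``x3_ekf_threshold`` (>= 0) come from calibration; each may be a scalar or
    a per-sample threshold curve on the measurement grid.  A declaration at time t
    requires the condition to hold in strictly more than ``majority`` of the
    samples in the window [t - window, t).  ``naive_drop`` is the fractional
    HCT drop of the naive comparator.
    """

    x3_lo_threshold: float = 0.0
    x3_ekf_threshold: float = 0.0
    window: float = 10.0
    majority: float = 0.5
    naive_drop: float = 0.10

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise InvalidInputError("window must be positive")
        if not (0.0 < self.majority < 1.0):
            raise InvalidInputError("majority must lie in (0,1)")
        if not (0.0 < self.naive_drop < 1.0):
            raise InvalidInputError("naive_drop must lie in (0,1)")


@dataclass(frozen=True)
class DetectionOutcome:
    """First declaration, and first declaration whose condition holds to run end.

    ``detect_idx`` is the earliest admissible sample whose trailing window
    satisfies the majority rule (None if never).  ``sustained_idx`` is the
    earliest declaration from which the instantaneous condition stays
    satisfied through the last sample (None if no such declaration), used by
    the corrected metrics.  ``sustained`` flags whether the first declaration
    itself is sustained.
    """

    detect_idx: int | None
    sustained_idx: int | None

    @property
    def sustained(self) -> bool:
        return self.detect_idx is not None and self.detect_idx == self.sustained_idx


@dataclass(frozen=True)
class RunResult:
    """Per-run, per-detector outcome of one in-silico evaluation."""

    vp_id: int
    scenario_id: str
    detector: str
    detect_time: float | None      # min from hemorrhage/resuscitation onset
    detect_time_sustained: float | None
    sustained: bool
    stop_time: float               # min from onset
    stop_reason: str               # bv25 | hct10 | cap
    t_limit: float                 # min(t_bv25, t_hct10, cap) from onset: NDT denominator
    nae: float | None              # rate-estimation error (hemorrhage runs only)

    def __post_init__(self) -> None:
        if self.detect_time is not None and self.detect_time > self.stop_time:
            raise InvalidInputError("detect_time cannot exceed stop_time")


def find_stop_time(traj: Trajectory, params: PatientParams) -> tuple[float, str]:
    """Earliest sample where >25% BV is lost or true HCT is below 10%.

    Returns ``(t_max, "cap")`` when neither rule fires within the trajectory.
    """
    bv_hit = (params.vb0 + traj.x1) < 0.75 * params.vb0
    hct_hit = traj.sigma < 0.10
    hits = np.flatnonzero(bv_hit | hct_hit)
    if len(hits) == 0:
        return float(traj.times[-1]), "cap"
    i = hits[0]
    return float(traj.times[i]), ("bv25" if bv_hit[i] else "hct10")


def _suffix_start(cond: np.ndarray) -> int | None:
    """Index where the trailing all-true run of ``cond`` begins (None if cond[-1] is False)."""
    if not cond[-1]:
        return None
    false_idx = np.flatnonzero(~cond)
    return 0 if len(false_idx) == 0 else int(false_idx[-1]) + 1


def windowed_detector(
    signature: np.ndarray,
    threshold: float,
    direction: Literal["below", "above"],
    cfg: DetectionConfig,
    dt: float = 1.0,
    min_index: int = 0,
) -> DetectionOutcome:
    """Apply the windowed majority rule to a uniformly sampled signature.

    A declaration at sample i requires strictly more than ``cfg.majority`` of
    the ``window/dt`` samples in [t_i - window, t_i) to satisfy the condition;
    the earliest admissible sample is one full window into the series (and at
    least ``min_index``, used to exclude the settling period).
    """
    signature = np.asarray(signature, dtype=float)
    w = int(round(cfg.window / dt))
    if len(signature) <= w:
        return DetectionOutcome(None, None)
    thr = np.asarray(threshold, dtype=float)
    if thr.ndim:  # time-varying threshold curve sampled on the same grid
        if len(thr) < len(signature):
            raise InvalidInputError("threshold curve shorter than signature")
        thr = thr[: len(signature)]
    # strict: the threshold is itself attainable by no-hemorrhage runs
    cond = signature < thr if direction == "below" else signature > thr
    csum = np.concatenate([[0], np.cumsum(cond)])
    # counts[j] = sum of cond[j : j+w]: the window ending just before sample
    # i = j + w, which must itself be a valid sample (j <= len - 1 - w)
    counts = (csum[w:] - csum[:-w])[: len(cond) - w]
    declared = counts > cfg.majority * w
    start = max(w, min_index)
    idx = np.flatnonzero(declared[start - w :])
    detect_idx = int(idx[0]) + start if len(idx) else None
    s = _suffix_start(cond)
    sustained_idx = None
    if s is not None:
        cand = np.flatnonzero(declared[max(start, s) - w :])
        if len(cand):
            sustained_idx = int(cand[0]) + max(start, s)
    return DetectionOutcome(detect_idx, sustained_idx)


def naive_hct_detector(
    sigma_meas: np.ndarray,
    sigma0: float,
    cfg: DetectionConfig,
    min_index: int = 0,
) -> DetectionOutcome:
    """Declare when measured HCT drops below (1 - naive_drop) of baseline.

    No windowing: the first sample at or past ``min_index`` satisfying the
    condition declares.  The sustained declaration mirrors the corrected rule.
    """
    if sigma0 <= 0:
        raise InvalidInputError("sigma0 must be positive")
    sigma_meas = np.asarray(sigma_meas, dtype=float)
    cond = sigma_meas <= (1.0 - cfg.naive_drop) * sigma0
    idx = np.flatnonzero(cond[min_index:])
    detect_idx = int(idx[0]) + min_index if len(idx) else None
    s = _suffix_start(cond)
    sustained_idx = max(s, min_index) if s is not None and detect_idx is not None else None
    return DetectionOutcome(detect_idx, sustained_idx)


def classify_run(
    result: RunResult, has_hemorrhage: bool, corrected: bool
) -> Literal["TP", "FP", "TN", "FN"]:
    """Confusion class of one run.

    Uncorrected: any declaration before the stop rules counts.  Corrected: the
    declaration must additionally start a condition streak that holds to the
    end of the evaluation (detections too late or transient count as negative).
    """
    t = result.detect_time_sustained if corrected else result.detect_time
    detected = t is not None and t <= result.stop_time
    if has_hemorrhage:
        return "TP" if detected else "FN"
    return "FP" if detected else "TN"


@dataclass(frozen=True)
class CalibrationResult:
    """Detection threshold curves and their provenance.

    The thresholds are functions of time since run start, sampled on the
    measurement grid: at each sample the LO threshold is the minimum x3_hat
    (and the EKF threshold the maximum) over all hemorrhage-free calibration
    runs still below their stop rules at that sample.  ``per_noise`` maps each
    HCT noise level to its own ``{"lo": curve, "ekf": curve}`` computed from
    the calibration runs at that level only: a deployed detector knows its
    sensor's noise specification (the same knowledge that sets the filter's
    Qv).  ``x3_lo_threshold`` / ``x3_ekf_threshold`` are the pooled global
    extremes (the most conservative scalar collapse of the curves).
    """

    x3_lo_threshold: float
    x3_ekf_threshold: float
    n_vp: int
    n_runs: int
    seed: int
    grid_hash: str
    per_noise: dict = field(default_factory=dict)

    def thresholds_at(self, noise_level: float):
        """(lo, ekf) threshold curves for a noise level (pooled scalars as fallback)."""
        for key, curves in self.per_noise.items():
            if abs(float(key) - noise_level) < 1e-12:
                return np.asarray(curves["lo"], dtype=float), np.asarray(
                    curves["ekf"], dtype=float
                )
        return self.x3_lo_threshold, self.x3_ekf_threshold

    def to_json(self) -> str:
        payload = dict(self.__dict__)
        payload["per_noise"] = {
            str(k): {"lo": list(map(float, v["lo"])), "ekf": list(map(float, v["ekf"]))}
            for k, v in self.per_noise.items()
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationResult":
        data = json.loads(text)
        data["per_noise"] = {
            float(k): {"lo": np.asarray(v["lo"]), "ekf": np.asarray(v["ekf"])}
            for k, v in data.get("per_noise", {}).items()
        }
        return cls(**data)


def calibrate_all(
    pop,
    grid,
    n_vp: int,
    seed: int,
    lo_cfg,
    ekf_cfg,
    settings=None,
    chunk_size: int = 4096,
) -> CalibrationResult:
    """Calibrate both thresholds from hemorrhage-free runs of the scenario grid.

    Every calibration run applies a scenario's resuscitation rate with the
    hemorrhage rate forced to zero; the LO threshold is the minimum x3_hat and
    the EKF threshold the maximum x3_hat observed across all runs and all
    post-settling samples up to each run's stop time.  The calibration cohort
    is drawn from a dedicated seed stream, disjoint from evaluation cohorts.
    """
    import hashlib

    from .engine import SimSettings, run_batch
    from .vpg import Cohort, derive_seed, sample_cohort

    if len(grid) == 0:
        raise ConfigurationError("calibration grid is empty")
    if n_vp <= 0:
        raise ConfigurationError("calibration cohort must be non-empty")
    settings = settings or SimSettings()
    cohort = sample_cohort(pop, n_vp, derive_seed(seed, 1))

    vp_idx, u_rates, noise, seeds = [], [], [], []
    for i in range(n_vp):
        for j, sc in enumerate(grid):
            vp_idx.append(i)
            u_rates.append(sc.u_rate)
            noise.append(sc.noise_level)
            seeds.append(derive_seed(seed, 1, i, j))
    vp_idx = np.asarray(vp_idx)
    u_rates = np.asarray(u_rates)
    noise = np.asarray(noise)
    seeds = np.asarray(seeds)

    levels = sorted({float(sc.noise_level) for sc in grid})
    n_t = settings.n_samples
    lo_min = {lev: np.full(n_t + 1, np.inf) for lev in levels}
    ekf_max = {lev: np.full(n_t + 1, -np.inf) for lev in levels}
    n_runs = len(vp_idx)
    for lo_chunk in range(0, n_runs, chunk_size):
        sl = slice(lo_chunk, min(lo_chunk + chunk_size, n_runs))
        idx = vp_idx[sl]
        sub = Cohort(
            cohort.vb0[idx], cohort.alpha_u[idx], cohort.alpha_h[idx],
            cohort.k[idx], cohort.sigma0[idx],
        )
        res = run_batch(
            sub, u_rates[sl], np.zeros(len(idx)), noise[sl], seeds[sl],
            lo_cfg, ekf_cfg, settings,
        )
        # mask samples after each run's stop so they cannot shape the curves
        alive = np.arange(n_t + 1)[None, :] <= res.stop_idx[:, None]
        sig_lo = np.where(alive, res.sig_lo, np.inf)
        sig_ekf = np.where(alive, res.sig_ekf, -np.inf)
        chunk_noise = noise[sl]
        for lev in levels:
            m = chunk_noise == lev
            if np.any(m):
                lo_min[lev] = np.minimum(lo_min[lev], sig_lo[m].min(axis=0))
                ekf_max[lev] = np.maximum(ekf_max[lev], sig_ekf[m].max(axis=0))

    start = settings.settle_idx
    per_noise = {}
    for lev in levels:
        # hold the last finite value where no calibration run is still alive
        lo_c, ekf_c = lo_min[lev], ekf_max[lev]
        lo_c[:start] = 0.0
        ekf_c[:start] = 0.0
        for curve, fill in ((lo_c, np.inf), (ekf_c, -np.inf)):
            bad = ~np.isfinite(curve)
            if np.any(bad):
                idx_last = np.maximum.accumulate(np.where(bad, 0, np.arange(n_t + 1)))
                curve[:] = curve[idx_last]
        per_noise[lev] = {"lo": lo_c, "ekf": ekf_c}

    grid_hash = hashlib.sha256(
        "|".join(sc.scenario_id for sc in grid).encode()
    ).hexdigest()[:16]
    return CalibrationResult(
        x3_lo_threshold=float(min(c["lo"][start:].min() for c in per_noise.values())),
        x3_ekf_threshold=float(max(c["ekf"][start:].max() for c in per_noise.values())),
        n_vp=n_vp,
        n_runs=n_runs,
        seed=seed,
        grid_hash=grid_hash,
        per_noise=per_noise,
    )


def calibrate_thresholds(
    pop, grid, estimator: Literal["lo", "ekf"], n_vp: int, seed: int,
    lo_cfg, ekf_cfg, settings=None,
) -> float:
    """Scalar threshold for one estimator (min rule for the LO, max for the EKF)."""
    cal = calibrate_all(pop, grid, n_vp, seed, lo_cfg, ekf_cfg, settings)
    if estimator == "lo":
        return cal.x3_lo_threshold
    if estimator == "ekf":
        return cal.x3_ekf_threshold
    raise ConfigurationError(f"unknown estimator {estimator!r}")
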