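"""Scenario grid, batch execution, and detection/estimation metrics.

The evaluation protocol crosses a cohort of virtual patients with a grid of
constant-rate scenarios: hemorrhage rates 0.01-0.10 L/min (step 0.01),
resuscitation rates 10-190% of the hemorrhage rate (step 20%), and HCT noise
levels 0-3%, plus a hemorrhage-free twin of every scenario carrying the same
absolute resuscitation rate.  Each run is scored for detection (confusion
class, uncorrected and corrected), detection speed (NDT: detection time over
time to 25% BV loss or 10% HCT) and rate-estimation accuracy (NAE: mean
absolute rate error over the last 10% of the run, normalized by the true
rate).
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detection import (
    CalibrationResult,
    DetectionConfig,
    RunResult,
    calibrate_all,
    classify_run,
    naive_hct_detector,
    windowed_detector,
)
from .ekf import EKFConfig
from .engine import STOP_NAMES, BatchResult, SimSettings, run_batch
from .errors import ConfigurationError, EmptyCohortError, InvalidInputError
from .lo import LOConfig, lo_rate_upper_bound
from .plant import PatientParams
from .vpg import Cohort, PopulationModel, derive_seed, nominal_patient, sample_cohort

__all__ = [
    "Scenario",
    "build_scenario_grid",
    "run_scenario",
    "compute_confusion_scores",
    "compute_ndt",
    "compute_nae",
    "paired_t_bonferroni",
    "full_grid_evaluation",
    "MetricsReport",
    "DEFAULT_HEM_RATES",
    "DEFAULT_U_FRACS",
    "DEFAULT_NOISE_LEVELS",
]

DEFAULT_HEM_RATES = tuple(np.round(np.arange(0.01, 0.101, 0.01), 3))
DEFAULT_U_FRACS = tuple(np.round(np.arange(0.1, 1.91, 0.2), 2))
DEFAULT_NOISE_LEVELS = (0.0, 0.01, 0.02, 0.03)
DETECTORS = ("lo", "ekf", "naive")


@dataclass(frozen=True)
class Scenario:
    """One constant-rate evaluation condition.

    ``h_rate`` is the hemorrhage rate actually applied (0 for the
    hemorrhage-free twin); ``u_rate`` is always ``u_frac * H`` of the parent
    hemorrhage rate, so twins exercise the same resuscitation input.
    """

    H: float
    u_frac: float
    noise_level: float
    with_hemorrhage: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.H <= 0.5):
            raise InvalidInputError("hemorrhage grid rate must be positive")
        if self.u_frac < 0 or self.noise_level < 0:
            raise InvalidInputError("u_frac and noise_level must be non-negative")

    @property
    def h_rate(self) -> float:
        return self.H if self.with_hemorrhage else 0.0

    @property
    def u_rate(self) -> float:
        return round(self.u_frac * self.H, 12)

    @property
    def scenario_id(self) -> str:
        tag = "hem" if self.with_hemorrhage else "nohem"
        return f"H{self.H:g}_f{self.u_frac:g}_n{self.noise_level:g}_{tag}"


def build_scenario_grid(
    hem_rates=DEFAULT_HEM_RATES,
    u_fracs=DEFAULT_U_FRACS,
    noise_levels=DEFAULT_NOISE_LEVELS,
    with_twins: bool = True,
) -> list[Scenario]:
    """Full factorial scenario list; the default grid has 800 scenarios
    (10 hemorrhage rates x 10 resuscitation fractions x 4 noise levels, each
    with a hemorrhage-free twin)."""
    grid = [
        Scenario(H=float(h), u_frac=float(f), noise_level=float(n), with_hemorrhage=True)
        for n in noise_levels
        for h in hem_rates
        for f in u_fracs
    ]
    if with_twins:
        grid += [
            Scenario(H=s.H, u_frac=s.u_frac, noise_level=s.noise_level, with_hemorrhage=False)
            for s in grid[: len(grid)]
        ]
    return grid


def compute_confusion_scores(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Standard detection scores; ratios with empty denominators are None."""
    if min(tp, fp, tn, fn) < 0:
        raise InvalidInputError("confusion counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise EmptyCohortError("no scored runs")

    def ratio(a, b):
        return a / b if b > 0 else None

    return {
        "precision": ratio(tp, tp + fp),
        "recall": ratio(tp, tp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": (tp + tn) / (tp + fp + tn + fn),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
    }


def compute_ndt(detect_time: float, t_bv25: float | None, t_hct10: float | None) -> float:
    """Normalized detection time: detection over the earlier survival limit."""
    limits = [t for t in (t_bv25, t_hct10) if t is not None]
    if not limits:
        raise InvalidInputError("at least one limit time is required")
    denom = min(limits)
    if denom <= 0:
        raise InvalidInputError("degenerate run: non-positive limit time")
    return detect_time / denom


def compute_nae(h_true: float, estimate: np.ndarray, times: np.ndarray | None = None) -> float:
    """Normalized absolute rate error over the final 10% of the evaluation."""
    if h_true <= 0:
        raise InvalidInputError("NAE is only defined for hemorrhage runs (H > 0)")
    estimate = np.asarray(estimate, dtype=float)
    if estimate.size == 0:
        raise InvalidInputError("empty estimate series")
    if times is not None:
        times = np.asarray(times, dtype=float)
        t_cut = times[-1] - 0.1 * (times[-1] - times[0])
        tail = estimate[times >= t_cut]
    else:
        k = max(1, math.ceil(0.1 * estimate.size))
        tail = estimate[-k:]
    return float(np.mean(np.abs(tail - h_true)) / h_true)


TTestResult = namedtuple("TTestResult", ["t", "p", "significant", "degenerate"])


def paired_t_bonferroni(metric_a, metric_b, n_comparisons: int) -> TTestResult:
    """Paired t-test with Bonferroni-corrected significance (p < 0.05/m).

    Zero-variance differences short-circuit: identical vectors are not
    significant; a constant nonzero difference is (flagged degenerate).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidInputError("paired samples must be equal-length 1-D, n >= 2")
    alpha = 0.05 / n_comparisons
    d = a - b
    if np.std(d) == 0:
        if np.all(d == 0):
            return TTestResult(0.0, 1.0, False, True)
        return TTestResult(math.copysign(math.inf, d[0]), 0.0, True, True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(t), float(p), bool(p < alpha), False)


def _score_run(
    res: BatchResult,
    i: int,
    vp_id: int,
    scenario: Scenario,
    sigma0: float,
    det_cfg: DetectionConfig,
    alpha_h_nominal: float,
) -> dict:
    """Score one run of a batch for all three detectors; returns row dicts."""
    s = res.settings
    settle = s.settle_idx
    end = int(res.stop_idx[i])
    w = int(round(det_cfg.window / s.dt_meas))
    min_idx = settle + w  # one full window past onset before any declaration
    t_on = s.t_settle

    sig_lo = res.sig_lo[i, : end + 1]
    sig_ekf = res.sig_ekf[i, : end + 1]
    sm = res.sigma_meas[i, : end + 1]

    outcomes = {
        "lo": windowed_detector(sig_lo, det_cfg.x3_lo_threshold, "below",
                                det_cfg, s.dt_meas, min_idx),
        "ekf": windowed_detector(sig_ekf, det_cfg.x3_ekf_threshold, "above",
                                 det_cfg, s.dt_meas, min_idx),
        "naive": naive_hct_detector(sm, sigma0, det_cfg, min_index=settle + 1),
    }

    stop_time = res.times[end] - t_on
    limits = [t - t_on for t in (res.t_bv25[i], res.t_hct10[i]) if np.isfinite(t)]
    t_limit = min(limits) if limits else s.t_max - t_on

    estimates = {
        "lo": lo_rate_upper_bound(sig_lo, alpha_h_nominal),
        "ekf": sig_ekf,
        "naive": None,
    }

    rows = {}
    for det, out in outcomes.items():
        nae = None
        if scenario.with_hemorrhage and estimates[det] is not None:
            nae = compute_nae(
                scenario.H, estimates[det][settle:], res.times[settle : end + 1]
            )
        result = RunResult(
            vp_id=vp_id,
            scenario_id=scenario.scenario_id,
            detector=det,
            detect_time=(res.times[out.detect_idx] - t_on
                         if out.detect_idx is not None else None),
            detect_time_sustained=(res.times[out.sustained_idx] - t_on
                                   if out.sustained_idx is not None else None),
            sustained=out.sustained,
            stop_time=stop_time,
            stop_reason=STOP_NAMES[int(res.stop_reason[i])],
            t_limit=t_limit,
            nae=nae,
        )
        cls = classify_run(result, scenario.with_hemorrhage, corrected=False)
        cls_cor = classify_run(result, scenario.with_hemorrhage, corrected=True)
        ndt = None
        if scenario.with_hemorrhage and result.detect_time is not None:
            ndt = compute_ndt(result.detect_time, result.t_limit, None)
        rows[det] = {
            "vp_id": vp_id,
            "scenario_id": scenario.scenario_id,
            "detector": det,
            "noise_level": scenario.noise_level,
            "with_hemorrhage": scenario.with_hemorrhage,
            "H": scenario.H,
            "u_rate": scenario.u_rate,
            "detect_time": result.detect_time,
            "detect_time_sustained": result.detect_time_sustained,
            "stop_time": result.stop_time,
            "stop_reason": result.stop_reason,
            "t_limit": result.t_limit,
            "cls": cls,
            "cls_corrected": cls_cor,
            "ndt": ndt,
            "nae": nae,
        }
    return rows


def run_scenario(
    patient: PatientParams,
    scenario: Scenario,
    lo_cfg: LOConfig,
    ekf_cfg: EKFConfig,
    det_cfg: DetectionConfig,
    seed: int,
    settings: SimSettings | None = None,
    vp_id: int = 0,
) -> dict[str, RunResult]:
    """Simulate one patient under one scenario and score all three detectors.

    This is the single-run path through the same batch engine (N = 1);
    reproducible under ``seed``.
    """
    settings = settings or SimSettings()
    cohort = Cohort.from_params([patient])
    res = run_batch(
        cohort,
        np.array([scenario.u_rate]),
        np.array([scenario.h_rate]),
        np.array([scenario.noise_level]),
        np.array([seed]),
        lo_cfg,
        ekf_cfg,
        settings,
    )
    rows = _score_run(
        res, 0, vp_id, scenario, patient.sigma0, det_cfg,
        lo_cfg.params_nominal.alpha_h,
    )
    out = {}
    for det, row in rows.items():
        out[det] = RunResult(
            vp_id=vp_id,
            scenario_id=scenario.scenario_id,
            detector=det,
            detect_time=row["detect_time"],
            detect_time_sustained=row["detect_time_sustained"],
            sustained=row["detect_time"] is not None
            and row["detect_time"] == row["detect_time_sustained"],
            stop_time=row["stop_time"],
            stop_reason=row["stop_reason"],
            t_limit=row["t_limit"],
            nae=row["nae"],
        )
    return out


@dataclass
class MetricsReport:
    """Cohort-level evaluation report.

    ``runs`` has one row per run per detector; ``per_vp`` one row per
    (vp, noise level, detector) with uncorrected and corrected scores;
    ``summary`` maps noise level -> detector -> metric -> (mean, sd) over VPs.
    """

    runs: pd.DataFrame
    per_vp: pd.DataFrame
    summary: dict
    thresholds: CalibrationResult
    tests: dict
    provenance: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for noise, dets in self.summary.items():
            for det, metrics in dets.items():
                for m, (mean, sd) in metrics.items():
                    rows.append(
                        {"noise_level": noise, "detector": det, "metric": m,
                         "mean": mean, "sd": sd}
                    )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "thresholds": {
                "x3_lo_threshold": self.thresholds.x3_lo_threshold,
                "x3_ekf_threshold": self.thresholds.x3_ekf_threshold,
                "n_vp": self.thresholds.n_vp,
                "n_runs": self.thresholds.n_runs,
                "grid_hash": self.thresholds.grid_hash,
            },
            "summary": {
                str(noise): {
                    det: {m: list(v) for m, v in mets.items()}
                    for det, mets in dets.items()
                }
                for noise, dets in self.summary.items()
            },
            "tests": {
                name: {"t": r.t, "p": r.p, "significant": r.significant,
                       "degenerate": r.degenerate}
                for name, r in self.tests.items()
            },
        }


_SCORED_METRICS = ("precision", "recall", "sensitivity", "specificity", "accuracy", "f1")


def _per_vp_metrics(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-(vp, noise, detector) confusion counts, scores, NDT and NAE means."""
    out = []
    for (vp, noise, det), grp in rows.groupby(["vp_id", "noise_level", "detector"]):
        rec = {"vp_id": vp, "noise_level": noise, "detector": det,
               "n_runs": len(grp)}
        for tag, col in (("", "cls"), ("corrected_", "cls_corrected")):
            counts = grp[col].value_counts()
            tp, fp = int(counts.get("TP", 0)), int(counts.get("FP", 0))
            tn, fn = int(counts.get("TN", 0)), int(counts.get("FN", 0))
            scores = compute_confusion_scores(tp, fp, tn, fn)
            rec.update({f"{tag}{m}": scores[m] for m in _SCORED_METRICS})
            rec.update({f"{tag}tp": tp, f"{tag}fp": fp, f"{tag}tn": tn, f"{tag}fn": fn})
        ndt = grp["ndt"].dropna()
        nae = grp.loc[grp["with_hemorrhage"], "nae"].dropna()
        rec["ndt_mean"] = float(ndt.mean()) if len(ndt) else None
        rec["nae_mean"] = float(nae.mean()) if len(nae) else None
        out.append(rec)
    return pd.DataFrame(out)


def full_grid_evaluation(config) -> MetricsReport:
    """Calibrate, run the evaluation grid on a fresh cohort, and score it.

    ``config`` is a :class:`hemoinfer.config.RunConfig`.  Deterministic given
    its master seed: the calibration cohort, evaluation cohort and every
    run's noise stream derive from independent counter-based sub-seeds.
    """
    from .config import RunConfig  # local import to avoid cycle

    cfg: RunConfig = config
    pop = cfg.population_model()
    nominal = nominal_patient(pop)
    lo_cfg = LOConfig(params_nominal=nominal, poles=tuple(cfg.lo.poles))
    ekf_cfg = cfg.ekf_config(pop, nominal)
    settings = cfg.sim_settings()
    seed = cfg.master_seed

    calib_grid = build_scenario_grid(
        cfg.grid.hem_rates, cfg.grid.u_fracs, cfg.grid.noise_levels_calib
    )
    thresholds = calibrate_all(
        pop, calib_grid, cfg.grid.n_vp_calib, seed, lo_cfg, ekf_cfg, settings,
        chunk_size=cfg.grid.chunk_size,
    )

    def det_cfg_for(noise_level: float) -> DetectionConfig:
        thr_lo, thr_ekf = thresholds.thresholds_at(noise_level)
        return DetectionConfig(
            x3_lo_threshold=thr_lo,
            x3_ekf_threshold=thr_ekf,
            window=cfg.detection.window,
            majority=cfg.detection.majority,
            naive_drop=cfg.detection.naive_drop,
        )

    det_cfgs = {
        float(n): det_cfg_for(float(n)) for n in cfg.grid.noise_levels_eval
    }

    eval_grid = build_scenario_grid(
        cfg.grid.hem_rates, cfg.grid.u_fracs, cfg.grid.noise_levels_eval
    )
    cohort = sample_cohort(pop, cfg.grid.n_vp_eval, derive_seed(seed, 2))

    vp_idx = np.repeat(np.arange(cfg.grid.n_vp_eval), len(eval_grid))
    scen_idx = np.tile(np.arange(len(eval_grid)), cfg.grid.n_vp_eval)
    u = np.array([eval_grid[j].u_rate for j in scen_idx])
    h = np.array([eval_grid[j].h_rate for j in scen_idx])
    noise = np.array([eval_grid[j].noise_level for j in scen_idx])
    seeds = np.array(
        [derive_seed(seed, 3, int(i), int(j)) for i, j in zip(vp_idx, scen_idx)]
    )

    rows = []
    n_runs = len(vp_idx)
    chunk = cfg.grid.chunk_size
    for start in range(0, n_runs, chunk):
        sl = slice(start, min(start + chunk, n_runs))
        idx = vp_idx[sl]
        sub = Cohort(cohort.vb0[idx], cohort.alpha_u[idx], cohort.alpha_h[idx],
                     cohort.k[idx], cohort.sigma0[idx])
        res = run_batch(sub, u[sl], h[sl], noise[sl], seeds[sl],
                        lo_cfg, ekf_cfg, settings)
        for r in range(len(idx)):
            g = start + r
            scenario = eval_grid[scen_idx[g]]
            scored = _score_run(
                res, r, int(vp_idx[g]), scenario,
                float(cohort.sigma0[vp_idx[g]]),
                det_cfgs[float(scenario.noise_level)], nominal.alpha_h,
            )
            rows.extend(scored.values())

    runs = pd.DataFrame(rows)
    per_vp = _per_vp_metrics(runs)

    summary: dict = {}
    for noise_level in sorted(runs["noise_level"].unique()):
        summary[float(noise_level)] = {}
        sub_vp = per_vp[per_vp["noise_level"] == noise_level]
        for det in DETECTORS:
            det_vp = sub_vp[sub_vp["detector"] == det]
            mets = {}
            for m in (*_SCORED_METRICS,
                      *[f"corrected_{x}" for x in _SCORED_METRICS],
                      "ndt_mean", "nae_mean"):
                vals = det_vp[m].dropna().astype(float)
                mets[m] = (
                    (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
                    if len(vals) else (None, None)
                )
            summary[float(noise_level)][det] = mets

    tests = {}
    primary = cfg.grid.primary_noise
    prim_vp = per_vp[per_vp["noise_level"] == primary]
    if len(prim_vp):
        pivots = {
            det: prim_vp[prim_vp["detector"] == det].set_index("vp_id")
            for det in DETECTORS
        }
        pairs = [("lo", "naive"), ("ekf", "naive"), ("ekf", "lo")]
        for metric in ("f1", "corrected_f1", "ndt_mean"):
            for a, b in pairs:
                va = pivots[a][metric].astype(float)
                vb = pivots[b][metric].reindex(va.index).astype(float)
                ok = va.notna() & vb.notna()
                if ok.sum() >= 2:
                    tests[f"{metric}:{a}_vs_{b}"] = paired_t_bonferroni(
                        va[ok].to_numpy(), vb[ok].to_numpy(), n_comparisons=3
                    )

    provenance = {
        "master_seed": seed,
        "config_hash": cfg.config_hash(),
        "n_vp_eval": cfg.grid.n_vp_eval,
        "n_vp_calib": cfg.grid.n_vp_calib,
        "n_eval_runs": int(n_runs),
        "n_scenarios": len(eval_grid),
    }
    return MetricsReport(
        runs=runs, per_vp=per_vp, summary=summary,
        thresholds=thresholds, tests=tests, provenance=provenance,
    )
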