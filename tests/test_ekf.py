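"""Extended Kalman filter: model derivatives, Jacobians, predict/correct, recovery."""

from dataclasses import replace

import numpy as np
import pytest

from hemoinfer import (
    Cohort,
    EKFConfig,
    EKFState,
    PatientParams,
    ekf_correct,
    ekf_dynamics,
    ekf_predict,
    ekf_rate_estimate,
    jacobian_F,
    jacobian_H,
    jacobian_Jtheta,
    run_batch,
)

P = PatientParams(vb0=5.0, alpha_u=0.5, alpha_h=2.0, k=0.1, sigma0=0.40)


def central_diff(f, x, eps=1e-6):
    x = np.asarray(x, dtype=float)
    cols = []
    for j in range(len(x)):
        dx = np.zeros_like(x)
        dx[j] = eps
        cols.append((f(x + dx) - f(x - dx)) / (2 * eps))
    return np.column_stack(cols)


class TestDynamics:
    def test_direct_evaluation(self):
        got = ekf_dynamics(np.array([0.0, 0.0, 0.03, 2.0]), 0.0, P)
        assert got == pytest.approx([-0.03, -0.01, 0.0, -0.012])

    def test_equilibrium(self):
        got = ekf_dynamics(np.array([0.7, 0.7, 0.0, 2.0]), 0.0, P)
        assert np.allclose(got, 0.0)

    def test_consistent_with_plant_rbc_loss(self):
        # dx4/dt = -x3 * sigma matches the plant's dVR/dt at identical state
        from hemoinfer import PlantState, plant_derivatives

        x = np.array([-0.5, 0.1, 0.04, 1.8])
        d = ekf_dynamics(x, 0.02, P)
        _, _, dvr = plant_derivatives(PlantState(x[0], x[1], x[3]), P, 0.02, x[2])
        assert d[3] == pytest.approx(dvr)


class TestJacobians:
    X = np.array([-0.4, 0.2, 0.035, 1.7])
    U = 0.04

    def test_F_matches_central_differences(self):
        f = jacobian_F(self.X, self.U, P)
        num = central_diff(lambda x: ekf_dynamics(x, self.U, P), self.X)
        assert np.max(np.abs(f - num)) < 1e-6

    def test_F_structure(self):
        f = jacobian_F(self.X, self.U, P)
        assert np.allclose(f[2], 0.0)  # random-walk row
        x0 = np.array([0.0, 0.0, 0.0, 2.0])
        f0 = jacobian_F(x0, 0.0, P)
        assert np.allclose(f0[3], [0.0, 0.0, -2.0 / 5.0, 0.0])

    def test_Jtheta_matches_central_differences(self):
        def f_of_theta(th):
            pp = PatientParams(th[0], th[1], th[2], th[3], P.sigma0)
            return ekf_dynamics(self.X, self.U, pp)

        j = jacobian_Jtheta(self.X, self.U, P)
        num = central_diff(f_of_theta, P.theta)
        assert np.max(np.abs(j - num)) < 1e-6

    def test_Jtheta_structure(self):
        assert np.allclose(jacobian_Jtheta(np.zeros(4), 0.0, P), 0.0)
        j = jacobian_Jtheta(self.X, self.U, P)
        assert j[1, 1] == pytest.approx(-self.U / (1 + P.alpha_u) ** 2)

    def test_H_matches_central_differences(self):
        h = jacobian_H(self.X, P)
        num = central_diff(
            lambda x: np.atleast_1d(x[3] / (x[0] + P.vb0)), self.X
        ).ravel()
        assert np.max(np.abs(h - num)) < 1e-6

    def test_H_direct(self):
        assert jacobian_H(np.array([0.0, 0.0, 0.0, 2.0]), P) == pytest.approx(
            [-0.08, 0.0, 0.0, 0.2]
        )
        assert jacobian_H(np.array([0.0, 0.0, 0.0, 0.0]), P)[0] == 0.0


@pytest.fixture()
def cfg(pop, nominal):
    return EKFConfig(params_nominal=nominal, q_theta=pop.q_theta, q_v=1e-4)


class TestPredict:
    def test_equilibrium_invariant_without_noise_sources(self, nominal):
        # equilibrium mean and zero prior uncertainty: nothing can move
        # (a nonzero P would still evolve through F P + P F')
        cfg0 = EKFConfig(params_nominal=nominal, q_theta=np.zeros((4, 4)),
                         q_v=1e-4, q_floor=0.0)
        x0 = np.array([0.0, 0.0, 0.0, 2.0])
        st = ekf_predict(EKFState(xhat=x0, p=np.zeros((4, 4))), u=0.0, dt=1.0, cfg=cfg0)
        assert np.allclose(st.xhat, x0)
        assert np.allclose(st.p, 0.0, atol=1e-15)

    def test_floor_growth_at_origin(self, nominal):
        # at the origin Jtheta = 0, so P grows by the floor alone: ~q*dt*I
        q = 1e-6
        cfg0 = EKFConfig(params_nominal=nominal, q_theta=np.zeros((4, 4)),
                         q_v=1e-4, q_floor=q)
        x0 = np.array([0.0, 0.0, 0.0, 0.0])
        st = ekf_predict(EKFState(xhat=x0, p=np.zeros((4, 4))), 0.0, 0.01, cfg0)
        assert np.allclose(st.p, q * 0.01 * np.eye(4), rtol=0.02)

    def test_covariance_matches_van_loan_discretization(self, cfg):
        # frozen-Jacobian linear oracle: P1 = Phi P0 Phi' + Qd via van Loan
        from scipy.linalg import expm

        x = np.array([-0.2, 0.1, 0.02, 1.9])
        p0 = np.diag([0.01, 0.01, 4e-4, 0.01])
        dt = 0.01  # short enough that the Jacobian barely moves
        f = jacobian_F(x, 0.03, cfg.params_nominal)
        j = jacobian_Jtheta(x, 0.03, cfg.params_nominal)
        qw = j @ cfg.q_theta @ j.T + cfg.q_floor * np.eye(4)
        m = np.zeros((8, 8))
        m[:4, :4] = -f * dt
        m[:4, 4:] = qw * dt
        m[4:, 4:] = f.T * dt
        e = expm(m)
        phi = e[4:, 4:].T
        qd = phi @ e[:4, 4:]
        oracle = phi @ p0 @ phi.T + qd
        st = ekf_predict(EKFState(xhat=x, p=p0), 0.03, dt, cfg, n_sub=1)
        # residual is O(dt^2) from the oracle freezing F at the initial state
        assert np.max(np.abs(st.p - oracle)) < 1e-9


class TestCorrect:
    def test_zero_innovation_keeps_mean(self, cfg):
        x = np.array([0.0, 0.0, 0.0, 2.0])
        st = EKFState(xhat=x, p=np.eye(4) * 0.01)
        new = ekf_correct(st, y=2.0 / 5.0, cfg=cfg)
        assert np.allclose(new.xhat, x)

    def test_infinite_noise_disables_update(self, nominal, pop):
        big = EKFConfig(params_nominal=nominal, q_theta=pop.q_theta, q_v=1e12)
        x = np.array([0.0, 0.0, 0.0, 2.0])
        st = EKFState(xhat=x, p=np.eye(4) * 0.01)
        new = ekf_correct(st, y=0.5, cfg=big)
        assert np.allclose(new.xhat, x, atol=1e-8)
        assert np.allclose(new.p, st.p, atol=1e-8)

    def test_matches_information_filter(self, cfg):
        # posterior covariance equals (P^-1 + H' H / Qv)^-1 for the same numbers
        x = np.array([0.1, -0.1, 0.01, 1.95])
        st = EKFState(xhat=x, p=np.eye(4))
        new = ekf_correct(st, y=0.41, cfg=cfg)
        h = jacobian_H(x, cfg.params_nominal)[None, :]
        oracle = np.linalg.inv(np.eye(4) + h.T @ h / cfg.qv_eff)
        assert np.max(np.abs(new.p - oracle)) < 1e-8

    def test_psd_after_corrections(self, nominal, lo_cfg, ekf_cfg, pop):
        # covariance stays numerically PSD along a noisy mismatched run
        from hemoinfer.ekf import run_ekf
        from hemoinfer.vpg import sample_cohort

        coh = sample_cohort(pop, 1, seed=21)
        res = run_batch(coh, np.array([0.05]), np.array([0.03]), np.array([0.01]),
                        np.array([3]), lo_cfg, ekf_cfg)
        end = int(res.stop_idx[0])
        cfg1 = replace(ekf_cfg, q_v=1e-4)
        st = EKFState(
            xhat=np.array([0.0, 0.0, 0.0, res.sigma_meas[0, 10] * nominal.vb0]),
            p=cfg1.p0.copy(),
        )
        for k in range(11, end + 1):
            st = ekf_predict(st, 0.05, 1.0, cfg1)
            st = ekf_correct(st, res.sigma_meas[0, k], cfg1)
            assert np.allclose(st.p, st.p.T, atol=1e-10)
            assert np.linalg.eigvalsh(st.p).min() >= -1e-10


class TestRateEstimate:
    def test_reads_x3(self):
        st = EKFState(xhat=np.array([0.0, 0.0, 0.05, 2.0]), p=np.eye(4))
        assert ekf_rate_estimate(st) == pytest.approx(0.05)

    def test_fresh_filter_reports_zero(self, cfg):
        st = EKFState(xhat=np.array([0.0, 0.0, 0.0, 0.4 * 5.0]), p=cfg.p0)
        assert ekf_rate_estimate(st) == 0.0

    @pytest.mark.parametrize("H", [0.01, 0.05, 0.1])
    def test_twin_experiment_recovery(self, H, nominal, lo_cfg, pop):
        # matched parameters, no measurement noise: the inferred hemorrhage
        # rate lands within 2% of truth by the end of the evaluation
        coh = Cohort.from_params([nominal])
        ekf_cfg = EKFConfig(params_nominal=nominal, q_theta=pop.q_theta,
                            q_v=0.0, qv_floor=1e-6)
        res = run_batch(coh, np.array([0.5 * H]), np.array([H]), np.array([0.0]),
                        np.array([0]), lo_cfg, ekf_cfg)
        end = int(res.stop_idx[0])
        assert abs(res.sig_ekf[0, end] - H) / H < 0.02

    def test_signature_within_three_sigma_without_hemorrhage(self, nominal, pop):
        # matched resuscitation-only run: x3_hat stays inside its own 3-sigma
        from hemoinfer.ekf import run_ekf

        cfg1 = EKFConfig(params_nominal=nominal, q_theta=pop.q_theta, q_v=1e-4)
        coh = Cohort.from_params([nominal])
        from hemoinfer import LOConfig

        res = run_batch(coh, np.array([0.05]), np.array([0.0]), np.array([0.01]),
                        np.array([5]), LOConfig(params_nominal=nominal), cfg1)
        end = int(res.stop_idx[0])
        sig, p33 = run_ekf(res.sigma_meas[:1, 10 : end + 1],
                           np.full((1, end - 9), 0.05), cfg1, store_p33=True)
        assert np.all(np.abs(sig[0]) <= 3.0 * np.sqrt(p33[0]) + 1e-12)
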