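"""IVA estimator tests: objective identities, recovery, ensembles, joint-ISI."""

import numpy as np
import pytest

from scvrelate import (
    BlockSpec,
    build_scv_covariance,
    iva_l_sos,
    joint_isi,
    mix,
    objective,
    reference_design,
    run_ensemble,
    sample_laplacian_scv,
    simulate,
)


class TestJointIsi:
    def test_exact_inverse_is_zero(self, rng):
        A = [rng.standard_normal((4, 4)) for _ in range(3)]
        W = [np.linalg.inv(a) for a in A]
        assert joint_isi(W, A) == pytest.approx(0.0, abs=1e-12)

    def test_shared_permutation_and_scaling_is_zero(self, rng):
        A = [rng.standard_normal((4, 4)) for _ in range(3)]
        P = np.eye(4)[[2, 0, 3, 1]]
        D = np.diag([2.0, -1.0, 0.5, 3.0])
        W = [P @ D @ np.linalg.inv(a) for a in A]
        assert joint_isi(W, A) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_crosstalk_is_one(self):
        A = [np.eye(3)] * 2
        W = [np.ones((3, 3))] * 2
        assert joint_isi(W, A) == pytest.approx(1.0)


class TestObjective:
    def test_logdet_and_density_terms_cancel_under_global_scaling(self, rng):
        # analytic identity of the profiled cost: scaling every W[k] by c
        # raises each 0.5 logdet C_r term by K log c, leaves the profiled
        # Laplacian term invariant (q is scale-free), and lowers the
        # -log|det W| term by R K log c — a net change of zero
        X = [rng.standard_normal((3, 400)) for _ in range(2)]
        W = [np.linalg.qr(rng.standard_normal((3, 3)))[0] for _ in range(2)]
        J0 = objective(W, X)
        for c in (2.0, 0.25):
            Wc = [w * c for w in W]
            assert objective(Wc, X) == pytest.approx(J0, rel=1e-6)

    def test_invariant_to_scv_permutation(self, rng):
        X = [rng.standard_normal((4, 300)) for _ in range(3)]
        W = [np.linalg.qr(rng.standard_normal((4, 4)))[0] for _ in range(3)]
        perm = [2, 0, 3, 1]
        Wp = [w[perm] for w in W]
        assert objective(Wp, X) == pytest.approx(objective(W, X), rel=1e-10)

    def test_singular_w_is_infinite(self, rng):
        X = [rng.standard_normal((3, 200))]
        W = [np.zeros((3, 3))]
        assert objective(W, X) == np.inf

    def test_planted_inverse_beats_random(self, mixture_rho05, rng):
        W_true = [np.linalg.inv(A) for A in mixture_rho05.mixing]
        J_true = objective(W_true, mixture_rho05.observations)
        wins = 0
        for _ in range(10):
            W_rand = [
                np.linalg.qr(rng.standard_normal((6, 6)))[0] for _ in range(10)
            ]
            wins += J_true <= objective(W_rand, mixture_rho05.observations)
        assert wins >= 9


class TestIvaLSos:
    def test_fixed_point_on_unmixed_sources(self, mixture_rho05):
        # feeding true sources with identity init: W stays a near-identity
        # up to sign/scale, and the objective barely moves
        X = [mixture_rho05.dataset_sources(k) for k in range(10)]
        res = iva_l_sos(X, seed=0, whiten=False, init="identity", max_iter=64)
        traj = res.objective_trajectory
        assert traj[0] - traj[-1] < 0.05 * abs(traj[0])
        for Wk in res.demixing.W:
            Gabs = np.abs(Wk)
            # dominant entry per row on the diagonal
            assert np.all(Gabs.argmax(axis=1) == np.arange(6))

    def test_objective_trajectory_non_increasing(self, mixture_rho05):
        res = iva_l_sos(mixture_rho05.observations, seed=3, max_iter=256)
        diffs = np.diff(res.objective_trajectory)
        assert np.all(diffs <= 1e-6)

    def test_sources_have_unit_variance_and_consistent_reshaping(
        self, mixture_rho05
    ):
        res = iva_l_sos(mixture_rho05.observations, seed=3, max_iter=256)
        for scv in res.sources:
            np.testing.assert_allclose(scv.var(axis=1), 1.0, atol=1e-8)
        # row r of S[k] equals row k of SCV r
        S0 = res.demixing.W[0] @ mixture_rho05.observations[0]
        for r in range(6):
            np.testing.assert_allclose(S0[r], res.sources[r][0], atol=1e-8)

    def test_two_dataset_correlation_recovery(self):
        # K=2, R=2: planted rho=0.8 within each SCV is recovered in the
        # estimated SCV correlations
        specs = [
            BlockSpec(K=2, blocks=((1, 2),), rho=0.8, noise_sd=0.02)
            for _ in range(2)
        ]
        sources = [
            sample_laplacian_scv(build_scv_covariance(s, i), 5000, seed=i)
            for i, s in enumerate(specs)
        ]
        sources = [S - S.mean(axis=1, keepdims=True) for S in sources]
        mx = mix(sources, seed=5)
        res = iva_l_sos(mx.observations, seed=1)
        rs = [abs(np.corrcoef(scv[0], scv[1])[0, 1]) for scv in res.sources]
        for r in sorted(rs, reverse=True):
            assert r == pytest.approx(0.8, abs=0.1)

    def test_planted_recovery_identity_mixing(self, design_rho05):
        mx = simulate(design_rho05, seed=7, mixing=[np.eye(6)] * 10)
        res = iva_l_sos(mx.observations, seed=2)
        assert joint_isi(res.demixing, mx.mixing) < 0.05

    def test_rank_deficient_input_instructs_pca(self, rng):
        X = [rng.standard_normal((3, 100)) for _ in range(2)]
        for x in X:
            x[2] = x[0] + x[1]
        with pytest.raises(ValueError, match="PCA"):
            iva_l_sos(X, seed=0)


class TestEnsemble:
    def test_single_run_trivial(self, mixture_rho05):
        ens = run_ensemble(mixture_rho05.observations, n_runs=1, seed=0,
                           max_iter=128)
        assert ens.selected == 0
        assert ens.pairwise_distance.shape == (1, 1)
        assert ens.pairwise_distance[0, 0] == 0.0

    def test_permuted_sign_flipped_duplicate_run_has_zero_distance(
        self, mixture_rho05
    ):
        from scvrelate.iva import _scv_match_distance

        res = iva_l_sos(mixture_rho05.observations, seed=5, max_iter=128)
        import copy

        dup = copy.deepcopy(res)
        perm = [3, 1, 5, 0, 2, 4]
        dup.sources = [res.sources[r] * (-1) ** r for r in perm]
        assert _scv_match_distance(res, dup) == pytest.approx(0.0, abs=1e-9)

    def test_selection_is_at_least_median_quality(self, design_rho05):
        mx = simulate(design_rho05, seed=21)
        ens = run_ensemble(mx.observations, n_runs=5, seed=21)
        isis = [joint_isi(r.demixing, mx.mixing) for r in ens.runs]
        assert joint_isi(ens.best.demixing, mx.mixing) <= np.median(isis) + 1e-12
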