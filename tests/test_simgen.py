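"""Generator tests: planted block covariances, Laplacian sampling, mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scvrelate import (
    BlockSpec,
    ScvDesign,
    build_scv_covariance,
    mix,
    reference_design,
    sample_laplacian_scv,
    simulate,
)


def eig_gt1(C):
    return int(np.sum(np.linalg.eigvalsh(C) > 1.0))


class TestBlockCovariance:
    def test_equicorrelation_single_block(self):
        # one all-dataset block: eigenvalues are 1+(K-1)rho and K-1 copies of 1-rho
        spec = BlockSpec(K=10, blocks=(tuple(range(1, 11)),), rho=0.2)
        C = build_scv_covariance(spec, 0)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C[~np.eye(10, dtype=bool)], 0.2)
        lam = np.sort(np.linalg.eigvalsh(C))
        assert lam[-1] == pytest.approx(1 + 9 * 0.2)
        assert eig_gt1(C) == 1

    def test_three_blocks_three_large_eigenvalues(self):
        spec = BlockSpec(
            K=10, blocks=((1, 2, 3, 4), (5, 6, 7), (8, 9, 10)), rho=0.2
        )
        assert eig_gt1(build_scv_covariance(spec, 0)) == 3

    def test_noise_preserves_count_with_high_probability(self):
        # Monte-Carlo oracle: the N(0, 0.05^2) perturbation rarely moves an
        # eigenvalue across 1 for well-separated blocks
        spec = BlockSpec(
            K=10, blocks=((1, 2, 3, 4), (5, 6, 7), (8, 9, 10)), rho=0.2,
            noise_sd=0.05,
        )
        hits = sum(
            eig_gt1(build_scv_covariance(spec, seed)) == 3 for seed in range(1000)
        )
        assert hits >= 990

    def test_off_block_entries_are_exactly_zero(self):
        spec = BlockSpec(K=6, blocks=((1, 2), (4, 5)), rho=0.4, noise_sd=0.05)
        C = build_scv_covariance(spec, 3)
        # dataset 3 and 6 are uncorrelated; rows are zero off-diagonal
        for i in (2, 5):
            off = np.delete(C[i], i)
            assert np.all(off == 0.0)
        assert np.allclose(C, C.T)

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.sampled_from([0.1, 0.3, 0.5, 0.7, 0.9]),
        st.lists(st.integers(min_value=2, max_value=4), min_size=1, max_size=3),
    )
    @settings(max_examples=60, deadline=None)
    def test_noiseless_count_equals_block_count(self, seed, rho, sizes):
        # spec invariant: a noiseless matrix with d blocks has exactly d
        # eigenvalues > 1, for any block sizes that fit
        K = sum(sizes) + 2
        blocks, start = [], 1
        for sz in sizes:
            blocks.append(tuple(range(start, start + sz)))
            start += sz
        spec = BlockSpec(K=K, blocks=tuple(blocks), rho=rho)
        assert eig_gt1(build_scv_covariance(spec, seed)) == len(sizes)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(K=5, blocks=((1,),), rho=0.5),            # singleton block
            dict(K=5, blocks=((1, 2), (2, 3)), rho=0.5),   # overlap
            dict(K=5, blocks=((1, 6),), rho=0.5),          # out of range
            dict(K=5, blocks=((1, 2),), rho=1.5),          # rho out of (0,1)
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            BlockSpec(**bad)


class TestReferenceDesign:
    def test_printed_constraints(self):
        des = reference_design(0.2)
        assert des.R == 6 and des.K == 10 and des.V == 1000
        assert des.true_d == (1, 2, 2, 2, 3, 4)
        assert des.true_labels == (1, 1, 1, 1, 2, 2, 2, 3, 3, 3)
        assert all(s.noise_sd == pytest.approx(0.05) for s in des.specs)
        # uncorrelated component counts per SCV
        assert [len(s.uncorrelated) for s in des.specs] == [0, 0, 1, 4, 0, 0]

    def test_json_roundtrip(self):
        des = reference_design(0.35, V=640, seed=9)
        back = ScvDesign.from_json(des.to_json())
        assert back == des


class TestLaplacianSampler:
    def test_identity_covariance_consistency(self):
        S = sample_laplacian_scv(np.eye(3), 100_000, seed=0)
        C = S @ S.T / S.shape[1]
        assert np.abs(C - np.eye(3)).max() < 0.02

    def test_planted_correlation_recovered(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.8
        S = sample_laplacian_scv(C, 100_000, seed=1)
        r = np.corrcoef(S[0], S[1])[0, 1]
        assert r == pytest.approx(0.8, abs=0.02)

    def test_marginals_are_heavy_tailed(self):
        # multivariate-Laplace marginal excess kurtosis is 3
        C = build_scv_covariance(
            BlockSpec(K=5, blocks=((1, 2, 3),), rho=0.5), 0
        )
        S = sample_laplacian_scv(C, 10_000, seed=2)
        m2 = (S**2).mean(axis=1)
        m4 = (S**4).mean(axis=1)
        excess = m4 / m2**2 - 3.0
        assert np.median(excess) > 1.0

    def test_sample_covariance_converges_with_V(self):
        C = build_scv_covariance(
            BlockSpec(K=4, blocks=((1, 2), (3, 4)), rho=0.6), 0
        )
        errs = []
        for V in (2_000, 32_000):
            S = sample_laplacian_scv(C, V, seed=3)
            errs.append(np.abs(S @ S.T / V - C).max())
        assert errs[1] < errs[0]

    def test_rejects_non_pd(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            sample_laplacian_scv(bad, 100, seed=0)


class TestMixing:
    def test_exact_reconstruction_and_shapes(self, mixture_rho05):
        mx = mixture_rho05
        assert len(mx.observations) == 10
        for k, Xk in enumerate(mx.observations):
            assert Xk.shape == (6, 1000)
            np.testing.assert_array_equal(
                Xk, mx.mixing[k] @ mx.dataset_sources(k)
            )

    def test_source_rows_standardised(self, mixture_rho05):
        for S in mixture_rho05.sources:
            assert np.abs(S.mean(axis=1)).max() < 1e-12
            assert np.allclose(S.var(axis=1), 1.0, atol=0.5)

    def test_identity_mixing_hook(self, design_rho05):
        eye = [np.eye(6)] * 10
        mx = simulate(design_rho05, seed=7, mixing=eye)
        for k, Xk in enumerate(mx.observations):
            np.testing.assert_array_equal(Xk, mx.dataset_sources(k))

    def test_pseudo_inverse_demixing_gives_zero_isi(self, mixture_rho05):
        from scvrelate import joint_isi

        W = [np.linalg.inv(A) for A in mixture_rho05.mixing]
        assert joint_isi(W, mixture_rho05.mixing) == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        s1 = rng.standard_normal((3, 50))
        s2 = rng.standard_normal((4, 50))
        with pytest.raises(ValueError):
            mix([s1, s2], seed=0)


def test_simulation_is_bit_reproducible(design_rho05):
    a = simulate(design_rho05, seed=42)
    b = simulate(design_rho05, seed=42)
    for Xa, Xb in zip(a.observations, b.observations):
        np.testing.assert_array_equal(Xa, Xb)
    c = simulate(design_rho05, seed=43)
    assert not np.array_equal(a.observations[0], c.observations[0])
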