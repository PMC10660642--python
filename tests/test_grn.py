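"""Message-passing network inference against an independently written
direct-iteration reference, plus the similarity/normalization primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grnrewire.grn import (
    Grn,
    PandaConfig,
    coexpression_network,
    continuous_tanimoto,
    normalize_prior,
    panda_infer,
)


# ---------------------------------------------------------------- primitives
class TestCoexpression:
    def test_diagonal_and_perfect_correlation(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        C = coexpression_network(X, ["a", "b"])
        assert C.loc["a", "a"] == 1.0
        assert C.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 5))
        genes = list("abcde")
        C = coexpression_network(X, genes)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / len(X)
        sd = X.std(axis=0)
        expected = cov / np.outer(sd, sd)
        np.testing.assert_allclose(C.values, expected, atol=1e-12)

    def test_zero_variance_gene_zeroed(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        C = coexpression_network(X, ["a", "b"])
        assert C.loc["a", "b"] == 0.0 and C.loc["b", "b"] == 1.0
        assert np.all(np.isfinite(C.values))

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            coexpression_network(np.ones((2, 3)), ["a", "b", "c"])


class TestTanimoto:
    def test_unit_self_similarity(self):
        x = np.array([[1.0, 0.0]])
        assert continuous_tanimoto(x, x)[0, 0] == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        x = np.array([[1.0, 0.0]])
        y = np.array([[0.0, 1.0]])
        assert continuous_tanimoto(x, y)[0, 0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        x = np.array([[1.0, 2.0]])
        y = np.array([[2.0, 1.0]])
        assert continuous_tanimoto(x, y)[0, 0] == pytest.approx(4 / np.sqrt(6))

    def test_both_zero_maps_to_zero(self):
        z = np.zeros((1, 3))
        assert continuous_tanimoto(z, z)[0, 0] == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            continuous_tanimoto(np.ones((2, 3)), np.ones((2, 4)))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(2, 6), st.integers(0, 10**6))
    def test_finite_and_bounded_by_selfnorm(self, n, m, k, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, k))
        Y = rng.normal(size=(m, k))
        T = continuous_tanimoto(X, Y)
        assert np.all(np.isfinite(T))


class TestNormalizePrior:
    def test_constant_matrix_all_zeros(self):
        np.testing.assert_array_equal(normalize_prior(np.full((3, 4), 2.0)), 0.0)

    def test_antisymmetric_2x2(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = normalize_prior(W)
        # independent recomputation: row z and column z are both [[-1,1],[1,-1]]
        np.testing.assert_allclose(out, np.array([[-1.0, 1.0], [1.0, -1.0]]))

    def test_mean_near_zero_random(self):
        rng = np.random.default_rng(1)
        out = normalize_prior(rng.normal(size=(10, 10)))
        assert abs(out.mean()) < 1e-10

    def test_degenerate_row_uses_overall(self):
        W = np.array([[5.0, 5.0], [1.0, 3.0]])
        out = normalize_prior(W)
        assert np.all(np.isfinite(out))


# ----------------------------------------------------- reference implementation
def naive_panda(motif, ppi, coexpr, alpha, iters):
    """Straight-line per-element loop implementing the same update equations,
    written independently of the vectorized path."""

    def nz(W):
        W = np.array(W, float)
        mu, sd = W.mean(), W.std()
        ov = (W - mu) / sd if sd > 0 else np.zeros_like(W)
        out = np.zeros_like(W)
        nr, nc = W.shape
        for i in range(nr):
            for j in range(nc):
                rsd, csd = W[i].std(), W[:, j].std()
                rz = (W[i, j] - W[i].mean()) / rsd if rsd > 0 else ov[i, j]
                cz = (W[i, j] - W[:, j].mean()) / csd if csd > 0 else ov[i, j]
                out[i, j] = 0.5 * (rz + cz)
        return out

    def tan(X, Y):
        out = np.zeros((X.shape[0], Y.shape[0]))
        for i in range(X.shape[0]):
            for j in range(Y.shape[0]):
                ip = float(np.dot(X[i], Y[j]))
                d2 = float(np.dot(X[i], X[i]) + np.dot(Y[j], Y[j]) - abs(ip))
                out[i, j] = ip / np.sqrt(d2) if d2 > 0 else 0.0
        return out

    def stab(S, inner, step):
        n = S.shape[0]
        if n < 2:
            return S
        off = np.array([[S[i, k] for k in range(n) if k != i] for i in range(n)])
        mu, sd = off.mean(), off.std()
        if sd > 0:
            diag = np.diag(S).copy()
            S = (S - mu) / sd
            for i in range(n):
                S[i, i] = diag[i]
        off = np.array([[S[i, k] for k in range(n) if k != i] for i in range(n)])
        for i in range(n):
            S[i, i] = off[i].std() * inner * np.exp(2 * alpha * step)
        return S

    W, P, C = nz(motif), nz(ppi), nz(coexpr)
    for it in range(1, iters + 1):
        R = tan(P, W.T)
        A = tan(W, C)
        Wn = (1 - alpha) * W + alpha * 0.5 * (R + A)
        P = (1 - alpha) * P + alpha * stab(tan(Wn, Wn), C.shape[0], it)
        C = (1 - alpha) * C + alpha * stab(tan(Wn.T, Wn.T), W.shape[0], it)
        W = Wn
    return W


@pytest.fixture()
def small_instance():
    rng = np.random.default_rng(42)
    motif = (rng.random((3, 4)) < 0.5).astype(float)
    motif[motif.sum(axis=1) == 0, 0] = 1.0
    ppi = np.eye(3)
    ppi[0, 1] = ppi[1, 0] = 1.0
    coexpr = np.corrcoef(rng.normal(size=(10, 4)), rowvar=False)
    tfs = [f"T{i}" for i in range(3)]
    genes = [f"G{j}" for j in range(4)]
    return (
        pd.DataFrame(motif, index=tfs, columns=genes),
        pd.DataFrame(ppi, index=tfs, columns=tfs),
        pd.DataFrame(coexpr, index=genes, columns=genes),
        motif,
        ppi,
        coexpr,
    )


class TestPandaInfer:
    @pytest.mark.parametrize("iters", [5, 50])
    def test_matches_direct_iteration_oracle(self, small_instance, iters):
        mdf, pdf, cdf, motif, ppi, coexpr = small_instance
        net = panda_infer(mdf, pdf, cdf, PandaConfig(alpha=0.1, tol=1e-30, max_iter=iters))
        ref = naive_panda(motif, ppi, coexpr, 0.1, iters)
        np.testing.assert_allclose(net.weights, ref, atol=1e-10)

    def test_alpha_zero_fixed_point(self, small_instance):
        mdf, pdf, cdf, motif, _, _ = small_instance
        net = panda_infer(mdf, pdf, cdf, PandaConfig(alpha=0.0, max_iter=10))
        np.testing.assert_array_equal(net.weights, normalize_prior(motif))

    def test_deterministic(self, small_instance):
        mdf, pdf, cdf, *_ = small_instance
        n1 = panda_infer(mdf, pdf, cdf, PandaConfig())
        n2 = panda_infer(mdf, pdf, cdf, PandaConfig())
        np.testing.assert_array_equal(n1.weights, n2.weights)
        assert n1.converged and n1.iterations_run == n2.iterations_run

    def test_change_statistic_shrinks_after_burn_in(self, small_instance):
        mdf, pdf, cdf, motif, ppi, coexpr = small_instance
        # track |W_t - W_{t-1}| via successive truncated runs of the oracle
        deltas = []
        prev = None
        for iters in range(1, 31):
            W = naive_panda(motif, ppi, coexpr, 0.1, iters)
            if prev is not None:
                deltas.append(np.abs(W - prev).mean())
            prev = W
        assert deltas[-1] < deltas[4]

    def test_permutation_equivariance(self, small_instance):
        mdf, pdf, cdf, *_ = small_instance
        net = panda_infer(mdf, pdf, cdf, PandaConfig(max_iter=20, tol=1e-30))
        perm = [2, 0, 1]
        mdf_p = mdf.iloc[perm]
        pdf_p = pdf.iloc[perm, perm]
        net_p = panda_infer(mdf_p, pdf_p, cdf, PandaConfig(max_iter=20, tol=1e-30))
        np.testing.assert_allclose(net_p.weights, net.weights[perm], atol=1e-12)

    def test_misaligned_inputs_rejected(self, small_instance):
        mdf, pdf, cdf, *_ = small_instance
        with pytest.raises(ValueError):
            panda_infer(mdf, pdf.iloc[::-1], cdf)
        bad_coexpr = cdf.iloc[:3, :3]
        with pytest.raises(ValueError):
            panda_infer(mdf, pdf, bad_coexpr)

    def test_module_boost_raises_block_weights(self):
        # coexpression support for a motif-linked TF block raises its edges
        # relative to a matched block differing only in coexpression
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n_tfs, n_genes = 6, 30
            motif = (rng.random((n_tfs, n_genes)) < 0.25).astype(float)
            block = list(range(6))
            other = list(range(6, 12))
            motif[0, block] = 1.0
            motif[0, other] = 1.0
            motif[1:, block] = 0.0
            motif[1:, other] = 0.0
            motif[motif.sum(axis=1) == 0, -1] = 1.0
            ppi = np.eye(n_tfs)
            lat = rng.normal(size=(200, 1))
            X = rng.normal(size=(200, n_genes))
            X[:, block] += 3.0 * lat  # boosted coexpressed block
            coexpr = np.corrcoef(X, rowvar=False)
            tfs = [f"T{i}" for i in range(n_tfs)]
            genes = [f"G{j}" for j in range(n_genes)]
            net = panda_infer(
                pd.DataFrame(motif, index=tfs, columns=genes),
                pd.DataFrame(ppi, index=tfs, columns=tfs),
                pd.DataFrame(coexpr, index=genes, columns=genes),
                PandaConfig(),
            )
            hits += net.weights[0, block].mean() > net.weights[0, other].mean()
        assert hits == 20

    def test_grn_validation(self):
        with pytest.raises(ValueError):
            Grn(tfs=["a"], genes=["x", "y"], weights=np.ones((2, 2)))
        with pytest.raises(ValueError):
            Grn(tfs=["a"], genes=["x"], weights=np.array([[np.inf]]))
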