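import numpy as np
import pytest

from fikat import assoc, kernels
from fikat.kernels import (
    DEFAULT_GAMMA,
    EmptyGeneError,
    collapse_max,
    concat_plof,
    phi_linear,
    phi_local_collapse,
    phi_rbp,
    position_similarity,
    rbp_similarity,
)


class TestCollapseMax:
    def test_max_weight_of_carried_variants(self):
        G = np.array([[1.0, 2.0], [0.0, 1.0], [0.0, 0.0]])
        w = np.array([0.8, 1.0])
        burden = collapse_max(G, w)
        assert burden.tolist() == [1.0, 1.0, 0.0]

    def test_unit_weights_give_carrier_indicator(self, rng):
        G = rng.binomial(2, 0.2, size=(50, 4)).astype(float)
        burden = collapse_max(G, np.ones(4))
        assert np.array_equal(burden, (G >= 1).any(axis=1).astype(float))

    def test_empty_gene_errors(self):
        with pytest.raises(EmptyGeneError):
            collapse_max(np.empty((5, 0)), np.empty(0))


class TestLinearFactor:
    def test_unit_weights_reproduce_centered_dosages(self, rng):
        G = rng.binomial(2, 0.2, size=(40, 3)).astype(float)
        phi = phi_linear(G, np.ones(3))
        assert np.allclose(phi.matrix, G - G.mean(axis=0))

    def test_weight_rescaling_leaves_p_invariant(self, small_design):
        y, X, G, w = small_design
        null = assoc.fit_null_ols(y, X)
        p1 = assoc.score_test(null, phi_linear(G, w))[1]
        p2 = assoc.score_test(null, phi_linear(G, 0.5 * w))[1]
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_weight_variants_dropped(self, rng):
        G = rng.binomial(2, 0.2, size=(40, 3)).astype(float)
        phi = phi_linear(G, np.array([1.0, 0.0, 0.5]), ["a", "b", "c"])
        assert phi.column_labels == ["a", "c"]

    def test_kernel_psd_on_random_instances(self, rng):
        for _ in range(10):
            G = rng.binomial(2, 0.2, size=(30, 5)).astype(float)
            w = rng.uniform(0.1, 1.0, 5)
            K = phi_linear(G, w).kernel()
            eig = np.linalg.eigvalsh(K)
            assert eig.min() >= -1e-8 * max(eig.max(), 1.0)


class TestLocalCollapse:
    def test_singleton_groups_reproduce_linear(self, rng):
        G = rng.binomial(2, 0.2, size=(40, 5)).astype(float)
        w = rng.uniform(0.1, 1.0, 5)
        lin = phi_linear(G, w)
        loc = phi_local_collapse(G, w, np.arange(5))
        assert np.allclose(lin.matrix, loc.matrix)

    def test_shared_position_sums_weighted_columns(self, rng):
        G = rng.binomial(2, 0.2, size=(40, 2)).astype(float)
        phi = phi_local_collapse(G, np.ones(2), np.array([7, 7]))
        G_c = G - G.mean(axis=0)
        assert phi.g == 1
        assert np.allclose(phi.matrix[:, 0], G_c.sum(axis=1))
        assert phi.column_labels == ["7"]

    def test_singleton_position_matches_single_variant_p(self, small_design):
        """A position with exactly one variant yields the same p as the
        single-variant score test on that variant."""
        y, X, G, _ = small_design
        null = assoc.fit_null_ols(y, X)
        g = G[:, [0]]
        phi = phi_local_collapse(g, np.array([1.0]), np.array([42]))
        p_pos = assoc.score_test(null, phi)[1]
        p_var = assoc.single_variant_test(null, g[:, 0])[2]
        assert p_pos == pytest.approx(p_var, rel=1e-9)

    def test_missing_position_errors(self, rng):
        G = rng.binomial(2, 0.2, size=(20, 2)).astype(float)
        with pytest.raises(ValueError):
            phi_local_collapse(G, np.ones(2), np.array([1.0, np.nan]))


class TestRbpKernel:
    def test_position_similarity_calibration(self):
        x = np.array([0.0, 50.0, 100.0])
        R = position_similarity(x, DEFAULT_GAMMA)
        assert R[0, 0] == 1.0
        assert R[0, 1] == pytest.approx(0.5)
        assert R[0, 2] == pytest.approx(0.5 ** (100**2 / 50**2)) == pytest.approx(0.0625)

    def test_similarity_signs(self):
        v = np.array([[0.5, 0.2], [0.5, 0.2], [-0.5, -0.2]])
        S = rbp_similarity(v, np.zeros(3))
        assert S[0, 1] == pytest.approx(1.0)
        assert S[0, 2] == pytest.approx(-1.0)

    def test_s_equals_elementwise_product_bruteforce(self, rng):
        m = 12
        V = rng.uniform(-1, 1, size=(m, 8))
        x = rng.uniform(0, 500, m)
        S = rbp_similarity(V, x)
        Q = np.empty((m, m))
        R = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                Q[i, j] = V[i] @ V[j] / (np.linalg.norm(V[i]) * np.linalg.norm(V[j]))
                R[i, j] = np.exp(-DEFAULT_GAMMA * (x[i] - x[j]) ** 2)
        assert np.allclose(S, Q * R, atol=1e-12)

    def test_zero_effect_vector_rejected(self):
        with pytest.raises(ValueError):
            rbp_similarity(np.zeros((2, 8)), np.zeros(2))

    def test_factor_reproduces_kernel(self, rng):
        G = rng.binomial(2, 0.2, size=(50, 6)).astype(float)
        w = rng.uniform(0.3, 1.0, 6)
        V = rng.uniform(-1, 1, size=(6, 8))
        x = np.sort(rng.uniform(0, 300, 6))
        phi = phi_rbp(G, w, V, x)
        G_c = G - G.mean(axis=0)
        S = rbp_similarity(V, x)
        K_expected = (G_c * np.sqrt(w)) @ S @ (G_c * np.sqrt(w)).T
        assert np.allclose(phi.kernel(), K_expected, atol=1e-8)

    def test_ridge_handles_duplicated_variants(self, rng):
        """Variants sharing position and effect vector make S singular;
        the escalating ridge still yields a usable factor."""
        G = rng.binomial(2, 0.2, size=(50, 2)).astype(float)
        V = np.tile(rng.uniform(-1, 1, 8), (2, 1))
        phi = phi_rbp(G, np.ones(2), V, np.array([10.0, 10.0]))
        assert np.all(np.isfinite(phi.matrix))


class TestConcatPlof:
    def test_appends_centered_burden(self, linear_factor, rng):
        burden = rng.binomial(1, 0.3, size=linear_factor.n).astype(float)
        out = concat_plof(linear_factor, burden)
        assert out.g == linear_factor.g + 1
        assert out.column_labels[-1] == "pLOF"
        assert out.matrix[:, -1] == pytest.approx(burden - burden.mean())
        assert out.has_plof_column

    def test_zero_burden_dropped(self, linear_factor):
        out = concat_plof(linear_factor, np.zeros(linear_factor.n))
        assert out.g == linear_factor.g and not out.has_plof_column

    def test_empty_factor_plus_burden(self, rng):
        empty = kernels.KernelFactor(np.empty((30, 0)), [], "linear")
        burden = rng.binomial(1, 0.4, 30).astype(float)
        out = concat_plof(empty, burden)
        assert out.g == 1 and out.column_labels == ["pLOF"]


def test_center_and_impute_fills_column_means(rng):
    G = rng.binomial(2, 0.3, size=(20, 2)).astype(float)
    G[3, 0] = np.nan
    out = kernels.center_and_impute(G)
    assert np.all(np.isfinite(out))
    assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
    assert out[3, 0] == pytest.approx(0.0, abs=1e-12)  # imputed to the mean
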