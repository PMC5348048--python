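"""Slope and interaction field estimation against analytic oracles."""

import numpy as np
import pytest

import microbeta as mb
from microbeta.fields import EstimationError


def _tables(A, T):
    n, d = A.shape
    m = T.shape[1]
    samples = tuple(f"s{k}" for k in range(n))
    return (mb.AbundanceTable(samples, tuple(f"t{j}" for j in range(d)),
                              A, mode="absolute"),
            mb.EnvironmentTable(samples, tuple(f"e{a}" for a in range(m)), T))


class TestEstimateP:
    def test_exact_linear_relation_forces_the_slope(self):
        T = np.arange(1.0, 7.0)[:, None]
        a, e = _tables(2.0 * T, T)
        field = mb.estimate_p(a, e)
        np.testing.assert_allclose(field.p[0, 0, :], 2.0, atol=1e-12)

    def test_constant_abundance_gives_zero_slopes(self):
        T = np.arange(1.0, 8.0)[:, None]
        a, e = _tables(np.full((7, 1), 3.0), T)
        field = mb.estimate_p(a, e)
        np.testing.assert_allclose(field.p, 0.0, atol=1e-12)

    def test_multilinear_gradients_recovered_exactly(self):
        # reduced variant: with every taxon an exact multilinear function of
        # the gradients, the full variant's design would be exactly singular
        # (abundance differences live in the span of gradient differences)
        rng = np.random.default_rng(0)
        T = rng.uniform(0.5, 2.0, size=(12, 2))
        A = np.column_stack([1.0 * T[:, 0] + 3.0 * T[:, 1] + 5.0,
                             2.0 * T[:, 0] - 0.5 * T[:, 1] + 6.0])
        a, e = _tables(A, T)
        field = mb.estimate_p(a, e, "reduced")
        # independent least-squares oracle, one reference sample
        k = 4
        dT = np.delete(T - T[k], k, axis=0)
        dA = np.delete(A[:, 0] - A[k, 0], k)
        oracle = np.linalg.lstsq(dT, dA, rcond=None)[0]
        np.testing.assert_allclose(field.p[0, :, k], oracle, atol=1e-8)
        np.testing.assert_allclose(field.p[0, 0, :], 1.0, atol=1e-8)
        np.testing.assert_allclose(field.p[0, 1, :], 3.0, atol=1e-8)
        np.testing.assert_allclose(field.p[1, 0, :], 2.0, atol=1e-8)
        np.testing.assert_allclose(field.p[1, 1, :], -0.5, atol=1e-8)

    def test_full_variant_reports_cross_slopes(self):
        rng = np.random.default_rng(1)
        T = rng.uniform(0.5, 2.0, size=(15, 1))
        # taxon 0 depends on taxon 1's abundance as well as the gradient
        A1 = 2.0 + 1.5 * T[:, 0] + rng.uniform(0, 0.01, 15)
        A0 = 1.0 + 0.5 * T[:, 0] + 2.0 * A1
        a, e = _tables(np.column_stack([A0, A1]), T)
        field = mb.estimate_p(a, e, "full")
        assert field.cross_slopes.shape == (2, 2, 15)
        np.testing.assert_allclose(field.cross_slopes[0, 1, :], 2.0, atol=1e-6)

    def test_too_few_samples_rejected(self):
        T = np.arange(1.0, 3.0)[:, None]
        a, e = _tables(2 * T, T)
        with pytest.raises(Exception, match="support"):
            mb.estimate_p(a, e)


class TestEstimateBeta:
    def test_constant_slope_field_gives_zero_interactions(self):
        rng = np.random.default_rng(2)
        T = rng.uniform(0.5, 2.0, size=(10, 1))
        A = np.column_stack([1 + T[:, 0], 2 + 0.5 * T[:, 0] ** 2])
        a, e = _tables(A, T)
        p = mb.LocalSlopeField(np.full((2, 1, 10), 1.7), a.taxon_ids,
                               e.param_ids, a.sample_ids)
        field = mb.estimate_beta(p, a, e)
        np.testing.assert_allclose(field.beta, 0.0, atol=1e-12)

    def test_quadratic_construction_recovers_cross_derivative(self):
        """A_1 = Theta^2, A_2 = Theta, so p_1 = 2 A_2 and dp_1/dA_2 = 2."""
        truth = mb.make_analytic_dataset(quadratic_pair=True, n_samples=41)
        a, e = truth.abundance, truth.environment
        p = mb.LocalSlopeField(truth.true_p, a.taxon_ids, e.param_ids,
                               a.sample_ids)
        field = mb.estimate_beta(p, a, e)
        # brute-force finite-difference oracle for dp_1/dA_2 on the curve
        theta = e.values[:, 0]
        fd = np.gradient(2 * theta, theta)  # = 2 everywhere
        coef = field.beta[0, 1, 0, :] * a.values[:, 0]  # undo 1/A_1k
        np.testing.assert_allclose(coef, fd, atol=1e-8)
        np.testing.assert_allclose(field.beta[0, 1, 0, :],
                                   2.0 / a.values[:, 0], atol=1e-8)

    def test_predator_prey_signs_dominate(self, predator_prey_truth):
        t = predator_prey_truth
        a, e = mb.align_tables(t.abundance, t.environment)
        a2, e2, _ = mb.preprocess(a, e)
        p = mb.estimate_p(a2, e2)
        field = mb.estimate_beta(p, a2, e2)
        frac_pos_12 = (field.beta[0, 1, 0, :] > 0).mean()
        frac_neg_21 = (field.beta[1, 0, 0, :] < 0).mean()
        assert frac_pos_12 > 0.8
        assert frac_neg_21 > 0.8

    def test_mismatched_field_rejected(self):
        rng = np.random.default_rng(3)
        T = rng.uniform(0.5, 2.0, size=(8, 1))
        A = np.column_stack([1 + T[:, 0], 2 + T[:, 0] ** 2])
        a, e = _tables(A, T)
        p = mb.LocalSlopeField(np.zeros((2, 1, 8)), ("x", "y"), e.param_ids,
                               a.sample_ids)
        with pytest.raises(EstimationError, match="identifiers"):
            mb.estimate_beta(p, a, e)

    def test_nonpositive_abundance_rejected(self):
        T = np.arange(1.0, 9.0)[:, None]
        A = np.column_stack([T[:, 0], T[:, 0] ** 2])
        A[3, 0] = 0.0
        a, e = _tables(A, T)
        p = mb.LocalSlopeField(np.zeros((2, 1, 8)), a.taxon_ids, e.param_ids,
                               a.sample_ids)
        with pytest.raises(EstimationError, match="strictly positive"):
            mb.estimate_beta(p, a, e)


class TestFieldContracts:
    def test_determinism_bit_identical(self, predator_prey_truth):
        t = predator_prey_truth
        a, e = mb.align_tables(t.abundance, t.environment)
        a2, e2, _ = mb.preprocess(a, e)
        f1 = mb.estimate_beta(mb.estimate_p(a2, e2), a2, e2)
        f2 = mb.estimate_beta(mb.estimate_p(a2, e2), a2, e2)
        np.testing.assert_array_equal(f1.beta, f2.beta)

    def test_long_format_serialization(self, tmp_path):
        rng = np.random.default_rng(4)
        beta = rng.normal(size=(2, 2, 1, 3))
        field = mb.LocalInteractionField(beta, ("a", "b"), ("pH",),
                                         ("s1", "s2", "s3"))
        path = tmp_path / "beta.tsv"
        field.write_tsv(path)
        import pandas as pd
        back = pd.read_csv(path, sep="\t", float_precision="round_trip")
        assert list(back.columns) == ["taxon_i", "taxon_j", "parameter",
                                      "sample", "value"]
        assert len(back) == beta.size
        row = back[(back.taxon_i == "a") & (back.taxon_j == "b")
                   & (back["sample"] == "s2")]
        assert row["value"].iloc[0] == beta[0, 1, 0, 1]
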