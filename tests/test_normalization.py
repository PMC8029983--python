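import numpy as np
import pandas as pd
import pytest

from panomix import AnalysisError, batch_adjust, log_cpm, tmm_factors
from conftest import make_matrix


def brute_force_tmm(obs, ref):
    """Independent trimmed-mean computation on M/A values (sorting based)."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    n_o, n_r = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    po, pr = obs[keep] / n_o, ref[keep] / n_r
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (n_o - obs[keep]) / (n_o * obs[keep]) + (n_r - ref[keep]) / (n_r * ref[keep])
    n = len(m)
    order_m = np.argsort(m, kind="stable")
    order_a = np.argsort(a, kind="stable")
    rank_m = np.empty(n, int)
    rank_m[order_m] = np.arange(1, n + 1)
    rank_a = np.empty(n, int)
    rank_a[order_a] = np.arange(1, n + 1)
    sel = (
        (rank_m > np.floor(n * 0.3))
        & (rank_m <= np.ceil(n * 0.7))
        & (rank_a > np.floor(n * 0.05))
        & (rank_a <= np.ceil(n * 0.95))
    )
    return 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))


class TestTmm:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 500, size=200)
        em = make_matrix(np.column_stack([col] * 4), kind="counts")
        f = tmm_factors(em)
        assert np.allclose(f.factors, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        col = rng.integers(1, 500, size=200)
        em = make_matrix(np.column_stack([col, 2 * col]), kind="counts")
        f = tmm_factors(em)
        assert np.allclose(f.factors, 1.0)

    def test_matches_brute_force_oracle(self, rng):
        # one sample with 5% very-high genes: its factor shrinks below 1
        base = rng.integers(20, 200, size=400)
        s2 = base.copy()
        hot = rng.choice(400, size=20, replace=False)
        s2[hot] *= 40
        em = make_matrix(np.column_stack([base, s2]), kind="counts")
        f = tmm_factors(em, ref="s0")
        assert f.factors["s1"] < f.factors["s0"]
        raw = brute_force_tmm(s2, base)
        expect = np.array([1.0, raw])
        expect /= np.exp(np.mean(np.log(expect)))
        assert np.allclose(f.factors.to_numpy(), expect, rtol=1e-10)
        assert f.factors["s1"] / f.factors["s0"] == pytest.approx(raw)

    def test_scale_invariance_of_a_sample(self, rng):
        # M values are exactly depth-invariant; the precision weights keep a
        # mild depth dependence, so factors agree to ~1%, not bit-exactly
        mat = rng.integers(1, 300, size=(300, 3))
        em1 = make_matrix(mat, kind="counts")
        mat2 = mat.copy()
        mat2[:, 1] *= 7
        em2 = make_matrix(mat2, kind="counts")
        f1 = tmm_factors(em1, ref="s0")
        f2 = tmm_factors(em2, ref="s0")
        assert np.allclose(f1.factors, f2.factors, atol=0.03)

    def test_geometric_mean_is_one(self, rng):
        em = make_matrix(rng.integers(0, 400, size=(300, 5)), kind="counts")
        f = tmm_factors(em)
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        em = make_matrix([[1, 0], [2, 0]], kind="counts")
        with pytest.raises(AnalysisError):
            tmm_factors(em)


class TestLogCpm:
    def _unit_factors(self, em):
        from panomix import NormFactors

        lib = em.values.sum()
        return NormFactors(
            factors=pd.Series(1.0, index=em.samples),
            lib_sizes=lib,
            ref_sample=str(em.samples[0]),
        )

    def test_arithmetic(self):
        em = make_matrix([[100.0, 100.0], [999900.0, 999900.0]], kind="counts")
        f = self._unit_factors(em)  # lib sizes 1e6
        out = log_cpm(em, f, prior=0.0)
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(100), abs=1e-9)

    def test_zero_count_finite_with_prior(self):
        em = make_matrix([[0, 5], [10, 5]], kind="counts")
        f = self._unit_factors(em)
        out = log_cpm(em, f, prior=0.5)
        assert np.isfinite(out.values.to_numpy()).all()

    def test_depth_invariance(self, rng):
        mat = rng.integers(0, 200, size=(50, 3))
        em1 = make_matrix(mat, kind="counts")
        em2 = make_matrix(mat * 2, kind="counts")
        out1 = log_cpm(em1, self._unit_factors(em1), prior=0.0)
        out2 = log_cpm(em2, self._unit_factors(em2), prior=0.0)
        ok = mat > 0
        assert np.allclose(out1.values.to_numpy()[ok], out2.values.to_numpy()[ok])

    def test_monotone_in_count(self):
        em = make_matrix([[1, 0], [5, 0], [25, 0]], kind="counts")
        out = log_cpm(em, self._unit_factors(em), prior=0.5)
        col = out.values.iloc[:, 0].to_numpy()
        assert col[0] < col[1] < col[2]


class TestBatchAdjust:
    def test_single_batch_identity(self, rng):
        em = make_matrix(rng.normal(size=(20, 6)))
        batches = pd.Series(["b1"] * 6, index=em.samples)
        out = batch_adjust(em, batches)
        pd.testing.assert_frame_equal(out.values, em.values)

    def test_offset_batches_equalized(self, rng):
        base = rng.normal(size=(20, 8))
        shifted = base.copy()
        shifted[:, 4:] += 3.0
        em = make_matrix(shifted)
        batches = pd.Series(["a"] * 4 + ["b"] * 4, index=em.samples)
        out = batch_adjust(em, batches)
        m = out.values.to_numpy()
        assert np.allclose(m[:, :4].mean(axis=1), m[:, 4:].mean(axis=1))

    def test_grand_mean_and_within_batch_variance_preserved(self, rng):
        em = make_matrix(rng.normal(size=(30, 10)))
        batches = pd.Series(["a"] * 5 + ["b"] * 5, index=em.samples)
        out = batch_adjust(em, batches)
        assert np.allclose(
            out.values.to_numpy().mean(axis=1), em.values.to_numpy().mean(axis=1)
        )
        for cols in (slice(0, 5), slice(5, 10)):
            assert np.allclose(
                out.values.to_numpy()[:, cols].var(axis=1),
                em.values.to_numpy()[:, cols].var(axis=1),
            )

    def test_singleton_batch_warns(self, rng):
        em = make_matrix(rng.normal(size=(5, 3)))
        batches = pd.Series(["a", "a", "b"], index=em.samples)
        with pytest.warns(UserWarning, match="single sample"):
            batch_adjust(em, batches)
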