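import numpy as np
import pytest
import scipy.linalg

from circust.cpca import (EigengenePair, circular_order, compute_eigengenes,
                          detect_outlier_samples, orient, project_to_circle)
from circust.fmm import fmm_fit
from circust.metrics import circular_correlation

from conftest import make_matrix

TWO_PI = 2 * np.pi


def _normalized(rows, **kw):
    return make_matrix(rows, state="normalized", **kw)


class TestComputeEigengenes:
    def test_trigonometric_rows_span_cos_sin(self):
        t = TWO_PI * np.arange(24) / 24
        rows = [np.cos(t + phi) for phi in TWO_PI * np.arange(6) / 6]
        eig = compute_eigengenes(_normalized(rows))
        assert eig.explained[0] == pytest.approx(0.5, abs=0.05)
        assert eig.explained[1] == pytest.approx(0.5, abs=0.05)
        basis = np.column_stack([np.cos(t), np.sin(t)])
        for e in (eig.e1, eig.e2):
            resid = e - basis @ np.linalg.lstsq(basis, e, rcond=None)[0]
            assert np.abs(resid).max() < 1e-10

    def test_eigengenes_orthogonal(self, rng):
        eig = compute_eigengenes(_normalized(rng.normal(size=(8, 20))))
        c1 = eig.e1 - eig.e1.mean()
        c2 = eig.e2 - eig.e2.mean()
        # right-singular vectors of the centered matrix are orthogonal
        assert abs(np.dot(eig.e1, eig.e2)) < 1e-8 * np.linalg.norm(c1) \
            * np.linalg.norm(c2) + 1e-8

    def test_rank_one_is_degenerate(self, rng):
        base = rng.normal(size=12)
        rows = np.outer(rng.uniform(1, 2, 5), base)
        with pytest.raises(ValueError, match="degenerate"):
            compute_eigengenes(_normalized(rows))

    def test_matches_independent_svd_oracle(self, rng):
        vals = rng.normal(size=(12, 30))
        eig = compute_eigengenes(_normalized(vals))
        centered = vals - vals.mean(axis=1, keepdims=True)
        _, s, vt = scipy.linalg.svd(centered, full_matrices=False)
        for got, i in ((eig.e1, 0), (eig.e2, 1)):
            want = s[i] * vt[i]
            err = min(np.abs(got - want).max(), np.abs(got + want).max())
            assert err < 1e-8


class TestProjectToCircle:
    def test_identity_on_unit_circle(self):
        t = TWO_PI * np.arange(20) / 20
        eig = EigengenePair(e1=np.cos(t), e2=np.sin(t), explained=(0.5, 0.5))
        diff = np.mod(project_to_circle(eig) - t + np.pi, TWO_PI) - np.pi
        assert np.abs(diff).max() < 1e-10

    def test_whitening_invariance(self, rng):
        e1, e2 = rng.normal(size=(2, 15))
        base = project_to_circle(EigengenePair(e1, e2, (0.6, 0.4)))
        scaled = project_to_circle(EigengenePair(e1, 5.0 * e2, (0.6, 0.4)))
        np.testing.assert_allclose(scaled, base, atol=1e-10)

    def test_matches_atan2_oracle(self, rng):
        e1, e2 = rng.normal(size=(2, 10))
        got = project_to_circle(EigengenePair(e1, e2, (0.6, 0.4)))
        w1 = (e1 - e1.mean()) / e1.std()
        w2 = (e2 - e2.mean()) / e2.std()
        want = np.mod(np.arctan2(w2, w1), TWO_PI)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestCircularOrder:
    def test_examples(self):
        np.testing.assert_array_equal(circular_order([0.1, 3.0, 1.5]),
                                      [0, 2, 1])
        np.testing.assert_array_equal(circular_order([1.0, 1.0, 0.5]),
                                      [2, 0, 1])

    def test_matches_argsort_oracle(self, rng):
        theta = rng.uniform(0, TWO_PI, 100)
        np.testing.assert_array_equal(circular_order(theta),
                                      np.argsort(theta))


class TestDetectOutliers:
    def test_clean_circle_flags_none(self):
        t = TWO_PI * np.arange(30) / 30
        eig = EigengenePair(np.cos(t), np.sin(t), (0.5, 0.5))
        assert detect_outlier_samples(eig) == set()

    def test_planted_outlier_flagged(self):
        t = TWO_PI * np.arange(30) / 30
        e1, e2 = np.cos(t), np.sin(t)
        e1[7], e2[7] = 6.0 * np.cos(t[7]), 6.0 * np.sin(t[7])
        assert detect_outlier_samples(
            EigengenePair(e1, e2, (0.5, 0.5))) == {7}

    def test_too_few_samples(self):
        t = TWO_PI * np.arange(9) / 9
        with pytest.raises(ValueError, match="at least 10"):
            detect_outlier_samples(EigengenePair(np.cos(t), np.sin(t),
                                                 (0.5, 0.5)))


def _seed_matrix(t, phases):
    rows = [np.cos(t - phi) for phi in phases.values()]
    return _normalized(rows, gene_ids=list(phases))


class TestOrient:
    def test_true_candidate_keeps_counterclockwise(self, rng):
        t = rng.uniform(0, TWO_PI, 50)
        x = _seed_matrix(t, {"DBP": np.pi / 2, "ARNTL": np.pi})
        ordering = orient(t, x)
        assert ordering.direction == "counterclockwise"
        tu = {g: fmm_fit(x.row(g), ordering.theta).t_u for g in ("DBP", "ARNTL")}
        assert np.mod(tu["ARNTL"] - tu["DBP"], TWO_PI) < np.pi

    def test_reflected_candidate_selects_clockwise(self, rng):
        t = rng.uniform(0, TWO_PI, 50)
        x = _seed_matrix(t, {"DBP": np.pi / 2, "ARNTL": np.pi})
        ordering = orient(np.mod(-t, TWO_PI), x)
        assert ordering.direction == "clockwise"
        assert circular_correlation(ordering.theta, t) > 0.99

    def test_reflection_mirrors_peaks(self, rng):
        t = rng.uniform(0, TWO_PI, 60)
        y = np.cos(t - 1.0) + 0.02 * rng.normal(size=60)
        tu = fmm_fit(y, t).t_u
        tu_ref = fmm_fit(y, np.mod(-t, TWO_PI)).t_u
        diff = np.abs(np.mod(tu + tu_ref + np.pi, TWO_PI) - np.pi)
        # exact up to the (asymmetric) local refinement step
        assert diff < 1e-2

    def test_prior_chain_selects_satisfying_direction(self, rng):
        t = rng.uniform(0, TWO_PI, 50)
        phases = {"DBP": 1.2, "CRY1": 2.6, "CRY2": 2.2, "ARNTL": np.pi}
        x = _seed_matrix(t, phases)
        prior = [[["DBP"], ["CRY1", "CRY2"], ["ARNTL"]]]
        ordering = orient(t, x, prior=prior)
        assert ordering.direction == "counterclockwise"

    def test_missing_pair_falls_back_then_errors(self, rng):
        t = rng.uniform(0, TWO_PI, 40)
        x = _seed_matrix(t, {"DBP": 1.0, "CRY2": 2.0})
        assert orient(t, x).direction in {"clockwise", "counterclockwise"}
        x2 = _seed_matrix(t, {"PER1": 1.0, "PER2": 2.0})
        with pytest.raises(ValueError, match="fallback"):
            orient(t, x2)


class TestOrderRecovery:
    def test_noise_free_recovery_up_to_rotation_reflection(self, rng):
        # at non-equispaced times the whitened projection is a monotone
        # (circular) deformation of true time: the ORDER is recovered
        # exactly up to rotation and reflection
        t = rng.uniform(0, TWO_PI, 50)
        phases = TWO_PI * np.arange(12) / 12
        x = _normalized([np.cos(t - p) for p in phases])
        theta = project_to_circle(compute_eigengenes(x))
        assert abs(circular_correlation(theta, t)) > 0.95
        est = list(np.argsort(theta, kind="stable"))
        true = list(np.argsort(t, kind="stable"))
        k = est.index(true[0])
        rot = est[k:] + est[:k]
        assert rot == true or rot == [true[0]] + true[1:][::-1]

    def test_permutation_equivariance(self, rng):
        t = rng.uniform(0, TWO_PI, 30)
        x = _normalized([np.cos(t - p) for p in np.linspace(0, 5, 8)])
        theta = project_to_circle(compute_eigengenes(x))
        perm = rng.permutation(30)
        xp = make_matrix(x.values[:, perm], state="normalized")
        theta_p = project_to_circle(compute_eigengenes(xp))
        np.testing.assert_allclose(theta_p, theta[perm], atol=1e-10)
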