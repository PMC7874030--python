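import numpy as np
import pytest

from synergylab import (SynergyNMF, candidate_ranks, classify, compute_coa,
                        compute_fwhm, nmf, overlaps)
from synergylab.synergy import (EPS, SynergyDecomposition,
                                multiplicative_update_step,
                                reconstruction_r2, select_rank_from_curve)


def _coa_bruteforce(h):
    """Literal evaluation of the circular center-of-mass formulas."""
    n = len(h)
    a = sum(np.cos(2 * np.pi * (t - 1) / n) * h[t - 1] for t in range(1, n + 1))
    b = sum(np.sin(2 * np.pi * (t - 1) / n) * h[t - 1] for t in range(1, n + 1))
    ang = np.arctan2(b, a) % (2 * np.pi)
    return n * ang / (2 * np.pi)


def _fwhm_bruteforce(h):
    h = np.asarray(h, float) - min(h)
    half = max(h) / 2
    return sum(1 for v in h if v > half)


class TestNMF:
    def test_exact_low_rank_reconstructed(self, rng):
        """An exactly rank-3 non-negative matrix reaches R^2 >= 0.999 at
        rank 3."""
        w0 = rng.uniform(0.1, 1, size=(13, 3))
        h0 = rng.uniform(0.1, 1, size=(3, 400))
        dec = nmf(w0 @ h0, rank=3, seed=0, n_restarts=3)
        assert dec.r2 >= 0.999

    def test_r2_monotone_within_restart(self, rng):
        """Each multiplicative update never decreases R^2 (within 1e-12)."""
        v = rng.uniform(0, 1, size=(13, 400))
        w = rng.uniform(size=(13, 2))
        h = rng.uniform(size=(2, 400))
        prev = reconstruction_r2(v, w, h)
        for _ in range(200):
            w, h = multiplicative_update_step(v, w, h)
            cur = reconstruction_r2(v, w, h)
            assert cur >= prev - 1e-12
            assert np.all(w >= 0) and np.all(h >= 0)
            prev = cur

    def test_higher_rank_not_worse(self, rng):
        w0 = rng.uniform(0.1, 1, size=(13, 4))
        h0 = rng.uniform(0.1, 1, size=(4, 300))
        v = w0 @ h0 + 0.01 * rng.uniform(size=(13, 300))
        r2s = [nmf(v, rank=r, seed=1, n_restarts=3).r2 for r in (2, 4, 6)]
        assert r2s[0] <= r2s[1] + 1e-6 and r2s[1] <= r2s[2] + 1e-6

    def test_stored_solution_is_best_restart(self, rng):
        v = rng.uniform(0, 1, size=(13, 200))
        dec = nmf(v, rank=3, seed=5)
        assert len(dec.restart_r2) == 10
        assert dec.r2 == pytest.approx(max(dec.restart_r2))

    def test_negative_input_rejected(self):
        v = -np.ones((13, 10))
        with pytest.raises(ValueError, match="non-negative"):
            nmf(v, rank=2, seed=0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nmf(np.ones((13, 10)), rank=2, seed=0)

    def test_muscle_permutation_equivariance(self, rng):
        """Permuting V's rows permutes W's rows and leaves H and R^2
        unchanged."""
        v = rng.uniform(0.05, 1, size=(13, 300))
        perm = rng.permutation(13)
        w = rng.uniform(size=(13, 3))
        h = rng.uniform(size=(3, 300))
        wp, hp = w[perm].copy(), h.copy()
        for _ in range(100):
            w, h = multiplicative_update_step(v, w, h)
            wp, hp = multiplicative_update_step(v[perm], wp, hp)
        np.testing.assert_allclose(wp, w[perm], rtol=1e-10)
        np.testing.assert_allclose(hp, h, rtol=1e-10)
        assert reconstruction_r2(v[perm], wp, hp) == pytest.approx(
            reconstruction_r2(v, w, h), abs=1e-12)

    def test_scale_indeterminacy_reconstruction(self, rng):
        """(W D, D^-1 H) reconstructs identically for positive diagonal D."""
        v = rng.uniform(0.05, 1, size=(13, 200))
        dec = nmf(v, rank=3, seed=2, n_restarts=2)
        d = np.diag(rng.uniform(0.5, 2.0, size=3))
        np.testing.assert_allclose((dec.w @ d) @ (np.linalg.inv(d) @ dec.h),
                                   dec.w @ dec.h, rtol=1e-9)

    def test_primitives_unit_max_normalized(self, rng):
        v = rng.uniform(0.05, 1, size=(13, 200))
        dec = nmf(v, rank=3, seed=2, n_restarts=2)
        np.testing.assert_allclose(dec.h.max(axis=1), 1.0)

    def test_estimator_sklearn_contract(self, rng):
        v = rng.uniform(0.05, 1, size=(13, 400))
        est = SynergyNMF(n_synergies=3, n_restarts=2, random_state=0)
        assert est.get_params()["n_synergies"] == 3
        est.fit(v)
        assert est.modules_.shape == (13, 3)
        assert est.primitives_.shape == (3, 400)
        h = est.transform(v)
        assert h.shape == (3, 400) and np.all(h >= 0)
        clone_params = SynergyNMF(**est.get_params()).get_params()
        assert clone_params == est.get_params()


class TestRankSelection:
    def test_candidate_ranks_for_13_muscles(self):
        assert list(candidate_ranks(13)) == list(range(1, 11))

    def test_elbow_curve_returns_four(self):
        """Saturating-then-linear curve with elbow at rank 4: the dropping
        loop removes ranks 1-3 and stops on the linear tail."""
        curve = {1: 0.5, 2: 0.75, 3: 0.9}
        curve.update({r: 0.97 + 0.005 * (r - 4) for r in range(4, 11)})
        assert select_rank_from_curve(curve) == 4

    def test_perfectly_linear_curve_returns_one(self):
        curve = {r: 0.5 + 0.01 * r for r in range(1, 11)}
        assert select_rank_from_curve(curve) == 1

    def test_exhaustion_returns_lower_of_two(self):
        # concave curve that never fits a line well: loop runs to 2 points
        curve = {1: 0.0, 2: 0.9, 3: 0.92, 4: 1.8, 5: 1.81}
        rank = select_rank_from_curve(curve, mse_threshold=1e-12)
        assert rank == 4


class TestCoA:
    def test_unit_impulse(self):
        h = np.zeros(200)
        h[100] = 1.0
        assert compute_coa(h) == pytest.approx(100.0)

    def test_symmetric_gaussian_center(self):
        t = np.arange(200)
        h = np.exp(-((t - 150) ** 2) / (2 * 15 ** 2))
        assert compute_coa(h) == pytest.approx(150.0, abs=0.5)

    def test_uniform_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_coa(np.ones(200))

    def test_matches_bruteforce(self, rng):
        """Agreement with the literal circular-statistics formulas on 100
        random primitives."""
        for _ in range(100):
            h = rng.uniform(0, 1, size=int(rng.integers(10, 300))) ** 2
            assert compute_coa(h) == pytest.approx(_coa_bruteforce(h),
                                                   abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_coa(np.array([1.0, -0.1, 0.5]))


class TestFWHM:
    def test_rectangular_pulse(self):
        h = np.zeros(200)
        h[30:70] = 1.0
        assert compute_fwhm(h) == 40

    def test_gaussian_sigma10(self):
        t = np.arange(200)
        h = np.exp(-((t - 100) ** 2) / (2 * 10 ** 2))
        assert compute_fwhm(h) in (23, 24)  # 2 sqrt(2 ln 2) sigma = 23.5

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            compute_fwhm(np.full(200, 0.4))

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            h = rng.uniform(0, 1, size=int(rng.integers(10, 300)))
            assert compute_fwhm(h) == _fwhm_bruteforce(h)


def _decomposition_from_primitives(prims, n_cycles=2):
    """Build a SynergyDecomposition whose mean primitives equal ``prims``."""
    h = np.hstack([np.vstack(prims)] * n_cycles)
    r = len(prims)
    w = np.eye(13)[:, :r] + 0.01
    return SynergyDecomposition(w=w, h=h, rank=r, r2=1.0, restart_r2=[1.0],
                                seed=0, n_iter=1, converged=True)


class TestClassification:
    def _gauss(self, c, s=8.0):
        t = np.arange(200)
        return np.exp(-((t - c) ** 2) / (2 * s ** 2))

    def test_four_shared_shapes_labelled_by_coa(self):
        prims = [self._gauss(c) for c in (120, 25, 85, 60)]
        decs = [_decomposition_from_primitives(prims) for _ in range(4)]
        out = classify(decs)
        by_index = {cs.synergy_index: cs.label for cs in out
                    if cs.trial_index == 0}
        assert by_index == {0: "stabilization", 1: "swing",
                            2: "weight_acceptance", 3: "touchdown"}
        for cs in out:
            assert cs.coa is not None and cs.fwhm is not None

    def test_two_peak_primitive_is_combined(self):
        base = [self._gauss(c) for c in (25, 85, 150)]
        blend = self._gauss(60) + self._gauss(150)
        decs = [_decomposition_from_primitives(base + [blend])
                for _ in range(3)]
        out = classify(decs)
        blended = [cs for cs in out if cs.synergy_index == 3]
        assert all(cs.label == "combined" for cs in blended)
        assert all(cs.coa is None and cs.fwhm is None for cs in blended)

    def test_identical_trials_cluster_tightly(self):
        prims = [self._gauss(c) for c in (30, 100)]
        decs = [_decomposition_from_primitives(prims) for _ in range(5)]
        out = classify(decs)
        clusters = {}
        for cs in out:
            clusters.setdefault(cs.cluster_id, []).append(cs.primitive)
        for members in clusters.values():
            assert len(members) == 5
            spread = np.ptp(np.vstack(members), axis=0)
            assert np.max(spread) < 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify([])


class TestOverlaps:
    def test_two_overlapping_rectangles(self):
        a = np.zeros(200)
        a[40:100] = 1.0
        b = np.zeros(200)
        b[70:130] = 1.0
        counts, mean = overlaps([[a, b]])
        assert counts.shape == (1, 200)
        np.testing.assert_array_equal(counts[0, 70:100], 1)
        assert counts[0].sum() == 30
        np.testing.assert_allclose(mean, counts[0])

    def test_disjoint_primitives_zero(self):
        a = np.zeros(200)
        a[10:40] = 1.0
        b = np.zeros(200)
        b[120:160] = 1.0
        counts, _ = overlaps([[a, b]])
        assert counts.sum() == 0

    def test_matches_bruteforce_count(self, rng):
        """Exact agreement with a per-point loop on random primitive sets."""
        for _ in range(100):
            prims = [rng.uniform(0, 1, size=50)
                     for _ in range(int(rng.integers(2, 6)))]
            counts, _ = overlaps([prims])
            for t in range(50):
                above = 0
                for p in prims:
                    q = p - p.min()
                    if q[t] > q.max() / 2:
                        above += 1
                assert counts[0, t] == max(above - 1, 0)

    def test_single_primitive_rejected(self):
        with pytest.raises(ValueError):
            overlaps([[np.ones(10)]])
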