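"""Kabsch superposition and the outlier-corrected scRMSD variants."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from refoldkit.superposition import (
    SuperpositionError,
    corrected_scrmsd,
    iterative_outlier_superpose,
    kabsch_superpose,
    per_residue_rmsd,
    scrmsd,
)

from conftest import make_divergent_tail_pair, make_hinged_pair, random_rigid_motion


def quaternion_rmsd_oracle(mobile, target, restarts=3, seed=0):
    """Minimal RMSD by numerical minimization over unit quaternions.

    Independent of the SVD route: translation is removed by centering,
    the rotation is parameterized by a quaternion and optimized
    numerically from several random starts.
    """
    mob = mobile - mobile.mean(axis=0)
    tar = target - target.mean(axis=0)

    def cost(q):
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        return np.sqrt(np.mean(np.sum((mob @ R.T - tar) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(restarts):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0 / np.linalg.norm(q0), method="Powell",
                       options={"xtol": 1e-10, "ftol": 1e-12})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd_mean == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(12, 3))
        R, t = random_rigid_motion(rng)
        res = kabsch_superpose(pts @ R.T + t, pts)
        assert res.rmsd_mean <= 1e-6

    def test_matches_quaternion_oracle(self, rng):
        """RMSD agrees with independent quaternion-parameterized minimization."""
        for i in range(100):
            a = rng.normal(scale=5.0, size=(10, 3))
            b = rng.normal(scale=5.0, size=(10, 3))
            ours = kabsch_superpose(a, b).rmsd_mean
            oracle = quaternion_rmsd_oracle(a, b, seed=i)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_matches_biotite_superimpose(self, rng):
        """Cross-check against an independently implemented superposition."""
        import biotite.structure as struc

        a = rng.normal(scale=5.0, size=(20, 3))
        b = rng.normal(scale=5.0, size=(20, 3))
        fitted, _ = struc.superimpose(b, a)
        ref_rmsd = float(struc.rmsd(b, fitted))  # biotite works in float32
        assert kabsch_superpose(a, b).rmsd_mean == pytest.approx(ref_rmsd, abs=1e-5)

    def test_no_reflection(self, rng):
        """Mirrored point sets must not be matched by an improper rotation."""
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        res = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert res.rmsd_mean > 0.1

    def test_result_invariants(self, rng):
        a = rng.normal(size=(30, 3))
        b = a + rng.normal(scale=0.5, size=(30, 3))
        res = kabsch_superpose(a, b)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert res.rmsd_mean == pytest.approx(
            np.sqrt(np.mean(res.per_residue_dev**2)), abs=1e-9
        )
        assert (res.per_residue_dev >= 0).all()

    def test_fit_mask_reports_all_residues(self, rng):
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[7:] += 20.0
        mask = np.ones(10, bool)
        mask[7:] = False
        res = kabsch_superpose(a, b, fit_mask=mask)
        assert res.per_residue_dev[:7] == pytest.approx(0.0, abs=1e-9)
        assert (res.per_residue_dev[7:] > 10).all()

    @pytest.mark.parametrize(
        "mobile, target, match",
        [
            (np.zeros((4, 3)), np.zeros((5, 3)), "length mismatch"),
            (np.zeros((2, 3)), np.zeros((2, 3)), "3 fit points"),
            (np.outer(np.arange(5.0), [1, 0, 0]),
             np.outer(np.arange(5.0), [0, 1, 0]), "collinear"),
        ],
    )
    def test_errors(self, mobile, target, match):
        with pytest.raises(SuperpositionError, match=match):
            kabsch_superpose(mobile, target)


class TestPerResidueRmsd:
    def test_identical_all_zero(self, rng):
        pts = rng.normal(size=(8, 3))
        assert per_residue_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, rng):
        a = rng.normal(size=(15, 3))
        b = a + rng.normal(scale=1.0, size=(15, 3))
        np.testing.assert_allclose(
            per_residue_rmsd(a, b), per_residue_rmsd(b, a), atol=1e-9
        )

    def test_single_displaced_residue(self, rng):
        """One residue pushed 5 Å off a large rigid body stands out cleanly."""
        a = rng.normal(scale=10.0, size=(100, 3))
        b = a.copy()
        centered = a[0] - a.mean(axis=0)
        ortho = np.cross(centered, [0.0, 0.0, 1.0])
        b[0] += 5.0 * ortho / np.linalg.norm(ortho)
        dev = per_residue_rmsd(b, a)
        assert 4.5 <= dev[0] <= 5.0
        assert (dev[1:] < 0.5).all()


class TestScrmsd:
    def test_identical(self, rng):
        pts = rng.normal(size=(10, 3))
        assert scrmsd(pts, pts, "mean") == pytest.approx(0.0, abs=1e-12)
        assert scrmsd(pts, pts, "median") == pytest.approx(0.0, abs=1e-12)

    def test_constant_deviation_mean_equals_median(self, rng):
        """All residues offset identically: the optimal fit absorbs the
        offset, so both aggregates agree (at zero)."""
        pts = rng.normal(size=(10, 3))
        shifted = pts + np.array([1.0, 2.0, 3.0])
        assert scrmsd(shifted, pts, "mean") == pytest.approx(
            scrmsd(shifted, pts, "median"), abs=1e-9
        )

    def test_aggregates_against_direct_formula(self):
        """80 residues at ~0.1 Å, 20 at ~8 Å: median tracks the bulk, the
        root-mean-square is dominated by the few large deviations."""
        rng = np.random.default_rng(3)
        a = rng.normal(scale=20.0, size=(100, 3))
        b = a.copy()
        directions = rng.normal(size=(100, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        b[:80] += 0.1 * directions[:80]
        b[80:] += 8.0 * directions[80:]
        dev = per_residue_rmsd(b, a)
        med = scrmsd(b, a, "median")
        mean = scrmsd(b, a, "mean")
        # against the direct formulas on the realized deviations
        assert med == pytest.approx(np.median(dev), abs=1e-12)
        assert mean == pytest.approx(np.sqrt(np.mean(dev**2)), abs=1e-12)
        # and against the construction arithmetic (fit absorbs little here)
        assert med < 0.5
        assert mean == pytest.approx(np.sqrt((80 * 0.01 + 20 * 64.0) / 100), rel=0.2)

    def test_rigid_motion_invariance(self, rng):
        a = rng.normal(size=(20, 3))
        b = a + rng.normal(scale=1.0, size=(20, 3))
        R, t = random_rigid_motion(rng)
        for aggregate in ("mean", "median"):
            assert scrmsd(a @ R.T + t, b, aggregate) == pytest.approx(
                scrmsd(a, b, aggregate), abs=1e-6
            )
        v0 = corrected_scrmsd(a, b)[0]
        v1 = corrected_scrmsd(a @ R.T + t, b)[0]
        assert v1 == pytest.approx(v0, abs=1e-6)


class TestCorrectedScrmsd:
    def test_identical_mad_zero_path(self, rng):
        pts = rng.normal(size=(10, 3))
        value, outliers, res = corrected_scrmsd(pts, pts)
        assert value == pytest.approx(0.0, abs=1e-12)
        assert not outliers.any()

    def test_uniform_noise_no_outlier_explosion(self, rng):
        """Homogeneous noise: the correction must not change the verdict."""
        a = rng.normal(scale=10.0, size=(60, 3))
        b = a + rng.normal(scale=0.3, size=(60, 3))
        plain = scrmsd(a, b, "median")
        value, outliers, _ = corrected_scrmsd(a, b)
        assert value == pytest.approx(plain, abs=0.15)

    def test_constant_deviations_equal_plain(self, rng):
        pts = rng.normal(size=(10, 3))
        shifted = pts + 1.0
        value, outliers, _ = corrected_scrmsd(shifted, pts)
        assert value == pytest.approx(scrmsd(shifted, pts, "median"), abs=1e-12)
        assert not outliers.any()

    def test_divergent_tail_rescued(self):
        """Core + bent tail: the plain mean blows past 2 Å while the
        corrected median recovers the core agreement; flagged outliers are
        concentrated in the tail."""
        target, pred_ca = make_divergent_tail_pair(seed=2, sigma=0.0)
        plain_mean = scrmsd(pred_ca, target.ca_coords, "mean")
        value, outliers, _ = corrected_scrmsd(pred_ca, target.ca_coords)
        assert plain_mean > 2.0
        assert value < plain_mean / 3
        assert outliers[80:].sum() >= outliers[:80].sum()
        assert outliers[80:].sum() >= 10

    def test_correction_dominance_on_tailed_pairs(self):
        for seed in range(10):
            target, pred = make_hinged_pair(seed)
            plain_mean = scrmsd(pred.ca_coords, target.ca_coords, "mean")
            value, outliers, _ = corrected_scrmsd(pred.ca_coords, target.ca_coords)
            assert value <= plain_mean


class TestIterative:
    def test_max_iter_one_equals_single_round(self, rng):
        target, pred = make_hinged_pair(11)
        single = corrected_scrmsd(pred.ca_coords, target.ca_coords)
        once = iterative_outlier_superpose(
            pred.ca_coords, target.ca_coords, max_iter=1
        )
        assert once[0] == single[0]
        assert np.array_equal(once[1], single[1])

    def test_no_outliers_fixed_point(self, rng):
        a = rng.normal(scale=10.0, size=(30, 3))
        b = a + rng.normal(scale=0.2, size=(30, 3))
        single = corrected_scrmsd(a, b)
        iterated = iterative_outlier_superpose(a, b, max_iter=10)
        assert iterated[0] == pytest.approx(single[0], abs=1e-9)

    def test_converges_to_core_fit_on_tail(self):
        """On a bent-tail pair the iterated rejection isolates the core:
        the final median matches a fit computed on the core alone."""
        target, pred_ca = make_divergent_tail_pair(seed=4, sigma=0.5)
        value, outliers, res = iterative_outlier_superpose(
            pred_ca, target.ca_coords, max_iter=10
        )
        core_fit = kabsch_superpose(pred_ca[:80], target.ca_coords[:80])
        # median over the full chain under a clean core fit: the 62.5th
        # percentile of the core deviations (tail occupies the top 20)
        expected = float(np.percentile(core_fit.per_residue_dev, 62.5))
        assert value == pytest.approx(expected, abs=0.3)
        assert value < 2.0
        assert outliers[80:].sum() >= 15
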