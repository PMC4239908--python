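"""Evaluation protocol: path normalization, error curves, cross-validation
tables and the paired t-test."""

import numpy as np
import pytest
from scipy import stats as sps

from skipose.errors import DataError
from skipose.evaluate import (aggregate_runs, cross_validate, ip_ground_error,
                              paired_t_test, path_normalize, pose_error)
from skipose.ip import estimate_ip
from skipose.simulate import make_cohort
from skipose.trajio import PoseSeries


def _pose_from(t, p, com_off=(0, 0, -0.5), ski_off=(0, 0, -1.2)):
    return PoseSeries(t, p, p + np.asarray(com_off), p + np.asarray(ski_off),
                      p + np.asarray(ski_off))


class TestPathNormalize:
    def test_constant_speed_straight_run(self):
        t = np.arange(0, 10, 0.1)
        pos = np.column_stack([2 * t, np.zeros_like(t), np.zeros_like(t)])
        values = 2 * t  # proportional to distance
        s, v = path_normalize(values, positions=pos, n_points=11)
        np.testing.assert_allclose(s, np.linspace(0, 1, 11), atol=1e-12)
        np.testing.assert_allclose(v, np.linspace(0, 20, 11) * 0.95 + 1, atol=2)
        np.testing.assert_allclose(v, values[-1] * s, atol=1e-9)

    def test_idempotent(self):
        t = np.arange(0, 5, 0.05)
        pos = np.column_stack([3 * t, np.sin(t), np.zeros_like(t)])
        vals = np.cos(t)
        s1, v1 = path_normalize(vals, positions=pos, n_points=100)
        pos1 = np.column_stack([s1 * 10, np.zeros_like(s1), np.zeros_like(s1)])
        s2, v2 = path_normalize(v1, positions=pos1, n_points=100)
        np.testing.assert_allclose(v2, v1, atol=1e-9)

    def test_circle_arc_matches_analytic_fractions(self):
        """On a circular arc, s equals the analytic angle fraction."""
        phi = np.linspace(0, np.pi / 2, 2001)
        pos = np.column_stack([30 * np.cos(phi), 30 * np.sin(phi),
                               np.zeros_like(phi)])
        s, v = path_normalize(phi, positions=pos, n_points=41)
        np.testing.assert_allclose(v, s * np.pi / 2, atol=1e-6)

    def test_duration_mode(self):
        t = np.linspace(0, 8, 100)
        s, v = path_normalize(t ** 2, t=t, n_points=5, by="duration")
        # linear interpolation on the 100-point source grid: O(dt²) error
        np.testing.assert_allclose(v, (s * 8) ** 2, atol=5e-3)

    def test_zero_length_rejected(self):
        pos = np.zeros((10, 3))
        with pytest.raises(DataError):
            path_normalize(np.arange(10.0), positions=pos)


class TestPoseError:
    def test_identical_poses_zero_error(self, short_run):
        err = pose_error(short_run, short_run)
        for v in err.values():
            np.testing.assert_array_equal(v, 0.0)

    def test_three_four_five_offset(self):
        t = np.arange(0, 1, 0.05)
        p = np.column_stack([t, t, t])
        ref = _pose_from(t, p)
        est = PoseSeries(t, p, ref.com + [0.03, 0.04, 0.0],
                         ref.ski_left, ref.ski_right)
        err = pose_error(est, ref)
        np.testing.assert_allclose(err["com"], 0.05, atol=1e-12)
        np.testing.assert_allclose(err["ski_mean"], 0.0, atol=1e-12)

    def test_random_offsets_match_direct_norm(self, rng):
        t = np.arange(0, 1, 0.05)
        p = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        ref = _pose_from(t, p)
        d_com = rng.normal(size=(t.size, 3))
        d_l = rng.normal(size=(t.size, 3))
        d_r = rng.normal(size=(t.size, 3))
        est = PoseSeries(t, p, ref.com + d_com, ref.ski_left + d_l,
                         ref.ski_right + d_r)
        err = pose_error(est, ref)
        np.testing.assert_allclose(err["com"], np.linalg.norm(d_com, axis=1),
                                   atol=1e-12)
        expect = 0.5 * (np.linalg.norm(d_l, axis=1)
                        + np.linalg.norm(d_r, axis=1))
        np.testing.assert_allclose(err["ski_mean"], expect, atol=1e-12)

    def test_mismatched_time_base_rejected(self, short_run):
        shifted = PoseSeries(short_run.t + 0.5, short_run.antenna,
                             short_run.com, short_run.ski_left,
                             short_run.ski_right)
        with pytest.raises(DataError):
            pose_error(shifted, short_run)


class TestIpGroundError:
    def test_balanced_zero_stance_recovery(self, default_skier, short_course):
        """Stance 0 and balanced geometry: the pendulum ground point is the
        mid-ski point to < 0.02 m."""
        from skipose.simulate import SkierSpec, make_course, make_run
        mesh, gates = make_course(short_course)
        skier = SkierSpec(stance_width_m=0.0)
        run = make_run((mesh, gates), skier, speed_spec=short_course)
        res = estimate_ip(run.antenna_trajectory(), mesh)
        err = ip_ground_error(res, run)
        assert np.sqrt(np.mean(err["ground_vs_midski"] ** 2)) < 0.02

    def test_midpoint_conventions(self, short_run):
        """Coincident skis: midpoint equals the ski position; symmetric
        stance: midpoint is independent of its width."""
        mid = short_run.mid_ski()
        collapsed = PoseSeries(short_run.t, short_run.antenna, short_run.com,
                               mid, mid)
        np.testing.assert_allclose(collapsed.mid_ski(), mid, atol=1e-12)
        half = short_run.ski_left - mid
        widened = PoseSeries(short_run.t, short_run.antenna, short_run.com,
                             mid + 2 * half, mid - 2 * half)
        np.testing.assert_allclose(widened.mid_ski(), mid, atol=1e-9)


class TestAggregateRuns:
    def test_single_run_mean_is_run_sd_zero(self):
        t = np.arange(0, 5, 0.05)
        pos = np.column_stack([4 * t, np.zeros_like(t), np.zeros_like(t)])
        e = np.abs(np.sin(t))
        curve = aggregate_runs([e], positions=[pos], n_points=50)
        np.testing.assert_allclose(curve.sd, 0.0, atol=1e-12)
        np.testing.assert_allclose(curve.mean, curve.per_run[0], atol=1e-12)

    def test_identical_runs_zero_sd(self):
        t = np.arange(0, 5, 0.05)
        pos = np.column_stack([4 * t, np.zeros_like(t), np.zeros_like(t)])
        e = np.abs(np.sin(t))
        curve = aggregate_runs([e, e, e], positions=[pos] * 3)
        np.testing.assert_allclose(curve.sd, 0.0, atol=1e-12)

    def test_hand_computed_mean_and_sd(self):
        t = np.arange(0, 1.05, 0.05)
        pos = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        e1 = np.full(t.size, 1.0)
        e2 = np.full(t.size, 3.0)
        curve = aggregate_runs([e1, e2], positions=[pos, pos], n_points=10)
        np.testing.assert_allclose(curve.mean, 2.0, atol=1e-12)
        np.testing.assert_allclose(curve.sd, 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def small_cohort(short_course):
    return make_cohort(n_skiers=2, runs_per_skier=(2, 2),
                       course=short_course, seed=3)


class TestCrossValidate:

    def test_table_dimensions(self, small_cohort):
        mesh, recs = small_cohort
        com_t, ski_t = cross_validate(recs, mesh, method="lwpr")
        assert com_t.mean.shape == (4, 2)
        assert ski_t.mean.shape == (4, 2)
        assert len(com_t.rows) == 4 and com_t.cols == ["S1", "S2"]
        assert np.all(com_t.mean >= 0)

    def test_single_skier_degenerate_table(self, short_course):
        mesh, recs = make_cohort(n_skiers=1, runs_per_skier=(2,),
                                 course=short_course, seed=3)
        com_t, _ = cross_validate(recs, mesh, method="lwpr")
        assert com_t.mean.shape == (2, 1)
        assert com_t.offdiagonal_values().size == 0

    def test_diagonal_mask_and_offdiagonal_count(self, small_cohort):
        mesh, recs = small_cohort
        com_t, _ = cross_validate(recs, mesh, method="lwpr")
        mask = com_t.diagonal_mask()
        assert mask.sum() == 4  # one own-skier cell per run row
        assert com_t.offdiagonal_values().size == 4  # 4 runs x 1 other skier

    def test_insufficient_runs_rejected(self, short_course):
        mesh, recs = make_cohort(n_skiers=1, runs_per_skier=(1,),
                                 course=short_course, seed=3)
        with pytest.raises(DataError):
            cross_validate(recs[:1], mesh)


class TestPairedTTest:
    def test_identical_vectors(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0 and r.df == 2

    def test_worked_example(self):
        """Differences (1,2,3,4): t = 2.5/(1.29099/2) ≈ 3.873, df = 3."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = paired_t_test(a, np.zeros(4))
        assert r.t == pytest.approx(3.8729833, abs=1e-6)
        assert r.df == 3

    def test_antisymmetry(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        assert paired_t_test(a, b).t == pytest.approx(-paired_t_test(b, a).t,
                                                      rel=1e-12)

    def test_matches_scipy_reference(self, rng):
        """Agreement with scipy.stats.ttest_rel to 1e-10 on random inputs."""
        for _ in range(20):
            n = rng.integers(5, 40)
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            ours = paired_t_test(a, b)
            ref = sps.ttest_rel(a, b)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert ours.df == n - 1

    def test_degenerate_conventions(self):
        r = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.p == 0.0 and np.isinf(r.t)
        with pytest.raises(DataError):
            paired_t_test([1.0], [2.0])
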