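import numpy as np
import pytest
from scipy import stats

from ripplepond import (
    DiscSpec,
    SimilarityTable,
    TemporalPattern,
    build_disc,
    cosine_similarity,
    estimate_period,
    invariance_sweep,
    normalize_tp,
    spearman_rho,
    transform_to_tp,
)
from ripplepond.errors import (
    EmptyPatternError,
    InvalidParameterError,
    NoPeriodError,
    UndefinedSimilarityError,
)


def tp_of(values, m=None):
    values = np.asarray(values)
    return TemporalPattern(values=values,
                           m=int(values.sum()) if m is None else m)


class TestNormalizeTp:
    def test_identity_when_support_matches_target(self):
        tp = tp_of([3, 1, 4, 1, 5], m=1)
        out = normalize_tp(tp, target_len=5)
        assert np.allclose(out.values, [3, 1, 4, 1, 5])

    def test_worked_resample_example(self):
        # support [4, 4] of an m=8 pattern resampled to 4 points
        out = normalize_tp(tp_of([0, 0, 4, 4], m=8), target_len=4)
        assert np.allclose(out.values, [0.5, 0.5, 0.5, 0.5])

    def test_division_by_size_cue(self):
        out = normalize_tp(tp_of([2, 4, 2]), target_len=3)
        assert out.m == 8
        assert np.allclose(out.values, [0.25, 0.5, 0.25])

    def test_idempotent_on_full_support_patterns(self):
        vals = np.array([0.2, 0.5, 0.1, 0.9, 0.4])
        once = normalize_tp(TemporalPattern(values=vals, m=1), target_len=5)
        twice = normalize_tp(
            TemporalPattern(values=once.values, m=1), target_len=5
        )
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(EmptyPatternError):
            normalize_tp(tp_of([0, 0, 0]))

    def test_scaled_circles_align_after_normalization(self, full_disc):
        size = 200
        c = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        rr = np.hypot(xx - c, yy - c)

        def norm_tp(radius):
            from ripplepond import project_frame, ripple

            img = (rr <= radius).astype(float)
            return normalize_tp(ripple(project_frame(img, full_disc, 0.5)))

        big, small = norm_tp(90.0), norm_tp(45.0)
        assert cosine_similarity(big.values, small.values) > 0.9


class TestSimilarityMetrics:
    def test_cosine_basic_identities(self):
        u = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(u, u) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity(u, -u) == pytest.approx(-1.0)

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity([0, 0], [1, 2])

    def test_spearman_monotone_transform_is_one(self):
        u = np.array([1.0, 2.5, 3.0, 10.0])
        assert spearman_rho(u, np.exp(u)) == pytest.approx(1.0)
        assert spearman_rho(u, u[::-1] * -1) == pytest.approx(1.0)

    def test_spearman_reversal_is_minus_one(self):
        u = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert spearman_rho(u, -u) == pytest.approx(-1.0)

    def test_spearman_ties_against_hand_ranking(self):
        # independent oracle: mean-rank ties + Pearson on the ranks
        u, v = np.array([1.0, 2, 2, 3]), np.array([1.0, 2, 3, 3])
        ranks_u = np.array([1.0, 2.5, 2.5, 4.0])
        ranks_v = np.array([1.0, 2.0, 3.5, 3.5])
        expected = stats.pearsonr(ranks_u, ranks_v).statistic
        assert spearman_rho(u, v) == pytest.approx(expected, abs=1e-12)

    def test_spearman_constant_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_metrics_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        u, v = rng.random(20), rng.random(20)
        assert cosine_similarity(3.7 * u, v) == pytest.approx(
            cosine_similarity(u, v), abs=1e-12
        )
        assert spearman_rho(u, 0.01 * v) == pytest.approx(
            spearman_rho(u, v), abs=1e-12
        )


@pytest.fixture(scope="module")
def mini_sweep_setup():
    layout = build_disc(DiscSpec(32, 24, trials=30, seed=3))
    from ripplepond import make_test_set

    images = [img for _, img in make_test_set(6, seed=11, size=96)]
    return layout, images


class TestInvarianceSweep:
    def test_identity_grid_point_is_perfect(self, mini_sweep_setup):
        layout, images = mini_sweep_setup
        for transform, ident in [("rotation", 0.0), ("scale", 1.0),
                                 ("translation", 0.0)]:
            tab = invariance_sweep(images, layout, transform,
                                   np.array([ident]), target_len=50)
            assert tab.mean_cos[0] == pytest.approx(1.0)
            assert tab.mean_rho[0] == pytest.approx(1.0)
            assert tab.n_used[0] == len(images)

    def test_deterministic(self, mini_sweep_setup):
        layout, images = mini_sweep_setup
        grid = np.array([0.0, 10.0])
        a = invariance_sweep(images, layout, "translation", grid)
        b = invariance_sweep(images, layout, "translation", grid)
        assert np.array_equal(a.mean_cos, b.mean_cos)
        assert np.array_equal(a.mean_rho, b.mean_rho)

    def test_rotation_by_one_arm_is_exact_in_sampling_mode(
        self, mini_sweep_setup
    ):
        layout, images = mini_sweep_setup
        arm = 2 * np.pi / layout.spec.arms
        tab = invariance_sweep(images, layout, "rotation",
                               np.array([0.0, arm, 2 * arm]))
        assert np.allclose(tab.mean_cos, 1.0, atol=1e-12)

    def test_vanishing_scale_excluded_from_mean(self, mini_sweep_setup):
        layout, images = mini_sweep_setup
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = invariance_sweep(images, layout, "scale",
                                   np.array([1.0, 1e-3]))
        assert tab.n_used[1] == 0 and np.isnan(tab.mean_cos[1])

    def test_empty_grid_rejected(self, mini_sweep_setup):
        layout, images = mini_sweep_setup
        with pytest.raises(InvalidParameterError):
            invariance_sweep(images, layout, "rotation", np.array([]))


class TestEstimatePeriod:
    @staticmethod
    def _table(grid, curve):
        return SimilarityTable(transform="rotation", grid=grid,
                               mean_cos=curve, mean_rho=curve,
                               n_used=np.ones(len(grid), int), n_images=1)

    def test_recovers_known_sinusoid_period(self):
        p = 0.05
        grid = np.linspace(0, 4 * p, 81)
        curve = np.cos(2 * np.pi * grid / p)
        est = estimate_period(self._table(grid, curve))
        assert abs(est - p) <= grid[1] - grid[0]

    def test_constant_curve_has_no_period(self):
        grid = np.linspace(0, 1, 32)
        with pytest.raises(NoPeriodError):
            estimate_period(self._table(grid, np.ones(32)))

    def test_non_rotation_table_rejected(self):
        tab = SimilarityTable(transform="scale", grid=np.arange(8.0),
                              mean_cos=np.arange(8.0),
                              mean_rho=np.arange(8.0),
                              n_used=np.ones(8, int), n_images=1)
        with pytest.raises(InvalidParameterError):
            estimate_period(tab)

    def test_nonuniform_grid_rejected(self):
        grid = np.array([0.0, 0.1, 0.5, 0.6, 1.2])
        with pytest.raises(InvalidParameterError):
            estimate_period(self._table(grid, np.cos(grid)))


class TestTransformToTp:
    def test_conservation_through_pipeline(self, mini_sweep_setup):
        layout, images = mini_sweep_setup
        for img in images:
            tp = transform_to_tp(img, layout)
            assert tp.values.sum() == tp.m > 0
            assert len(tp.values) == layout.spec.per_arm
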