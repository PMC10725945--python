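import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionmap.core import LesionStack, ReferenceGrid, build_stack
from lesionmap.simulate import SimulationConfig, generate_cohort
from lesionmap.vlsm import (
    DesignMatrix,
    DesignSpec,
    bh_fdr,
    build_design,
    default_min_lesion_count,
    extract_roi,
    fit_voxelwise_glm,
    permutation_null,
    run_vlsm,
    voxel_inclusion,
)
from tests.conftest import make_clinical


def tiny_stack(data: np.ndarray) -> LesionStack:
    """Stack whose grid is a flat (V,1,1) line, for hand-built voxel patterns."""
    n, v = data.shape
    grid = ReferenceGrid(shape=(v, 1, 1))
    return LesionStack(grid=grid, patient_ids=[f"P{i + 1:04d}" for i in range(n)], data=data)


class TestDesignSpec:
    def test_bad_outcome(self):
        with pytest.raises(ValueError):
            DesignSpec(outcome="karnofsky")

    def test_too_few_permutations_refused(self):
        with pytest.raises(ValueError, match="[pP]ermutations"):
            DesignSpec(outcome="kps", n_permutations=50)

    def test_unknown_covariate(self):
        with pytest.raises(ValueError):
            DesignSpec(outcome="kps", covariates=("age", "bmi"))


class TestBuildDesign:
    def test_shape_and_columns(self):
        # n must exceed the 5 design columns for the full-rank invariant to hold
        clin = make_clinical(8)
        dm = build_design(clin, DesignSpec(outcome="kps"))
        assert dm.values.shape == (8, 5)
        assert dm.columns == ["intercept", "kps", "age", "sex", "volume"]

    def test_standardized_columns_zero_mean_unit_sd(self):
        clin = make_clinical(30)
        dm = build_design(clin, DesignSpec(outcome="kps"))
        for j, name in enumerate(dm.columns):
            if name in ("kps", "age", "volume"):
                assert abs(dm.values[:, j].mean()) < 1e-12
                assert dm.values[:, j].std() == pytest.approx(1.0)

    def test_sex_coding(self):
        clin = make_clinical(10)
        dm = build_design(clin, DesignSpec(outcome="kps", covariates=("sex",)))
        expected = (clin["sex"] == "male").astype(float).to_numpy()
        assert np.array_equal(dm.values[:, 2], expected)

    def test_constant_column_rejected(self):
        clin = make_clinical(10)
        clin["age"] = 50.0
        with pytest.raises(ValueError, match="constant|rank"):
            build_design(clin, DesignSpec(outcome="kps"))

    def test_missing_values_listed(self):
        clin = make_clinical(5)
        clin.loc[2, "age"] = np.nan
        with pytest.raises(ValueError, match=str(clin.loc[2, "patient_id"])):
            build_design(clin, DesignSpec(outcome="kps"))

    def test_log_time_option(self):
        clin = make_clinical(20)
        a = build_design(clin, DesignSpec(outcome="os"))
        b = build_design(clin, DesignSpec(outcome="os", log_time=True))
        assert not np.allclose(a.values[:, 1], b.values[:, 1])


class TestVoxelInclusion:
    def test_definition(self):
        data = np.zeros((10, 3), dtype=np.uint8)
        data[:, 1] = 1  # all patients -> excluded (no contrast)
        data[:5, 2] = 1  # half -> included for k <= 5
        stack = tiny_stack(data)
        analyzed = voxel_inclusion(stack, 5).reshape(-1)
        assert analyzed.tolist() == [0, 0, 1]

    def test_default_rule(self):
        assert default_min_lesion_count(60) == 5
        assert default_min_lesion_count(150) == 8
        assert default_min_lesion_count(1000) == 50

    def test_empty_warns(self):
        data = np.zeros((10, 2), dtype=np.uint8)
        data[0, 0] = 1
        with pytest.warns(UserWarning, match="inclusion"):
            analyzed = voxel_inclusion(tiny_stack(data), 5)
        assert analyzed.sum() == 0


class TestGLMOracle:
    """Dual-route check: vectorized fit vs per-voxel statsmodels OLS."""

    def test_matches_statsmodels_on_random_voxels(self):
        import statsmodels.api as sm

        cfg = SimulationConfig(n_patients=120, seed=42)
        clin, masks, _ = generate_cohort(cfg)
        stack = build_stack(masks, clin)
        spec = DesignSpec(outcome="kps")
        design = build_design(clin, spec)
        analyzed = voxel_inclusion(stack, default_min_lesion_count(120))
        statmap = fit_voxelwise_glm(stack, design, analyzed)

        flat_idx = np.nonzero(analyzed.reshape(-1))[0]
        rng = np.random.default_rng(0)
        for v in rng.choice(flat_idx, size=10, replace=False):
            y = stack.data[:, v].astype(float)
            fit = sm.OLS(y, design.values).fit()
            i, j, k = np.unravel_index(v, stack.grid.shape)
            assert statmap.t[i, j, k] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert statmap.beta[i, j, k] == pytest.approx(fit.params[1], abs=1e-8)

    def test_sign_convention_adverse_positive(self):
        # lesion present exactly in the 10 lowest-KPS patients -> strongly adverse
        clin = make_clinical(20, seed=1)
        # varied within both halves so the lesion indicator is not an exact
        # linear function of the outcome column (which would zero the residual)
        clin["kps"] = np.array([30, 30, 40, 40, 50, 50, 60, 60, 60, 60,
                                70, 80, 80, 90, 90, 90, 100, 100, 100, 100])
        data = np.zeros((20, 4), dtype=np.uint8)
        data[:10, 0] = 1  # the low-KPS half
        data[::2, 1] = 1
        data[1::2, 2] = 1
        data[5:15, 3] = 1
        stack = tiny_stack(data)
        spec = DesignSpec(outcome="kps", covariates=())
        design = build_design(clin, spec)
        statmap = fit_voxelwise_glm(stack, design, np.ones(stack.grid.shape, dtype=np.uint8))
        t_adv = statmap.t_adv.reshape(-1)
        assert t_adv[0] > 5.0

    def test_null_t_distribution(self):
        # independent binary voxels: outcome t statistic follows Student-t(df)
        rng = np.random.default_rng(0)
        n, V = 200, 1000
        clin = make_clinical(n, seed=3)
        design = build_design(clin, DesignSpec(outcome="kps"))
        data = (rng.random((n, V)) < 0.3).astype(np.uint8)
        stack = tiny_stack(data)
        statmap = fit_voxelwise_glm(stack, design, np.ones(stack.grid.shape, dtype=np.uint8))
        t = statmap.t.reshape(-1)
        t = t[np.isfinite(t)]
        assert stats.kstest(t, "t", args=(statmap.df,)).pvalue > 0.01

    def test_df(self):
        clin = make_clinical(30)
        design = build_design(clin, DesignSpec(outcome="kps"))
        data = np.zeros((30, 2), dtype=np.uint8)
        data[:10, 0] = 1
        data[10:25, 1] = 1
        statmap = fit_voxelwise_glm(tiny_stack(data), design, np.ones((2, 1, 1), dtype=np.uint8))
        assert statmap.df == 30 - 5


class TestBhFdr:
    def test_stepup_two_values(self):
        reject, adj = bh_fdr([0.01, 0.5], 0.05)
        assert reject.tolist() == [True, False]

    def test_stepup_both_rejected(self):
        # p_(2) = 0.04 <= 2*0.05/2 so both fall
        reject, _ = bh_fdr([0.03, 0.04], 0.05)
        assert reject.tolist() == [True, True]

    def test_all_ones(self):
        reject, adj = bh_fdr([1.0, 1.0, 1.0], 0.05)
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_empty(self):
        reject, adj = bh_fdr([], 0.05)
        assert reject.size == 0 and adj.size == 0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.beta(0.4, 3.0, size=200)
        reject, adj = bh_fdr(p, 0.05)
        sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(reject, sm_rej)
        assert adj == pytest.approx(sm_adj)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(n_patients=80, seed=9)
    clin, masks, _ = generate_cohort(cfg)
    stack = build_stack(masks, clin)
    spec = DesignSpec(outcome="kps", n_permutations=100, seed=123)
    design = build_design(clin, spec)
    analyzed = voxel_inclusion(stack, default_min_lesion_count(80))
    statmap = fit_voxelwise_glm(stack, design, analyzed)
    return stack, design, analyzed, spec, statmap


class TestPermutationNull:
    def test_deterministic_with_seed(self, fitted):
        stack, design, analyzed, spec, statmap = fitted
        a = permutation_null(stack, design, analyzed, spec, statmap=statmap)
        b = permutation_null(stack, design, analyzed, spec, statmap=statmap)
        assert np.array_equal(a.pvalues, b.pvalues)
        assert np.array_equal(a.threshold, b.threshold)

    def test_pvalue_bounds(self, fitted):
        stack, design, analyzed, spec, statmap = fitted
        null = permutation_null(stack, design, analyzed, spec, statmap=statmap)
        floor = 1.0 / (spec.n_permutations + 1)
        assert np.all(null.pvalues >= floor - 1e-12)
        assert np.all(null.pvalues <= 1.0)
        assert np.all(np.isfinite(null.threshold))

    def test_freedman_lane_scheme_runs(self, fitted):
        stack, design, analyzed, _, statmap = fitted
        spec = DesignSpec(outcome="kps", n_permutations=100, seed=123, permutation_scheme="freedman_lane")
        null = permutation_null(stack, design, analyzed, spec, statmap=statmap)
        assert null.scheme == "freedman_lane"
        assert np.all((null.pvalues > 0) & (null.pvalues <= 1))

    def test_strong_voxel_hits_pvalue_floor(self):
        # a voxel whose lesion pattern exactly tracks the worst outcomes
        clin = make_clinical(30, seed=2)
        clin["kps"] = np.sort(clin["kps"].to_numpy())
        data = np.zeros((30, 5), dtype=np.uint8)
        data[:10, 0] = 1  # the 10 worst KPS
        rng = np.random.default_rng(0)
        data[:, 1:] = rng.random((30, 4)) < 0.4
        stack = tiny_stack(data)
        spec = DesignSpec(outcome="kps", covariates=(), n_permutations=200, seed=1)
        design = build_design(clin, spec)
        analyzed = np.ones(stack.grid.shape, dtype=np.uint8)
        statmap = fit_voxelwise_glm(stack, design, analyzed)
        null = permutation_null(stack, design, analyzed, spec, statmap=statmap)
        assert null.pvalues[0] == pytest.approx(1.0 / 201.0)


class TestExtractRoi:
    def test_limiting_case_roi_equals_analyzed(self):
        cfg = SimulationConfig(n_patients=60, seed=21)
        clin, masks, _ = generate_cohort(cfg)
        stack = build_stack(masks, clin)
        spec = DesignSpec(outcome="kps", alpha=1.0, threshold_rule="none", n_permutations=100, seed=5)
        _, _, roi = run_vlsm(stack, clin, spec)
        analyzed = voxel_inclusion(stack, default_min_lesion_count(60))
        assert np.array_equal(roi.mask, analyzed)

    def test_roi_subset_of_analyzed(self):
        cfg = SimulationConfig(n_patients=80, seed=13, kps_effect=-30.0)
        clin, masks, _ = generate_cohort(cfg)
        stack = build_stack(masks, clin)
        spec = DesignSpec(outcome="kps", n_permutations=100, seed=2)
        statmap, null, roi = run_vlsm(stack, clin, spec, label="ROI1")
        assert np.all(roi.mask <= statmap.analyzed)
        assert roi.label == "ROI1"
        assert roi.provenance["outcome"] == "kps"

    def test_recovery_with_strong_effect(self):
        cfg = SimulationConfig(n_patients=150, seed=1, kps_effect=-25.0)
        clin, masks, truth = generate_cohort(cfg)
        stack = build_stack(masks, clin)
        spec = DesignSpec(outcome="kps", n_permutations=200, seed=11)
        _, _, roi = run_vlsm(stack, clin, spec)
        eff = truth.effect_region.astype(bool)
        r = roi.mask.astype(bool)
        dice = 2 * np.logical_and(r, eff).sum() / (r.sum() + eff.sum())
        assert dice >= 0.3

    def test_null_cohort_empty_roi(self):
        cfg = SimulationConfig(n_patients=80, seed=2, kps_effect=0.0, os_log_hazard_effect=0.0)
        clin, masks, _ = generate_cohort(cfg)
        stack = build_stack(masks, clin)
        spec = DesignSpec(outcome="kps", n_permutations=100, seed=3)
        _, _, roi = run_vlsm(stack, clin, spec)
        assert roi.n_voxels == 0

    def test_empty_analyzed_set_is_noop(self):
        cfg = SimulationConfig(n_patients=60, seed=21)
        clin, masks, _ = generate_cohort(cfg)
        stack = build_stack(masks, clin)
        spec = DesignSpec(outcome="kps", n_permutations=100, seed=5, min_lesion_count=30)
        with pytest.warns(UserWarning, match="inclusion"):
            statmap, null, roi = run_vlsm(stack, clin, spec)
        assert roi.n_voxels == 0
        assert null.pvalues.size == 0


class TestMonotonicity:
    def test_roi_grows_with_effect_size(self):
        # stronger lesion-outcome coupling never shrinks mean ROI size
        sizes = {}
        for eff in (0.0, -15.0, -30.0):
            total = 0
            for seed in range(4):
                cfg = SimulationConfig(n_patients=100, seed=seed, kps_effect=eff)
                clin, masks, _ = generate_cohort(cfg)
                stack = build_stack(masks, clin)
                spec = DesignSpec(outcome="kps", n_permutations=100, seed=seed + 50)
                _, _, roi = run_vlsm(stack, clin, spec)
                total += roi.n_voxels
            sizes[eff] = total / 4
        assert sizes[0.0] <= sizes[-15.0] <= sizes[-30.0]
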