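import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from sklearn.base import clone

import skintemp as st
from skintemp.errors import EmptyDesignError, SingularDesignError
from skintemp.reference import REFERENCE_WEIGHTS
from skintemp.sites import GROUP_SITES, SiteCode, SiteGroup
from skintemp.subsetfit import (
    DEFAULT_RANK_TOL,
    LinearCompositeModel,
    SensorSubset,
    build_design,
    enumerate_subsets,
    fit_all,
    fit_weights,
    reconstruct,
)
from skintemp.synthetic import apply_nonwear, generate_cohort

from conftest import grid_search_weights


class TestEnumerate:
    def test_counts_31_proximal_15_distal(self):
        assert len(enumerate_subsets(SiteGroup.PROX)) == 31  # 2^5 - 1
        assert len(enumerate_subsets(SiteGroup.DIST)) == 15  # 2^4 - 1

    def test_order_is_size_then_id_and_starts_with_singletons(self):
        subs = enumerate_subsets(SiteGroup.PROX)
        singles = {s.canonical_id for s in subs[:5]}
        assert singles == {"A", "LIA", "RIA", "LMT", "RMT"}
        keys = [(len(s), s.canonical_id) for s in subs]
        assert keys == sorted(keys)

    def test_subset_rejects_foreign_sites(self):
        with pytest.raises(ValueError, match="do not belong"):
            SensorSubset.from_codes(SiteGroup.PROX, ["A", "LF"])
        with pytest.raises(ValueError, match="nonempty"):
            SensorSubset(SiteGroup.DIST, frozenset())


class TestBuildDesign:
    def test_full_prox_design_has_13x480_rows(self, nogap_cohort):
        subset = SensorSubset(SiteGroup.PROX, frozenset(GROUP_SITES[SiteGroup.PROX]))
        d = build_design(nogap_cohort, subset)
        assert (d.n, d.p) == (13 * 480, 5)
        # removing RMT keeps N, drops one column
        four = SensorSubset.from_codes(SiteGroup.PROX, ["A", "LIA", "RIA", "LMT"])
        d4 = build_design(nogap_cohort, four)
        assert (d4.n, d4.p) == (6240, 4)

    def test_gap_in_one_subject_reduces_every_proximal_subset_by_its_length(self):
        cfg = st.SyntheticConfig(seed=19, nonwear_rate_per_day=0.0)
        cohort = generate_cohort(cfg)
        apply_nonwear(cohort.recordings[3],
                      [st.NonWearEvent(100, 10, GROUP_SITES[SiteGroup.PROX])])
        cohort = st.preprocess(cohort)
        for subset in enumerate_subsets(SiteGroup.PROX)[:6]:
            assert build_design(cohort, subset).n == 6240 - 10
        # distal designs are untouched (complete-case rule is per group)
        dist_full = SensorSubset(SiteGroup.DIST, frozenset(GROUP_SITES[SiteGroup.DIST]))
        assert build_design(cohort, dist_full).n == 6240

    def test_rows_are_appended_in_ascending_subject_order(self, nogap_cohort):
        subset = SensorSubset.from_codes(SiteGroup.DIST, ["LF"])
        d = build_design(nogap_cohort, subset)
        assert list(np.unique(d.subject_ids)) == sorted(nogap_cohort.subject_ids)
        boundaries = np.flatnonzero(d.subject_ids[1:] != d.subject_ids[:-1])
        assert len(boundaries) == 12  # 13 contiguous blocks

    def test_empty_design_raises(self, tiny_config):
        cohort = generate_cohort(tiny_config)
        for rec in cohort:
            apply_nonwear(rec, [st.NonWearEvent(0, rec.n_samples(), GROUP_SITES[SiteGroup.PROX])])
        subset = SensorSubset.from_codes(SiteGroup.PROX, ["A"])
        with pytest.raises(EmptyDesignError):
            build_design(cohort, subset)


class TestLinearCompositeModel:
    def test_exact_single_column_representation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(33, 1, size=50)
        model = LinearCompositeModel().fit(x[:, None], x)
        assert model.coef_[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(model.predict(x[:, None]), x)

    def test_matches_normal_equations_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3)) + 30
        y = X @ [0.5, 0.2, 0.3] + rng.normal(0, 0.1, 200)
        model = LinearCompositeModel().fit(X, y)
        w_normal = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.coef_, w_normal, rtol=1e-8)

    def test_matches_refined_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        y = 0.7 * X[:, 0] + 0.3 * X[:, 1] + rng.normal(0, 0.05, 30)
        model = LinearCompositeModel().fit(X, y)
        w_grid = grid_search_weights(X, y)
        np.testing.assert_allclose(model.coef_, w_grid, atol=1e-6)

    def test_singular_design_rejected_with_offending_columns(self):
        x = np.linspace(30, 35, 40)
        X = np.column_stack([x, 2 * x, np.random.default_rng(3).normal(size=40)])
        with pytest.raises(SingularDesignError, match=r"\[0, 1\]"):
            LinearCompositeModel().fit(X, x)

    def test_sklearn_estimator_protocol(self):
        model = LinearCompositeModel(rank_tol=1e-8)
        assert model.get_params() == {"rank_tol": 1e-8}
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_input_validation(self):
        model = LinearCompositeModel()
        with pytest.raises(ValueError, match="rows"):
            model.fit(np.ones((3, 1)), np.ones(4))
        with pytest.raises(EmptyDesignError):
            model.fit(np.empty((0, 2)), np.empty(0))
        with pytest.raises(ValueError, match="finite"):
            model.fit(np.array([[1.0], [np.nan]]), np.ones(2))


class TestFitWeights:
    def test_full_proximal_fit_recovers_reference_weights(self, default_cohort):
        subset = SensorSubset(SiteGroup.PROX, frozenset(GROUP_SITES[SiteGroup.PROX]))
        d = build_design(default_cohort, subset)
        w = fit_weights(d)
        expected = REFERENCE_WEIGHTS[SiteGroup.PROX]
        for site in GROUP_SITES[SiteGroup.PROX]:
            assert w.weight(site) == pytest.approx(expected[site], abs=1e-8)
        that = reconstruct(d, w)
        assert st.mse(d.T, that) <= 1e-16

    def test_full_distal_fit_recovers_quarter_weights(self, default_cohort):
        subset = SensorSubset(SiteGroup.DIST, frozenset(GROUP_SITES[SiteGroup.DIST]))
        w = fit_weights(build_design(default_cohort, subset))
        for site in GROUP_SITES[SiteGroup.DIST]:
            assert w.weight(site) == pytest.approx(0.25, abs=1e-8)

    def test_excluded_sites_carry_weight_exactly_zero(self, default_cohort):
        subset = SensorSubset.from_codes(SiteGroup.PROX, ["A", "RIA", "RMT"])
        w = fit_weights(build_design(default_cohort, subset))
        assert w.weight(SiteCode.LIA) == 0.0
        assert w.weight(SiteCode.LMT) == 0.0
        assert len(w.full_group_array()) == 5

    def test_residual_orthogonal_to_columns(self, default_cohort):
        for subset in enumerate_subsets(SiteGroup.DIST)[:8]:
            d = build_design(default_cohort, subset)
            w = fit_weights(d)
            resid = d.T - reconstruct(d, w)
            lhs = np.abs(d.X.T @ resid).max()
            assert lhs < 1e-8 * np.abs(d.X.T @ d.T).max()

    def test_single_site_noisy_copy_of_reference_recovers_weight_one(self):
        # craft the abdominal trace so that the proximal reference equals it
        # up to additive noise; the single-sensor fit must approach weight 1
        biases = []
        for noise_sd in (0.2, 0.002):
            cfg = st.SyntheticConfig(seed=23, nonwear_rate_per_day=0.0,
                                     quantization_step=0.0)
            cohort = generate_cohort(cfg)
            w_a = REFERENCE_WEIGHTS[SiteGroup.PROX][SiteCode.A]
            rng = np.random.default_rng(5)
            for rec in cohort:
                rest = np.zeros(rec.n_samples())
                for site, wgt in REFERENCE_WEIGHTS[SiteGroup.PROX].items():
                    if site is not SiteCode.A:
                        rest += wgt * rec[site].values
                rec[SiteCode.A].values[:] = rest / (1 - w_a) + rng.normal(0, noise_sd, rest.size)
            d = build_design(cohort, SensorSubset.from_codes(SiteGroup.PROX, ["A"]))
            w = fit_weights(d)
            biases.append(abs(w.weight(SiteCode.A) - 1.0))
            assert biases[-1] < noise_sd
        assert biases[1] < biases[0]  # bias shrinks with the noise


class TestFitAll:
    def test_tables_have_expected_shape_and_zero_full_set_rows(self, default_cohort):
        prox = fit_all(default_cohort, SiteGroup.PROX)
        dist = fit_all(default_cohort, SiteGroup.DIST)
        assert (len(prox), len(dist)) == (31, 15)
        assert not prox.failures and not dist.failures
        top = prox.rows[-1]
        assert len(top.subset) == 5
        for metric in (top.mse, top.mae, top.cve, top.q1, top.q3):
            assert abs(metric) < 1e-9
        for site in GROUP_SITES[SiteGroup.DIST]:
            assert dist.rows[-1].weights.weight(site) == pytest.approx(0.25, abs=1e-8)

    def test_training_mse_non_increasing_on_nested_subsets(self, default_cohort):
        for group in SiteGroup:
            table = fit_all(default_cohort, group)
            by_set = {row.subset.included: row.mse for row in table.rows}
            for small, small_mse in by_set.items():
                for big, big_mse in by_set.items():
                    if small < big:
                        assert small_mse >= big_mse - 1e-12

    def test_failed_subsets_are_recorded_not_raised(self):
        cfg = st.SyntheticConfig(seed=29, nonwear_rate_per_day=0.0)
        cohort = generate_cohort(cfg)
        for rec in cohort:  # make the infra-clavicular pair exactly collinear
            rec[SiteCode.RIA].values[:] = rec[SiteCode.LIA].values
        table = fit_all(st.preprocess(cohort), SiteGroup.PROX)
        assert any("LIA" in sid and "RIA" in sid for sid in table.failures)
        assert len(table) + len(table.failures) == 31


@settings(deadline=None, max_examples=25, derandomize=True)
@given(hst.integers(min_value=0, max_value=10_000))
def test_property_lls_beats_any_perturbed_weight(seed):
    """The fitted weights minimize the sum of squares: any perturbation
    can only increase it."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(40, 3)) + 30
    y = X @ rng.uniform(0, 0.5, 3) + rng.normal(0, 0.1, 40)
    model = LinearCompositeModel().fit(X, y)
    best = np.sum((y - model.predict(X)) ** 2)
    for _ in range(5):
        w = model.coef_ + rng.normal(0, 0.05, 3)
        assert np.sum((y - X @ w) ** 2) >= best - 1e-9
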