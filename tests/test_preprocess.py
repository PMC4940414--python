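"""Normalization, imputation, REML components, BLUP shrinkage, descriptives."""

import numpy as np
import pandas as pd
import pytest

from traitnet import (
    SimulationConfig,
    annotation_frame,
    compute_blups,
    descriptive_stats,
    fit_variance_components,
    generate_panel,
    impute_missing,
    normalize_metabolites,
    normalize_panel,
    standardize_enzymes,
)
from traitnet.containers import IMPUTED, OBSERVED, ReplicateProfileTable
from traitnet.preprocess import (
    VarianceComponents,
    _balanced_oneway_reml,
    _reml_oneway,
    bin_h2,
)
from conftest import make_normalized


def _long_table(records, metabolites, enzymes):
    data = pd.DataFrame.from_records(
        records,
        columns=["line_id", "replicate_id", "plate_id", "feature_id", "value",
                 "control_value"],
    )
    return ReplicateProfileTable(data, annotation_frame(metabolites, enzymes))


class TestNormalizeMetabolites:
    def test_divides_by_control(self):
        table = _long_table(
            [("L1", "r1", None, "m1", 1000.0, 500.0),
             ("L2", "r1", None, "m1", 300.0, 100.0),
             ("L3", "r1", None, "m1", 600.0, 200.0),
             ("L4", "r1", None, "m1", 900.0, 300.0)],
            ["m1"], [],
        )
        out = normalize_metabolites(table).values["m1"]
        assert out.tolist() == [2.0, 3.0, 3.0, 3.0]

    def test_zero_control_error_names_sample(self):
        table = _long_table(
            [("L1", "r1", None, "m1", 1.0, 0.0),
             ("L2", "r1", None, "m1", 1.0, 2.0)],
            ["m1"], [],
        )
        with pytest.raises(ValueError, match="line=L1"):
            normalize_metabolites(table)

    def test_enzyme_columns_untouched(self):
        table = _long_table(
            [("L1", "r1", None, "m1", 10.0, 2.0),
             ("L1", "r1", "p1", "e1", 7.0, None)],
            ["m1"], ["e1"],
        )
        out = normalize_metabolites(table).values
        assert out.loc[("L1", "r1"), "e1"] == 7.0
        assert out.loc[("L1", "r1"), "m1"] == 5.0


class TestStandardizeEnzymes:
    def test_hand_example_two_values_single_plate(self):
        # plate mean 3 -> (2/3, 4/3); overall mean 1 -> (-1/3, +1/3)
        table = _long_table(
            [("L1", "r1", "p1", "e1", 2.0, None),
             ("L2", "r1", "p1", "e1", 4.0, None)],
            [], ["e1"],
        )
        out = standardize_enzymes(table).values["e1"]
        assert out.to_numpy() == pytest.approx([-1 / 3, 1 / 3])

    def test_constant_plate_gives_zeros(self):
        table = _long_table(
            [("L1", "r1", "p1", "e1", 5.0, None),
             ("L2", "r1", "p1", "e1", 5.0, None),
             ("L3", "r1", "p1", "e1", 5.0, None)],
            [], ["e1"],
        )
        assert standardize_enzymes(table).values["e1"].to_numpy() == pytest.approx(
            [0.0, 0.0, 0.0]
        )

    @pytest.mark.parametrize("method", ["divide", "subtract"])
    def test_per_enzyme_mean_is_zero(self, method):
        rng = np.random.default_rng(4)
        records = []
        for i in range(12):
            plate = f"p{i % 3}"
            for e in ("e1", "e2"):
                records.append((f"L{i}", "r1", plate, e, rng.uniform(1, 9), None))
        table = _long_table(records, [], ["e1", "e2"])
        out = standardize_enzymes(table, plate_method=method).values
        assert out["e1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["e2"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_plate_mean_is_error(self):
        table = _long_table(
            [("L1", "r1", "p1", "e1", -1.0, None),
             ("L2", "r1", "p1", "e1", 1.0, None)],
            [], ["e1"],
        )
        with pytest.raises(ValueError, match="plate mean is zero"):
            standardize_enzymes(table)


class TestImputation:
    def test_no_missing_identity(self):
        m = make_normalized(np.arange(24.0).reshape(6, 4), 3, 2)
        out = impute_missing(m, n_components=2)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert (out.provenance == OBSERVED).all().all()

    def test_rank_one_cell_recovered_exactly(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        v = np.array([2.0, 5.0, 7.0, 3.0])
        X = np.outer(u, v)
        removed = X[2, 1]
        X[2, 1] = np.nan
        m = make_normalized(X, 3, 2)
        out = impute_missing(m, n_components=1)
        got = out.values.iloc[2, 1]
        assert abs(got - removed) / abs(removed) < 1e-6
        assert out.provenance.iloc[2, 1] == IMPUTED

    def test_observed_cells_bitwise_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        mask = rng.random(X.shape) < 0.1
        X[mask] = np.nan
        m = make_normalized(X, 10, 2)
        out = impute_missing(m, n_components=2)
        obs = ~np.isnan(X)
        assert np.array_equal(out.values.to_numpy()[obs], X[obs])
        assert not np.isnan(out.values.to_numpy()).any()

    def test_fully_missing_column_error_names_feature(self):
        X = np.ones((6, 3))
        X[:, 1] = np.nan
        m = make_normalized(X, 3, 2)
        with pytest.raises(ValueError, match="f1"):
            impute_missing(m, n_components=1)

    def test_panel_imputation_beats_mean_imputation(self):
        """On a correlated panel, EM-PCA error < marginal-sd (mean) baseline."""
        from traitnet import CorrelationBlock

        cfg = SimulationConfig(n_lines=60, n_replicates=4, n_metabolites=12,
                               n_enzymes=0, missing_rate=0.057, h2=0.7, seed=21)
        cfg.blocks = [CorrelationBlock("A", cfg.metabolite_ids[:6], 0.9),
                      CorrelationBlock("B", cfg.metabolite_ids[6:], 0.9)]
        table, _ = generate_panel(cfg)
        complete_cfg = SimulationConfig(**{**cfg.__dict__, "missing_rate": 0.0})
        complete_table, _ = generate_panel(complete_cfg)
        norm = normalize_panel(table)
        truth_norm = normalize_panel(complete_table)
        filled = impute_missing(norm, n_components=3)
        miss = norm.values.isna().to_numpy()
        err = (filled.values.to_numpy() - truth_norm.values.to_numpy())[miss]
        rmse = np.sqrt(np.mean(err**2))
        col_means = np.nanmean(norm.values.to_numpy(), axis=0)
        baseline = (np.broadcast_to(col_means, norm.values.shape)
                    - truth_norm.values.to_numpy())[miss]
        assert rmse < np.sqrt(np.mean(baseline**2))
        assert rmse < 1.0  # below the total phenotypic sd


class TestVarianceComponents:
    def test_zero_residual_limit_h2_one(self):
        vals = np.repeat([[1.0], [2.0], [5.0]], 3, axis=0)
        m = make_normalized(vals, 3, 3)
        comps = fit_variance_components(m)
        assert comps.h2["f0"] == 1.0
        assert comps.table.loc["f0", "sigma2_e"] == 0.0

    def test_equal_line_means_h2_near_zero(self):
        rng = np.random.default_rng(1)
        n_lines, n_reps = 40, 5
        noise = rng.normal(0, 1, size=(n_lines * n_reps, 1))
        m = make_normalized(noise, n_lines, n_reps)
        comps = fit_variance_components(m)
        assert comps.h2["f0"] < 0.08

    def test_constant_feature_flagged_degenerate_not_zero(self):
        m = make_normalized(np.ones((8, 1)), 4, 2)
        comps = fit_variance_components(m)
        assert comps.table.loc["f0", "degenerate"]
        assert np.isnan(comps.h2["f0"])

    def test_balanced_closed_form_agrees_with_mixedlm_reml(self):
        """Dual route: ANOVA closed form vs statsmodels MixedLM on balanced data."""
        rng = np.random.default_rng(8)
        groups = np.repeat(np.arange(12), 4)
        g_eff = rng.normal(0, np.sqrt(2.0), 12)
        y = g_eff[groups] + rng.normal(0, 1.0, len(groups))
        s2g_a, s2e_a = _balanced_oneway_reml(y, groups)
        s2g_b, s2e_b = _reml_oneway(y, groups.astype(str))
        assert s2g_a == pytest.approx(s2g_b, rel=1e-4, abs=1e-6)
        assert s2e_a == pytest.approx(s2e_b, rel=1e-4)

    def test_h2_recovery_on_planted_panel(self):
        errors = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(n_lines=100, n_replicates=5, n_metabolites=10,
                                   n_enzymes=0, missing_rate=0.0, h2=0.5, seed=seed)
            table, truth = generate_panel(cfg)
            comps = fit_variance_components(normalize_panel(table))
            h2_true = pd.Series(truth.h2_true())
            errors.append((comps.h2 - h2_true).abs().mean())
        assert np.mean(errors) < 0.05

    def test_affine_invariance_of_h2(self):
        rng = np.random.default_rng(3)
        g = np.repeat(rng.normal(0, 1, 15), 4)
        y = g + rng.normal(0, 0.8, len(g))
        m = make_normalized(y[:, None], 15, 4)
        comps = fit_variance_components(m)
        m2 = make_normalized((3.7 * y + 11.0)[:, None], 15, 4)
        comps2 = fit_variance_components(m2)
        assert comps2.h2["f0"] == pytest.approx(comps.h2["f0"], abs=1e-8)


def _components(features, s2g, s2e):
    table = pd.DataFrame(
        {"sigma2_g": s2g, "sigma2_e": s2e, "h2": np.nan, "degenerate": False},
        index=pd.Index(features, name="feature_id"),
    )
    return VarianceComponents(table)


class TestBlups:
    def test_hand_worked_balanced_toy(self):
        # line means 10 and 14, mu=12; shrink = 1/(1 + (2/2)/1) = 0.5 -> -1, +1
        vals = np.array([[9.0], [11.0], [13.0], [15.0]])
        m = make_normalized(vals, 2, 2)
        comps = _components(["f0"], [1.0], [2.0])
        blups = compute_blups(m, comps)
        assert blups.grand_means["f0"] == pytest.approx(12.0)
        assert blups.values["f0"].to_numpy() == pytest.approx([-1.0, 1.0])

    def test_zero_residual_limit_equals_line_mean_deviation(self):
        vals = np.array([[10.0], [10.0], [14.0], [14.0]])
        m = make_normalized(vals, 2, 2)
        comps = _components(["f0"], [4.0], [0.0])
        blups = compute_blups(m, comps)
        assert blups.values["f0"].to_numpy() == pytest.approx([-2.0, 2.0])

    def test_zero_genetic_variance_gives_all_zero_blups(self):
        rng = np.random.default_rng(5)
        m = make_normalized(rng.normal(size=(12, 1)), 6, 2)
        comps = _components(["f0"], [0.0], [1.0])
        blups = compute_blups(m, comps)
        assert (blups.values["f0"] == 0.0).all()

    def test_shrinkage_never_exceeds_line_mean_deviation(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(5, 2, size=(40, 3))
        m = make_normalized(vals, 10, 4)
        comps = fit_variance_components(m)
        blups = compute_blups(m, comps)
        lines = m.line_index()
        for f in m.values.columns:
            line_means = m.values[f].groupby(lines).mean()
            dev = (line_means - line_means.mean()).abs()
            assert (blups.values[f].abs() <= dev + 1e-12).all()


class TestDescriptiveStats:
    def test_cv_hand_arithmetic(self):
        # BLUP + grand mean = (2, 4, 6): mean 4, sample sd 2 -> CV 0.5
        from traitnet.containers import BlupMatrix

        blups = BlupMatrix(
            pd.DataFrame({"f0": [-2.0, 0.0, 2.0]},
                         index=pd.Index(["L1", "L2", "L3"], name="line_id")),
            pd.Series({"f0": 4.0}),
        )
        stats = descriptive_stats(blups)
        assert stats.table.loc["f0", "cv"] == pytest.approx(0.5)
        assert stats.table.loc["f0", "variance"] == pytest.approx(4.0)

    def test_constant_feature_zero_variance_zero_cv(self):
        from traitnet.containers import BlupMatrix

        blups = BlupMatrix(
            pd.DataFrame({"f0": [0.0, 0.0, 0.0]},
                         index=pd.Index(["L1", "L2", "L3"], name="line_id")),
            pd.Series({"f0": 3.0}),
        )
        stats = descriptive_stats(blups)
        assert stats.table.loc["f0", "variance"] == 0.0
        assert stats.table.loc["f0", "cv"] == 0.0

    def test_h2_binning_oracle(self):
        h2 = pd.Series([0.05, 0.15, 0.95])
        assert bin_h2(h2).tolist() == [0, 1, 9]
        # 1.0 belongs to the closed top bin
        assert bin_h2(pd.Series([1.0])).tolist() == [9]

    def test_bin_counts_partition_features(self, small_panel):
        _, table, _ = small_panel
        norm = normalize_panel(table)
        filled = impute_missing(norm, n_components=2)
        comps = fit_variance_components(filled)
        blups = compute_blups(filled, comps)
        stats = descriptive_stats(blups, comps)
        assert stats.h2_bin_counts.sum() == comps.h2.notna().sum()
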