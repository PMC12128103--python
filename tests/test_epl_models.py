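"""Reaction recipes, descriptor aggregation, barrier models and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyroepl.epl_models import (
    PUBLISHED_EPL,
    AggregateDescriptors,
    DescriptorTable,
    EPLModel,
    RecipeWarning,
    aggregate_descriptors,
    build_recipe,
    evaluate_metrics,
    fit_epl,
    predict_barrier,
    split_dataset,
)
from pyroepl.fixtures import synthetic_regression_dataset

# the printed site/bond/pair lists of the eleven reaction channels
GOLDEN_RECIPES = {
    ("ring_opening", None): (
        (("C1", "f0"), ("O", "f-"), ("O1", "f-")),
        ("V(C1,O)",),
        ("C1-O", "O1-H_O1"),
    ),
    ("ring_contraction_FF1", None): (
        (("C1", "f0"), ("C2", "f0"), ("C3", "f0"), ("O1", "f-"), ("O2", "f-")),
        ("V(C1,O1)",),
        ("C2-C3", "C1-O1", "O2-H_O2"),
    ),
    ("ring_contraction_FF2", None): (
        (("C1", "f0"), ("C2", "f0"), ("O", "f-"), ("O1", "f-"), ("O2", "f-")),
        ("V(C1,O)", "V(C2,O2)"),
        ("C1-O", "C2-O2", "O1-H_O1"),
    ),
    ("elimination", 1): (
        (("C1", "f0"), ("C2", "f0"), ("O1", "f-")),
        ("V(C1,O1)",),
        ("C1-O1", "C2-H2"),
    ),
    ("elimination", 2): (
        (("C2", "f0"), ("C1", "f0"), ("O2", "f-")),
        ("V(C2,O2)",),
        ("C2-O2", "C1-H1"),
    ),
    ("elimination", 3): (
        (("C3", "f0"), ("C2", "f0"), ("O2", "f-")),
        ("V(C2,O2)",),
        ("C2-O2", "C3-H3"),
    ),
    ("elimination", 4): (
        (("C3", "f0"), ("C2", "f0"), ("O3", "f-")),
        ("V(C3,O3)",),
        ("C3-O3", "C2-H2"),
    ),
    ("elimination", 5): (
        (("C4", "f0"), ("C3", "f0"), ("O3", "f-")),
        ("V(C3,O3)",),
        ("C3-O3", "C4-H4"),
    ),
    ("elimination", 6): (
        (("C4", "f0"), ("C3", "f0"), ("O4", "f-")),
        ("V(C4,O4)",),
        ("C4-O4", "C4-H4"),
    ),
    ("elimination", 7): (
        (("C5", "f0"), ("C4", "f0"), ("O4", "f-")),
        ("V(C4,O4)",),
        ("C4-O4", "C5-H5"),
    ),
}


class TestBuildRecipe:
    @pytest.mark.parametrize("key", sorted(GOLDEN_RECIPES, key=str))
    def test_recipe_matches_golden_lists_token_for_token(self, key):
        cls, idx = key
        sites, bonds, pairs = GOLDEN_RECIPES[key]
        recipe = build_recipe(cls, index=idx)
        assert recipe.fukui_sites == sites
        assert recipe.bonds == bonds
        assert recipe.pairs == pairs

    @pytest.mark.parametrize("bad", [0, 8, -1])
    def test_elimination_channel_out_of_range(self, bad):
        with pytest.raises(ValueError, match="1..7"):
            build_recipe("elimination", index=bad)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown reaction class"):
            build_recipe("isomerization")

    def test_substituted_hydroxyl_relabels_proton_pair_with_warning(self):
        with pytest.warns(RecipeWarning, match="CH3COOH"):
            recipe = build_recipe("ring_contraction_FF1",
                                  substitution={2: "acetyl"})
        assert "O2-H_O2" not in recipe.pairs
        assert "O2-Cacetyl2" in recipe.pairs
        assert recipe.notes

    def test_substituted_elimination_warns_about_leaving_molecule(self):
        with pytest.warns(RecipeWarning, match="CH3COOH"):
            recipe = build_recipe("elimination", index=2,
                                  substitution={2: "acetyl"})
        # labels are unchanged: the linkage oxygen is still O2
        assert recipe.pairs == ("C2-O2", "C1-H1")
        assert recipe.notes

    def test_unrelated_substitution_leaves_recipe_unchanged(self):
        recipe = build_recipe("ring_opening", substitution={2: "acetyl"})
        assert recipe.pairs == ("C1-O", "O1-H_O1")
        assert not recipe.notes


def _toy_table():
    table = DescriptorTable()
    table.add_fukui("xylose", "C1", 0.10, 0.02, 0.03)
    table.add_fukui("xylose", "O", 0.05, 0.06, 0.05)
    table.add_fukui("xylose", "O1", 0.07, 0.09, 0.08)
    table.add_bond("xylose", "V(C1,O)", 1.25)
    table.add_pair("xylose", "C1-O", 0.80)
    table.add_pair("xylose", "O1-H_O1", 0.40)
    return table


class TestAggregation:
    def test_ring_opening_means(self):
        recipe = build_recipe("ring_opening")
        agg = aggregate_descriptors(recipe, _toy_table(), "xylose")
        # f0(C1)=0.03, f-(O)=0.06, f-(O1)=0.09 -> mean 0.06
        assert agg.f_bar == pytest.approx(0.06)
        assert agg.n_bar == pytest.approx(1.25)
        assert agg.dg_bar == pytest.approx(0.60)

    def test_two_bond_mean(self):
        table = _toy_table()
        table.add_fukui("xylose", "C2", 0.0, 0.0, 0.02)
        table.add_fukui("xylose", "O2", 0.0, 0.05, 0.0)
        table.add_bond("xylose", "V(C2,O2)", 1.45)
        table.add_pair("xylose", "C2-O2", 0.70)
        recipe = build_recipe("ring_contraction_FF2")
        agg = aggregate_descriptors(recipe, table, "xylose")
        assert agg.n_bar == pytest.approx((1.25 + 1.45) / 2)

    def test_missing_label_raises_with_its_name(self):
        recipe = build_recipe("ring_contraction_FF1")
        with pytest.raises(KeyError, match="C2"):
            aggregate_descriptors(recipe, _toy_table(), "xylose")

    def test_duplicate_keys_rejected(self):
        table = _toy_table()
        with pytest.raises(ValueError, match="duplicate"):
            table.add_fukui("xylose", "C1", 0, 0, 0)

    def test_table_round_trips_through_delimited_text(self, tmp_path):
        table = _toy_table()
        path = tmp_path / "desc.tsv"
        table.to_csv(path)
        back = DescriptorTable.from_csv(path)
        assert back.fukui == pytest.approx(table.fukui)
        assert back.bond_population == pytest.approx(table.bond_population)
        assert back.pair_index == pytest.approx(table.pair_index)


class TestPredictBarrier:
    def test_packaged_intercepts_at_zero_descriptors(self):
        zero = AggregateDescriptors(0.0, 0.0, 0.0)
        assert predict_barrier(PUBLISHED_EPL["DFT"], zero) == pytest.approx(-18.80)
        assert predict_barrier(PUBLISHED_EPL["DLPNO"], zero) == pytest.approx(7.72)

    def test_affine_hand_evaluation(self):
        agg = AggregateDescriptors(0.1, 1.3, 0.5)
        assert predict_barrier(PUBLISHED_EPL["DFT"], agg) == pytest.approx(
            42.204, abs=1e-9
        )

    @settings(deadline=None, max_examples=50)
    @given(
        f=st.floats(0.0, 0.2), n=st.floats(0.0, 2.0), g=st.floats(0.0, 1.5),
        t=st.floats(0.0, 1.0),
    )
    def test_prediction_interpolates_linearly_toward_zero(self, f, n, g, t):
        model = PUBLISHED_EPL["G4"]
        full = predict_barrier(model, AggregateDescriptors(f, n, g))
        part = predict_barrier(model, AggregateDescriptors(t * f, t * n, t * g))
        expected = model.c_0 + t * (full - model.c_0)
        assert part == pytest.approx(expected, abs=1e-9)


class TestMetrics:
    def test_worked_residuals(self):
        # p = 1 keeps n > p + 1 for the three-residual worked example
        mae, rmse, _ = evaluate_metrics([1.0, -1.0, 3.0], [0.0, 0.0, 0.0], p=1)
        assert mae == pytest.approx(5 / 3, abs=1e-4)
        assert rmse == pytest.approx(np.sqrt(11 / 3), abs=1e-4)

    def test_perfect_predictions(self):
        mae, rmse, r2a = evaluate_metrics([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert mae == 0.0 and rmse == 0.0 and r2a == 1.0

    def test_adjusted_r2_formula(self):
        # engineered so R^2 = 0.9 at n=10: then R2_adj = 1 - 0.1*9/6 = 0.85
        rng = np.random.default_rng(0)
        ref = np.arange(10.0)
        ss_tot = np.sum((ref - ref.mean()) ** 2)
        resid = np.sqrt(0.1 * ss_tot / 10)  # each residual equal
        pred = ref + resid
        mae, rmse, r2a = evaluate_metrics(pred, ref, p=3)
        assert r2a == pytest.approx(1 - (1 - 0.9) * 9 / 6, abs=1e-12)

    def test_too_few_points_for_adjusted_r2(self):
        with pytest.raises(ValueError, match="n > p"):
            evaluate_metrics([1, 2, 3], [1, 2, 3], p=3)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=40))
    def test_mae_never_exceeds_rmse(self, residuals):
        pred = np.asarray(residuals)
        ref = np.zeros_like(pred)
        mae, rmse, _ = evaluate_metrics(pred, ref)
        assert mae <= rmse + 1e-12


class TestFitEpl:
    def test_noiseless_rows_recover_exact_coefficients(self):
        truth = PUBLISHED_EPL["CBS"]
        rows = synthetic_regression_dataset(truth, n=40, noise_sigma=0.0, seed=3)
        report = fit_epl(rows)
        got = report.model.coefficients()
        assert np.allclose(got, truth.coefficients(), atol=1e-8)
        assert report.rmse < 1e-8

    def test_underdetermined_fit_rejected(self):
        rows = synthetic_regression_dataset(PUBLISHED_EPL["DFT"], n=3, seed=0)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_epl(rows)

    def test_collinear_descriptors_rejected(self):
        rows = [
            (AggregateDescriptors(f, 2 * f, 0.5), 1.0 + f) for f in
            np.linspace(0.02, 0.12, 8)
        ]
        with pytest.raises(ValueError, match="collinear"):
            fit_epl(rows)

    def test_coefficient_coverage_under_noise(self):
        # 100 seeded replicates at sigma = 1 kcal/mol, n = 200: each
        # coefficient should land within 3 standard errors of the truth in
        # at least 95% of replicates (3 SE ~ 99.7% nominal coverage)
        truth = PUBLISHED_EPL["DFT"]
        hits = np.zeros(4)
        n_rep = 100
        for rep in range(n_rep):
            rows = synthetic_regression_dataset(
                truth, n=200, noise_sigma=1.0, seed=1000 + rep
            )
            report = fit_epl(rows)
            err = np.abs(report.model.coefficients() - truth.coefficients())
            hits += err <= 3.0 * np.asarray(report.std_errors)
        assert np.all(hits / n_rep >= 0.95)

    def test_validation_metrics_reported(self):
        truth = PUBLISHED_EPL["G4"]
        rows = synthetic_regression_dataset(truth, n=50, noise_sigma=0.5, seed=9)
        report = fit_epl(rows[:40], validation=rows[40:])
        assert report.validation_mae is not None
        assert report.validation_mae <= report.validation_rmse


class TestSplitDataset:
    def test_sizes_and_determinism(self):
        train, val = split_dataset(100, fraction=0.8, seed=42)
        assert len(train) == 80 and len(val) == 20
        assert split_dataset(100, fraction=0.8, seed=42) == (train, val)
        assert not set(train) & set(val)

    def test_different_seed_changes_split(self):
        assert split_dataset(100, seed=1) != split_dataset(100, seed=2)

    def test_stratified_split_preserves_class_shares(self):
        labels = ["a"] * 50 + ["b"] * 30 + ["c"] * 20
        train, val = split_dataset(100, fraction=0.8, seed=7, labels=labels)
        counts = {c: sum(1 for i in train if labels[i] == c) for c in "abc"}
        assert abs(counts["a"] - 40) <= 1
        assert abs(counts["b"] - 24) <= 1
        assert abs(counts["c"] - 16) <= 1

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_dataset(3, labels=["a", "a", "b"])

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            split_dataset(10, fraction=1.5)
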