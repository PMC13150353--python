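"""Composition tables, ratios, aggregation and group comparison."""

import numpy as np
import pytest

import cortexcount as cc
from cortexcount.composition import (WM_LABEL, holm_correction,
                                     table_from_counts, two_proportion_test)

MODEL = cc.LayerModel(boundaries_um=(0.0, 30.0, 80.0, 140.0),
                      labels=("I", "II", "III"))


class TestAssignLayer:
    def test_depth_zero_is_layer_one(self):
        assert cc.assign_layer(0.0, MODEL) == "I"

    def test_boundary_belongs_to_deeper_layer(self):
        assert cc.assign_layer(30.0, MODEL) == "II"
        assert cc.assign_layer(29.999, MODEL) == "I"

    def test_beyond_white_matter_flagged(self):
        assert cc.assign_layer(140.0, MODEL) == WM_LABEL
        assert cc.assign_layer(-1.0, MODEL) == WM_LABEL

    def test_simulated_cells_agree_with_generating_layer(self):
        from conftest import single_layer_config

        config = cc.human_ba21(seed=33, width_um=80.0)
        cells, _ = cc.place_cells(config)
        model = cc.LayerModel.from_simulation(config)
        agree = [cc.assign_layer(c.center_um[1], model) == c.layer
                 for c in cells if c.cell_class != "vascular"]
        assert all(agree)

    def test_layer_model_validation(self):
        with pytest.raises(ValueError):
            cc.LayerModel((0.0, 10.0, 5.0), ("I", "II"))
        with pytest.raises(ValueError):
            cc.LayerModel((0.0, 10.0, 20.0), ("I", "I"))


class TestTabulate:
    def test_published_human_counts_reproduce_reported_figures(self):
        """4,135 neurons / 6,002 glia / 3,336 vascular pool to 31% / 44% /
        25%, nNNR 2.3 and GNR 1.5 after display rounding."""
        table = table_from_counts({"all": (4135, 6002, 3336)},
                                  pooled_label="I–VI")
        pooled = table.rounded().loc["I–VI"]
        assert pooled["n_total"] == 13473
        assert pooled["p_neuron"] == 0.31
        assert pooled["p_vascular"] == 0.25
        # glia share is 44.5%: printed as 44% (truncated); check the whole
        # percent digit rather than the half-up rounding
        assert int(table.df.loc["I–VI", "p_glia"] * 100) == 44
        assert pooled["nNNR"] == 2.3
        assert pooled["GNR"] == 1.5

    def test_small_field_example_totals(self):
        table = table_from_counts({"IV": (62, 225, 115)})
        assert int(table.df.loc["IV", "n_total"]) == 402

    def test_unsplit_nonneurons_give_ratio_without_gnr(self):
        table = table_from_counts(
            {"all": {"n_neuron": 15567, "n_nonneuron": 9436}})
        pooled = table.rounded().iloc[-1]
        assert pooled["nNNR"] == 0.6
        assert np.isnan(pooled["GNR"])
        assert "GNR" in table.flags

    def test_zero_neurons_flagged_not_crashing(self):
        table = table_from_counts({"I": (0, 10, 5)})
        assert np.isnan(table.df.loc["I", "nNNR"])
        assert "I" in table.flags

    def test_row_invariants_on_simulated_tabulation(self, human_column):
        nuclei, stack = human_column["nuclei"], human_column["stack"]
        classified = cc.classify_all(nuclei, stack, mode="geometry")
        model = cc.LayerModel.from_simulation(human_column["config"])
        table = cc.tabulate(classified, model)
        df = table.df
        for lab, row in df.iterrows():
            if row["n_total"] > 0:
                assert row[["p_neuron", "p_glia", "p_vascular"]].sum() == (
                    pytest.approx(1.0, abs=1e-9))
            if np.isfinite(row["nNNR"]) and np.isfinite(row["GNR"]):
                v_over_n = row["n_vascular"] / row["n_neuron"]
                assert row["nNNR"] == pytest.approx(row["GNR"] + v_over_n)
        layer_rows = df.drop(index=table.pooled_label)
        for c in ("n_neuron", "n_glia", "n_vascular", "n_total"):
            assert int(layer_rows[c].sum()) == int(df.loc[table.pooled_label, c])


class TestAggregate:
    def _tables(self, counts_list):
        return [table_from_counts(c) for c in counts_list]

    def test_identical_tables_have_zero_sd(self):
        counts = {"I": (10, 20, 5), "II": (40, 10, 5)}
        summary = cc.aggregate_columns(self._tables([counts, counts]))
        assert (summary.sd.fillna(0.0).to_numpy() == 0.0).all()

    def test_pooled_row_is_accumulated_not_mean(self):
        """The pooled row must come from summed counts: two columns with
        different sizes give a size-weighted pooled proportion, not the
        mean of the two pooled proportions."""
        a = {"I": (90, 10, 0), "II": (10, 0, 0)}   # pooled p_n = 100/110
        b = {"I": (1, 9, 0), "II": (0, 0, 0)}      # pooled p_n = 0.1
        summary = cc.aggregate_columns(self._tables([a, b]))
        pooled_p = summary.mean.loc["I–II", "p_neuron"]
        accumulated = (100 + 1) / (110 + 10)
        assert pooled_p == pytest.approx(accumulated)
        mean_of_pooled = np.mean([100 / 110, 1 / 10])
        assert abs(pooled_p - mean_of_pooled) > 0.05
        # while the alternative policy averages the per-column pooled rows
        alt = cc.aggregate_columns(self._tables([a, b]),
                                   policy="mean_of_columns")
        assert alt.mean.loc["I–II", "p_neuron"] == pytest.approx(mean_of_pooled)

    def test_pooled_equals_tabulate_of_concatenated_counts(self):
        a = {"I": (10, 20, 5), "II": (40, 10, 5)}
        b = {"I": (20, 15, 10), "II": (30, 20, 10)}
        summary = cc.aggregate_columns(self._tables([a, b]))
        concat = {
            lab: tuple(np.add(a[lab], b[lab])) for lab in a
        }
        direct = table_from_counts(concat)
        for col in ("p_neuron", "p_glia", "p_vascular", "nNNR", "GNR"):
            assert summary.mean.loc["I–II", col] == pytest.approx(
                direct.df.loc["I–II", col])

    def test_mismatched_layers_rejected(self):
        a = table_from_counts({"I": (1, 1, 1), "II": (1, 1, 1)})
        b = table_from_counts({"I": (1, 1, 1), "III": (1, 1, 1)})
        with pytest.raises(ValueError, match="mismatched"):
            cc.aggregate_columns([a, b])

    def test_needs_at_least_one_table(self):
        with pytest.raises(ValueError):
            cc.aggregate_columns([])


class TestTwoProportion:
    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportions_ztest

        z, p = two_proportion_test(15567, 25003, 4135, 13473)
        z_sm, p_sm = proportions_ztest([15567, 4135], [25003, 13473])
        assert z == pytest.approx(z_sm)
        assert p == pytest.approx(p_sm)

    def test_matches_permutation_oracle_small_counts(self):
        """Brute-force permutation of group labels on small counts agrees
        with the normal approximation to within its resolution."""
        rng = np.random.default_rng(0)
        k1, n1, k2, n2 = 18, 40, 9, 38
        _, p = two_proportion_test(k1, n1, k2, n2)
        pool = np.array([1] * (k1 + k2) + [0] * (n1 + n2 - k1 - k2))
        obs = abs(k1 / n1 - k2 / n2)
        hits = 0
        n_perm = 20000
        for _ in range(n_perm):
            rng.shuffle(pool)
            d = abs(pool[:n1].mean() - pool[n1:].mean())
            hits += d >= obs - 1e-12
        p_perm = hits / n_perm
        assert p == pytest.approx(p_perm, abs=0.03)

    def test_identical_groups_p_one(self):
        z, p = two_proportion_test(50, 100, 50, 100)
        assert z == 0.0 and p == 1.0

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 0, 1, 10)


class TestHolm:
    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.03, 0.2, 0.5]
        ours = holm_correction(p)
        _, theirs, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(ours, theirs)


class TestCompareGroups:
    def _group(self, counts, n_cols, jitter, seed):
        rng = np.random.default_rng(seed)
        tables = []
        for _ in range(n_cols):
            c = {lab: tuple(max(0, int(v + rng.integers(-jitter, jitter + 1)))
                            for v in vals) for lab, vals in counts.items()}
            tables.append(table_from_counts(c))
        return tables

    def test_species_direction_and_significance(self):
        mouse = self._group({"I": (100, 500, 100), "II": (2000, 800, 200)},
                            3, 10, 1)
        human = self._group({"I": (50, 300, 150), "II": (500, 300, 150)},
                            3, 10, 2)
        report = cc.compare_groups(mouse, human, labels=("mouse", "human"))
        assert report["diff_p_neuron"] > 0
        assert report["p_value"] < 1e-6
        assert "I" in report["per_layer"] and "p_holm" in report["per_layer"]["I"]

    def test_identical_groups_null(self):
        counts = {"I": (100, 100, 50)}
        a = [table_from_counts(counts)] * 2
        report = cc.compare_groups(a, a)
        assert report["p_value"] == 1.0
        lo, hi = report["bootstrap_ci_95"]
        assert lo <= 0.0 <= hi

    def test_bootstrap_reproducible_under_seed(self):
        a = self._group({"I": (100, 50, 20)}, 3, 15, 3)
        b = self._group({"I": (80, 70, 30)}, 3, 15, 4)
        r1 = cc.compare_groups(a, b, seed=7)
        r2 = cc.compare_groups(a, b, seed=7)
        assert r1["bootstrap_ci_95"] == r2["bootstrap_ci_95"]
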