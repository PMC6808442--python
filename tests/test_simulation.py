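import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyweb import (
    HerbivoreOccurrence,
    PlotDataset,
    TreeRecord,
    build_matrix,
    compare_schemes,
    compute_f_thresh,
    family_scheme,
    network_summary,
    plot_baseline_metrics,
    pool_plots,
    prune_dataset,
    rarefy_species,
    round_half_up,
    select_family_species,
    select_threshold_species,
    simulate_scheme,
    summarize_ci,
    threshold_scheme,
)
from canopyweb.metrics import METRIC_NAMES
from canopyweb.simulation import RarefactionDraw, SelectionScheme, assemble_matrix


def dataset_from_shares(shares, plot_foliage=100.0):
    """One plot; one tree per species with foliage = share × plot_foliage."""
    trees = [
        TreeRecord(f"T{i}", "P1", f"sp{i}", "F", share * plot_foliage)
        for i, share in enumerate(shares)
    ]
    occ = [HerbivoreOccurrence(f"T{i}", "M1", 1) for i in range(len(shares))]
    return PlotDataset.from_records(trees, occ)


class TestPoolingAndSelection:
    def test_mean_plot_foliage(self):
        trees = [
            TreeRecord("T1", "P1", "a", "F", 100.0),
            TreeRecord("T2", "P2", "b", "F", 300.0),
        ]
        occ = [HerbivoreOccurrence("T1", "M1", 1)]
        pooled = pool_plots(PlotDataset.from_records(trees, occ))
        assert pooled.mean_plot_foliage == 200.0
        assert pooled.data.trees["foliage_m2"].sum() == 400.0

    def test_single_plot_pooling_is_identity(self, toy_dataset):
        sub = toy_dataset.subset_plots(["P1"])
        pooled = pool_plots(sub)
        assert pooled.mean_plot_foliage == sub.foliage_per_plot().iloc[0]

    def test_pooled_stems_sum(self, small_forest):
        pooled = pool_plots(small_forest)
        assert len(pooled.data.trees) == small_forest.stems_per_plot().sum()

    @pytest.mark.parametrize("q,expected", [(0.2, 1), (0.5, 1), (0.8, 2), (1.0, 3)])
    def test_threshold_prefix_rule(self, q, expected):
        pooled = pool_plots(dataset_from_shares([0.5, 0.3, 0.2]))
        assert len(select_threshold_species(pooled, q)) == expected

    def test_threshold_monotone_in_q(self, small_pooled):
        sizes = [len(select_threshold_species(small_pooled, q)) for q in
                 (0.1, 0.2, 0.4, 0.6, 0.8, 1.0)]
        assert sizes == sorted(sizes)

    def test_family_rule(self):
        trees = [
            TreeRecord("T1", "P1", "a1", "FamA", 150.0),
            TreeRecord("T2", "P1", "a2", "FamA", 100.0),
            TreeRecord("T3", "P1", "b1", "FamB", 150.0),
        ]
        occ = [HerbivoreOccurrence("T1", "M1", 1)]
        pooled = pool_plots(PlotDataset.from_records(trees, occ))
        # FamA reaches 250 >= 200, FamB (150) does not; top FamA species is a1
        assert select_family_species(pooled, 200.0) == ["a1"]
        with pytest.raises(ValueError):
            select_family_species(pooled, 500.0)

    def test_every_species_own_family(self):
        trees = [
            TreeRecord(f"T{i}", "P1", f"sp{i}", f"Fam{i}", 250.0) for i in range(4)
        ]
        occ = [HerbivoreOccurrence("T0", "M1", 1)]
        pooled = pool_plots(PlotDataset.from_records(trees, occ))
        assert select_family_species(pooled, 200.0) == [f"sp{i}" for i in range(4)]

    def test_f_thresh_arithmetic(self):
        pooled = pool_plots(dataset_from_shares([1.0], plot_foliage=3500.0))
        assert compute_f_thresh(pooled, 7) == 500.0
        assert compute_f_thresh(pooled, 1) == 3500.0
        with pytest.raises(ValueError):
            compute_f_thresh(pooled, 0)


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "x,expected", [(2.4, 2), (2.5, 3), (2.6, 3), (0.5, 1), (0.49, 0), (3.0, 3)]
    )
    def test_ties_go_up(self, x, expected):
        assert round_half_up(x) == expected

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_within_half_of_input(self, x):
        r = round_half_up(x)
        assert abs(r - x) <= 0.5
        if abs(x - round(x)) == 0.5:
            assert r >= x  # tie goes up


class TestSummarizeCIProperties:
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
                    min_size=2, max_size=50),
           st.sampled_from(["percentile", "t"]))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_bounds_bracket_mean(self, values, method):
        mean, lo, hi = summarize_ci(values, method)
        assert lo - 1e-9 <= mean <= hi + 1e-9


def one_tree_species(c_f=4, foliage=10.0):
    trees = [TreeRecord("T1", "P1", "sp", "F", foliage)]
    occ = [HerbivoreOccurrence("T1", f"M{k}", 1) for k in range(c_f)]
    return pool_plots(PlotDataset.from_records(trees, occ))


class TestRarefySpecies:
    def test_half_tree_keeps_half_caterpillars(self):
        pooled = one_tree_species(c_f=4, foliage=10.0)
        draw = rarefy_species(pooled, "sp", 5.0, np.random.default_rng(0))
        assert draw.partial_tree == "T1"
        assert draw.fraction == pytest.approx(0.5)
        assert draw.included_foliage == pytest.approx(5.0)
        assert draw.occurrences["count"].sum() == 2

    def test_quota_above_total_takes_everything(self):
        pooled = one_tree_species(c_f=4, foliage=10.0)
        draw = rarefy_species(pooled, "sp", 50.0, np.random.default_rng(0))
        assert draw.partial_tree is None
        assert draw.fraction == 1.0
        assert draw.shortfall
        assert draw.occurrences["count"].sum() == 4

    def test_exact_landing_takes_whole_tree(self):
        pooled = one_tree_species(c_f=4, foliage=10.0)
        draw = rarefy_species(pooled, "sp", 10.0, np.random.default_rng(0))
        assert draw.partial_tree is None
        assert draw.occurrences["count"].sum() == 4

    def test_fractional_count_rounds_half_up_and_subsample_is_uniform(self):
        # f = 0.5 of C_f = 5 -> always round_half_up(2.5) = 3 kept; each of
        # the 5 individuals equally often (hypergeometric uniformity)
        pooled = one_tree_species(c_f=5, foliage=10.0)
        seen = {f"M{k}": 0 for k in range(5)}
        n = 2000
        for s in range(n):
            draw = rarefy_species(pooled, "sp", 5.0, np.random.default_rng(s))
            assert draw.occurrences["count"].sum() == 3
            for m in draw.occurrences["morphospecies_id"]:
                seen[m] += 1
        for m, cnt in seen.items():
            # expect 3/5 inclusion; ±4 sigma of Binomial(n, .6)
            assert abs(cnt / n - 0.6) < 4 * np.sqrt(0.6 * 0.4 / n), m

    def test_foliage_conservation_property(self, small_pooled):
        species = small_pooled.species_foliage()
        rng_master = np.random.default_rng(99)
        for s in range(200):
            sp = species.index[int(rng_master.integers(len(species)))]
            f_thresh = float(rng_master.uniform(0.1, 1.5) * species[sp])
            draw = rarefy_species(small_pooled, sp, f_thresh, np.random.default_rng(s))
            target = min(f_thresh, species[sp])
            assert draw.included_foliage == pytest.approx(target, rel=1e-9)


class TestSimulateScheme:
    def test_same_seed_same_result(self, small_pooled):
        scheme = threshold_scheme(small_pooled, 0.4)
        a = simulate_scheme(small_pooled, scheme, n_reps=5, base_seed=7)
        b = simulate_scheme(small_pooled, scheme, n_reps=5, base_seed=7)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_seed_layout_prefix_stable(self, small_pooled):
        scheme = threshold_scheme(small_pooled, 0.4)
        short = simulate_scheme(small_pooled, scheme, n_reps=4, base_seed=3)
        long = simulate_scheme(small_pooled, scheme, n_reps=8, base_seed=3)
        pd.testing.assert_frame_equal(short.replicates, long.replicates.iloc[:4])

    def test_identity_limit_reproduces_pooled_network(self, small_pooled):
        species = sorted(small_pooled.data.trees["species"].unique())
        cap = float(small_pooled.species_foliage().max()) + 1.0
        scheme = SelectionScheme(
            kind="abundance_threshold", name="all", selected_species=species, f_thresh=cap
        )
        result = simulate_scheme(small_pooled, scheme, n_reps=3, base_seed=0)
        expected = network_summary(build_matrix(small_pooled.data)).as_dict()
        for metric in METRIC_NAMES:
            np.testing.assert_allclose(
                result.replicates[metric], expected[metric], rtol=1e-12, equal_nan=True
            )
            row = result.summary.set_index("metric").loc[metric]
            assert row["ci_lo"] == pytest.approx(row["ci_hi"])  # zero width

    def test_mean_richness_matches_independent_loop(self, small_pooled):
        # straight-line re-implementation of the replicate loop
        scheme = threshold_scheme(small_pooled, 0.4)
        result = simulate_scheme(small_pooled, scheme, n_reps=6, base_seed=11)
        richness = []
        for r in range(6):
            rng = np.random.default_rng(11 + r)
            kept = []
            for sp in sorted(scheme.selected_species):
                part = rarefy_species(small_pooled, sp, scheme.f_thresh, rng)
                kept.append(part.occurrences)
            occ = pd.concat(kept, ignore_index=True)
            richness.append(occ.loc[occ["count"] > 0, "morphospecies_id"].nunique())
        assert result.replicates["herbivore_richness"].tolist() == richness

    def test_subsampled_total_never_exceeds_pool(self, small_pooled):
        scheme = threshold_scheme(small_pooled, 0.2)
        total = small_pooled.data.total_occurrence_count()
        for r in range(5):
            rng = np.random.default_rng(r)
            draw = RarefactionDraw(seed=r)
            for sp in sorted(scheme.selected_species):
                draw.parts.append(rarefy_species(small_pooled, sp, scheme.f_thresh, rng))
            assert draw.total_herbivores() <= total


class TestBaselineAndComparison:
    def test_per_plot_composition(self, small_forest):
        d = prune_dataset(small_forest)
        result = plot_baseline_metrics(d)
        assert len(result.replicates) == d.n_plots
        for i, plot in enumerate(d.plot_ids):
            expected = network_summary(build_matrix(d, plots=[plot]))
            assert result.replicates["connectance"].iloc[i] == pytest.approx(
                expected.connectance
            )

    def test_two_plot_mean_is_midpoint(self, toy_dataset):
        result = plot_baseline_metrics(toy_dataset)
        conn = result.replicates["connectance"]
        row = result.summary.set_index("metric").loc["connectance"]
        assert row["mean"] == pytest.approx((conn.iloc[0] + conn.iloc[1]) / 2)

    def test_comparison_table_shape_and_flags(self, small_pooled, small_forest):
        d = prune_dataset(small_forest)
        baseline = plot_baseline_metrics(d)
        sim = simulate_scheme(small_pooled, threshold_scheme(small_pooled, 0.2),
                              n_reps=5, base_seed=0)
        table = compare_schemes([baseline, sim])
        assert len(table) == 2 * len(METRIC_NAMES)
        # a result compared against itself always overlaps
        self_table = compare_schemes([baseline], baseline="plots")
        assert not self_table["nonoverlap_vs_baseline"].any()


class TestSummarizeCI:
    def test_constant_vector_zero_width(self):
        mean, lo, hi = summarize_ci([2.0, 2.0, 2.0], "percentile")
        assert mean == lo == hi == 2.0

    def test_t_interval_symmetric(self):
        mean, lo, hi = summarize_ci([0.0, 1.0], "t")
        assert mean == pytest.approx(0.5)
        assert hi - mean == pytest.approx(mean - lo)

    def test_percentile_bounds_near_normal_quantiles(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(2000)
        mean, lo, hi = summarize_ci(v, "percentile")
        assert lo == pytest.approx(-1.96, abs=0.15)
        assert hi == pytest.approx(1.96, abs=0.15)

    def test_too_few_values_flagged(self):
        mean, lo, hi = summarize_ci([1.0], "percentile")
        assert mean == 1.0 and np.isnan(lo) and np.isnan(hi)

    def test_nans_excluded(self):
        mean, _, _ = summarize_ci([1.0, np.nan, 3.0], "percentile")
        assert mean == 2.0
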