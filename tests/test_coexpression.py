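"""Responsive calls, differential tests, and correlation K-means."""

import numpy as np
import pandas as pd
import pytest

from consortium_coupling.core_model import (
    Axis,
    ExpressionMatrix,
    SteadyStateCondition,
    validate_design,
)
from consortium_coupling.coexpression import (
    CoexpressionError,
    _lloyd,
    _standardize_rows,
    call_responsive,
    count_responsive,
    cross_species_summary,
    kmeans_correlation,
    label_patterns,
    pattern_templates,
    test_differential as differential_test,
)
from consortium_coupling import normalization as nz
from consortium_coupling.synthetic_data import make_genomes, simulate_expression


def _axis(name="irradiance", values=(197.0, 1190.0, 1995.0), fixed=0.0):
    conds = tuple(
        SteadyStateCondition(f"C{i}", v if name == "irradiance" else 1995.0,
                             0.0 if name == "irradiance" else v, 2)
        for i, v in enumerate(values)
    )
    return Axis(name=name, conditions=conds, fixed_value=fixed)


AXIS = _axis()


def _means(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows, index=list(AXIS.labels)).T


class TestCallResponsive:
    def test_fold_uses_pseudocount(self):
        calls = call_responsive(_means({"g": [10.0, 17.0, 25.0]}), AXIS)
        # (25 + 0.5) / (10 + 0.5) = 2.4286, responsive up
        assert calls.loc["g", "fold_change"] == pytest.approx(25.5 / 10.5)
        assert calls.loc["g", "responsive"]
        assert calls.loc["g", "direction"] == "up"

    def test_below_threshold_not_called(self):
        calls = call_responsive(_means({"g": [10.0, 15.0, 19.9]}), AXIS)
        assert not calls.loc["g", "responsive"]
        assert calls.loc["g", "direction"] == "none"

    def test_downward_response_symmetric(self):
        calls = call_responsive(_means({"g": [20.0, 15.0, 9.5]}), AXIS)
        assert calls.loc["g", "responsive"]
        assert calls.loc["g", "direction"] == "down"

    def test_interior_conditions_ignored(self):
        calls = call_responsive(_means({"g": [10.0, 500.0, 11.0]}), AXIS)
        assert not calls.loc["g", "responsive"]

    def test_swapping_extremes_flips_direction_only(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(1, 100, size=(30, 3))
        df = pd.DataFrame(values, columns=list(AXIS.labels),
                          index=[f"g{i}" for i in range(30)])
        fwd = call_responsive(df, AXIS)
        rev = call_responsive(df.iloc[:, ::-1].set_axis(list(AXIS.labels), axis=1), AXIS)
        assert (fwd["responsive"] == rev["responsive"]).all()
        swapped = fwd["direction"].map({"up": "down", "down": "up", "none": "none"})
        assert (rev["direction"] == swapped).all()

    def test_count_empty_and_flat(self, toy_gene_table):
        flat = _means({"cyA": [10.0, 10.0, 10.0], "cyB": [3.0, 3.0, 3.0]})
        calls = call_responsive(flat, AXIS)
        assert count_responsive(calls) == 0
        assert count_responsive(calls, toy_gene_table, species="cyanobacterium") == 0


class TestDifferential:
    @pytest.fixture
    def design(self, toy_design):
        return toy_design

    def test_identical_conditions_nothing_significant(self, design):
        rng = np.random.default_rng(0)
        values = rng.uniform(10, 100, size=(50, 1))
        df = pd.DataFrame(
            np.tile(values, (1, 10)),
            index=[f"g{i}" for i in range(50)],
            columns=list(design.samples),
        )
        res = differential_test(ExpressionMatrix(df), design, "LL-LO", "HL-LO")
        assert np.allclose(res["log2_fold_change"], 0.0)
        assert (res["p_value"] == 1.0).all()
        assert not res["significant"].any()

    def test_planted_fold_changes_detected(self, small_truth, binary_design):
        genes = make_genomes(small_truth, 1)
        counts, truth = simulate_expression(genes, binary_design, small_truth, 1)
        factors = nz.size_factors(counts)
        expr = nz.per_kb_expression(counts, factors, genes)
        res = differential_test(expr, binary_design, "LL-LO", "HL-LO")
        planted = truth.index[
            (truth["shape_irradiance"] == "increasing")
            & (truth["species"] == "cyanobacterium")
        ]
        flat = truth.index[
            (truth["shape_irradiance"] == "flat") & (truth["shape_pO2"] == "flat")
        ]
        # 4-fold planted genes overwhelmingly significant, flat genes not
        assert res.loc[planted, "significant"].mean() >= 0.9
        assert res.loc[flat, "significant"].mean() <= 0.01

    def test_single_replicate_rejected(self, design):
        df = pd.DataFrame(
            np.ones((3, 10)), index=list("abc"), columns=list(design.samples)
        )
        with pytest.raises(CoexpressionError, match="replicates"):
            differential_test(ExpressionMatrix(df.iloc[:, :4]), design, "LL-LO", "nope")

    def test_bh_adjustment_monotone_in_rank(self, design):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.uniform(5, 500, size=(80, 10)),
            index=[f"g{i}" for i in range(80)],
            columns=list(design.samples),
        )
        res = differential_test(ExpressionMatrix(df), design, "LL-LO", "HL-HO")
        ordered = res.sort_values("p_value")
        assert (np.diff(ordered["adjusted_p"].to_numpy()) >= -1e-12).all()
        assert (res["adjusted_p"] >= res["p_value"] - 1e-12).all()


def _template_profiles(n_per_shape=10, noise=0.0, seed=0, length=3):
    rng = np.random.default_rng(seed)
    templates = pattern_templates(length)
    rows, ids, shapes = [], [], []
    for name, vec in templates.items():
        for i in range(n_per_shape):
            rows.append(vec * rng.uniform(0.5, 2.0) + rng.normal(0, noise, length))
            ids.append(f"{name}_{i}")
            shapes.append(name)
    return pd.DataFrame(rows, index=ids), pd.Series(shapes, index=ids)


class TestKmeansCorrelation:
    def test_separable_templates_recovered_perfectly(self):
        profiles, shapes = _template_profiles(10)
        result = kmeans_correlation(profiles, k=4, seed=0, n_init=10)
        sizes = result.assignments.groupby(result.assignments).size()
        assert sorted(sizes) == [10, 10, 10, 10]
        labels = result.assignments.map(result.pattern_labels)
        assert (labels == shapes).all()
        # centroids correlate perfectly with their templates
        templates = pattern_templates(3)
        for c, name in result.pattern_labels.items():
            r = float(result.centroids[c] @ templates[name]) / 3
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_scale_and_shift_invariance(self):
        profiles, _ = _template_profiles(8, noise=0.15, seed=3)
        base = kmeans_correlation(profiles, k=4, seed=1, n_init=10)
        transformed = profiles.copy()
        transformed.iloc[::2] = transformed.iloc[::2] * 10.0
        transformed.iloc[1::2] = transformed.iloc[1::2] + 5.0
        moved = kmeans_correlation(transformed, k=4, seed=1, n_init=10)
        assert (base.assignments == moved.assignments).all()

    def test_deterministic_under_fixed_seed(self):
        profiles, _ = _template_profiles(6, noise=0.3, seed=4)
        a = kmeans_correlation(profiles, k=4, seed=9, n_init=5)
        b = kmeans_correlation(profiles, k=4, seed=9, n_init=5)
        assert (a.assignments == b.assignments).all()
        assert np.array_equal(a.centroids, b.centroids)
        assert a.objective == b.objective

    def test_objective_non_increasing_and_fixpoint(self):
        profiles, _ = _template_profiles(10, noise=0.5, seed=5, length=5)
        X = _standardize_rows(profiles.to_numpy(), profiles.index)
        rng = np.random.default_rng(0)
        for _ in range(5):
            idx = rng.choice(len(X), size=4, replace=False)
            assign, centroids, history = _lloyd(X, X[idx].copy())
            assert (np.diff(history) <= 1e-9).all()
            # final assignment is a fixpoint
            assign2, _, _ = _lloyd(X, centroids, max_iter=1)
            assert (assign2 == assign).all()

    def test_fewer_distinct_profiles_than_k(self):
        df = pd.DataFrame([[1, 2, 3]] * 6, index=[f"g{i}" for i in range(6)], dtype=float)
        with pytest.raises(CoexpressionError, match="distinct"):
            kmeans_correlation(df, k=4, seed=0, n_init=2)

    def test_constant_profile_rejected(self):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1, 2, 3], [3, 2, 1], [1, 3, 1]],
            index=list("abcd"),
        )
        with pytest.raises(CoexpressionError, match="constant"):
            kmeans_correlation(df, k=2, seed=0)


class TestLabelPatterns:
    def test_archetype_centroids_labeled(self):
        centroids = np.array(
            [
                [-1.0, 2.0, -1.0],  # tent
                [3.0, 2.0, 1.0],  # decreasing
                [0.0, 5.0, 10.0],  # increasing
                [2.0, -1.0, 2.0],  # inverse tent
            ]
        )
        labels = label_patterns(centroids)
        assert labels == {0: "tent", 1: "decreasing", 2: "increasing", 3: "inverse-tent"}

    def test_permutation_consistency(self):
        rng = np.random.default_rng(2)
        centroids = np.array(
            [[-1.0, 2.0, -1.0], [3.0, 2.0, 1.0], [0.0, 5.0, 10.0], [2.0, -1.0, 2.0]]
        )
        labels = label_patterns(centroids)
        perm = rng.permutation(4)
        permuted = label_patterns(centroids[perm])
        assert [permuted[i] for i in range(4)] == [labels[p] for p in perm]

    def test_labels_unique(self):
        rng = np.random.default_rng(11)
        centroids = rng.normal(size=(4, 3))
        labels = label_patterns(centroids)
        assert len(set(labels.values())) == 4


class TestCrossSpeciesSummary:
    def test_toy_counts_sum_to_input(self, toy_gene_table):
        df = pd.DataFrame(
            [[1, 2, 4], [4, 2, 1], [1, 3, 1], [3, 1, 3]],
            index=["cyA", "cyB", "cyC", "heA"],
            dtype=float,
        )
        result = kmeans_correlation(df, k=4, seed=0, n_init=4)
        table = cross_species_summary(result, toy_gene_table)
        assert table[["cyanobacterium", "heterotroph"]].to_numpy().sum() == 4

    def test_single_species_input_zero_other_column(self, toy_gene_table):
        df = pd.DataFrame(
            [[1, 2, 4], [4, 2, 1], [1, 3, 1]],
            index=["cyA", "cyB", "cyC"],
            dtype=float,
        )
        result = kmeans_correlation(df, k=3, seed=0, n_init=4)
        table = cross_species_summary(result, toy_gene_table)
        assert (table["heterotroph"] == 0).all()


@pytest.fixture(scope="module")
def clustered(small_truth, binary_design):
    genes = make_genomes(small_truth, 1)
    counts, truth = simulate_expression(genes, binary_design, small_truth, 1)
    factors = nz.size_factors(counts)
    expr = nz.per_kb_expression(counts, factors, genes)
    axes = validate_design(binary_design)
    means = nz.condition_means(expr, binary_design)
    profiles = nz.axis_profiles(means, axes.irradiance)
    scaled = nz.normalize_profile(profiles)
    kept = nz.variance_mask(scaled, 0.30)
    result = kmeans_correlation(
        nz.axis_profiles(scaled.values.loc[list(kept)], axes.irradiance),
        k=4,
        seed=1,
        n_init=20,
    )
    return genes, truth, result


class TestPlantedRecovery:
    """Truth-record comparisons on the scaled-down synthetic dataset."""

    def test_planted_shapes_recovered(self, clustered):
        _, truth, result = clustered
        labels = result.assignments.map(result.pattern_labels)
        planted = truth.loc[labels.index]
        nonflat = planted["shape_irradiance"] != "flat"
        recovery = (labels[nonflat] == planted.loc[nonflat, "shape_irradiance"]).mean()
        assert recovery >= 0.95

    def test_species_counts_match_truth_crosstab(self, clustered):
        genes, truth, result = clustered
        table = cross_species_summary(result, genes)
        labels = result.assignments.map(result.pattern_labels)
        planted = truth.loc[labels.index]
        for cluster, row in table.iterrows():
            shape = row["pattern"]
            for sp in ("cyanobacterium", "heterotroph"):
                expected = (
                    (planted["shape_irradiance"] == shape)
                    & (planted["species"] == sp)
                ).sum()
                if expected:
                    assert row[sp] >= 0.9 * expected
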