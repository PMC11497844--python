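"""Empirical reference panels, KS comparisons, stability."""

import numpy as np
import pytest

from popexpress.model_io import ExpressionModel, ModelVariant
from popexpress.reference import (
    build_reference,
    compare_populations,
    ks_two_sample,
    population_af,
    read_panel,
    stability_test,
    write_panel,
)


def _single_variant_model(weight=1.0):
    return ExpressionModel(
        "t", {"g1": [ModelVariant("v1", "A", "G", weight)]}
    )


def test_single_variant_mean_near_expectation():
    panel = build_reference(_single_variant_model(), {"v1": 0.5}, "eas",
                            n_reps=500, seed=0)
    ref = panel.genes["g1"]
    assert set(np.unique(ref.values)) <= {0.0, 1.0, 2.0}
    assert 0.9 <= ref.mean <= 1.1  # E = 2*AF*w = 1
    assert ref.n_variants == 1


def test_zero_af_gives_constant_zero():
    # AF must be a valid binomial probability; 0 means the effect allele is absent
    model = _single_variant_model(weight=2.5)
    panel = build_reference(model, {"v1": 0.0}, "eas", n_reps=100, seed=1)
    assert np.all(panel.genes["g1"].values == 0)
    assert panel.genes["g1"].sd == 0.0


def test_seed_determinism(small_models, small_freq):
    p1 = build_reference(small_models[0], small_freq, "pop1", n_reps=100, seed=5)
    p2 = build_reference(small_models[0], small_freq, "pop1", n_reps=100, seed=5)
    for gene in p1.genes:
        np.testing.assert_array_equal(p1.genes[gene].values, p2.genes[gene].values)


def test_unmatched_variants_dropped_and_counted():
    model = ExpressionModel(
        "t",
        {
            "g1": [ModelVariant("v1", "A", "G", 1.0),
                   ModelVariant("v2", "C", "T", 2.0)],
            "g2": [ModelVariant("v3", "G", "A", 1.0)],
        },
    )
    panel = build_reference(model, {"v1": 0.3}, "eas", n_reps=50, seed=0)
    assert list(panel.genes) == ["g1"]
    assert panel.genes["g1"].n_variants == 1
    assert panel.n_omitted_genes == 1
    assert panel.n_dropped_variants == 1


def test_panel_means_converge_to_analytic(small_models, small_freq):
    """Every gene mean lies within 4 SEs of sum_k w_k * 2 * AF_k."""
    n_reps = 2000
    panel = build_reference(small_models[0], small_freq, "pop1",
                            n_reps=n_reps, seed=3)
    af = population_af(small_freq, "pop1")
    for gene, ref in panel.genes.items():
        variants = [v for v in small_models[0].genes[gene] if v.variant_id in af]
        w = np.array([v.weight for v in variants])
        p = np.array([af[v.variant_id] for v in variants])
        expected = float(np.sum(w * 2 * p))
        se = np.sqrt(np.sum(w**2 * 2 * p * (1 - p)) / n_reps)
        assert abs(ref.mean - expected) <= 4 * se + 1e-12


# ---------------------------------------------------------------------------
# KS


def test_ks_identity_and_disjoint():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    d, p = ks_two_sample(x, x)
    assert d == 0.0 and p == pytest.approx(1.0)
    d2, _ = ks_two_sample([0, 0, 0, 0], [1, 1, 1, 1])
    assert d2 == 1.0


def test_ks_matches_brute_force_sup(rng):
    """KS D equals the exhaustive sup of |F_x - F_y| over the pooled support."""
    for _ in range(20):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8) + 0.5
        d, _ = ks_two_sample(x, y)
        support = np.concatenate([x, y])
        brute = max(
            abs(np.mean(x <= t) - np.mean(y <= t)) for t in support
        )
        assert d == pytest.approx(brute, rel=1e-12)


def test_ks_undersized_rejected():
    with pytest.raises(ValueError):
        ks_two_sample([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# stability and population comparison


def test_stability_threshold_worked_example(small_models, small_freq):
    panel = build_reference(small_models[0], small_freq, "pop1", 100, seed=1)
    res = stability_test(panel, panel, alpha=0.05)
    assert res.n_significant == 0  # panel vs itself
    # the Bonferroni threshold scales as alpha / genes compared
    assert res.threshold == pytest.approx(0.05 / res.n_genes_compared)


def test_stability_null_different_rep_counts(small_models, small_freq):
    """Independent 500- vs 2000-rep panels from one generator: no flagged
    genes.  Bonferroni at alpha = 0.05 makes this a >= 95%-probability event
    under the null; the fixed seeds pin one such draw."""
    p500 = build_reference(small_models[0], small_freq, "pop1", 500, seed=23)
    p2000 = build_reference(small_models[0], small_freq, "pop1", 2000, seed=24)
    res = stability_test(p500, p2000)
    assert res.n_significant == 0


def test_compare_populations_mean_diff_pct():
    model = _single_variant_model()
    pa = build_reference(model, {"v1": 0.05}, "a", 500, seed=1)
    pb = build_reference(model, {"v1": 0.45}, "b", 500, seed=2)
    comp = compare_populations(pa, pb)
    row = comp.gene("g1")
    assert row["significant"]  # AF 0.05 vs 0.45 separates at 5e-8
    expected_pct = (pa.genes["g1"].mean - pb.genes["g1"].mean) / abs(
        pb.genes["g1"].mean) * 100
    assert row["mean_diff_pct"] == pytest.approx(expected_pct)


def test_mean_diff_pct_formula():
    # mean_A = 0.1 vs mean_B = 0.7 -> -85.7%
    assert (0.1 - 0.7) / abs(0.7) * 100 == pytest.approx(-85.71, abs=0.01)


def test_compare_symmetry_under_swap(small_models, small_freq):
    pa = build_reference(small_models[0], small_freq, "pop1", 200, seed=4)
    pb = build_reference(small_models[0], small_freq, "pop2", 200, seed=5)
    ab = compare_populations(pa, pb)
    ba = compare_populations(pb, pa)
    np.testing.assert_allclose(ab.table["ks_statistic"], ba.table["ks_statistic"])
    np.testing.assert_allclose(ab.table["p_value"], ba.table["p_value"])
    # mean_diff_pct flips sign (up to the changed denominator)
    assert np.all(
        np.sign(ab.table["mean_diff_pct"]) == -np.sign(ba.table["mean_diff_pct"])
    )


def test_null_comparison_rarely_significant(small_models, small_freq):
    pa = build_reference(small_models[0], small_freq, "pop1", 300, seed=6)
    pb = build_reference(small_models[0], small_freq, "pop1", 300, seed=7)
    comp = compare_populations(pa, pb)  # same population, different seeds
    assert comp.n_significant == 0


def test_bonferroni_mode_threshold(small_models, small_freq):
    pa = build_reference(small_models[0], small_freq, "pop1", 100, seed=8)
    pb = build_reference(small_models[0], small_freq, "pop2", 100, seed=9)
    comp = compare_populations(pa, pb, mode="bonferroni_1_over_m")
    assert comp.threshold == pytest.approx(1.0 / len(comp.table))


def test_panel_round_trip(tmp_path, small_models, small_freq):
    panel = build_reference(small_models[0], small_freq, "pop1", 50, seed=10)
    path = tmp_path / "panel.tsv"
    write_panel(panel, path)
    back = read_panel(path)
    assert back.population == "pop1"
    assert back.n_reps == 50
    assert list(back.genes) == list(panel.genes)
    for gene in panel.genes:
        np.testing.assert_array_equal(back.genes[gene].values,
                                      panel.genes[gene].values)
        assert back.genes[gene].n_variants == panel.genes[gene].n_variants
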