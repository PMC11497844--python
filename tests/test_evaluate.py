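"""Percentile ranking, subject reports and dataset summaries."""

import numpy as np
import pytest

from popexpress.evaluate import (
    dataset_summary,
    make_report,
    percentile_rank,
    reference_interval,
    write_report,
    write_summary,
)
from popexpress.model_io import PredictionMatrix
from popexpress.reference import (
    GeneReference,
    ReferencePanel,
    build_reference,
    compare_populations,
)


def _panel_from_values(values_by_gene, population="pop1"):
    n_reps = len(next(iter(values_by_gene.values())))
    genes = {
        g: GeneReference.from_values(g, np.asarray(v, dtype=float), n_variants=3)
        for g, v in values_by_gene.items()
    }
    return ReferencePanel("t", population, n_reps, genes)


def test_percentile_rank_counting_definition():
    ref = np.arange(1, 501, dtype=float)
    assert percentile_rank(0.0, ref) == 0.0
    assert percentile_rank(500.0, ref) == 100.0
    assert percentile_rank(12.5, ref) == pytest.approx(2.4)  # 12 of 500
    with pytest.raises(ValueError):
        percentile_rank(1.0, [])


def test_percentile_rank_ties_inclusive():
    assert percentile_rank(1.0, [0.0, 1.0, 1.0, 2.0]) == 75.0


def test_report_rows_subject_major():
    panel = _panel_from_values({
        "gA": np.linspace(0, 1, 10),
        "gB": np.linspace(-1, 1, 10),
        "gC": np.linspace(5, 6, 10),
    })
    pm = PredictionMatrix(
        [("F1", "S1"), ("F2", "S2")],
        ["gA", "gB", "gC", "gX"],
        np.array([[0.5, 0.0, 5.5, 9.0], [0.05, -2.0, 6.0, 9.0]]),
    )
    rows, unmatched = make_report(pm, panel)
    assert len(rows) == 2 * 3
    assert [r.gene_id for r in rows[:3]] == ["gA", "gB", "gC"]
    assert rows[0].family_id == "F1" and rows[3].family_id == "F2"
    assert unmatched == ["gX"]
    # value below every reference draw
    assert rows[4].percentile_rank == 0.0
    # subject deviation column
    assert rows[0].subject_dev == pytest.approx(0.5 - panel.genes["gA"].mean)


def test_report_median_value_ranks_near_50():
    values = np.arange(1, 502, dtype=float)  # odd count, median 251
    panel = _panel_from_values({"g": values})
    pm = PredictionMatrix([("F", "S")], ["g"], np.array([[251.0]]))
    rows, _ = make_report(pm, panel)
    assert rows[0].percentile_rank == pytest.approx(100 * 251 / 501)


def test_report_carries_comparison_flags(small_models, small_freq):
    pa = build_reference(small_models[0], small_freq, "pop1", 100, seed=1)
    pb = build_reference(small_models[0], small_freq, "pop2", 100, seed=2)
    comp = compare_populations(pa, pb)
    gene_ids = list(pa.genes)
    pm = PredictionMatrix(
        [("F", "S")], gene_ids, np.zeros((1, len(gene_ids)))
    )
    rows, _ = make_report(pm, pa, comp)
    flags = {r.gene_id: r.pop_diff_flag for r in rows}
    for _, crow in comp.table.iterrows():
        assert flags[crow["gene"]] == ("Sig." if crow["significant"] else "Nonsig.")


def test_no_gene_overlap_rejected():
    panel = _panel_from_values({"g1": np.arange(10.0)})
    pm = PredictionMatrix([("F", "S")], ["other"], np.zeros((1, 1)))
    with pytest.raises(ValueError):
        make_report(pm, panel)


def test_reference_interval_quantiles():
    ref = GeneReference.from_values("g", np.arange(1, 501, dtype=float), 1)
    lo, hi = reference_interval(ref, 0.95)
    assert lo == pytest.approx(13.475)
    assert hi == pytest.approx(487.525)
    assert reference_interval(ref, 1.0) == (1.0, 500.0)
    const = GeneReference.from_values("c", np.full(10, 7.0), 1)
    assert reference_interval(const) == (7.0, 7.0)
    with pytest.raises(ValueError):
        reference_interval(ref, 0.0)


def test_dataset_summary_formulas():
    panel = _panel_from_values({"g": np.linspace(1.0, 3.0, 500)})  # mean 2.0
    values = np.concatenate([np.full(45, 2.0), np.full(16, 100.0)])[:, None]
    pm = PredictionMatrix(
        [(f"F{i}", f"S{i}") for i in range(61)], ["g"], values
    )
    rows = dataset_summary(pm, panel, {"g": 80}, {"g": 100})
    (row,) = rows
    assert row.ref_mean == pytest.approx(2.0)
    assert row.abs_diff == pytest.approx(abs(values.mean() - 2.0))
    assert row.ratio_diff == pytest.approx(row.abs_diff / 2.0)
    assert row.snp_ratio == pytest.approx(0.8)
    assert row.ge_match_ref_num == 45  # the 100.0 outliers fall outside the CI
    assert row.ge_match_ref_ratio == pytest.approx(45 / 61, abs=5e-5)


def test_dataset_summary_degenerate_denominators():
    panel = _panel_from_values({"g": np.zeros(100)})
    pm = PredictionMatrix([("F", "S")], ["g"], np.array([[0.0]]))
    (row,) = dataset_summary(pm, panel, {"g": 0}, {"g": 0})
    assert row.ratio_diff is None
    assert row.snp_ratio is None


def test_writers_emit_expected_headers(tmp_path):
    panel = _panel_from_values({"g": np.linspace(0, 1, 20)})
    pm = PredictionMatrix([("F", "S")], ["g"], np.array([[0.4]]))
    rows, _ = make_report(pm, panel)
    report_path = tmp_path / "report.tsv"
    write_report(rows, report_path)
    header = report_path.read_text().splitlines()[0].split("\t")
    assert header[:5] == ["FID", "IID", "gene", "value", "percentile_rank"]
    summary_path = tmp_path / "summary.tsv"
    write_summary(dataset_summary(pm, panel, {"g": 1}, {"g": 2}), summary_path)
    sheader = summary_path.read_text().splitlines()[0].split("\t")
    assert sheader == [
        "Gene", "Ref.Mean", "Ref.Sd", "Data.Mean", "Data.Sd", "Abs.Diff",
        "Ratio.Diff", "Data.SNP.Num", "Predixcan_SNP.Num", "SNP.Ratio",
        "GE.Match.Ref.Num", "GE.Match.Ref.Ratio",
    ]


def test_self_rank_uniformity(small_models, small_freq):
    """Ranking a panel's own draws yields ~uniform percentile ranks."""
    panel = build_reference(small_models[0], small_freq, "pop1", 500, seed=13)
    # pick the most polymorphic gene: near-continuous draws, few rank ties
    gene = max(panel.genes.values(), key=lambda r: r.n_variants)
    ranks = np.array([percentile_rank(v, gene.values) for v in gene.values])
    # with mostly-distinct draws the ranks hit multiples of 100/n roughly once each
    assert 40.0 < ranks.mean() < 60.0
    assert (ranks > 0).all() and (ranks <= 100).all()
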