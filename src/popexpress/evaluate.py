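"""Score user-supplied predicted expression against a reference panel.

Two reports are produced:

* a **subject-level report**: for each subject and each gene shared with the
  panel, the percentile rank of the predicted value among the panel's
  empirical draws, the panel's per-gene summary (variant count, mean, SD),
  and the population-comparison verdict (Sig./Nonsig. plus the percent mean
  difference between the two populations' panels);
* a **dataset-level summary** per gene: dataset mean/SD versus panel
  mean/SD, their absolute and relative difference, the SNP-availability
  ratio of the user's genotype data, and how many subjects' predictions
  fall inside the panel's empirical central interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_io import PredictionMatrix
from .reference import GeneReference, PopulationComparison, ReferencePanel

__all__ = [
    "ReportRow",
    "DatasetSummaryRow",
    "percentile_rank",
    "make_report",
    "reference_interval",
    "dataset_summary",
    "write_report",
    "write_summary",
]


@dataclass(frozen=True)
class ReportRow:
    family_id: str
    individual_id: str
    gene_id: str
    predicted_value: float
    percentile_rank: float  # 0-100, multiples of 100/n_reps
    n_variants: int
    ref_mean: float
    ref_sd: float
    pop_diff_flag: str  # 'Sig.' or 'Nonsig.'
    mean_diff_pct: Optional[float]
    subject_dev: float  # predicted_value - ref_mean (subject-level deviation)


@dataclass(frozen=True)
class DatasetSummaryRow:
    gene_id: str
    ref_mean: float
    ref_sd: float
    data_mean: float
    data_sd: float
    abs_diff: float
    ratio_diff: Optional[float]
    data_snp_num: int
    predixcan_snp_num: int
    snp_ratio: Optional[float]
    ge_match_ref_num: int
    ge_match_ref_ratio: float


def percentile_rank(value: float, reference_values) -> float:
    """Percentile position of ``value`` among the reference draws.

    Counting definition, ties inclusive:
    ``100 * #{reference <= value} / n``.
    """
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference vector")
    return 100.0 * np.count_nonzero(ref <= value) / ref.size


def make_report(
    predictions: PredictionMatrix,
    panel: ReferencePanel,
    comparison: Optional[PopulationComparison] = None,
) -> tuple[list[ReportRow], list[str]]:
    """Build the subject-level report.

    Rows are grouped by subject (input order) with genes in panel order;
    returns ``(rows, unmatched_genes)`` where the second element lists
    prediction genes absent from the panel.
    """
    pred_col = {g: j for j, g in enumerate(predictions.gene_ids)}
    matched = [g for g in panel.genes if g in pred_col]
    unmatched = [g for g in predictions.gene_ids if g not in panel.genes]
    if not matched:
        raise ValueError("no overlap between prediction genes and panel genes")
    comp_by_gene: dict[str, tuple[str, Optional[float]]] = {}
    if comparison is not None:
        for _, row in comparison.table.iterrows():
            pct = row["mean_diff_pct"]
            comp_by_gene[row["gene"]] = (
                "Sig." if row["significant"] else "Nonsig.",
                None if pd.isna(pct) else float(pct),
            )
    rows: list[ReportRow] = []
    for i, (fid, iid) in enumerate(predictions.subject_ids):
        for gene in matched:
            ref = panel.genes[gene]
            value = float(predictions.values[i, pred_col[gene]])
            flag, pct = comp_by_gene.get(gene, ("Nonsig.", None))
            rows.append(
                ReportRow(
                    family_id=fid,
                    individual_id=iid,
                    gene_id=gene,
                    predicted_value=value,
                    percentile_rank=percentile_rank(value, ref.values),
                    n_variants=ref.n_variants,
                    ref_mean=ref.mean,
                    ref_sd=ref.sd,
                    pop_diff_flag=flag,
                    mean_diff_pct=pct,
                    subject_dev=value - ref.mean,
                )
            )
    return rows, unmatched


def reference_interval(
    gene_ref: GeneReference, level: float = 0.95
) -> tuple[float, float]:
    """Empirical central interval of the reference draws.

    Linear-interpolation quantiles at (1-level)/2 and 1-(1-level)/2;
    level = 1 gives (min, max).
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    tail = (1 - level) / 2
    lo, hi = np.quantile(gene_ref.values, [tail, 1 - tail], method="linear")
    return float(lo), float(hi)


def dataset_summary(
    predictions: PredictionMatrix,
    panel: ReferencePanel,
    data_snp_counts: Mapping[str, int],
    model_snp_counts: Mapping[str, int],
    level: float = 0.95,
) -> list[DatasetSummaryRow]:
    """Per-gene dataset-vs-panel summary.

    ``data_snp_counts`` gives the number of model SNPs present in the user's
    genotype data per gene; ``model_snp_counts`` the number the model
    requires.  A subject "matches the reference" when their predicted value
    lies inside the closed central interval of the panel's draws.
    """
    pred_col = {g: j for j, g in enumerate(predictions.gene_ids)}
    n_subjects = len(predictions.subject_ids)
    rows: list[DatasetSummaryRow] = []
    for gene, ref in panel.genes.items():
        if gene not in pred_col:
            continue
        if gene not in data_snp_counts or gene not in model_snp_counts:
            raise KeyError(f"missing SNP counts for gene {gene}")
        values = predictions.values[:, pred_col[gene]]
        data_mean = float(values.mean())
        data_sd = float(values.std(ddof=1)) if n_subjects > 1 else 0.0
        abs_diff = abs(data_mean - ref.mean)
        ratio_diff = abs_diff / abs(ref.mean) if abs(ref.mean) >= 1e-12 else None
        n_model = int(model_snp_counts[gene])
        n_data = int(data_snp_counts[gene])
        snp_ratio = n_data / n_model if n_model > 0 else None
        lo, hi = reference_interval(ref, level)
        n_match = int(np.count_nonzero((values >= lo) & (values <= hi)))
        rows.append(
            DatasetSummaryRow(
                gene_id=gene,
                ref_mean=ref.mean,
                ref_sd=ref.sd,
                data_mean=data_mean,
                data_sd=data_sd,
                abs_diff=abs_diff,
                ratio_diff=ratio_diff,
                data_snp_num=n_data,
                predixcan_snp_num=n_model,
                snp_ratio=snp_ratio,
                ge_match_ref_num=n_match,
                ge_match_ref_ratio=n_match / n_subjects,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# TSV writers (ranks and ratios printed at 4 decimals; full precision kept
# in the in-memory rows)

_REPORT_COLUMNS = [
    "FID", "IID", "gene", "value", "percentile_rank", "n_variants",
    "ref_mean", "ref_sd", "pop_diff", "mean_diff_pct", "subject_dev",
]

_SUMMARY_COLUMNS = [
    "Gene", "Ref.Mean", "Ref.Sd", "Data.Mean", "Data.Sd", "Abs.Diff",
    "Ratio.Diff", "Data.SNP.Num", "Predixcan_SNP.Num", "SNP.Ratio",
    "GE.Match.Ref.Num", "GE.Match.Ref.Ratio",
]


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.4f}"


def write_report(rows: Sequence[ReportRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join([
                    r.family_id, r.individual_id, r.gene_id,
                    _fmt(r.predicted_value), _fmt(r.percentile_rank),
                    str(r.n_variants), _fmt(r.ref_mean), _fmt(r.ref_sd),
                    r.pop_diff_flag, _fmt(r.mean_diff_pct), _fmt(r.subject_dev),
                ]) + "\n"
            )


def write_summary(rows: Sequence[DatasetSummaryRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join([
                    r.gene_id, _fmt(r.ref_mean), _fmt(r.ref_sd),
                    _fmt(r.data_mean), _fmt(r.data_sd), _fmt(r.abs_diff),
                    _fmt(r.ratio_diff), str(r.data_snp_num),
                    str(r.predixcan_snp_num), _fmt(r.snp_ratio),
                    str(r.ge_match_ref_num), _fmt(r.ge_match_ref_ratio),
                ]) + "\n"
            )
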