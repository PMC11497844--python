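"""Allele-frequency-driven empirical gene-expression reference panels.

A reference panel emulates a population's expected expression distribution
without individual genotypes: for each repetition, every model variant is
assigned a dosage drawn Binomial(2, AF) from the population allele frequency
(one pseudo-individual under Hardy-Weinberg, variants independent — no LD),
and the gene's linear predictor is evaluated.  Repeating 500 times per gene
yields an empirical distribution whose mean, standard deviation and variant
count summarize the population's expected prediction for that gene.

Panels from two populations (e.g. East Asian vs non-Finnish European) are
compared gene-by-gene with two-sample Kolmogorov-Smirnov tests; the same
test run between panels built with different repetition counts checks the
panel's stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import ExpressionModel
from .popdiff import VariantFrequency

__all__ = [
    "GeneReference",
    "ReferencePanel",
    "StabilityResult",
    "PopulationComparison",
    "population_af",
    "build_reference",
    "ks_two_sample",
    "stability_test",
    "compare_populations",
    "read_panel",
    "write_panel",
]


@dataclass(frozen=True)
class GeneReference:
    """Empirical expression distribution of one gene in one population."""

    gene_id: str
    values: np.ndarray  # n_reps predicted-expression draws
    mean: float
    sd: float  # sample SD (n-1 denominator)
    n_variants: int  # model variants with frequency information

    @classmethod
    def from_values(cls, gene_id: str, values: np.ndarray, n_variants: int) -> "GeneReference":
        values = np.asarray(values, dtype=float)
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return cls(gene_id, values, float(values.mean()), sd, n_variants)


@dataclass
class ReferencePanel:
    tissue: str
    population: str
    n_reps: int
    genes: dict[str, GeneReference]
    seed: Optional[int] = None
    n_omitted_genes: int = 0  # genes whose variants all lacked frequency records
    n_dropped_variants: int = 0  # variants without frequency records, over kept genes

    def __post_init__(self):
        for ref in self.genes.values():
            if ref.values.size != self.n_reps:
                raise ValueError(
                    f"gene {ref.gene_id}: {ref.values.size} values != n_reps={self.n_reps}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)


def population_af(
    freq: Sequence[VariantFrequency], population: str
) -> dict[str, float]:
    """Per-variant allele frequency of one population ('pop1' or 'pop2').

    Uses the AF field when present, else AC/AN; variants lacking both are
    omitted from the mapping.
    """
    if population not in ("pop1", "pop2"):
        raise ValueError("population must be 'pop1' or 'pop2'")
    out: dict[str, float] = {}
    for vf in freq:
        rec = vf.pop1 if population == "pop1" else vf.pop2
        if rec.af is not None:
            out[vf.variant_id] = rec.af
        elif rec.ac is not None and rec.an is not None:
            out[vf.variant_id] = rec.ac / rec.an
    return out


def build_reference(
    model: ExpressionModel,
    freq: Sequence[VariantFrequency] | Mapping[str, float],
    population: str,
    n_reps: int = 500,
    seed: Optional[int] = None,
) -> ReferencePanel:
    """Build the empirical reference panel for one population.

    ``freq`` is either a variant-frequency table (the population label
    selects the side) or a ready ``variant_id -> AF`` mapping (any label).
    Model variants without a frequency record are dropped from their gene
    and counted; genes losing every variant are omitted and counted.
    """
    if isinstance(freq, Mapping):
        af = dict(freq)
    else:
        af = population_af(freq, population)
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneReference] = {}
    n_omitted = 0
    n_dropped = 0
    for gene_id, variants in model.genes.items():
        kept = [v for v in variants if v.variant_id in af]
        if not kept:
            n_omitted += 1
            continue
        n_dropped += len(variants) - len(kept)
        p = np.array([af[v.variant_id] for v in kept])
        w = np.array([v.weight for v in kept])
        dosages = rng.binomial(2, p, size=(n_reps, len(kept)))
        genes[gene_id] = GeneReference.from_values(gene_id, dosages @ w, len(kept))
    return ReferencePanel(
        tissue=model.tissue,
        population=population,
        n_reps=n_reps,
        genes=genes,
        seed=seed,
        n_omitted_genes=n_omitted,
        n_dropped_variants=n_dropped,
    )


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test, asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("KS test needs at least 2 values per sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class StabilityResult:
    """Per-gene KS comparison of two panels under a Bonferroni threshold."""

    table: pd.DataFrame  # columns: gene ks_statistic p_value significant
    threshold: float  # alpha / n_genes_compared
    n_genes_compared: int
    n_significant: int
    mismatched_genes: tuple[str, ...]  # genes present in only one panel


def stability_test(
    panel_a: ReferencePanel, panel_b: ReferencePanel, alpha: float = 0.05
) -> StabilityResult:
    """KS-compare shared genes between two panels at threshold alpha/m."""
    shared = [g for g in panel_a.genes if g in panel_b.genes]
    if not shared:
        raise ValueError("panels share no genes")
    mismatched = tuple(
        sorted(set(panel_a.genes).symmetric_difference(panel_b.genes))
    )
    threshold = alpha / len(shared)
    rows = []
    for gene in shared:
        d, p = ks_two_sample(panel_a.genes[gene].values, panel_b.genes[gene].values)
        rows.append({
            "gene": gene, "ks_statistic": d, "p_value": p,
            "significant": p < threshold,
        })
    table = pd.DataFrame(rows)
    return StabilityResult(
        table=table,
        threshold=threshold,
        n_genes_compared=len(shared),
        n_significant=int(table["significant"].sum()),
        mismatched_genes=mismatched,
    )


@dataclass(frozen=True)
class PopulationComparison:
    """Gene-by-gene KS comparison of two populations' panels.

    ``mean_diff_pct`` is (mean_A - mean_B) / |mean_B| * 100 — the percent
    by which population A's expected expression deviates from population
    B's; absent (NaN) where |mean_B| < 1e-12.
    """

    table: pd.DataFrame  # columns: gene ks_statistic p_value significant mean_diff_pct
    threshold: float
    mode: str  # 'fixed' or 'bonferroni_1_over_m'

    def gene(self, gene_id: str) -> pd.Series:
        rows = self.table[self.table["gene"] == gene_id]
        if rows.empty:
            raise KeyError(gene_id)
        return rows.iloc[0]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def compare_populations(
    panel_a: ReferencePanel,
    panel_b: ReferencePanel,
    p_threshold: float = 5e-8,
    mode: str = "fixed",
) -> PopulationComparison:
    """Compare two populations' panels gene-by-gene.

    ``mode='fixed'`` flags genes at ``p < p_threshold`` (default the
    genome-wide 5e-8); ``mode='bonferroni_1_over_m'`` uses 1/m where m is
    the number of genes compared.
    """
    shared = [g for g in panel_a.genes if g in panel_b.genes]
    if not shared:
        raise ValueError("panels share no genes")
    if mode == "fixed":
        threshold = p_threshold
    elif mode == "bonferroni_1_over_m":
        threshold = 1.0 / len(shared)
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    rows = []
    for gene in shared:
        ra, rb = panel_a.genes[gene], panel_b.genes[gene]
        d, p = ks_two_sample(ra.values, rb.values)
        pct = (
            (ra.mean - rb.mean) / abs(rb.mean) * 100
            if abs(rb.mean) >= 1e-12
            else np.nan
        )
        rows.append({
            "gene": gene, "ks_statistic": d, "p_value": p,
            "significant": p < threshold, "mean_diff_pct": pct,
        })
    return PopulationComparison(pd.DataFrame(rows), threshold, mode)


# ---------------------------------------------------------------------------
# panel serialization: TSV with one row per gene plus a JSON metadata sidecar


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["gene", "n_variants", "mean", "sd"] + [
            f"v{i + 1}" for i in range(panel.n_reps)
        ]
        fh.write("\t".join(header) + "\n")
        for ref in panel.genes.values():
            fields = [ref.gene_id, str(ref.n_variants), repr(ref.mean), repr(ref.sd)]
            fields += [repr(float(v)) for v in ref.values]
            fh.write("\t".join(fields) + "\n")
    meta = {
        "tissue": panel.tissue,
        "population": panel.population,
        "n_reps": panel.n_reps,
        "seed": panel.seed,
        "n_omitted_genes": panel.n_omitted_genes,
        "n_dropped_variants": panel.n_dropped_variants,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_panel(path: str | Path) -> ReferencePanel:
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty panel file")
    header = lines[0].split("\t")
    n_reps = len(header) - 4
    genes: dict[str, GeneReference] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        gene_id = fields[0]
        values = np.array([float(x) for x in fields[4:]])
        genes[gene_id] = GeneReference(
            gene_id=gene_id,
            values=values,
            mean=float(fields[2]),
            sd=float(fields[3]),
            n_variants=int(fields[1]),
        )
    return ReferencePanel(
        tissue=meta.get("tissue", path.stem),
        population=meta.get("population", "unknown"),
        n_reps=meta.get("n_reps", n_reps),
        genes=genes,
        seed=meta.get("seed"),
        n_omitted_genes=meta.get("n_omitted_genes", 0),
        n_dropped_variants=meta.get("n_dropped_variants", 0),
    )
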