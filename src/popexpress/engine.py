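"""The linear prediction core and the rank-based inverse normal transform.

Predicted expression of gene *s* for one subject is the weighted sum of
effect-allele dosages over the gene's model variants::

    Y_s = sum_k  w_{k,s} * X_k

where ``w_{k,s}`` is the trained weight of variant *k* for gene *s* and
``X_k`` the subject's dosage (0-2 copies of the effect allele).  Model
variants absent from the genotype data are, by default, imputed as
homozygous reference (dosage 0), the standard wild-type substitution used
when array content or imputation quality leaves model SNPs unobserved.
"""

from __future__ import annotations

import enum

import numpy as np
from scipy import special, stats

from .model_io import DosageMatrix, ExpressionModel, PredictionMatrix

__all__ = [
    "MissingPolicy",
    "MissingVariantError",
    "predict_expression",
    "inverse_normal_transform",
]


class MissingPolicy(enum.Enum):
    """How to treat model variants absent from the dosage matrix."""

    WILD_TYPE_ZERO = "wild_type_zero"  # impute homozygous reference (dosage 0)
    ERROR = "error"


class MissingVariantError(KeyError):
    """Raised under ``MissingPolicy.ERROR`` when model variants are unobserved."""

    def __init__(self, missing: dict[str, list[str]]):
        self.missing = missing
        n = sum(len(v) for v in missing.values())
        super().__init__(
            f"{n} model variants missing from dosage data: "
            + "; ".join(f"{g}: {', '.join(v)}" for g, v in missing.items())
        )


def predict_expression(
    model: ExpressionModel,
    dosages: DosageMatrix,
    policy: MissingPolicy = MissingPolicy.WILD_TYPE_ZERO,
) -> PredictionMatrix:
    """Predict expression for every subject and every model gene.

    Returns a :class:`PredictionMatrix` whose ``meta['variant_counts']`` maps
    each gene to ``(n_model_variants, n_observed_variants)``, i.e. the number
    of variants the model defines versus the number actually present in the
    dosage data.

    Under ``WILD_TYPE_ZERO``, unobserved model variants contribute
    ``weight * 0``; under ``ERROR`` any unobserved variant aborts with the
    full list of missing ids.
    """
    if model.n_genes == 0:
        raise ValueError("model is empty")
    col = {vid: j for j, vid in enumerate(dosages.variant_ids)}
    n_subjects = len(dosages.subject_ids)
    gene_ids = model.gene_ids
    values = np.zeros((n_subjects, len(gene_ids)))
    counts: dict[str, tuple[int, int]] = {}
    missing: dict[str, list[str]] = {}

    for j, gene in enumerate(gene_ids):
        variants = model.genes[gene]
        idx = [col[v.variant_id] for v in variants if v.variant_id in col]
        weights = np.array(
            [v.weight for v in variants if v.variant_id in col], dtype=float
        )
        absent = [v.variant_id for v in variants if v.variant_id not in col]
        if absent:
            missing[gene] = absent
        counts[gene] = (len(variants), len(idx))
        if idx:
            values[:, j] = dosages.dosages[:, idx] @ weights

    if missing and policy is MissingPolicy.ERROR:
        raise MissingVariantError(missing)
    return PredictionMatrix(
        subject_ids=list(dosages.subject_ids),
        gene_ids=gene_ids,
        values=values,
        meta={"variant_counts": counts, "missing_variants": missing},
    )


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset.

    Maps the sample to standard-normal quantiles via
    ``Phi^{-1}((rank - 3/8) / (n + 1/4))`` with ties receiving their average
    rank; output order matches input order.  Requires n >= 2 and at least
    two distinct values (a constant sample has no meaningful ranks).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if x.size < 2:
        raise ValueError("inverse normal transform needs n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("all values identical: ranks are degenerate")
    ranks = stats.rankdata(x, method="average")
    return special.ndtri((ranks - 0.375) / (x.size + 0.25))
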