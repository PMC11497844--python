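"""Synthetic fixtures with controlled population structure.

Generates expression models, two-population allele-frequency tables,
genotype dosage matrices and prediction matrices whose shapes mimic the
published regime of tissue expression models (per-gene cis-variant counts
spanning 1 to a few hundred with a mean near 30; small zero-centered
heavy-tailed weights) so every other module is testable without external
downloads.  Population structure is injected explicitly: a chosen fraction
of variants get population-2 allele frequencies shifted by a chosen delta,
and allele counts are drawn binomially so the tables carry realistic
sampling noise.  No linkage disequilibrium is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import engine
from .model_io import (
    DosageMatrix,
    ExpressionModel,
    ModelVariant,
    PredictionMatrix,
)
from .popdiff import PopulationRecord, VariantFrequency
from .reference import population_af

__all__ = [
    "SyntheticConfig",
    "make_models",
    "make_frequencies",
    "make_genotypes",
    "make_predictions",
]

_ALLELES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic generator.

    ``variant_count_max_lu`` is the upper end of the log-uniform per-gene
    variant-count law; the default 150 puts the law's mean at ~30 (the
    published average per-gene count) while counts are always clamped to
    [1, 430], the published min/max range.  Weights default to
    Laplace(0, 0.02), a zero-centered heavy-tailed law whose |w| quintiles
    are the same order of magnitude as published weight-level thresholds.
    """

    n_tissues: int = 2
    n_genes: int = 50
    variant_count_max_lu: int = 150
    weight_scale: float = 0.02
    diff_fraction: float = 0.3
    delta_af: float = 0.1
    an_per_pop: int = 20_000
    n_subjects: int = 61
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tissues, self.n_genes, self.n_subjects, self.an_per_pop) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.diff_fraction <= 1:
            raise ValueError("diff_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _variant_counts(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    raw = np.exp(rng.uniform(0.0, np.log(cfg.variant_count_max_lu), size=n))
    return np.clip(np.round(raw).astype(int), 1, 430)


def make_models(cfg: SyntheticConfig) -> list[ExpressionModel]:
    """Per-tissue models with log-uniform variant counts and Laplace weights.

    Variant ids follow the ``chr_pos_ref_alt_build`` token convention and
    are unique across all tissues and genes.
    """
    rng = np.random.default_rng(cfg.seed)
    models = []
    pos = 10_000
    for t in range(cfg.n_tissues):
        genes: dict[str, list[ModelVariant]] = {}
        counts = _variant_counts(cfg, cfg.n_genes, rng)
        for g in range(cfg.n_genes):
            variants = []
            for _ in range(counts[g]):
                ref, alt = rng.choice(4, size=2, replace=False)
                pos += rng.integers(100, 1000)
                vid = f"1_{pos}_{_ALLELES[ref]}_{_ALLELES[alt]}_b38"
                weight = float(rng.laplace(0.0, cfg.weight_scale))
                variants.append(
                    ModelVariant(vid, _ALLELES[ref], _ALLELES[alt], weight)
                )
            genes[f"gene_{g + 1:04d}"] = variants
        models.append(ExpressionModel(tissue=f"tissue_{t + 1}", genes=genes))
    return models


def make_frequencies(
    models: list[ExpressionModel] | ExpressionModel,
    cfg: SyntheticConfig,
) -> list[VariantFrequency]:
    """Two-population frequency table over every unique model variant.

    Population 1 AFs are Uniform(0.05, 0.5); an exact
    ``round(diff_fraction * n)`` subset of variants gets population 2 AF
    shifted by +/- delta_af (clamped to [0.001, 0.999]), the rest equal AF.
    Allele counts are Binomial(AN, AF) per population and the stored AF is
    AC/AN, so the table carries finite-sample noise.
    """
    if isinstance(models, ExpressionModel):
        models = [models]
    if not models:
        raise ValueError("no models supplied")
    seen: dict[str, None] = {}
    for model in models:
        for vid in model.variant_ids():
            seen.setdefault(vid, None)
    vids = list(seen)
    n = len(vids)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    af1 = rng.uniform(0.05, 0.5, size=n)
    n_diff = int(round(cfg.diff_fraction * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    shift = np.zeros(n)
    shift[diff_idx] = rng.choice([-1.0, 1.0], size=n_diff) * cfg.delta_af
    af2 = np.clip(af1 + shift, 0.001, 0.999)
    an = cfg.an_per_pop
    ac1 = rng.binomial(an, af1)
    ac2 = rng.binomial(an, af2)
    table = []
    for i, vid in enumerate(vids):
        table.append(
            VariantFrequency(
                vid,
                PopulationRecord(ac=int(ac1[i]), an=an, af=ac1[i] / an),
                PopulationRecord(ac=int(ac2[i]), an=an, af=ac2[i] / an),
            )
        )
    return table


def make_genotypes(
    freq: list[VariantFrequency],
    population: str,
    n_subjects: int,
    seed: Optional[int] = None,
) -> DosageMatrix:
    """Hardy-Weinberg dosages: Binomial(2, AF_pop) per subject and variant."""
    af = population_af(freq, population)
    if not af:
        raise ValueError(f"no allele frequencies available for {population!r}")
    rng = np.random.default_rng(seed)
    vids = list(af)
    p = np.array([af[v] for v in vids])
    dosages = rng.binomial(2, p, size=(n_subjects, len(vids))).astype(float)
    subjects = [(f"F{i + 1}", f"S{i + 1}") for i in range(n_subjects)]
    return DosageMatrix(subjects, vids, dosages)


def make_predictions(
    model: ExpressionModel, genotypes: DosageMatrix
) -> PredictionMatrix:
    """Predict expression from synthetic genotypes via the linear engine."""
    return engine.predict_expression(model, genotypes)
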