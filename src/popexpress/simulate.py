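"""Simulation framework quantifying how population-differentiated variants
shift predicted expression.

The framework pools |weight| values across all supplied tissue models into
one ascending vector, cuts it into five near-equal contiguous segments, and
labels segments 1, 3 and 5 the *low*, *medium* and *high* weight levels.
A scenario is a four-parameter combination:

* number of model variants per gene (defaults 1, 30, 200, 430 — the printed
  minimum, average, large and maximum per-gene variant counts of the
  PredictDB tissue models),
* minor allele frequency, 0.05-0.45 in steps of 0.1 (5 values),
* proportion of population-differentiated variants, 0-0.4 in steps of 0.05
  (9 values),
* the weight level of the differentiated variants (low/medium/high).

Per scenario, ``n_diff = round(diff_proportion * n_variants)`` variants get
weights sampled from the chosen level and the remainder from the low level;
weights are drawn once and held fixed while dosages are redrawn
Binomial(2, MAF) for each of the 500 repetitions, yielding 500 predicted
expression values Y = sum w*X per scenario.  Scenarios with higher
differentiated proportion and level are then compared with the
zero-proportion baseline of their stratum via means and empirical CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_io import ExpressionModel

__all__ = [
    "WeightPool",
    "ScenarioSpec",
    "ScenarioResult",
    "GridSummary",
    "ECDF",
    "build_weight_pool",
    "sample_dosages",
    "simulate_scenario",
    "run_grid",
    "ecdf",
    "summarize_vs_baseline",
    "DEFAULT_N_VARIANTS",
    "DEFAULT_MAF_GRID",
    "DEFAULT_DIFF_GRID",
    "WEIGHT_GROUPS",
]

DEFAULT_N_VARIANTS = (1, 30, 200, 430)
DEFAULT_MAF_GRID = tuple(0.05 + 0.1 * i for i in range(5))
DEFAULT_DIFF_GRID = tuple(round(0.05 * i, 2) for i in range(9))
WEIGHT_GROUPS = ("low", "medium", "high")

_GROUP_SEGMENT = {"low": 0, "medium": 2, "high": 4}


@dataclass(frozen=True)
class WeightPool:
    """Ascending pooled |weight| vector partitioned into five segments.

    ``segment_bounds`` are (start, stop) index ranges; segment sizes differ
    by at most one, any remainder going to the earliest segments.
    """

    sorted_abs_weights: np.ndarray
    segment_bounds: tuple[tuple[int, int], ...]

    def segment(self, index: int) -> np.ndarray:
        lo, hi = self.segment_bounds[index]
        return self.sorted_abs_weights[lo:hi]

    def group(self, name: str) -> np.ndarray:
        """Weights of the named level (low/medium/high)."""
        return self.segment(_GROUP_SEGMENT[name])

    def group_bounds(self) -> dict[str, tuple[float, float]]:
        """(min, max) |weight| of each named level."""
        return {
            name: (float(self.group(name).min()), float(self.group(name).max()))
            for name in WEIGHT_GROUPS
        }


@dataclass(frozen=True)
class ScenarioSpec:
    n_variants: int
    maf: float
    diff_proportion: float
    weight_group: str
    n_reps: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0 <= self.diff_proportion < 1:
            raise ValueError("diff_proportion must lie in [0, 1)")
        if self.weight_group not in _GROUP_SEGMENT:
            raise ValueError(f"unknown weight group {self.weight_group!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")

    @property
    def n_diff(self) -> int:
        """Number of differentiated variants, rounded half-up."""
        return int(np.floor(self.diff_proportion * self.n_variants + 0.5))


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    weights: np.ndarray  # fixed per scenario: diff-group weights first, then low
    values: np.ndarray  # n_reps predicted-expression draws
    degenerate: bool = False  # n_diff == 0 with a non-low group requested

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class GridSummary:
    """Per-scenario means and their difference/ratio vs the zero-proportion
    baseline of the same (n_variants, maf, weight_group) stratum."""

    table: pd.DataFrame  # columns: n_variants maf diff_proportion weight_group
    #          mean diff_vs_baseline ratio_vs_baseline


def build_weight_pool(models: Iterable[ExpressionModel]) -> WeightPool:
    """Pool |weight| over every weight row of every model (no deduplication),
    sort ascending, and cut into five near-equal contiguous segments."""
    weights = [
        abs(v.weight)
        for model in models
        for variants in model.genes.values()
        for v in variants
    ]
    if not weights:
        raise ValueError("weight pool is empty")
    pooled = np.sort(np.asarray(weights, dtype=float), kind="stable")
    n = pooled.size
    base, rem = divmod(n, 5)
    sizes = [base + (1 if i < rem else 0) for i in range(5)]
    bounds = []
    start = 0
    for size in sizes:
        bounds.append((start, start + size))
        start += size
    return WeightPool(pooled, tuple(bounds))


def sample_dosages(
    n_variants: int, maf: float, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. Binomial(2, maf) dosages, shape (n_reps, n_variants),
    variant-major stream order."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    return rng.binomial(2, maf, size=(n_variants, n_reps)).T.astype(float)


def simulate_scenario(pool: WeightPool, spec: ScenarioSpec) -> ScenarioResult:
    """Run one scenario: fix weights, redraw dosages per repetition."""
    for name in WEIGHT_GROUPS:
        if pool.group(name).size == 0:
            raise ValueError(f"pool segment for {name!r} group is empty")
    rng = np.random.default_rng(spec.seed)
    n_diff = spec.n_diff
    degenerate = n_diff == 0 and spec.weight_group != "low"
    # weights drawn once per scenario and held fixed over the repetitions;
    # skipping zero-size draws keeps the RNG stream identical across groups
    # when n_diff == 0
    parts = []
    if n_diff:
        parts.append(rng.choice(pool.group(spec.weight_group), size=n_diff))
    if spec.n_variants - n_diff:
        parts.append(rng.choice(pool.group("low"), size=spec.n_variants - n_diff))
    weights = np.concatenate(parts)
    dosages = sample_dosages(spec.n_variants, spec.maf, spec.n_reps, rng)
    values = dosages @ weights
    return ScenarioResult(spec, weights, values, degenerate)


def _sub_seed(master_seed: int, index: int) -> int:
    """Deterministic per-scenario seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def run_grid(
    pool: WeightPool,
    n_variants_list: Sequence[int] = DEFAULT_N_VARIANTS,
    maf_list: Sequence[float] = DEFAULT_MAF_GRID,
    diff_list: Sequence[float] = DEFAULT_DIFF_GRID,
    groups: Sequence[str] = WEIGHT_GROUPS,
    n_reps: int = 500,
    seed: int = 0,
) -> list[ScenarioResult]:
    """One scenario per grid combination (4 x 5 x 9 x 3 = 540 at defaults),
    each independently reproducible from its derived sub-seed."""
    results = []
    index = 0
    for n_variants in n_variants_list:
        for maf in maf_list:
            for group in groups:
                for diff in diff_list:
                    spec = ScenarioSpec(
                        n_variants=n_variants,
                        maf=maf,
                        diff_proportion=diff,
                        weight_group=group,
                        n_reps=n_reps,
                        seed=_sub_seed(seed, index),
                    )
                    results.append(simulate_scenario(pool, spec))
                    index += 1
    return results


@dataclass(frozen=True)
class ECDF:
    """Right-continuous empirical CDF: F(x) = #{values <= x} / n."""

    support: np.ndarray  # sorted sample values
    probabilities: np.ndarray  # cumulative probability at each support point

    def __call__(self, x) -> np.ndarray | float:
        idx = np.searchsorted(self.support, x, side="right")
        out = idx / self.support.size
        return float(out) if np.isscalar(x) else out


def ecdf(values) -> ECDF:
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("cannot build an ECDF from an empty sample")
    return ECDF(x, np.arange(1, x.size + 1) / x.size)


def summarize_vs_baseline(results: Sequence[ScenarioResult]) -> GridSummary:
    """Mean expression per scenario plus difference and ratio against the
    diff_proportion = 0 scenario of the same stratum."""
    rows = []
    baselines: dict[tuple, float] = {}
    for res in results:
        s = res.spec
        if s.diff_proportion == 0:
            baselines[(s.n_variants, s.maf, s.weight_group)] = res.mean
    for res in results:
        s = res.spec
        key = (s.n_variants, s.maf, s.weight_group)
        if key not in baselines:
            raise ValueError(f"missing diff_proportion = 0 baseline for stratum {key}")
        base = baselines[key]
        mean = res.mean
        ratio = mean / base if abs(base) >= 1e-12 else np.nan
        rows.append({
            "n_variants": s.n_variants,
            "maf": s.maf,
            "diff_proportion": s.diff_proportion,
            "weight_group": s.weight_group,
            "mean": mean,
            "diff_vs_baseline": mean - base,
            "ratio_vs_baseline": ratio,
        })
    return GridSummary(pd.DataFrame(rows))


def plot_ecdf_panels(results: Sequence[ScenarioResult], out_dir: str | Path) -> list[Path]:
    """One panel per (n_variants, weight_group) with ECDF lines colored by
    differentiated proportion, faceted over MAF."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panels: dict[tuple[int, str], list[ScenarioResult]] = {}
    for res in results:
        panels.setdefault((res.spec.n_variants, res.spec.weight_group), []).append(res)
    written = []
    for (n_variants, group), members in sorted(panels.items()):
        mafs = sorted({r.spec.maf for r in members})
        fig, axes = plt.subplots(1, len(mafs), figsize=(3 * len(mafs), 3), squeeze=False)
        for ax, maf in zip(axes[0], mafs):
            for res in sorted(
                (r for r in members if r.spec.maf == maf),
                key=lambda r: r.spec.diff_proportion,
            ):
                F = ecdf(res.values)
                ax.step(F.support, F.probabilities, where="post",
                        label=f"{res.spec.diff_proportion:g}")
            ax.set_title(f"MAF={maf:g}")
            ax.set_xlabel("predicted expression")
        axes[0][0].set_ylabel("ECDF")
        axes[0][-1].legend(title="diff prop.", fontsize=6)
        fig.suptitle(f"{n_variants} variants, {group} weight group")
        fig.tight_layout()
        path = out_dir / f"ecdf_{n_variants}variants_{group}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
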