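"""Chiasma scoring and distributional statistics.

Chiasmata are scored cytologically from metaphase I bivalent shapes: a rod
bivalent carries one chiasma, a ring bivalent two, a pair of univalents
none. The per-cell chiasma count is the sum over bivalents; this caps each
bivalent at two and therefore slightly underestimates true crossover
numbers (the simulator retains raw event counts so the bias is measurable).

Distributional tools mirror the classical cytogenetic workflow: sample
mean +/- SD per genotype, a Pearson chi-square goodness-of-fit test against
a Poisson with estimated mean, and the pooled-variance two-sample t-test
computed from summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BivalentRecord",
    "CellSummary",
    "PoissonGofResult",
    "TTestResult",
    "chiasmata_from_shape",
    "cell_chiasma_frequency",
    "cell_summaries_from_table",
    "summarize_genotype",
    "poisson_gof",
    "pooled_t_test",
    "retention_percent",
    "class1_fraction",
    "fold_change",
]

_SHAPE_SCORE = {"univalent_pair": 0, "rod": 1, "ring": 2}


@dataclass(frozen=True)
class BivalentRecord:
    """Shape class of one homolog pair at metaphase I."""

    cell_id: str
    shape_class: str


@dataclass(frozen=True)
class CellSummary:
    """Per-cell chiasma count and number of true bivalents (rods + rings)."""

    cell_id: str
    chiasma_count: int
    bivalent_count: int


@dataclass(frozen=True)
class PoissonGofResult:
    chi2: float
    df: int
    p_value: float
    bin_edges: tuple[int, ...]
    lambda_hat: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float


def chiasmata_from_shape(shape_class: str) -> int:
    """Score one bivalent: univalent_pair -> 0, rod -> 1, ring -> 2."""
    try:
        return _SHAPE_SCORE[shape_class]
    except KeyError:
        raise ValueError(
            f"unknown shape class {shape_class!r}; expected one of {sorted(_SHAPE_SCORE)}"
        ) from None


def cell_chiasma_frequency(records: Sequence[BivalentRecord]) -> CellSummary:
    """Sum per-bivalent chiasma scores for one cell.

    ``bivalent_count`` counts true bivalents only (rods and rings);
    univalent pairs are connections that failed to form.
    """
    if not records:
        raise ValueError("cannot summarise a cell with no bivalent records")
    ids = {r.cell_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records span multiple cells: {sorted(ids)}")
    scores = [chiasmata_from_shape(r.shape_class) for r in records]
    return CellSummary(
        cell_id=records[0].cell_id,
        chiasma_count=sum(scores),
        bivalent_count=sum(s > 0 for s in scores),
    )


def cell_summaries_from_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a cells table to one row per cell.

    Expects the simulator's table dialect (cell_id, genotype, shape_class,
    ...). Returns columns cell_id, genotype, chiasma_count, bivalent_count.
    """
    scores = cells["shape_class"].map(_SHAPE_SCORE)
    if scores.isna().any():
        bad = cells.loc[scores.isna(), "shape_class"].unique()
        raise ValueError(f"unknown shape class labels: {sorted(bad)}")
    out = (
        cells.assign(_score=scores)
        .groupby(["cell_id", "genotype"], sort=True)["_score"]
        .agg(chiasma_count="sum", bivalent_count=lambda s: int((s > 0).sum()))
        .reset_index()
    )
    return out


def summarize_genotype(counts: Iterable[int]) -> tuple[float, float, int]:
    """Sample mean, sample SD (ddof=1) and n of per-cell chiasma counts."""
    x = np.asarray(list(counts), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two cells to estimate mean and SD")
    return float(x.mean()), float(x.std(ddof=1)), int(x.size)


def poisson_gof(counts: Sequence[int], min_expected: float = 1.0) -> PoissonGofResult:
    """Pearson chi-square goodness of fit of counts to Poisson(mean).

    The rate is estimated by the sample mean. Integer categories
    0..max(counts) are used, with an open upper tail; adjacent categories
    are pooled inward from both ends until every expected frequency is at
    least ``min_expected``. Degrees of freedom are (#categories after
    pooling) - 2: one constraint for the total and one for the estimated
    rate.
    """
    x = np.asarray(counts)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.any(x < 0) or not np.issubdtype(x.dtype, np.integer):
        x_f = np.asarray(counts, dtype=float)
        if np.any(x_f < 0) or np.any(x_f != np.floor(x_f)):
            raise ValueError("counts must be non-negative integers")
        x = x_f.astype(int)
    n = x.size
    lam = float(x.mean())
    if lam == 0:
        raise ValueError("degenerate sample: all counts are zero")
    if int(x.min()) == int(x.max()):
        warnings.warn("degenerate sample: all counts identical", RuntimeWarning)
    kmax = int(x.max())
    support = np.arange(kmax + 1)
    probs = stats.poisson.pmf(support, lam)
    probs = np.append(probs, stats.poisson.sf(kmax, lam))  # open upper tail
    observed = np.append(np.bincount(x, minlength=kmax + 1), 0).astype(float)
    expected = n * probs

    # pool inward from both ends until each expected count is adequate
    edges = list(range(len(expected) + 1))  # category i covers [edges[i], edges[i+1])
    obs, exp = observed.tolist(), expected.tolist()
    while len(exp) > 3 and exp[0] < min_expected:
        o, e = obs.pop(0), exp.pop(0)
        obs[0] += o
        exp[0] += e
        edges.pop(1)
    while len(exp) > 3 and exp[-1] < min_expected:
        o, e = obs.pop(), exp.pop()
        obs[-1] += o
        exp[-1] += e
        edges.pop(-2)
    df = len(exp) - 2
    if df < 1:
        raise ValueError("too few categories after pooling; need df >= 1")
    obs_a, exp_a = np.asarray(obs), np.asarray(exp)
    chi2 = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    return PoissonGofResult(
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        bin_edges=tuple(int(e) for e in edges[:-1]),
        lambda_hat=lam,
    )


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Classical pooled-variance two-sample t-test from summary statistics.

    df = n1 + n2 - 2; the p-value is two-sided. Matches
    ``scipy.stats.ttest_ind_from_stats(equal_var=True)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            raise ZeroDivisionError("t undefined: zero variance and equal means")
        return TTestResult(t=float(np.inf) if mean1 > mean2 else float(-np.inf), df=df, p_value=0.0)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TTestResult(t=float(t), df=df, p_value=float(2.0 * stats.t.sf(abs(t), df)))


def retention_percent(mutant_mean: float, wt_mean: float) -> float:
    """Percentage of the wild-type chiasma frequency retained in a mutant."""
    if wt_mean <= 0:
        raise ValueError("wild-type mean must be positive")
    return 100.0 * mutant_mean / wt_mean


def class1_fraction(class1_marker_mean: float, total_co_mean: float) -> float:
    """Percent of crossovers attributable to the interference-sensitive
    (class I) pathway, from the marker-focus mean and the total CO mean."""
    if total_co_mean <= 0:
        raise ValueError("total crossover mean must be positive")
    return 100.0 * class1_marker_mean / total_co_mean


def fold_change(value: float, reference: float) -> float:
    """Simple ratio ``value / reference`` (e.g. mutant vs WT focus counts)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return value / reference
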