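"""Deng's grey relational analysis against a criterion sequence.

Grey relational analysis (GRA) ranks how closely each inspected sequence
x_i tracks a standard sequence x_0 across positions k = 1…n.  Here the
standard sequence is the athletes' pre-jump height and each inspected
sequence is one candidate indicator.  After mean normalization (each
sequence divided by its own mean), the per-position Deng coefficient is

    corr(x0(k), xi(k)) = (Δmin + p·Δmax) / (Δ0i(k) + p·Δmax)

with Δ0i(k) = |x0(k) − xi(k)|, Δmin/Δmax the *global* minimum/maximum
absolute difference over all inspected sequences and positions, and p the
distinguishing coefficient (0.5 by convention).  The grey relational grade
of an indicator is the mean of its coefficients; grades near 1 indicate an
indicator whose trend follows the criterion closely.  Grades are
classified strong (> 0.9), moderate (0.8–0.9 inclusive) or weak (< 0.8).

Because Δmin and Δmax are global, a grade depends on which other
indicators are present in the table; this matches the definition used in
the motivating study and is the standard Deng formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidSpecificationError,
    NormalizationError,
    UndefinedCorrelationError,
)
from .synthetic_cohort import CohortMatrix

__all__ = [
    "GRASequences",
    "GRAResult",
    "mean_normalize",
    "gra_coefficients",
    "gra_grade",
    "rank_and_classify",
    "pearson",
    "run_gra_table",
]

STRONG_CUT = 0.9
WEAK_CUT = 0.8


@dataclass
class GRASequences:
    """A standard sequence x0 plus m inspected sequences of equal length n."""

    standard: np.ndarray
    inspected: np.ndarray  # shape (m, n)
    names: list[str]
    p: float = 0.5

    def __post_init__(self) -> None:
        self.standard = np.asarray(self.standard, dtype=float)
        self.inspected = np.atleast_2d(np.asarray(self.inspected, dtype=float))
        if self.standard.ndim != 1 or self.standard.size < 2:
            raise InvalidSpecificationError("standard sequence needs length n >= 2")
        if self.inspected.shape[1] != self.standard.size:
            raise InvalidSpecificationError(
                "inspected sequences must match the standard sequence length"
            )
        if len(self.names) != self.inspected.shape[0]:
            raise InvalidSpecificationError("one name per inspected sequence required")
        if not 0.0 <= self.p <= 1.0:
            raise InvalidSpecificationError(
                f"distinguishing coefficient p={self.p} outside [0, 1]"
            )


@dataclass
class GRAResult:
    """Normalized sequences, deltas, Deng coefficients and derived grades."""

    names: list[str]
    p: float
    normalized_standard: np.ndarray
    normalized_inspected: np.ndarray
    deltas: np.ndarray  # (m, n), |x0(k) − xi(k)| on normalized data
    delta_min: float
    delta_max: float
    coefficients: np.ndarray  # (m, n)
    grades: np.ndarray | None = None


def mean_normalize(sequence: Sequence[float]) -> np.ndarray:
    """Divide a sequence by its mean; the output has mean exactly 1.

    Undefined (raises) when the mean is not strictly positive — no silent
    shifting is applied to rescue negative-mean sequences.
    """
    x = np.asarray(sequence, dtype=float)
    mu = x.mean()
    if mu <= 0:
        raise NormalizationError(
            f"mean normalization undefined for sequence mean {mu:g} <= 0"
        )
    return x / mu


def gra_coefficients(seqs: GRASequences) -> GRAResult:
    """Compute per-position Deng coefficients for every inspected sequence.

    Δmin and Δmax are taken globally over all sequences and positions.  In
    the degenerate case Δmax = 0 (every sequence identical to the standard
    after normalization) all coefficients are defined as 1.
    """
    x0 = mean_normalize(seqs.standard)
    xi = np.vstack([mean_normalize(row) for row in seqs.inspected])
    deltas = np.abs(xi - x0)
    delta_min = float(deltas.min())
    delta_max = float(deltas.max())
    if delta_max == 0.0:
        coeffs = np.ones_like(deltas)
    else:
        coeffs = (delta_min + seqs.p * delta_max) / (deltas + seqs.p * delta_max)
    return GRAResult(
        names=list(seqs.names),
        p=seqs.p,
        normalized_standard=x0,
        normalized_inspected=xi,
        deltas=deltas,
        delta_min=delta_min,
        delta_max=delta_max,
        coefficients=coeffs,
    )


def gra_grade(result: GRAResult) -> GRAResult:
    """Fill in grades: the arithmetic mean of each sequence's coefficients."""
    result.grades = result.coefficients.mean(axis=1)
    return result


def rank_and_classify(
    grades: Sequence[float],
    names: Sequence[str] | None = None,
    strong_cut: float = STRONG_CUT,
    weak_cut: float = WEAK_CUT,
) -> pd.DataFrame:
    """Rank grades descending and attach strength classes.

    Class boundaries: strong iff grade > ``strong_cut``; weak iff grade <
    ``weak_cut``; moderate on the closed interval in between (a grade of
    exactly 0.9 is moderate).  Ties in grade keep input order.  The result
    is ordered by rank with columns ``rank``, ``indicator``, ``grade``,
    ``class``.
    """
    g = np.asarray(grades, dtype=float)
    if names is None:
        names = [f"seq_{i + 1}" for i in range(g.size)]
    names = list(names)
    if len(names) != g.size:
        raise InvalidSpecificationError("one name per grade required")
    order = np.argsort(-g, kind="stable")
    classes = np.where(g > strong_cut, "strong", np.where(g < weak_cut, "weak", "moderate"))
    out = pd.DataFrame(
        {
            "rank": np.arange(1, g.size + 1),
            "indicator": [names[i] for i in order],
            "grade": g[order],
            "class": classes[order],
        }
    )
    return out.reset_index(drop=True)


class PearsonResult(NamedTuple):
    r: float
    p_value: float
    significant: bool  # two-sided p < 0.05


def pearson(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> PearsonResult:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedCorrelationError(
            "Pearson correlation needs two equal-length sequences of length >= 3"
        )
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined for a zero-variance sequence"
        )
    res = stats.pearsonr(x, y)
    return PearsonResult(
        r=float(res.statistic), p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


def run_gra_table(
    cohort: CohortMatrix,
    p: float = 0.5,
    strong_cut: float = STRONG_CUT,
    weak_cut: float = WEAK_CUT,
    direction_alignment: bool = False,
) -> pd.DataFrame:
    """Full ranked report: Pearson r, significance, grade, class per indicator.

    Every non-criterion column of the cohort is one inspected sequence; the
    criterion column is the standard sequence.  Grades use a single global
    Δmin/Δmax across all indicators.  Rows are ordered by descending grade
    with columns ``Sort``, ``Indicator``, ``Pearson_r``, ``significant``,
    ``Grey_grade``, ``Class``.

    With ``direction_alignment`` (off by default, matching the published
    analysis) a sequence whose Pearson correlation with the criterion is
    negative is reflected about twice its mean before GRA, so a declining
    trend is compared on the same footing as a rising one.
    """
    names = cohort.indicator_names
    x0 = cohort.criterion_values
    xi = cohort.indicator_values()

    pearsons = [pearson(row, x0) for row in xi]
    if direction_alignment:
        xi = xi.copy()
        for i, pr in enumerate(pearsons):
            if pr.r < 0:
                xi[i] = 2.0 * xi[i].mean() - xi[i]

    seqs = GRASequences(standard=x0, inspected=xi, names=names, p=p)
    result = gra_grade(gra_coefficients(seqs))
    ranked = rank_and_classify(result.grades, names, strong_cut, weak_cut)

    by_name = {n: pr for n, pr in zip(names, pearsons)}
    return pd.DataFrame(
        {
            "Sort": ranked["rank"],
            "Indicator": ranked["indicator"],
            "Pearson_r": [by_name[n].r for n in ranked["indicator"]],
            "significant": [by_name[n].significant for n in ranked["indicator"]],
            "Grey_grade": ranked["grade"],
            "Class": ranked["class"],
        }
    )
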