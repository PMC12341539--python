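"""Moment-matched synthetic athlete cohorts.

The raw athlete-by-indicator data behind the pre-jump-height indicator
system were never deposited; only per-indicator summary moments (mean, SD)
and each indicator's Pearson correlation with the criterion (pre-jump
height) are published.  This module turns such a moment specification into
cohort matrices, so every downstream stage — screening, factor reduction,
grey relational analysis — can run on data with the published first and
second moments.

Two generators are provided:

``generate_exact``
    Constructs a cohort whose *sample* means, SDs (n−1 divisor) and
    indicator–criterion Pearson correlations equal the specification to
    floating-point accuracy.  This requires n ≥ m+2 where m counts all
    variables (indicators plus criterion), because the centered random
    matrix must have full column rank.

``generate_sampled``
    Draws i.i.d. rows from the multivariate normal implied by the
    specification; sample moments then match only in expectation.  This is
    the mode for cohort sizes below the rank-feasibility bound (e.g. the
    original 16-athlete scale with 17 variables).

Only criterion correlations are published, so the full correlation matrix
is completed under a single-latent-factor assumption: the unknown
indicator–indicator correlation is the product r_i · r_j
(:func:`build_target_correlation` with ``fill_strategy="rank_one"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import (
    CohortParseError,
    InfeasibleExactMatchError,
    InvalidSpecificationError,
    SingularDataError,
)

__all__ = [
    "MomentSpec",
    "CohortMatrix",
    "build_target_correlation",
    "generate_exact",
    "generate_sampled",
]

#: floor applied to eigenvalues when repairing a completed correlation matrix
EIG_CLIP = 1e-6

#: bounded retries when a random draw yields a singular empirical covariance
MAX_REDRAWS = 5


@dataclass(frozen=True)
class MomentSpec:
    """Target moments for a synthetic cohort.

    Parameters
    ----------
    indicator_names
        Unique labels, one per indicator.
    means, sds
        Per-indicator target mean and standard deviation (SDs must be
        strictly positive).
    criterion_name, criterion_mean, criterion_sd
        The criterion variable (pre-jump height in the motivating study).
    criterion_corrs
        Target Pearson correlation of each indicator with the criterion;
        every value must lie strictly inside (−1, 1).
    """

    indicator_names: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    criterion_name: str
    criterion_mean: float
    criterion_sd: float
    criterion_corrs: tuple[float, ...]

    def __post_init__(self) -> None:
        names = tuple(self.indicator_names)
        object.__setattr__(self, "indicator_names", names)
        object.__setattr__(self, "means", tuple(float(v) for v in self.means))
        object.__setattr__(self, "sds", tuple(float(v) for v in self.sds))
        object.__setattr__(
            self, "criterion_corrs", tuple(float(v) for v in self.criterion_corrs)
        )
        m = len(names)
        if len(set(names)) != m:
            raise InvalidSpecificationError("indicator names must be unique")
        if self.criterion_name in names:
            raise InvalidSpecificationError(
                "criterion name collides with an indicator name"
            )
        if not (len(self.means) == len(self.sds) == len(self.criterion_corrs) == m):
            raise InvalidSpecificationError(
                "indicator_names, means, sds and criterion_corrs must have equal length"
            )
        if any(s <= 0 for s in self.sds) or self.criterion_sd <= 0:
            raise InvalidSpecificationError("all SDs must be strictly positive")
        if any(abs(r) >= 1 for r in self.criterion_corrs):
            raise InvalidSpecificationError(
                "all criterion correlations must satisfy |r| < 1"
            )

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_names)

    @property
    def column_names(self) -> list[str]:
        """Criterion first, then indicators in specification order."""
        return [self.criterion_name, *self.indicator_names]

    @property
    def all_means(self) -> np.ndarray:
        return np.array([self.criterion_mean, *self.means])

    @property
    def all_sds(self) -> np.ndarray:
        return np.array([self.criterion_sd, *self.sds])

    @classmethod
    def from_dict(cls, payload: dict) -> "MomentSpec":
        """Build from the YAML/JSON layout::

            criterion: {name: ..., mean: ..., sd: ...}
            indicators:
              - {name: ..., mean: ..., sd: ..., r: ...}
        """
        try:
            crit = payload["criterion"]
            inds = payload["indicators"]
            return cls(
                indicator_names=tuple(d["name"] for d in inds),
                means=tuple(d["mean"] for d in inds),
                sds=tuple(d["sd"] for d in inds),
                criterion_name=crit["name"],
                criterion_mean=float(crit["mean"]),
                criterion_sd=float(crit["sd"]),
                criterion_corrs=tuple(d["r"] for d in inds),
            )
        except (KeyError, TypeError) as exc:
            raise InvalidSpecificationError(
                f"malformed moment specification: missing key {exc}"
            ) from exc

    def to_dict(self) -> dict:
        return {
            "criterion": {
                "name": self.criterion_name,
                "mean": self.criterion_mean,
                "sd": self.criterion_sd,
            },
            "indicators": [
                {"name": n, "mean": m, "sd": s, "r": r}
                for n, m, s, r in zip(
                    self.indicator_names, self.means, self.sds, self.criterion_corrs
                )
            ],
        }


@dataclass
class CohortMatrix:
    """An athletes × variables numeric table with a designated criterion column.

    The criterion column holds the standard sequence x0 for grey relational
    analysis; every other column is an inspected sequence.
    """

    frame: pd.DataFrame
    criterion: str

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise CohortParseError(f"duplicate column names: {dupes}")
        if cols.count(self.criterion) != 1:
            raise CohortParseError(
                f"criterion column {self.criterion!r} must appear exactly once"
            )
        if len(self.frame) < 3:
            raise CohortParseError(
                f"cohort needs at least 3 rows, got {len(self.frame)}"
            )
        if self.frame.isna().any().any():
            rows = self.frame.index[self.frame.isna().any(axis=1)].tolist()
            raise CohortParseError(f"missing values in rows {rows}")
        non_numeric = [
            c for c in cols if not np.issubdtype(self.frame[c].dtype, np.number)
        ]
        if non_numeric:
            raise CohortParseError(f"non-numeric columns: {non_numeric}")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def indicator_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.criterion]

    @property
    def criterion_values(self) -> np.ndarray:
        return self.frame[self.criterion].to_numpy(dtype=float)

    def indicator_values(self) -> np.ndarray:
        """(m, n) array of inspected sequences, one row per indicator."""
        return self.frame[self.indicator_names].to_numpy(dtype=float).T


def build_target_correlation(
    criterion_corrs: Sequence[float], fill_strategy: str = "rank_one"
) -> np.ndarray:
    """Complete a full correlation matrix from criterion correlations only.

    The criterion occupies row/column 0.  Under ``rank_one`` the unknown
    indicator–indicator entry (i, j) is filled with r_i · r_j — exactly the
    correlation structure of variables loading on a single latent factor
    that the criterion measures without error.  Under ``zero`` indicators
    are mutually uncorrelated given nothing (off-diagonal 0), which is not
    positive definite in general and is likewise repaired.

    Positive definiteness is enforced by clipping eigenvalues at ``EIG_CLIP``,
    reconstructing, and rescaling to unit diagonal.
    """
    r = np.asarray(criterion_corrs, dtype=float)
    if r.ndim != 1:
        raise InvalidSpecificationError("criterion_corrs must be a 1-D sequence")
    if np.any(np.abs(r) >= 1):
        raise InvalidSpecificationError("all |r| must be < 1")
    if fill_strategy not in {"rank_one", "zero"}:
        raise InvalidSpecificationError(f"unknown fill_strategy {fill_strategy!r}")

    m = r.size + 1
    R = np.eye(m)
    R[0, 1:] = r
    R[1:, 0] = r
    if fill_strategy == "rank_one":
        R[1:, 1:] = np.outer(r, r)
        np.fill_diagonal(R, 1.0)

    w = np.linalg.eigvalsh(R)
    if w.min() <= EIG_CLIP:
        vals, vecs = np.linalg.eigh(R)
        vals = np.clip(vals, EIG_CLIP, None)
        R = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        # the repair can perturb the published criterion correlations; keep
        # the perturbation, as exact PDness takes precedence over the fill
    return R


def _cohort_from_matrix(data: np.ndarray, spec: MomentSpec) -> CohortMatrix:
    frame = pd.DataFrame(data, columns=spec.column_names)
    return CohortMatrix(frame=frame, criterion=spec.criterion_name)


def generate_exact(spec: MomentSpec, n: int, seed: int) -> CohortMatrix:
    """Generate a cohort whose sample moments equal the specification exactly.

    Construction: draw an n × m standard-normal matrix, center its columns,
    whiten against the empirical covariance (n−1 divisor), re-impose the
    completed target correlation through its Cholesky factor, then scale by
    the target SDs and shift by the target means.  Sample means, SDs and
    all correlations of the output therefore equal the targets to roundoff.

    Raises
    ------
    InfeasibleExactMatchError
        If n < m+2 (centered draws cannot have full column rank with margin).
    SingularDataError
        If ``MAX_REDRAWS`` consecutive draws give a singular covariance
        (probability zero for continuous draws; guards degenerate streams).
    """
    m = spec.n_indicators + 1
    if n < m + 2:
        raise InfeasibleExactMatchError(
            f"exact moment matching with {m} variables needs n >= {m + 2}, got {n};"
            " use generate_sampled for smaller cohorts"
        )
    R = build_target_correlation(spec.criterion_corrs, "rank_one")
    L = np.linalg.cholesky(R)

    rng = np.random.default_rng(seed)
    for _ in range(MAX_REDRAWS):
        X = rng.standard_normal((n, m))
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / (n - 1)
        try:
            C = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            continue
        break
    else:
        raise SingularDataError(
            f"empirical covariance singular after {MAX_REDRAWS} draws"
        )

    # Z has exact zero column means and exact identity sample covariance
    Z = scipy.linalg.solve_triangular(C, Xc.T, lower=True).T
    Y = Z @ L.T
    data = Y * spec.all_sds + spec.all_means
    return _cohort_from_matrix(data, spec)


def generate_sampled(spec: MomentSpec, n: int, seed: int) -> CohortMatrix:
    """Draw n i.i.d. athletes from the multivariate normal implied by the spec.

    Sample moments converge to the targets as n grows but match only in
    expectation; this is the mode for cohorts too small for exact matching.
    """
    if n < 3:
        raise InvalidSpecificationError(f"cohort needs n >= 3 rows, got {n}")
    R = build_target_correlation(spec.criterion_corrs, "rank_one")
    sds = spec.all_sds
    cov = R * np.outer(sds, sds)
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, len(sds)))
    data = Z @ L.T + spec.all_means
    return _cohort_from_matrix(data, spec)
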