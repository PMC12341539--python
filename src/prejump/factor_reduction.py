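"""Diagnostics-gated principal-component reduction of indicator blocks.

Each primary index (anthropometry, physical quality, specialized technique,
perceptual ability, psychological quality) groups several measured
indicators.  The block is streamlined into a few representative indicators
by the SPSS-style sequence: KMO sampling adequacy and Bartlett's test of
sphericity gate the analysis; principal components of the correlation
matrix with eigenvalue strictly greater than 1 are retained; varimax
rotation (Kaiser row normalization on by default) sharpens the structure;
each indicator is assigned to the component carrying its largest absolute
loading, and the strongest assigned indicator above a loading threshold
(0.4) represents the component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateKMOError,
    DiagnosticsUnavailableError,
    InvalidMatrixError,
)
from .synthetic_cohort import CohortMatrix

__all__ = [
    "FactorSolution",
    "kmo",
    "bartlett_sphericity",
    "extract_components",
    "varimax",
    "varimax_criterion",
    "select_representatives",
    "reduce_block",
]

logger = logging.getLogger(__name__)


class KMOResult(NamedTuple):
    overall: float
    per_indicator: np.ndarray  # per-variable MSA values


class BartlettResult(NamedTuple):
    chi2: float
    df: int
    p_value: float


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InvalidMatrixError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise InvalidMatrixError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise InvalidMatrixError("correlation matrix must have unit diagonal")
    return R


def kmo(correlation_matrix: np.ndarray) -> KMOResult:
    """Kaiser–Meyer–Olkin measure of sampling adequacy.

    Compares observed correlations r_ij with the anti-image partial
    correlations q_ij obtained from the scaled inverse of the matrix:

        KMO = Σ_{i≠j} r_ij² / (Σ_{i≠j} r_ij² + Σ_{i≠j} q_ij²)

    Also returns the per-variable measures (same ratio restricted to row i).
    Values above 0.5 are conventionally deemed adequate for factoring.
    """
    R = _check_corr(correlation_matrix)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise DiagnosticsUnavailableError(
            "correlation matrix is singular; KMO undefined"
        ) from exc
    if not np.all(np.isfinite(Rinv)) or np.linalg.cond(R) > 1e12:
        raise DiagnosticsUnavailableError(
            "correlation matrix is numerically singular; KMO undefined"
        )
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)  # anti-image partial correlations
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.where(off, R, 0.0) ** 2
    q2 = np.where(off, Q, 0.0) ** 2
    num = r2.sum()
    den = num + q2.sum()
    if num == 0.0:
        raise DegenerateKMOError(
            "all off-diagonal correlations are zero; KMO is 0/0"
        )
    per = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    return KMOResult(overall=float(num / den), per_indicator=per)


def bartlett_sphericity(correlation_matrix: np.ndarray, n: int) -> BartlettResult:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = −(n − 1 − (2p + 5)/6) · ln det(R) on p(p−1)/2 degrees of freedom,
    where p is the number of indicators and n the sample size.  A small
    p-value licenses factor extraction.
    """
    R = _check_corr(correlation_matrix)
    p = R.shape[0]
    if n <= p:
        raise InvalidMatrixError(f"sample size n={n} must exceed p={p} indicators")
    det = np.linalg.det(R)
    if det <= 0:
        raise InvalidMatrixError(f"det(R) = {det:g} is not positive")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(det)
    df = p * (p - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return BartlettResult(chi2=float(chi2), df=df, p_value=p_value)


def extract_components(
    correlation_matrix: np.ndarray, eigen_cut: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """PCA extraction on a correlation matrix with the Kaiser criterion.

    Returns ``(eigenvalues, loadings)``: all eigenvalues sorted descending
    (ties broken by original position), and the loading matrix for the
    components whose eigenvalue is *strictly* greater than ``eigen_cut``.
    Loading column j is eigenvector_j · sqrt(eigenvalue_j), sign-fixed so
    the maximum-magnitude entry of each column is positive.
    """
    R = _check_corr(correlation_matrix)
    w, V = np.linalg.eigh(R)
    order = np.argsort(-w, kind="stable")
    w = w[order]
    V = V[:, order]
    keep = w > eigen_cut
    w_keep = np.clip(w[keep], 0.0, None)
    loadings = V[:, keep] * np.sqrt(w_keep)
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return w, loadings


def varimax_criterion(loadings: np.ndarray) -> float:
    """Varimax objective: sum over components of the variance of squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation toward simple structure.

    Maximizes the variance of squared loadings within each component via the
    classic SVD iteration, optionally after Kaiser row normalization (rows
    scaled to unit communality during rotation, rescaled afterwards — the
    SPSS default).  Returns ``(rotated_loadings, rotation_matrix)`` with
    ``rotated = loadings @ rotation_matrix`` and the rotation orthogonal.

    A single-column input is returned unchanged.  On non-convergence the
    best rotation found so far is returned with a warning, never an
    exception.
    """
    A = np.asarray(loadings, dtype=float)
    if A.ndim != 2:
        raise InvalidMatrixError("loadings must be 2-D")
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)

    h = np.sqrt((A**2).sum(axis=1))
    if kaiser_normalize:
        scale = np.where(h > 0, h, 1.0)
        A_work = A / scale[:, None]
    else:
        scale = np.ones(p)
        A_work = A

    T = np.eye(k)
    d_old = 0.0
    converged = False
    for _ in range(max_iter):
        B = A_work @ T
        u, s, vt = np.linalg.svd(
            A_work.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        T = u @ vt
        d = s.sum()
        if d_old != 0.0 and d - d_old < tol * d:
            converged = True
            break
        d_old = d
    if not converged:
        warnings.warn(
            f"varimax did not converge in {max_iter} iterations; "
            "returning best rotation found",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("varimax non-convergence after %d iterations", max_iter)

    rotated = (A_work @ T) * scale[:, None]
    # re-apply the sign convention after rotation
    for j in range(k):
        col = rotated[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            rotated[:, j] = -col
            T[:, j] = -T[:, j]
    return rotated, T


def select_representatives(
    rotated_loadings: np.ndarray,
    indicator_names: Sequence[str],
    loading_threshold: float = 0.4,
) -> tuple[dict[int, str | None], dict[int, list[str]]]:
    """Choose one representative indicator per rotated component.

    Every indicator is assigned to the component on which its absolute
    loading is largest; within each component, the assigned indicator with
    the largest absolute loading is the representative, provided that
    loading exceeds ``loading_threshold``.  Components whose best assigned
    loading does not exceed the threshold get representative ``None``.

    Returns ``(representatives, assigned)`` keyed by component index; the
    ``assigned`` lists preserve input indicator order and partition the
    indicators.
    """
    L = np.asarray(rotated_loadings, dtype=float)
    names = list(indicator_names)
    if L.size == 0 or L.shape[1] == 0:
        raise InvalidMatrixError("no components to select representatives from")
    if L.shape[0] != len(names):
        raise InvalidMatrixError("loadings and indicator names are not conformable")

    assignment = np.argmax(np.abs(L), axis=1)
    representatives: dict[int, str | None] = {}
    assigned: dict[int, list[str]] = {}
    for j in range(L.shape[1]):
        members = [i for i in range(len(names)) if assignment[i] == j]
        assigned[j] = [names[i] for i in members]
        if not members:
            representatives[j] = None
            continue
        best = max(members, key=lambda i: abs(L[i, j]))
        if abs(L[best, j]) > loading_threshold:
            representatives[j] = names[best]
        else:
            representatives[j] = None
            logger.warning(
                "component %d: best loading %.3f <= threshold %.3f; no representative",
                j,
                abs(L[best, j]),
                loading_threshold,
            )
    return representatives, assigned


@dataclass
class FactorSolution:
    """Complete record of one block's factor reduction."""

    block_name: str
    indicator_names: list[str]
    correlation_matrix: np.ndarray
    kmo: float
    kmo_per_indicator: np.ndarray
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    n_retained: int
    rotated_loadings: np.ndarray
    contributions: np.ndarray  # percent variance per retained component
    representatives: dict[int, str | None]
    assigned: dict[int, list[str]]
    loading_threshold: float
    diagnostics_ok: bool
    diagnostic_message: str = ""

    @property
    def cumulative_contribution(self) -> float:
        return float(np.sum(self.contributions))

    def representative_names(self) -> list[str]:
        return [r for _, r in sorted(self.representatives.items()) if r is not None]


def reduce_block(
    cohort: CohortMatrix,
    block_name: str,
    columns: Sequence[str],
    kmo_min: float = 0.5,
    bartlett_alpha: float = 0.05,
    eigen_cut: float = 1.0,
    loading_threshold: float = 0.4,
    kaiser_normalize: bool = True,
) -> FactorSolution:
    """Run the full reduction pipeline on one indicator block.

    Sequence: correlation matrix → KMO → Bartlett → PCA extraction →
    varimax → representative selection.  When KMO ≤ ``kmo_min`` or the
    Bartlett p-value ≥ ``bartlett_alpha``, a diagnostic-failure solution is
    returned (``diagnostics_ok=False``) and no components are extracted —
    the block is not silently factored.
    """
    columns = list(columns)
    missing = [c for c in columns if c not in cohort.frame.columns]
    if missing:
        raise InvalidMatrixError(f"block {block_name!r}: unknown columns {missing}")
    X = cohort.frame[columns].to_numpy(dtype=float)
    n = X.shape[0]
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)

    kmo_res = kmo(R)
    bart = bartlett_sphericity(R, n)
    logger.info(
        "block %s: KMO=%.4f (gate > %.2f), Bartlett chi2=%.3f df=%d p=%.3g (gate < %.2f)",
        block_name, kmo_res.overall, kmo_min, bart.chi2, bart.df, bart.p_value,
        bartlett_alpha,
    )

    p = len(columns)
    base = dict(
        block_name=block_name,
        indicator_names=columns,
        correlation_matrix=R,
        kmo=kmo_res.overall,
        kmo_per_indicator=kmo_res.per_indicator,
        bartlett_chi2=bart.chi2,
        bartlett_df=bart.df,
        bartlett_p=bart.p_value,
        loading_threshold=loading_threshold,
    )
    if kmo_res.overall <= kmo_min or bart.p_value >= bartlett_alpha:
        msg = (
            f"diagnostics failed: KMO={kmo_res.overall:.4f} (need > {kmo_min}), "
            f"Bartlett p={bart.p_value:.4g} (need < {bartlett_alpha})"
        )
        return FactorSolution(
            eigenvalues=np.linalg.eigvalsh(R)[::-1],
            n_retained=0,
            rotated_loadings=np.empty((p, 0)),
            contributions=np.empty(0),
            representatives={},
            assigned={},
            diagnostics_ok=False,
            diagnostic_message=msg,
            **base,
        )

    eigenvalues, loadings = extract_components(R, eigen_cut=eigen_cut)
    k = loadings.shape[1]
    if k == 0:
        return FactorSolution(
            eigenvalues=eigenvalues,
            n_retained=0,
            rotated_loadings=loadings,
            contributions=np.empty(0),
            representatives={},
            assigned={},
            diagnostics_ok=True,
            diagnostic_message="no eigenvalue exceeded the retention cut",
            **base,
        )
    rotated, _ = varimax(loadings, kaiser_normalize=kaiser_normalize)
    contributions = (rotated**2).sum(axis=0) / p * 100.0
    reps, assigned = select_representatives(rotated, columns, loading_threshold)
    for j, rep in sorted(reps.items()):
        logger.info(
            "block %s component %d: contribution %.2f%%, representative %s",
            block_name, j + 1, contributions[j], rep,
        )
    return FactorSolution(
        eigenvalues=eigenvalues,
        n_retained=k,
        rotated_loadings=rotated,
        contributions=contributions,
        representatives=reps,
        assigned=assigned,
        diagnostics_ok=True,
        **base,
    )
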