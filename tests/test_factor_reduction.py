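"""Factor reduction: KMO, Bartlett, extraction, varimax, representatives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prejump import (
    CohortMatrix,
    bartlett_sphericity,
    extract_components,
    kmo,
    reduce_block,
    select_representatives,
    varimax,
)
from prejump.errors import (
    DegenerateKMOError,
    DiagnosticsUnavailableError,
    InvalidMatrixError,
)
from prejump.factor_reduction import varimax_criterion


def random_correlation(p: int, seed: int, n: int = 60) -> np.ndarray:
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    R = np.corrcoef(X, rowvar=False)
    return (R + R.T) / 2


def equicorrelation(p: int, r: float) -> np.ndarray:
    R = np.full((p, p), r)
    np.fill_diagonal(R, 1.0)
    return R


class TestKMO:
    @pytest.mark.parametrize("r", [0.1, -0.5, 0.9])
    def test_two_variable_kmo_is_half(self, r):
        # with two variables the partial correlation equals the simple one
        assert kmo(equicorrelation(2, r)).overall == pytest.approx(0.5)

    @pytest.mark.parametrize("p,seed", [(3, 0), (4, 1), (5, 2), (5, 3)])
    def test_matches_pairwise_partial_correlation_oracle(self, p, seed):
        """Inverse-matrix KMO equals KMO built from Schur-complement partials."""
        R = random_correlation(p, seed)
        r2 = q2 = 0.0
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                rest = [k for k in range(p) if k not in (i, j)]
                if rest:
                    sub = np.ix_([i, j], rest)
                    cond = R[np.ix_([i, j], [i, j])] - R[sub] @ np.linalg.solve(
                        R[np.ix_(rest, rest)], R[np.ix_(rest, [i, j])]
                    )
                    pc = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
                else:
                    pc = R[i, j]
                r2 += R[i, j] ** 2
                q2 += pc**2
        assert kmo(R).overall == pytest.approx(r2 / (r2 + q2), abs=1e-10)

    def test_identity_matrix_is_degenerate(self):
        with pytest.raises(DegenerateKMOError):
            kmo(np.eye(4))

    def test_singular_matrix_unavailable(self):
        R = equicorrelation(3, 0.5)
        R[2] = R[1]
        R[:, 2] = R[:, 1]
        R[2, 2] = 1.0
        with pytest.raises((DiagnosticsUnavailableError, InvalidMatrixError)):
            kmo(R)


class TestBartlett:
    def test_identity_gives_zero_statistic(self):
        res = bartlett_sphericity(np.eye(5), n=30)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_variable_closed_form(self):
        # det = 1 - r^2 = 0.75, multiplier = 20 - 1 - 9/6 = 17.5
        res = bartlett_sphericity(equicorrelation(2, 0.5), n=20)
        assert res.chi2 == pytest.approx(-17.5 * np.log(0.75))
        assert res.df == 1

    def test_sample_size_must_exceed_dimension(self):
        with pytest.raises(InvalidMatrixError):
            bartlett_sphericity(np.eye(5), n=5)


class TestExtractComponents:
    def test_identity_retains_nothing_under_strict_cut(self):
        w, loadings = extract_components(np.eye(4))
        np.testing.assert_allclose(w, np.ones(4))
        assert loadings.shape == (4, 0)

    def test_equicorrelation_spectrum_and_loadings(self):
        # closed form: 1 + (p-1)r and (p-1)-fold 1 - r
        w, loadings = extract_components(equicorrelation(3, 0.5))
        np.testing.assert_allclose(w, [2.0, 0.5, 0.5])
        assert loadings.shape == (3, 1)
        np.testing.assert_allclose(loadings[:, 0], np.sqrt(2 / 3), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_eigenvalue_sum_equals_dimension(self, seed):
        p = 4 + seed % 3
        w, _ = extract_components(random_correlation(p, seed))
        assert w.sum() == pytest.approx(p, abs=1e-8)
        assert np.all(np.diff(w) <= 1e-12)  # descending

    def test_sign_convention_makes_dominant_entry_positive(self):
        _, loadings = extract_components(random_correlation(5, 9))
        for j in range(loadings.shape[1]):
            col = loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestVarimax:
    def test_perfect_simple_structure_is_a_fixed_point(self):
        L = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        rotated, T = varimax(L, kaiser_normalize=False)
        np.testing.assert_allclose(np.abs(rotated), np.abs(L), atol=1e-8)
        np.testing.assert_allclose(T @ T.T, np.eye(2), atol=1e-10)

    def test_single_column_returned_unchanged(self):
        L = np.array([[0.8], [0.7]])
        rotated, T = varimax(L)
        np.testing.assert_allclose(rotated, L)
        np.testing.assert_allclose(T, np.eye(1))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_planar_grid_search_oracle(self, seed):
        """2-component optimum found by a 0.001-radian angle sweep."""
        rng = np.random.default_rng(seed)
        L = rng.normal(scale=0.5, size=(6, 2))
        rotated, _ = varimax(L, kaiser_normalize=False)
        best = max(
            varimax_criterion(
                L @ np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            )
            for t in np.arange(0.0, np.pi / 2, 0.001)
        )
        assert varimax_criterion(rotated) == pytest.approx(best, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels_rotation_criterion(self, seed):
        """Independent GPA-based rotation reaches the same criterion value."""
        statsmodels_rotation = pytest.importorskip(
            "statsmodels.multivariate.factor_rotation"
        )
        rng = np.random.default_rng(100 + seed)
        _, L = extract_components(random_correlation(6, 200 + seed))
        if L.shape[1] < 2:
            pytest.skip("needs at least two retained components")
        rotated, _ = varimax(L, kaiser_normalize=False)
        ref, _ = statsmodels_rotation.rotate_factors(L, "varimax")
        assert varimax_criterion(rotated) == pytest.approx(
            varimax_criterion(ref), abs=1e-6
        )

    @pytest.mark.parametrize("kaiser", [True, False])
    @pytest.mark.parametrize("seed", range(3))
    def test_rotation_preserves_communalities_and_orthogonality(self, seed, kaiser):
        _, L = extract_components(random_correlation(7, 50 + seed))
        rotated, T = varimax(L, kaiser_normalize=kaiser)
        np.testing.assert_allclose(T @ T.T, np.eye(T.shape[0]), atol=1e-10)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-8
        )

    def test_no_further_rotation_improves_the_criterion(self):
        rng = np.random.default_rng(77)
        L = rng.normal(scale=0.5, size=(8, 2))
        rotated, _ = varimax(L, kaiser_normalize=False, tol=1e-12)
        base = varimax_criterion(rotated)
        for t in np.linspace(0.001, np.pi / 2, 200):
            G = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            assert varimax_criterion(rotated @ G) <= base + 1e-9


class TestSelectRepresentatives:
    def test_max_loading_assignment_rule(self):
        L = np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.6]])
        reps, assigned = select_representatives(L, ["i1", "i2", "i3"])
        assert reps == {0: "i1", 1: "i2"}
        assert assigned == {0: ["i1"], 1: ["i2", "i3"]}

    def test_below_threshold_component_gets_no_representative(self):
        reps, _ = select_representatives(np.array([[0.3]]), ["only"])
        assert reps == {0: None}

    def test_every_indicator_assigned_to_exactly_one_component(self):
        rng = np.random.default_rng(8)
        L = rng.normal(size=(9, 3))
        names = [f"v{i}" for i in range(9)]
        _, assigned = select_representatives(L, names)
        pooled = [n for members in assigned.values() for n in members]
        assert sorted(pooled) == sorted(names)

    def test_empty_loading_matrix_rejected(self):
        with pytest.raises(InvalidMatrixError):
            select_representatives(np.empty((0, 0)), [])


def latent_factor_cohort(k: int, n: int, seed: int) -> tuple[CohortMatrix, list[str]]:
    """k orthogonal latent factors, 3 indicators each with loadings .9/.8/.7."""
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n, k))
    cols, expected = {}, []
    for j in range(k):
        for rank, lam in enumerate((0.9, 0.8, 0.7)):
            noise = rng.standard_normal(n) * np.sqrt(1 - lam**2)
            cols[f"f{j}_i{rank}"] = lam * factors[:, j] + noise
        expected.append(f"f{j}_i0")
    cols["crit"] = rng.standard_normal(n) + 5.0
    return CohortMatrix(pd.DataFrame(cols), criterion="crit"), expected


class TestReduceBlock:
    def test_strong_one_factor_block_retains_one_component(self):
        spec_cols = [f"v{i}" for i in range(5)]
        rng = np.random.default_rng(3)
        f = rng.standard_normal(200)
        frame = pd.DataFrame(
            {c: np.sqrt(0.6) * f + np.sqrt(0.4) * rng.standard_normal(200)
             for c in spec_cols}
        )
        frame["crit"] = rng.standard_normal(200)
        cohort = CohortMatrix(frame, criterion="crit")
        sol = reduce_block(cohort, "one_factor", spec_cols)
        assert sol.diagnostics_ok
        assert sol.kmo > 0.5
        assert sol.bartlett_p < 0.05
        assert sol.n_retained == 1

    def test_independent_indicators_fail_the_diagnostic_gate(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {f"v{i}": rng.standard_normal(200) for i in range(5)}
        )
        frame["crit"] = rng.standard_normal(200)
        sol = reduce_block(CohortMatrix(frame, criterion="crit"), "null", [f"v{i}" for i in range(5)])
        assert not sol.diagnostics_ok
        assert sol.n_retained == 0
        assert "diagnostics failed" in sol.diagnostic_message

    @pytest.mark.parametrize("k", [2, 3])
    def test_recovers_latent_factor_count_and_representatives(self, k):
        cohort, expected = latent_factor_cohort(k, n=500, seed=k)
        block = [c for c in cohort.frame.columns if c != "crit"]
        sol = reduce_block(cohort, "latent", block)
        assert sol.diagnostics_ok
        assert sol.n_retained == k
        assert sorted(sol.representative_names()) == sorted(expected)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(p=st.integers(3, 7), seed=st.integers(0, 10_000))
def test_extraction_plus_rotation_conserves_structure(p, seed):
    """Eigenvalues sum to p; varimax preserves each row's communality."""
    R = random_correlation(p, seed)
    w, L = extract_components(R)
    assert w.sum() == pytest.approx(p, abs=1e-8)
    if L.shape[1] >= 2:
        rotated, _ = varimax(L)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-8
        )
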