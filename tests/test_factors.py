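import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riverwq.factors import (
    bartlett_sphericity,
    classify_loadings,
    kmo,
    loadings_table,
    pca_fa,
    percent_variance,
    suitability,
    varimax_rotate,
    _varimax_criterion,
)


def equicorrelated(p, r):
    return np.full((p, p), r) + (1 - r) * np.eye(p)


def random_loadings(rng, p=4, k=2):
    L = rng.normal(size=(p, k))
    # keep communalities < 1 as for genuine correlation loadings
    return L / (np.abs(L).sum(axis=1, keepdims=True) + 0.5)


class TestPcaFa:
    def test_eigenvalue_sum_equals_variable_count(self, tiny):
        matrix, _ = tiny
        fl = pca_fa(matrix.values, retain=3)
        assert fl.eigenvalues.sum() == pytest.approx(11.0, abs=1e-8)

    def test_percent_variance_accounting(self):
        assert percent_variance([4.76], 11)[0] == pytest.approx(43.27, abs=0.01)
        assert percent_variance([1.87], 11)[0] == pytest.approx(17.00, abs=0.01)

    def test_independent_columns_are_spherical(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(5000, 6)))
        fl = pca_fa(X, retain=6)
        assert np.allclose(fl.eigenvalues, 1.0, atol=0.12)
        assert np.allclose(fl.percent_variance, 100 / 6, atol=2.0)

    def test_zero_variance_column_named_in_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        with pytest.raises(ValueError, match="b"):
            pca_fa(X, retain=1)

    def test_loadings_reproduce_correlations(self):
        # with all factors retained, L L' reconstructs R exactly
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 4)) @ rng.normal(size=(4, 4)))
        fl = pca_fa(X, retain=4)
        L = fl.loadings.to_numpy()
        assert np.allclose(L @ L.T, X.corr().to_numpy(), atol=1e-8)


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = pd.DataFrame([[0.9, 0.0], [0.85, 0.0], [0.0, 0.8], [0.0, 0.75]])
        fl = pca_fa(pd.DataFrame(np.random.default_rng(2).normal(size=(50, 4))),
                    retain=2)
        fl.loadings = L
        rot = varimax_rotate(fl)
        got = np.sort(np.abs(rot.loadings.to_numpy()).ravel())
        want = np.sort(np.abs(L.to_numpy()).ravel())
        assert np.allclose(got, want, atol=1e-6)

    def test_communalities_preserved(self, tiny):
        matrix, _ = tiny
        fl = pca_fa(matrix.values, retain=3)
        rot = varimax_rotate(fl)
        assert np.allclose(rot.communalities, fl.communalities, atol=1e-8)

    def test_criterion_matches_angle_grid_search(self):
        rng = np.random.default_rng(3)
        L = random_loadings(rng, p=4, k=2)
        fl = pca_fa(pd.DataFrame(rng.normal(size=(50, 4))), retain=2)
        fl.loadings = pd.DataFrame(L, index=fl.loadings.index,
                                   columns=fl.loadings.columns)
        rot = varimax_rotate(fl, kaiser_normalize=False)
        got = _varimax_criterion(rot.loadings.to_numpy())
        best = max(
            _varimax_criterion(L @ np.array(
                [[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]]))
            for t in np.linspace(0, np.pi / 2, 20001))
        assert got == pytest.approx(best, abs=1e-4)

    def test_single_factor_unchanged(self, tiny):
        matrix, _ = tiny
        fl = pca_fa(matrix.values, retain=1)
        rot = varimax_rotate(fl)
        assert rot.loadings.equals(fl.loadings)


class TestDiagnostics:
    def test_kmo_equicorrelated_closed_form(self):
        # p=3, r=0.5: partials are 1/3, KMO = 1.5/(1.5 + 2/3)
        assert kmo(equicorrelated(3, 0.5)) == pytest.approx(0.6923, abs=1e-4)

    def test_kmo_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            A = rng.normal(size=(40, 5))
            R = np.corrcoef(A, rowvar=False)
            assert 0 < kmo(R) <= 1

    def test_kmo_brute_force_partials(self):
        # oracle: pairwise partial correlations from the precision matrix
        rng = np.random.default_rng(5)
        A = rng.normal(size=(60, 4))
        R = np.corrcoef(A, rowvar=False)
        S = np.linalg.inv(R)
        num = den_q = 0.0
        p = 4
        for i in range(p):
            for j in range(p):
                if i != j:
                    num += R[i, j] ** 2
                    den_q += (S[i, j] / np.sqrt(S[i, i] * S[j, j])) ** 2
        assert kmo(R) == pytest.approx(num / (num + den_q), abs=1e-12)

    def test_bartlett_identity_is_null(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), 100)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert df == 10

    def test_bartlett_equicorrelated_worked_example(self):
        chi2, df, p = bartlett_sphericity(equicorrelated(3, 0.5), 100)
        assert chi2 == pytest.approx((99 - 11 / 6) * np.log(2.0), abs=1e-6)
        assert chi2 == pytest.approx(67.35, abs=0.01)
        assert df == 3
        assert p == pytest.approx(stats.chi2.sf(chi2, 3), abs=1e-12)

    def test_bartlett_increases_with_n(self):
        R = equicorrelated(4, 0.3)
        chi_small, _, _ = bartlett_sphericity(R, 50)
        chi_big, _, _ = bartlett_sphericity(R, 500)
        assert chi_big > chi_small

    def test_suitability_on_synthetic_data(self, tiny):
        matrix, _ = tiny
        d = suitability(matrix.values)
        assert 0 < d.kmo <= 1
        assert d.bartlett_df == 55
        assert d.bartlett_p < 0.05  # strongly correlated factor structure


class TestLoadingClassification:
    def test_bands(self, tiny):
        matrix, _ = tiny
        fl = pca_fa(matrix.values, retain=2)
        fl.loadings.iloc[:3, 0] = [0.85, -0.76, 0.42]
        labels = classify_loadings(fl)
        assert labels.iloc[0, 0] == "strong"
        assert labels.iloc[1, 0] == "strong"   # absolute value rule
        assert labels.iloc[2, 0] == "none"

    def test_moderate_band_inclusive(self, tiny):
        matrix, _ = tiny
        fl = pca_fa(matrix.values, retain=1)
        fl.loadings.iloc[:3, 0] = [0.5, 0.7, 0.71]
        labels = classify_loadings(fl)
        assert list(labels.iloc[:3, 0]) == ["moderate", "moderate", "strong"]

    def test_table_layout_has_footer_rows(self, tiny):
        matrix, _ = tiny
        table = loadings_table(varimax_rotate(pca_fa(matrix.values, retain=3)))
        assert list(table.index[-3:]) == ["Eigenvalues", "% of Variance",
                                          "Cumulative %"]
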