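"""Missing-data PCA: scaling, the four fitters, reconstruction and the drop rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import subspace_angles

import surfmap as sm
from surfmap.mdpca import (
    PCAModel,
    autoscale,
    drop_sparse_rows,
    fit_bpca,
    fit_nipals,
    fit_nlpca,
    fit_ppca,
    fit_table,
    impute,
    reconstruct,
    variance_captured,
)
from surfmap.synthetic import GeneratorConfig, generate_table
from surfmap.table import DescriptorSpec, DescriptorTable, TableError


def _table(values, mask=None, sources=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if mask is None:
        mask = np.isfinite(values)
    row_meta = pd.DataFrame(
        {"id": [f"r{i}" for i in range(n)], "charge_class": ["neutral"] * n,
         "designer": [False] * n}
    )
    if sources is None:
        sources = ["computed"] * p
    col_meta = [
        DescriptorSpec(f"d{j}", "molecular" if s == "computed" else "emulsion", s)
        for j, s in enumerate(sources)
    ]
    return DescriptorTable(np.where(mask, values, np.nan), mask, row_meta, col_meta)


# ---------------------------------------------------------------------------
# autoscale
# ---------------------------------------------------------------------------

def test_autoscale_complete_column():
    X, mask, params = autoscale(_table([[1.0, 0.0], [2.0, 1.0], [3.0, 2.0]]))
    np.testing.assert_allclose(X[:, 0], [-1.0, 0.0, 1.0])
    assert params.mean[0] == 2.0 and params.sd[0] == 1.0


def test_autoscale_skips_missing_cells():
    table = _table([[2.0, 1.0], [np.nan, 2.0], [4.0, 3.0]])
    X, mask, params = autoscale(table)
    np.testing.assert_allclose(X[[0, 2], 0], [-0.7071067811865475, 0.7071067811865475])
    assert np.isnan(X[1, 0]) and not mask[1, 0]


def test_autoscale_rejects_constant_column():
    with pytest.raises(TableError, match="d0"):
        autoscale(_table([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))


@given(st.integers(0, 2**31 - 1))
def test_autoscale_observed_moments(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(5.0, 3.0, size=(12, 4))
    mask = rng.random((12, 4)) > 0.2
    mask[:2] = True  # keep every column >= 2 observed
    X, m, _ = autoscale(_table(np.where(mask, values, np.nan)))
    for j in range(4):
        col = X[m[:, j], j]
        assert abs(col.mean()) < 1e-10
        assert np.isclose(col.std(ddof=1), 1.0)


# ---------------------------------------------------------------------------
# NIPALS
# ---------------------------------------------------------------------------

def test_nipals_exact_on_rank_one_matrix():
    rng = np.random.default_rng(0)
    X = np.outer(rng.standard_normal(15), rng.standard_normal(4))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    model = fit_nipals(X, np.ones_like(X, dtype=bool), 1)
    assert model.r2_cumulative[0] == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_nipals_matches_svd_oracle_on_complete_data(seed):
    """Complete-data NIPALS is ordinary PCA: scores/loadings match the SVD per
    component up to sign and per-component R² agrees to 1e-8."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 51))
    p = int(rng.integers(5, 21))
    k = 5
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    mask = np.ones_like(X, dtype=bool)
    model = fit_nipals(X, mask, k)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    den = float((X**2).sum())
    r2_svd = np.cumsum(s[:k] ** 2) / den
    for c in range(k):
        assert abs(np.dot(model.loadings[:, c], Vt[c])) > 1.0 - 1e-8
        t_svd = U[:, c] * s[c]
        cos_t = abs(model.scores[:, c] @ t_svd) / (
            np.linalg.norm(model.scores[:, c]) * np.linalg.norm(t_svd)
        )
        assert cos_t > 1.0 - 1e-8
        assert model.r2_cumulative[c] == pytest.approx(r2_svd[c], abs=1e-8)


def test_nipals_bit_identical_across_runs():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((30, 10))
    mask = rng.random((30, 10)) > 0.15
    m1 = fit_nipals(X, mask, 3)
    m2 = fit_nipals(X, mask, 3)
    assert np.array_equal(m1.scores, m2.scores)
    assert np.array_equal(m1.loadings, m2.loadings)


def test_nipals_loadings_unit_norm_and_canonical_sign():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((25, 8))
    mask = rng.random((25, 8)) > 0.1
    model = fit_nipals(X, mask, 3)
    for c in range(3):
        col = model.loadings[:, c]
        assert np.linalg.norm(col) == pytest.approx(1.0, abs=1e-12)
        assert col[np.argmax(np.abs(col))] > 0


# ---------------------------------------------------------------------------
# PPCA
# ---------------------------------------------------------------------------

def test_ppca_complete_data_spans_principal_subspace():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 8))
    X -= X.mean(axis=0)
    mask = np.ones_like(X, dtype=bool)
    model = fit_ppca(X, mask, 3)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    angles = subspace_angles(model.loadings, Vt[:3].T)
    assert np.max(angles) < 1e-6


def test_ppca_imputation_beats_noise_floor():
    cfg = GeneratorConfig(n_rows=100, n_cols=25, rank=3, noise_sd=0.1,
                          missing_rate=0.10, n_classes=1, seed=42)
    table, truth = generate_table(cfg)
    model = fit_table(table, "ppca", 3)
    filled = impute(model, table)
    hidden = ~table.mask
    rmse = float(np.sqrt(np.mean((filled.values[hidden] - truth.values_full[hidden]) ** 2)))
    assert rmse < 2 * cfg.noise_sd


def test_ppca_deterministic_with_default_init():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((30, 8))
    mask = rng.random((30, 8)) > 0.1
    m1 = fit_ppca(X, mask, 2)
    m2 = fit_ppca(X, mask, 2)
    assert np.array_equal(m1.scores, m2.scores)
    assert np.array_equal(m1.loadings, m2.loadings)


# ---------------------------------------------------------------------------
# BPCA
# ---------------------------------------------------------------------------

def test_bpca_complete_data_agrees_with_pca_subspace():
    # strong low-rank signal: ARD shrinkage is negligible and the principal
    # subspace matches ordinary PCA tightly
    rng = np.random.default_rng(7)
    Z = rng.standard_normal((60, 3)) * [4.0, 3.0, 2.0]
    W = np.linalg.qr(rng.standard_normal((10, 3)))[0]
    X = Z @ W.T + rng.normal(scale=0.05, size=(60, 10))
    X -= X.mean(axis=0)
    mask = np.ones_like(X, dtype=bool)
    model = fit_bpca(X, mask, 3)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    assert np.max(subspace_angles(model.loadings, Vt[:3].T)) < 1e-4


def test_bpca_tracks_ppca_at_low_missingness():
    cfg = GeneratorConfig(n_rows=80, n_cols=20, rank=3, noise_sd=0.1,
                          missing_rate=0.05, n_classes=1, seed=5)
    table, _ = generate_table(cfg)
    X, mask, _ = autoscale(table)
    r2_p = fit_ppca(X, mask, 3).r2_cumulative[-1]
    r2_b = fit_bpca(X, mask, 3).r2_cumulative[-1]
    assert abs(r2_p - r2_b) < 0.02


def test_bpca_deterministic():
    rng = np.random.default_rng(13)
    X = rng.standard_normal((30, 8))
    mask = rng.random((30, 8)) > 0.1
    m1 = fit_bpca(X, mask, 2)
    m2 = fit_bpca(X, mask, 2)
    assert np.array_equal(m1.scores, m2.scores)


# ---------------------------------------------------------------------------
# NLPCA
# ---------------------------------------------------------------------------

def test_nlpca_outperforms_linear_pca_on_curved_manifold():
    """One nonlinear component captures a half-circle that linear PCA cannot."""
    theta = np.linspace(0.0, np.pi, 60)
    P = np.column_stack([np.cos(theta), np.sin(theta)])
    P = (P - P.mean(axis=0)) / P.std(axis=0, ddof=1)
    mask = np.ones_like(P, dtype=bool)
    r2_linear = fit_nipals(P, mask, 1).r2_cumulative[-1]
    r2_nl = fit_nlpca(P, mask, 1, seed=0).r2_cumulative[-1]
    assert r2_nl >= r2_linear + 0.05


def test_nlpca_seed_dependence_and_reproducibility():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((40, 8))
    mask = rng.random((40, 8)) > 0.12
    a = fit_nlpca(X, mask, 3, seed=1)
    b = fit_nlpca(X, mask, 3, seed=2)
    a2 = fit_nlpca(X, mask, 3, seed=1)
    assert np.array_equal(a.scores, a2.scores)  # same seed: reproducible
    assert np.std(a.scores[:, 0] - b.scores[:, 0]) > 0  # different seed: different PCs


# ---------------------------------------------------------------------------
# reconstruct / variance_captured
# ---------------------------------------------------------------------------

def _toy_model(scores, loadings, method="nipals"):
    scores = np.asarray(scores, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    return PCAModel(method=method, k=scores.shape[1], scores=scores, loadings=loadings,
                    scaling=None, r2_cumulative=np.zeros(scores.shape[1]),
                    converged=True, iterations=0)


def test_reconstruct_zero_components_is_zero_matrix():
    model = _toy_model(np.ones((3, 2)), np.ones((4, 2)))
    assert np.array_equal(reconstruct(model, 0), np.zeros((3, 4)))
    with pytest.raises(ValueError):
        reconstruct(model, 3)


def test_reconstruct_exact_at_full_rank_and_nested_rss_monotone():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((20, 6))
    X -= X.mean(axis=0)
    mask = np.ones_like(X, dtype=bool)
    model = fit_nipals(X, mask, 2)
    rss1 = np.sum((X - reconstruct(model, 1)) ** 2)
    rss2 = np.sum((X - reconstruct(model, 2)) ** 2)
    assert rss2 <= rss1

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    exact = fit_nipals(X, mask, min(20, 6))
    np.testing.assert_allclose(reconstruct(exact), X, atol=1e-8)


def test_variance_captured_hand_example():
    # 3×2 matrix and a rank-1 model checked against pencil-and-paper arithmetic
    X = np.array([[1.0, 2.0], [0.0, 0.0], [-1.0, -2.0]])
    mask = np.ones_like(X, dtype=bool)
    t = np.array([[1.0], [0.0], [-1.0]])
    p = np.array([[1.0], [1.5]])
    model = _toy_model(t, p)
    # residuals: col1 exact, col2 rows ±0.5 -> num = 0.5, den = 10
    assert variance_captured(model, X, mask) == pytest.approx(1.0 - 0.5 / 10.0)
    assert variance_captured(model, X, mask, 0) == 0.0


def test_variance_captured_perfect_reconstruction_is_one():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((10, 3))
    X -= X.mean(axis=0)
    model = fit_nipals(X, np.ones_like(X, dtype=bool), 3)
    assert variance_captured(model, X, np.ones_like(X, dtype=bool)) == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# impute
# ---------------------------------------------------------------------------

def test_impute_identity_on_complete_table():
    rng = np.random.default_rng(6)
    table = _table(rng.standard_normal((12, 4)) + 5.0)
    model = fit_table(table, "nipals", 2)
    filled = impute(model, table)
    assert np.array_equal(filled.values, table.values)


def test_rank_one_completion_is_exact():
    """A noiseless rank-1 matrix with one masked cell has a unique completion;
    NIPALS on the observed cells reproduces the hidden value to 1e-8."""
    rng = np.random.default_rng(8)
    t = rng.standard_normal(15)
    t -= t.mean()
    X = np.outer(t, rng.standard_normal(4) * 2.0)
    mask = np.ones_like(X, dtype=bool)
    mask[3, 2] = False
    model = fit_nipals(np.where(mask, X, np.nan), mask, 1)
    assert reconstruct(model)[3, 2] == pytest.approx(X[3, 2], abs=1e-8)


def test_impute_never_alters_observed_cells():
    rng = np.random.default_rng(10)
    values = rng.normal(3.0, 2.0, size=(20, 6))
    mask = rng.random((20, 6)) > 0.15
    mask[:2] = True
    table = _table(np.where(mask, values, np.nan), mask)
    for method in ("nipals", "ppca", "bpca", "nlpca"):
        model = fit_table(table, method, 2, seed=0)
        filled = impute(model, table)
        assert np.array_equal(filled.values[mask], table.values[mask])  # bit-exact
        assert filled.mask.all()


# ---------------------------------------------------------------------------
# drop rule
# ---------------------------------------------------------------------------

def _drop_table():
    # 5 × 8: first 6 columns experimental, last 2 computed
    values = np.arange(40, dtype=float).reshape(5, 8) + 1.0
    mask = np.ones((5, 8), dtype=bool)
    mask[2, :6] = False  # row 2 missing 6 experimental cells
    mask[4, :5] = False  # row 4 missing exactly 5 -> retained
    sources = ["literature"] * 3 + ["measured"] * 3 + ["computed"] * 2
    return _table(np.where(mask, values, np.nan), mask, sources)


def test_drop_rule_is_strictly_greater_than_threshold():
    table = _drop_table()
    kept, removed = drop_sparse_rows(table, max_missing=5)
    assert removed == ["r2"]
    assert kept.n_rows == 4
    assert "r4" in kept.ids  # boundary case: exactly 5 missing is retained


def test_drop_rule_idempotent():
    table = _drop_table()
    once, _ = drop_sparse_rows(table, max_missing=5)
    twice, removed = drop_sparse_rows(once, max_missing=5)
    assert removed == []
    assert np.array_equal(once.values[once.mask], twice.values[twice.mask])


def test_drop_rule_counts_only_experimental_columns():
    values = np.ones((4, 4)) * np.arange(1, 5)
    mask = np.ones((4, 4), dtype=bool)
    mask[1, 2:] = False  # 2 computed cells missing: not counted
    sources = ["literature", "measured", "computed", "computed"]
    table = _table(np.where(mask, values, np.nan), mask, sources)
    kept, removed = drop_sparse_rows(table, max_missing=1)
    assert removed == [] and kept.n_rows == 4


# ---------------------------------------------------------------------------
# cross-method invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["nipals", "ppca", "bpca", "nlpca"])
def test_r2_cumulative_nondecreasing(method, paper_table):
    model = fit_table(paper_table, method, 4, seed=0)
    diffs = np.diff(model.r2_cumulative)
    assert np.all(diffs >= -1e-10)
    assert np.all(model.r2_cumulative <= 1.0 + 1e-12)
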