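"""Missing-data PCA: NIPALS, PPCA, BPCA and NLPCA on incomplete tables.

The descriptor table mixes units (mM, eV, Debye, Å³, counts, mV), so every
fit operates on the autoscaled matrix: each column z-scored over its observed
entries. Missing cells are handled natively by each algorithm:

* **NIPALS** — sequential rank-1 extraction whose score/loading regressions
  simply skip unobserved cells; fully deterministic.
* **PPCA** — probabilistic PCA (isotropic Gaussian factor model) fitted by
  expectation–maximization with missing coordinates integrated out of the
  E-step; deterministic SVD-based initialization.
* **BPCA** — the same latent model with automatic-relevance-determination
  priors on the loading columns, fitted by a variational EM that re-estimates
  missing cells each sweep; deterministic.
* **NLPCA** — inverse-model autoassociative network: free latent scores feed
  one tanh hidden layer reconstructing the descriptors; the squared error is
  summed over observed cells only, and results depend on the initialization
  seed.

All methods share one contract: a :class:`PCAModel` with scores, loadings,
cumulative variance-captured R² (observed-cell reconstruction R² of the
autoscaled matrix), plus ``reconstruct``/``variance_captured``/``impute``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .table import DescriptorTable, EXPERIMENTAL_SOURCES, TableError

METHODS = ("nipals", "ppca", "bpca", "nlpca")


@dataclass
class ScalingParams:
    """Per-column observed-entry mean and sample standard deviation."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class PCAModel:
    """Common result object for the four missing-data PCA algorithms."""

    method: str
    k: int
    scores: np.ndarray  # n × k
    loadings: np.ndarray  # p × k
    scaling: Optional[ScalingParams]
    r2_cumulative: np.ndarray  # length k
    converged: bool
    iterations: int
    seed: Optional[int] = None
    extras: dict = field(default_factory=dict)


class FitError(RuntimeError):
    """An algorithm violated one of its own guarantees (e.g. EM likelihood drop)."""


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def autoscale(table: DescriptorTable) -> tuple[np.ndarray, np.ndarray, ScalingParams]:
    """Z-score each column over its observed entries.

    Returns ``(X, mask, params)`` where X has nan at missing cells and each
    column's observed entries have mean 0 and sample standard deviation 1.
    """
    table.check_observations()
    values, mask = table.values, table.mask
    means = np.empty(table.n_cols)
    sds = np.empty(table.n_cols)
    for j in range(table.n_cols):
        col = values[mask[:, j], j]
        means[j] = col.mean()
        sds[j] = col.std(ddof=1)
        if sds[j] == 0.0:
            raise TableError(
                f"column {table.col_meta[j].name!r} has zero variance over observed entries"
            )
    X = np.where(mask, (values - means) / sds, np.nan)
    return X, mask.copy(), ScalingParams(mean=means, sd=sds)


def _canonical_signs(scores: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Make each loading column's largest-|.| element positive (in place).

    Returns the ±1 flip applied to each column.
    """
    flips = np.ones(loadings.shape[1])
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
            scores[:, c] = -scores[:, c]
            flips[c] = -1.0
    return flips


def _filled(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.where(mask, X, 0.0)


# ---------------------------------------------------------------------------
# reconstruction metric (shared)
# ---------------------------------------------------------------------------

def reconstruct(model: PCAModel, k: Optional[int] = None) -> np.ndarray:
    """Rank-``k`` reconstruction on the autoscaled scale.

    For NLPCA at full rank the network forward pass is used (the nonlinear
    reconstruction is the method's point); truncated NLPCA reconstructions use
    the best linear map stored in the loadings.
    """
    if k is None:
        k = model.k
    if k > model.k:
        raise ValueError(f"requested {k} components from a {model.k}-component model")
    if model.method == "nlpca" and k == model.k and "network" in model.extras:
        return _nlpca_forward(model.extras["network"], model.scores)
    return model.scores[:, :k] @ model.loadings[:, :k].T


def variance_captured(
    model: PCAModel, X: np.ndarray, mask: np.ndarray, k: Optional[int] = None
) -> float:
    """Observed-cell reconstruction R² = 1 − Σ(x−x̂)²/Σx² on the scaled matrix."""
    if not mask.any():
        raise ValueError("mask has no observed cells")
    Xhat = reconstruct(model, k)
    num = float(np.sum((X[mask] - Xhat[mask]) ** 2))
    den = float(np.sum(X[mask] ** 2))
    return 1.0 - num / den


def _r2_curve(
    scores: np.ndarray, loadings: np.ndarray, X: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    den = float(np.sum(X[mask] ** 2))
    out = np.empty(scores.shape[1])
    for k in range(1, scores.shape[1] + 1):
        Xhat = scores[:, :k] @ loadings[:, :k].T
        out[k - 1] = 1.0 - float(np.sum((X[mask] - Xhat[mask]) ** 2)) / den
    return out


# ---------------------------------------------------------------------------
# NIPALS
# ---------------------------------------------------------------------------

def fit_nipals(
    X: np.ndarray,
    mask: np.ndarray,
    k: int,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> PCAModel:
    """Sequential NIPALS extraction skipping missing cells.

    Each component alternates least-squares updates of the score and loading
    vectors with sums restricted to observed cells, normalizes the loading,
    iterates to ``tol`` on the relative score change, then deflates observed
    cells. No randomness anywhere: repeated runs are bit-identical.
    """
    n, p = X.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n, p)={min(n, p)}")
    M = mask.astype(float)
    R = _filled(X, mask)
    scores = np.zeros((n, k))
    loadings = np.zeros((p, k))
    converged = True
    total_iter = 0
    eps = np.finfo(float).tiny
    for comp in range(k):
        j0 = int(np.argmax(np.sum(R * R, axis=0)))
        t = R[:, j0].copy()
        if not np.any(t):
            t = np.ones(n)
        comp_converged = False
        for _ in range(max_iter):
            total_iter += 1
            pj = (R.T @ t) / (M.T @ (t * t) + eps)
            pj /= np.linalg.norm(pj) + eps
            t_new = (R @ pj) / (M @ (pj * pj) + eps)
            if np.linalg.norm(t_new - t) <= tol * (np.linalg.norm(t_new) + eps):
                t = t_new
                comp_converged = True
                break
            t = t_new
        if not comp_converged:
            warnings.warn(
                f"NIPALS component {comp + 1} did not converge in {max_iter} iterations",
                stacklevel=2,
            )
            converged = False
        pj = (R.T @ t) / (M.T @ (t * t) + eps)
        pj /= np.linalg.norm(pj) + eps
        scores[:, comp] = t
        loadings[:, comp] = pj
        R -= np.where(mask, np.outer(t, pj), 0.0)
    _canonical_signs(scores, loadings)
    r2 = _r2_curve(scores, loadings, X, mask)
    return PCAModel(
        method="nipals",
        k=k,
        scores=scores,
        loadings=loadings,
        scaling=None,
        r2_cumulative=r2,
        converged=converged,
        iterations=total_iter,
    )


# ---------------------------------------------------------------------------
# PPCA (EM with missing data)
# ---------------------------------------------------------------------------

def _factor_estep(X, mask, W, sigma2):
    """Posterior latent moments per row; returns (means n×k, covariances n×k×k)."""
    n = X.shape[0]
    k = W.shape[1]
    means = np.zeros((n, k))
    covs = np.zeros((n, k, k))
    eye = np.eye(k)
    for i in range(n):
        o = mask[i]
        Wo = W[o]
        A = Wo.T @ Wo + sigma2 * eye
        Ainv = np.linalg.inv(A)
        means[i] = Ainv @ (Wo.T @ X[i, o])
        covs[i] = sigma2 * Ainv
    return means, covs


def _observed_loglik(X, mask, W, sigma2):
    """Observed-data log-likelihood, evaluated row-wise via the Woodbury identity."""
    n = X.shape[0]
    k = W.shape[1]
    ll = 0.0
    for i in range(n):
        o = mask[i]
        x = X[i, o]
        Wo = W[o]
        d = x.size
        A = Wo.T @ Wo + sigma2 * np.eye(k)
        _, logdetA = np.linalg.slogdet(A)
        logdetC = (d - k) * np.log(sigma2) + logdetA
        u = Wo.T @ x
        quad = (x @ x - u @ np.linalg.solve(A, u)) / sigma2
        ll += -0.5 * (d * np.log(2 * np.pi) + logdetC + quad)
    return ll


def _noise_update(X, mask, W, means, covs):
    sse = 0.0
    for i in range(X.shape[0]):
        o = mask[i]
        r = X[i, o] - W[o] @ means[i]
        sse += r @ r + np.trace(W[o] @ covs[i] @ W[o].T)
    return max(sse / int(mask.sum()), 1e-12)


def _rotate_factor_model(W: np.ndarray, means: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert (W, posterior means) into unit-norm loadings and matched scores.

    SVD of W = U S Vᵀ gives orthonormal directions U (the loadings) ordered by
    singular value; scores are rotated so scores @ loadingsᵀ equals means @ Wᵀ.
    """
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    scores = means @ Vt.T * s
    loadings = U.copy()
    _canonical_signs(scores, loadings)
    return scores, loadings


def fit_ppca(
    X: np.ndarray,
    mask: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: str = "svd",
) -> PCAModel:
    """Probabilistic PCA by EM with missing cells integrated out.

    Model: x = W z + ε with z ~ N(0, I) and isotropic noise ε ~ N(0, σ²I); the
    mean is fixed at zero because fits run on the autoscaled matrix. Default
    initialization is the SVD of the zero-imputed matrix (deterministic);
    ``init='random'`` draws W from ``seed`` for optional restarts. Stops when
    the observed-data log-likelihood improves by less than ``tol`` relative,
    and raises :class:`FitError` if the likelihood ever decreases beyond
    numerical slack.
    """
    n, p = X.shape
    if k >= p:
        raise ValueError(f"k={k} must be < p={p}")
    rng = np.random.default_rng(seed)
    if init == "svd":
        _, s, Vt = np.linalg.svd(_filled(X, mask), full_matrices=False)
        W = Vt[:k].T * (s[:k] / np.sqrt(n))
        sigma2 = float((s[k:] ** 2).sum() / (n * max(p - k, 1))) + 1e-6
    elif init == "random":
        W = rng.standard_normal((p, k)) * 0.1
        sigma2 = 1.0
    else:
        raise ValueError(f"unknown init {init!r}")

    ll_old = -np.inf
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        means, covs = _factor_estep(X, mask, W, sigma2)
        second = means[:, :, None] * means[:, None, :] + covs  # n×k×k
        W_new = np.empty_like(W)
        for j in range(p):
            rows = mask[:, j]
            A = second[rows].sum(axis=0)
            b = means[rows].T @ X[rows, j]
            W_new[j] = np.linalg.solve(A, b)
        W = W_new
        sigma2 = _noise_update(X, mask, W, means, covs)
        ll = _observed_loglik(X, mask, W, sigma2)
        if ll < ll_old - 1e-6 * (1.0 + abs(ll_old)):
            raise FitError(
                f"PPCA observed-data log-likelihood decreased ({ll_old:.6g} -> {ll:.6g})"
            )
        if ll - ll_old < tol * (1.0 + abs(ll_old)):
            ll_old = ll
            converged = True
            break
        ll_old = ll
    if not converged:
        warnings.warn(f"PPCA did not converge in {max_iter} EM iterations", stacklevel=2)

    means, _ = _factor_estep(X, mask, W, sigma2)
    scores, loadings = _rotate_factor_model(W, means)
    r2 = _r2_curve(scores, loadings, X, mask)
    return PCAModel(
        method="ppca",
        k=k,
        scores=scores,
        loadings=loadings,
        scaling=None,
        r2_cumulative=r2,
        converged=converged,
        iterations=iterations,
        seed=seed,
        extras={"sigma2": sigma2, "loglik": ll_old},
    )


# ---------------------------------------------------------------------------
# BPCA (variational EM with ARD priors)
# ---------------------------------------------------------------------------

def fit_bpca(
    X: np.ndarray,
    mask: np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> PCAModel:
    """Bayesian PCA with automatic-relevance priors on loading columns.

    Same latent Gaussian model as PPCA, but each loading column w_l carries a
    precision hyperparameter α_l re-estimated every sweep (α_l = p/‖w_l‖²)
    that shrinks irrelevant components toward zero. Missing cells are
    re-estimated from the current reconstruction each iteration; the fit stops
    when the largest imputed-cell change drops below ``tol`` (on complete data,
    when the relative log-likelihood change does). Deterministic
    (zero-imputed-SVD initialization, no randomness).
    """
    n, p = X.shape
    if k >= p:
        raise ValueError(f"k={k} must be < p={p}")
    _, s, Vt = np.linalg.svd(_filled(X, mask), full_matrices=False)
    W = Vt[:k].T * (s[:k] / np.sqrt(n))
    sigma2 = float((s[k:] ** 2).sum() / (n * max(p - k, 1))) + 1e-6
    alpha = np.ones(k)
    missing = ~mask
    imputed_old = np.zeros(int(missing.sum()))
    ll_old = -np.inf
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        means, covs = _factor_estep(X, mask, W, sigma2)
        second = means[:, :, None] * means[:, None, :] + covs
        W_new = np.empty_like(W)
        reg = sigma2 * np.diag(alpha)
        for j in range(p):
            rows = mask[:, j]
            A = second[rows].sum(axis=0) + reg
            b = means[rows].T @ X[rows, j]
            W_new[j] = np.linalg.solve(A, b)
        W = W_new
        alpha = np.clip(p / (np.sum(W**2, axis=0) + 1e-10), None, 1e10)
        sigma2 = _noise_update(X, mask, W, means, covs)
        ll = _observed_loglik(X, mask, W, sigma2)
        # the ARD penalty allows small raw-likelihood dips; only gross
        # degradation (or non-finite values) indicates an implementation bug
        if not np.isfinite(ll) or ll < ll_old - 0.1 * (1.0 + abs(ll_old)):
            raise FitError(f"BPCA observed-data fit degraded ({ll_old:.6g} -> {ll:.6g})")
        if missing.any():
            imputed = (means @ W.T)[missing]
            change = float(np.max(np.abs(imputed - imputed_old)))
            imputed_old = imputed
            if iterations > 1 and change < tol:
                converged = True
                break
        else:
            if iterations > 1 and ll - ll_old < tol * (1.0 + abs(ll_old)):
                converged = True
                break
        ll_old = ll
    if not converged:
        warnings.warn(f"BPCA did not converge in {max_iter} iterations", stacklevel=2)
    means, _ = _factor_estep(X, mask, W, sigma2)
    scores, loadings = _rotate_factor_model(W, means)
    r2 = _r2_curve(scores, loadings, X, mask)
    return PCAModel(
        method="bpca",
        k=k,
        scores=scores,
        loadings=loadings,
        scaling=None,
        r2_cumulative=r2,
        converged=converged,
        iterations=iterations,
        extras={"sigma2": sigma2, "alpha": alpha},
    )


# ---------------------------------------------------------------------------
# NLPCA (inverse autoassociative network)
# ---------------------------------------------------------------------------

def _nlpca_forward(network: dict, Z: np.ndarray) -> np.ndarray:
    H = np.tanh(Z @ network["W1"] + network["b1"])
    return H @ network["W2"] + network["b2"]


def fit_nlpca(
    X: np.ndarray,
    mask: np.ndarray,
    k: int,
    seed: int = 0,
    hidden_units: Optional[int] = None,
    epochs: int = 3000,
    lr: float = 0.01,
) -> PCAModel:
    """Inverse-model nonlinear PCA.

    Free latent scores Z (one row per surfactant) feed a single tanh hidden
    layer that reconstructs all descriptors; the squared error is summed over
    observed cells only, and Z, weights and biases are trained jointly by
    full-batch gradient descent (step halved whenever a step would increase
    the loss). Initialization is drawn from ``seed``, so different seeds give
    materially different principal components — the behaviour that motivates
    preferring a deterministic method for the final map.

    Score columns are ordered by greedy incremental linear R²; loadings are
    the best linear map from the ordered scores to the data, and the final
    entry of ``r2_cumulative`` uses the network reconstruction itself.
    """
    n, p = X.shape
    if k >= p:
        raise ValueError(f"k={k} must be < p={p}")
    if hidden_units is None:
        hidden_units = max(2 * k + 2, 8)
    rng = np.random.default_rng(seed)
    Xf = _filled(X, mask)
    Mf = mask.astype(float)

    params = [
        rng.standard_normal((n, k)) * 0.1,  # Z
        rng.standard_normal((k, hidden_units)) / np.sqrt(k),  # W1
        np.zeros(hidden_units),  # b1
        rng.standard_normal((hidden_units, p)) / np.sqrt(hidden_units),  # W2
        np.zeros(p),  # b2
    ]

    def loss_of(ps):
        Z_, W1_, b1_, W2_, b2_ = ps
        E = (np.tanh(Z_ @ W1_ + b1_) @ W2_ + b2_ - Xf) * Mf
        return 0.5 * float(np.sum(E * E))

    step = lr
    loss = loss_of(params)
    for _ in range(epochs):
        Z, W1, b1, W2, b2 = params
        H = np.tanh(Z @ W1 + b1)
        E = (H @ W2 + b2 - Xf) * Mf
        dW2 = H.T @ E
        db2 = E.sum(axis=0)
        dA = (E @ W2.T) * (1.0 - H * H)
        dW1 = Z.T @ dA
        db1 = dA.sum(axis=0)
        dZ = dA @ W1.T
        trial = [
            Z - step * dZ,
            W1 - step * dW1,
            b1 - step * db1,
            W2 - step * dW2,
            b2 - step * db2,
        ]
        new_loss = loss_of(trial)
        if not np.isfinite(new_loss):
            raise FitError("NLPCA loss diverged; try a smaller step size (lr)")
        if new_loss > loss:
            step *= 0.5
            if step < 1e-12:
                break
            continue
        params = trial
        loss = new_loss
    Z, W1, b1, W2, b2 = params

    order = _greedy_score_order(Z, X, mask)
    scores = Z[:, order]
    loadings = _masked_linear_map(scores, X, mask).T
    flips = _canonical_signs(scores, loadings)
    # Fold the column permutation and sign flips into the first network layer so
    # the stored network reproduces its reconstruction from the stored scores:
    # Z_original = scores @ T with T[c, order[c]] = flip_c.
    T = np.zeros((k, k))
    for c, orig in enumerate(order):
        T[c, orig] = flips[c]
    network = {"W1": T @ W1, "b1": b1, "W2": W2, "b2": b2}

    r2 = _r2_curve(scores, loadings, X, mask)
    den = float(np.sum(X[mask] ** 2))
    Xhat = _nlpca_forward(network, scores)
    r2_net = 1.0 - float(np.sum((X[mask] - Xhat[mask]) ** 2)) / den
    if k > 1 and r2_net < r2[-2]:
        # network underperforms its own linear map at full rank: keep the model
        # usable but drop the network so reconstruct() stays monotone in k
        network = None
        r2_net = r2[-1]
    r2[-1] = r2_net

    extras = {"hidden_units": hidden_units, "final_loss": loss}
    if network is not None:
        extras["network"] = network
    return PCAModel(
        method="nlpca",
        k=k,
        scores=scores,
        loadings=loadings,
        scaling=None,
        r2_cumulative=r2,
        converged=True,
        iterations=epochs,
        seed=seed,
        extras=extras,
    )


def _greedy_score_order(Z: np.ndarray, X: np.ndarray, mask: np.ndarray) -> list[int]:
    """Order latent columns by greedy incremental observed-cell R²."""
    k = Z.shape[1]
    remaining = list(range(k))
    order: list[int] = []
    den = float(np.sum(X[mask] ** 2))
    while remaining:
        best_c, best_r2 = remaining[0], -np.inf
        for c in remaining:
            cols = order + [c]
            B = _masked_linear_map(Z[:, cols], X, mask)
            Xhat = Z[:, cols] @ B
            r2 = 1.0 - float(np.sum((X[mask] - Xhat[mask]) ** 2)) / den
            if r2 > best_r2:
                best_c, best_r2 = c, r2
        order.append(best_c)
        remaining.remove(best_c)
    return order


def _masked_linear_map(Z: np.ndarray, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Least-squares map B with Z B ≈ X over observed cells (per-column fits)."""
    B = np.zeros((Z.shape[1], X.shape[1]))
    for j in range(X.shape[1]):
        rows = mask[:, j]
        B[:, j] = np.linalg.lstsq(Z[rows], X[rows, j], rcond=None)[0]
    return B


# ---------------------------------------------------------------------------
# high-level fitting and imputation
# ---------------------------------------------------------------------------

def fit_table(
    table: DescriptorTable,
    method: str,
    k: int,
    seed: int = 0,
    **kwargs,
) -> PCAModel:
    """Autoscale ``table`` and fit one of the four methods; attaches scaling."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    X, mask, scaling = autoscale(table)
    if method == "nipals":
        model = fit_nipals(X, mask, k, **kwargs)
    elif method == "ppca":
        model = fit_ppca(X, mask, k, seed=seed, **kwargs)
    elif method == "bpca":
        model = fit_bpca(X, mask, k, **kwargs)
    else:
        model = fit_nlpca(X, mask, k, seed=seed, **kwargs)
    model.scaling = scaling
    return model


def impute(model: PCAModel, table: DescriptorTable) -> DescriptorTable:
    """Fill missing cells from the model reconstruction; observed cells untouched.

    The reconstruction lives on the autoscaled scale and is mapped back
    through the stored :class:`ScalingParams`; observed cells are copied
    bit-exactly from the input.
    """
    if model.scaling is None:
        raise ValueError("model lacks scaling parameters; fit it with fit_table")
    if model.scores.shape[0] != table.n_rows or model.loadings.shape[0] != table.n_cols:
        raise ValueError(
            f"model shape ({model.scores.shape[0]}×{model.loadings.shape[0]}) does not "
            f"match table ({table.n_rows}×{table.n_cols})"
        )
    raw_hat = reconstruct(model) * model.scaling.sd + model.scaling.mean
    values = np.where(table.mask, table.values, raw_hat)
    return DescriptorTable(
        values,
        np.ones_like(table.mask),
        table.row_meta.reset_index(drop=True).copy(),
        list(table.col_meta),
    )


def drop_sparse_rows(
    table: DescriptorTable,
    max_missing: int = 5,
    sources: Iterable[str] = EXPERIMENTAL_SOURCES,
) -> tuple[DescriptorTable, list[str]]:
    """Remove surfactants missing more than ``max_missing`` experimental cells.

    Rows whose missing-cell count among the selected descriptor sources is
    strictly greater than the threshold are dropped (a row missing exactly
    ``max_missing`` is retained). Returns the reduced table and the removed
    ids. Mirrors the published 100 → 91 surfactant filter.
    """
    cols = table.column_indices(sources)
    if cols.size:
        missing_counts = (~table.mask[:, cols]).sum(axis=1)
    else:
        missing_counts = np.zeros(table.n_rows, dtype=int)
    keep = missing_counts <= max_missing
    removed = [i for i, kept in zip(table.ids, keep) if not kept]
    if not keep.any():
        warnings.warn("drop_sparse_rows removed every row", stacklevel=2)
    new = DescriptorTable(
        table.values[keep],
        table.mask[keep],
        table.row_meta.loc[keep].reset_index(drop=True).copy(),
        list(table.col_meta),
    )
    return new, removed
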