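"""Unsupervised and supervised multivariate models for omics matrices.

The centrepiece is a two-class orthogonal projection to latent structures
discriminant analysis (OPLS-DA) built on the NIPALS construction: class
labels are coded y in {-1, +1}, orthogonal (y-uncorrelated) variation is
deflated from X component by component, and a single predictive component is
fit on the residual.  Model quality is summarised by R2X, R2Y and a
cross-validated Q2 (stratified k-fold, refit per fold), guarded against
overfitting by a label-permutation test, and per-feature relevance is scored
with VIP (variable importance in projection, normalised so the mean squared
VIP equals 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .matrix import IntensityMatrix


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(m: IntensityMatrix, n_components: int = 2):
    """Principal component analysis of samples (features as variables).

    Returns (scores, loadings, explained_variance_ratio).  Scores are
    n_samples x n_components; loadings columns are orthonormal.
    """
    X = m.values.to_numpy(dtype=float).T  # samples x features
    n, p = X.shape
    if n < 2:
        raise ModelError("PCA needs at least 2 samples")
    if n_components > min(n, p):
        raise ModelError(f"n_components {n_components} exceeds min(dims) {min(n, p)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude loading entry positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = (U * s)[:, :n_components]
    loadings = Vt[:n_components].T
    var = s**2
    evr = (var / var.sum())[:n_components] if var.sum() > 0 else np.zeros(n_components)
    return scores, loadings, evr


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    """Fitted two-class OPLS-DA model (single predictive component)."""

    feature_ids: list[str]
    w: np.ndarray              # predictive weights, unit norm
    p: np.ndarray              # predictive loadings
    t: np.ndarray              # predictive scores (training samples)
    q: float                   # y-loading of the predictive component
    w_ortho: np.ndarray        # (n_ortho, p) orthogonal weights, unit norm
    p_ortho: np.ndarray        # (n_ortho, p) orthogonal loadings
    t_ortho: np.ndarray        # (n_samples, n_ortho) orthogonal scores
    x_mean: np.ndarray
    y_mean: float
    r2x: float
    r2y: float
    q2: float
    n_ortho: int
    n_folds: int
    ssy_explained: float = 0.0

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Deflate orthogonal variation from new samples, return t scores."""
        Xc = X - self.x_mean
        for k in range(self.n_ortho):
            t_o = Xc @ self.w_ortho[k]
            Xc = Xc - np.outer(t_o, self.p_ortho[k])
        return Xc @ self.w

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class prediction (sign gives the class)."""
        return self.transform(X) * self.q + self.y_mean


@dataclass
class PermutationResult:
    n_permutations: int
    observed_q2: float
    observed_r2y: float
    permuted_q2: list[float] = field(default_factory=list)
    permuted_r2y: list[float] = field(default_factory=list)
    p_q2: float = 1.0
    p_r2y: float = 1.0


def _fit_opls_core(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """NIPALS OPLS on centered X, centered y; returns component arrays."""
    n, p = X.shape
    ssx0 = float((X**2).sum())
    cov = X.T @ y
    norm = np.linalg.norm(cov)
    if norm == 0:
        raise ModelError("y carries no covariance with X (degenerate fit)")
    w = cov / norm
    W_o = np.zeros((n_ortho, p))
    P_o = np.zeros((n_ortho, p))
    T_o = np.zeros((n, n_ortho))
    Xd = X
    for k in range(n_ortho):
        t = Xd @ w
        pl = Xd.T @ t / (t @ t)
        w_o = pl - (w @ pl) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            raise ModelError(
                f"no orthogonal variation left for component {k + 1} "
                f"(n_ortho too large for the data rank)"
            )
        w_o = w_o / n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[k], P_o[k], T_o[:, k] = w_o, p_o, t_o
    t = Xd @ w
    pl = Xd.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    ssy = float(y @ y)
    r2y = 1.0 - float(((y - t * q) ** 2).sum()) / ssy if ssy > 0 else 0.0
    ssx_model = float((np.outer(t, pl) ** 2).sum()) + sum(
        float((np.outer(T_o[:, k], P_o[k]) ** 2).sum()) for k in range(n_ortho)
    )
    r2x = ssx_model / ssx0 if ssx0 > 0 else 0.0
    return w, pl, t, q, W_o, P_o, T_o, r2x, r2y


def _stratified_folds(y01: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Deterministic stratified fold assignment (seeded shuffle per class)."""
    folds = np.zeros(len(y01), dtype=int)
    for cls in np.unique(y01):
        idx = np.flatnonzero(y01 == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def fit_oplsda(
    m: IntensityMatrix,
    n_ortho: int = 1,
    n_folds: int = 7,
    cv_seed: int = 0,
) -> OplsdaModel:
    """Fit OPLS-DA on a preprocessed matrix with stratified k-fold Q2.

    ``m`` must contain exactly two groups, each with at least ``n_folds``
    members.  y is coded +1 (case) / -1 (control) and centered; Q2 refits
    the whole model per fold and accumulates PRESS on held-out samples.
    """
    m.require_two_groups()
    X = m.values.to_numpy(dtype=float).T
    y_raw = m.group_labels()
    counts = [int((y_raw == v).sum()) for v in (1.0, -1.0)]
    if min(counts) < n_folds:
        raise ModelError(
            f"each group needs >= n_folds={n_folds} samples, got {counts}"
        )
    if n_ortho >= min(X.shape) - 1:
        raise ModelError("n_ortho too large for the matrix rank")
    x_mean = X.mean(axis=0)
    y_mean = float(y_raw.mean())
    Xc = X - x_mean
    yc = y_raw - y_mean
    w, pl, t, q, W_o, P_o, T_o, r2x, r2y = _fit_opls_core(Xc, yc, n_ortho)

    rng = np.random.default_rng(cv_seed)
    folds = _stratified_folds(y_raw, n_folds, rng)
    press = 0.0
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if te.sum() == 0:
            continue
        xm = X[tr].mean(axis=0)
        ym = float(y_raw[tr].mean())
        wf, plf, tf, qf, Wof, Pof, _, _, _ = _fit_opls_core(
            X[tr] - xm, y_raw[tr] - ym, n_ortho
        )
        Xte = X[te] - xm
        for k in range(n_ortho):
            t_o = Xte @ Wof[k]
            Xte = Xte - np.outer(t_o, Pof[k])
        yhat = (Xte @ wf) * qf + ym
        press += float(((y_raw[te] - yhat) ** 2).sum())
    ssy_tot = float((yc**2).sum())
    q2 = 1.0 - press / ssy_tot if ssy_tot > 0 else 0.0

    return OplsdaModel(
        feature_ids=m.feature_ids, w=w, p=pl, t=t, q=q,
        w_ortho=W_o, p_ortho=P_o, t_ortho=T_o,
        x_mean=x_mean, y_mean=y_mean,
        r2x=r2x, r2y=r2y, q2=q2, n_ortho=n_ortho, n_folds=n_folds,
        ssy_explained=float((t * q) @ (t * q)),
    )


def permutation_test(
    m: IntensityMatrix,
    n_ortho: int = 1,
    n_folds: int = 7,
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation test of OPLS-DA Q2 and R2Y.

    The whole pipeline (including the cross-validated Q2) is refit on each
    permuted label vector; p-values follow the add-one rule
    ``p = (1 + #{permuted >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ModelError("n_perm must be >= 1")
    observed = fit_oplsda(m, n_ortho=n_ortho, n_folds=n_folds, cv_seed=seed)
    rng = np.random.default_rng(seed)
    perm_q2, perm_r2y = [], []
    samples = m.samples
    for _ in range(n_perm):
        shuffled = samples.copy()
        shuffled["group"] = rng.permutation(samples["group"].to_numpy())
        mp = IntensityMatrix(m.values, shuffled)
        cv_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fit = fit_oplsda(mp, n_ortho=n_ortho, n_folds=n_folds, cv_seed=cv_seed)
            perm_q2.append(fit.q2)
            perm_r2y.append(fit.r2y)
        except ModelError:
            # a degenerate permutation explains nothing; count it as null-like
            perm_q2.append(-np.inf)
            perm_r2y.append(0.0)
    p_q2 = (1 + sum(v >= observed.q2 for v in perm_q2)) / (1 + n_perm)
    p_r2y = (1 + sum(v >= observed.r2y for v in perm_r2y)) / (1 + n_perm)
    return PermutationResult(
        n_permutations=n_perm,
        observed_q2=observed.q2, observed_r2y=observed.r2y,
        permuted_q2=perm_q2, permuted_r2y=perm_r2y,
        p_q2=p_q2, p_r2y=p_r2y,
    )


def compute_vip(model: OplsdaModel, include_orthogonal: bool = False) -> dict[str, float]:
    """Variable importance in projection.

    VIP_j = sqrt( F * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ) with F
    the feature count.  By default only the predictive component enters the
    sum (the common software convention); orthogonal components may be
    included, weighted by the (near-zero) y-variance they explain.
    """
    F = len(model.feature_ids)
    ssy_p = model.ssy_explained
    if ssy_p <= 0:
        raise ModelError("predictive component explains no y variance")
    num = ssy_p * (model.w / np.linalg.norm(model.w)) ** 2
    den = ssy_p
    if include_orthogonal:
        for k in range(model.n_ortho):
            t_o = model.t_ortho[:, k]
            # y-variance captured by the orthogonal score (≈ 0 by design)
            ssy_o = float((t_o @ (model.t * model.q)) ** 2 / max(t_o @ t_o, 1e-300))
            num = num + ssy_o * (model.w_ortho[k] / np.linalg.norm(model.w_ortho[k])) ** 2
            den += ssy_o
    vip = np.sqrt(F * num / den)
    return dict(zip(model.feature_ids, vip.tolist()))


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(
    m: IntensityMatrix, axis: str = "samples", method: str = "average"
):
    """Agglomerative clustering (Euclidean, average linkage by default).

    Returns (ordered ids, linkage matrix).  ``axis`` selects whether samples
    or features are clustered.
    """
    if axis == "samples":
        X = m.values.to_numpy(dtype=float).T
        ids = m.sample_ids
    elif axis == "features":
        X = m.values.to_numpy(dtype=float)
        ids = m.feature_ids
    else:
        raise ModelError(f"axis must be 'samples' or 'features', got {axis!r}")
    if len(ids) < 2:
        raise ModelError("clustering needs at least 2 items")
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    order = [ids[i] for i in leaves_list(Z)]
    return order, Z
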