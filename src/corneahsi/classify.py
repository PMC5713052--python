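"""Binary soft-margin SVM with linear and Gaussian-RBF kernels.

The decision function is

    f(x) = sum_i alpha_i y_i K(x_i, x) + b,

with the Gaussian radial basis function kernel
``K(u, v) = exp(-||u - v||^2 / (2 sigma^2))`` parameterised by its width
``sigma`` (the common precision form is ``gamma = 1 / (2 sigma^2)``).  The
dual problem is solved by sequential minimal optimisation (SMO) with
maximal-violating-pair working-set selection, to a KKT tolerance of 1e-6.

Feature columns are normalised to unit Euclidean norm before training
(``normalize_columns``).  Evaluation is by stratified k-fold cross
validation: out-of-fold decision values are pooled and scored as the area
under the ROC curve, alongside the fraction correct, an out-of-sample mean
squared error on {0, 1}-coded labels, and the confusion matrix (healthy =
negative, injured = positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SVMModel",
    "EvalReport",
    "normalize_columns",
    "grbf_kernel",
    "svm_train",
    "svm_decide",
    "roc_auc",
    "confusion",
    "cross_validate",
]


def normalize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each feature column to unit Euclidean norm.

    Returns the scaled matrix and the per-column norms, so a test set can
    be scaled by the norms fitted on training data.
    """
    X = np.asarray(X, dtype=np.float64)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("cannot normalise an all-zero feature column")
    return X / norms, norms


def grbf_kernel(xi: np.ndarray, xj: np.ndarray, sigma: float) -> float:
    """Gaussian RBF kernel value exp(-||xi - xj||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    if xi.shape != xj.shape:
        raise ValueError("kernel arguments must have equal dimension")
    d2 = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: str, sigma: float) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "grbf":
        if sigma <= 0:
            raise ValueError("kernel width sigma must be positive")
        d2 = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * (A @ B.T)
        )
        return np.exp(-np.clip(d2, 0.0, None) / (2.0 * sigma**2))
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class SVMModel:
    """A trained SVM: support vectors, dual coefficients and bias."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i per support vector
    bias: float
    kernel: str
    sigma: float | None
    C: float
    iterations: int
    alpha: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


def svm_train(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    kernel: str = "grbf",
    sigma: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200_000,
) -> SVMModel:
    """Solve the soft-margin dual by SMO.

    ``y`` must hold both labels from {-1, +1}.  Working-set selection picks
    the maximal violating pair; the solver stops when the KKT gap drops
    below ``tol``.  The iteration count (number of pair updates) is stored
    on the model.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    if not (np.all(np.isin(y, (-1.0, 1.0))) and len(np.unique(y)) == 2):
        raise ValueError("y must contain both classes, coded -1/+1")
    if C <= 0:
        raise ValueError("box constraint C must be positive")
    n = len(y)
    K = _kernel_matrix(X, X, kernel, sigma)
    alpha = np.zeros(n)
    u = np.zeros(n)  # decision values without bias: sum_s alpha_s y_s K_st
    iterations = 0
    m_val = M_val = 0.0
    for _ in range(max_iter):
        neg_E = y - u  # equals -y_t * grad_t of the dual objective
        up = ((alpha < C - 1e-12) & (y > 0)) | ((alpha > 1e-12) & (y < 0))
        low = ((alpha < C - 1e-12) & (y < 0)) | ((alpha > 1e-12) & (y > 0))
        up_idx = np.flatnonzero(up)
        low_idx = np.flatnonzero(low)
        i = up_idx[np.argmax(neg_E[up_idx])]
        j = low_idx[np.argmin(neg_E[low_idx])]
        m_val = neg_E[i]
        M_val = neg_E[j]
        if m_val - M_val <= tol:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        eta = max(eta, 1e-12)
        # Two-variable analytic step along the equality constraint.
        delta = (neg_E[i] - neg_E[j]) / eta
        if y[i] == y[j]:
            L = max(0.0, alpha[i] + alpha[j] - C)
            H = min(C, alpha[i] + alpha[j])
            new_j = np.clip(alpha[j] - y[j] * delta, L, H)
        else:
            L = max(0.0, alpha[j] - alpha[i])
            H = min(C, C + alpha[j] - alpha[i])
            new_j = np.clip(alpha[j] - y[j] * delta, L, H)
        new_i = alpha[i] + y[i] * y[j] * (alpha[j] - new_j)
        d_i = new_i - alpha[i]
        d_j = new_j - alpha[j]
        alpha[i], alpha[j] = new_i, new_j
        u += d_i * y[i] * K[i] + d_j * y[j] * K[j]
        iterations += 1
        if d_i == 0 and d_j == 0:
            break
    bias = float((m_val + M_val) / 2.0)
    sv = alpha > 1e-12
    return SVMModel(
        support_vectors=X[sv].copy(),
        dual_coef=(alpha * y)[sv].copy(),
        bias=bias,
        kernel=kernel,
        sigma=sigma if kernel == "grbf" else None,
        C=C,
        iterations=iterations,
        alpha=alpha,
        y=y,
    )


def svm_decide(model: SVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and hard labels for test points.

    ``f(x) = sum_i (alpha_i y_i) K(x_i, x) + b``; the label is sign(f) with
    f = 0 deciding positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if model.support_vectors.shape[1] != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: model has {model.support_vectors.shape[1]} features, "
            f"input has {X.shape[1]}"
        )
    K = _kernel_matrix(X, model.support_vectors, model.kernel, model.sigma or 1.0)
    f = K @ model.dual_coef + model.bias
    labels = np.where(f >= 0, 1.0, -1.0)
    return f, labels


def roc_auc(decision_values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and area under the curve by threshold sweep.

    Thresholds run over the distinct decision values; the area uses the
    trapezoid rule and therefore equals the Mann-Whitney pair-counting
    statistic with ties counted one half.  Returns ``(points, auc)`` where
    points is an ``(m, 2)`` array of (FPR, TPR) from (0, 0) to (1, 1).
    """
    scores = np.asarray(decision_values, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    pos = y > 0
    n_pos = int(pos.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    # Indices where the threshold changes (last element of each tie group).
    distinct = np.flatnonzero(np.diff(sorted_scores, append=np.nan))
    tps = np.cumsum(sorted_pos)[distinct]
    fps = np.cumsum(~sorted_pos)[distinct]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def confusion(pred_labels: np.ndarray, true_labels: np.ndarray) -> tuple[int, int, int, int]:
    """Counts (TN, FP, FN, TP); healthy = negative (-1), injured = positive (+1)."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth must be nonempty and equal-length")
    tn = int(np.sum((pred < 0) & (true < 0)))
    fp = int(np.sum((pred > 0) & (true < 0)))
    fn = int(np.sum((pred < 0) & (true > 0)))
    tp = int(np.sum((pred > 0) & (true > 0)))
    return tn, fp, fn, tp


@dataclass
class EvalReport:
    """Cross-validated evaluation: pooled ROC/AUC, errors and fold layout."""

    roc_points: np.ndarray
    auc: float
    mse_error: float
    accuracy: float
    confusion: tuple[int, int, int, int]
    iterations: int
    folds: np.ndarray
    seed: int
    decision_values: np.ndarray
    pred_labels: np.ndarray


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign samples to k folds, stratified by class, shuffled by seed."""
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if k == n:  # leave-one-out: no randomness, one sample per fold
        return np.arange(n)
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    C: float = 1.0,
    kernel: str = "grbf",
    sigma: float = 1.0,
    seed: int = 0,
    joint_normalization: bool = False,
) -> EvalReport:
    """Stratified k-fold cross validation with pooled out-of-fold scoring.

    With ``joint_normalization`` the feature columns are scaled to unit
    norm once over the full sample (the historical convention for the
    printed classification grid); otherwise norms are fitted per fold on
    the training part only and applied to the held-out part.

    The pooled out-of-fold decision values give the ROC/AUC; the MSE error
    compares predicted and true labels coded {0, 1} out of sample.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    folds = stratified_folds(y, k, seed)
    if joint_normalization:
        X_all, _ = normalize_columns(X)
    decision = np.empty(len(y))
    pred = np.empty(len(y))
    iterations = 0
    for f in range(k):
        test = folds == f
        train = ~test
        if not test.any():
            continue
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {f}: training part lost one class")
        if joint_normalization:
            Xtr, Xte = X_all[train], X_all[test]
        else:
            Xtr, norms = normalize_columns(X[train])
            Xte = X[test] / norms
        model = svm_train(Xtr, y[train], C=C, kernel=kernel, sigma=sigma)
        fvals, labels = svm_decide(model, Xte)
        decision[test] = fvals
        pred[test] = labels
        iterations += model.iterations
    points, auc = roc_auc(decision, y)
    true01 = (y + 1) / 2
    pred01 = (pred + 1) / 2
    mse = float(np.mean((pred01 - true01) ** 2))
    acc = float(np.mean(pred == y))
    return EvalReport(
        roc_points=points,
        auc=auc,
        mse_error=mse,
        accuracy=acc,
        confusion=confusion(pred, y),
        iterations=iterations,
        folds=folds,
        seed=seed,
        decision_values=decision,
        pred_labels=pred,
    )
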