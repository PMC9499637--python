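"""Chemometrics core: autoscaling, PCA, NIPALS PLS-DA, VIP scores.

PLS-DA is implemented as PLS1 regression on a centered 0/1 class dummy via
the NIPALS algorithm.  For a single response the NIPALS weight direction has
the closed form w_a ∝ X_a' y_a, so each component is one deflation step —
no inner iteration is needed.  Variable importance in projection (VIP)
follows the standard definition

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a )

where SSY_a = q_a² t_a't_a is the response sum of squares explained by
component a; the scores T are mutually orthogonal and Σ_j VIP_j² = p holds
algebraically for every fitted model.

Class assignment uses a configurable threshold on the predicted dummy
(default 0.5; a prediction of exactly 0.5 goes to the positive class).
Sign indeterminacies in PCA are fixed by forcing the largest-magnitude
loading entry of each component to be positive, so repeated fits are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


# ---------------------------------------------------------------------------
# autoscaling
# ---------------------------------------------------------------------------

def autoscale(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise mean-centering and unit-variance scaling (n−1 SD).

    Zero-variance columns cannot be scaled; they are neutralized — centered
    to exactly zero with a unit scale factor, which makes them inert in any
    downstream linear model — and a warning is logged.  If *every* column is
    constant an error is raised.

    Returns ``(X_scaled, centers, scales)``; the stored transform is what
    must be applied to out-of-sample rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("autoscale expects a 2-D matrix")
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    constant = scales <= 0
    if constant.all():
        raise ValueError("every column is constant; autoscaling undefined")
    if constant.any():
        log.warning("autoscale: %d zero-variance column(s) neutralized",
                    int(constant.sum()))
        scales = scales.copy()
        scales[constant] = 1.0
    return (X - centers) / scales, centers, scales


@dataclass
class Autoscaler:
    """Stored autoscale transform for train/test-consistent scaling."""

    centers: np.ndarray | None = None
    scales: np.ndarray | None = None

    def fit(self, X) -> "Autoscaler":
        _, self.centers, self.scales = autoscale(X)
        return self

    def transform(self, X) -> np.ndarray:
        if self.centers is None:
            raise RuntimeError("Autoscaler not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.centers.shape[0]:
            raise ValueError(
                f"feature count mismatch: {X.shape[1]} vs {self.centers.shape[0]}")
        return (X - self.centers) / self.scales

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    loadings: np.ndarray            # p x k, orthonormal columns
    scores: np.ndarray              # n x k
    explained_variance: np.ndarray  # eigenvalues of the covariance, length k
    variance_fractions: np.ndarray  # share of total variance, length k
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None


def pca(X_scaled, k: int | None = None) -> PCAModel:
    """SVD-based PCA of an already centered (typically autoscaled) matrix.

    Scores are X·loadings; variance fractions are eigenvalue shares of the
    total variance.  Component signs follow the largest-|loading| rule.
    """
    X = np.asarray(X_scaled, dtype=float)
    n, p = X.shape
    max_k = min(n - 1, p)
    if k is None:
        k = max_k
    if k > max_k:
        raise ValueError(f"k={k} exceeds min(n-1, p)={max_k}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s ** 2 / (n - 1)
    total = eig.sum()
    loadings = Vt[:k].T.copy()
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = X @ loadings
    fractions = eig[:k] / total if total > 0 else np.zeros(k)
    return PCAModel(loadings, scores, eig[:k], fractions)


def pca_autoscaled(X, k: int | None = None) -> PCAModel:
    """Autoscale then PCA; the transform is stored on the model."""
    Xs, centers, scales = autoscale(X)
    model = pca(Xs, k)
    model.centers, model.scales = centers, scales
    return model


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1 on a class dummy)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted two-class PLS-DA model.

    ``classes`` maps the dummy coding: classes[0] -> 0, classes[1] -> 1
    (classes[1] is the positive class).  Weights are unit-norm; scores are
    mutually orthogonal.  ``ssy`` holds the per-component explained response
    sum of squares used by the VIP formula.
    """

    classes: tuple
    weights: np.ndarray      # p x A (unit columns)
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # A,
    scores: np.ndarray       # n x A (training scores)
    ssy: np.ndarray          # A,
    y_mean: float
    scaler: Autoscaler | None = None
    threshold: float = 0.5

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients b with y_hat = y_mean + X_scaled·b."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        R = W @ np.linalg.solve(P.T @ W, np.eye(W.shape[1]))
        return R @ q


def _nipals_pls1(X: np.ndarray, y01: np.ndarray, n_components: int):
    """NIPALS PLS1 core on preprocessed X and a 0/1 response.

    Returns (W, P, q, T, ssy, y_mean, a_eff); stops early (a_eff < A) when
    the residual X carries no covariance with y, i.e. rank is exhausted.
    """
    n, p = X.shape
    Xr = X.copy()
    y_mean = float(y01.mean())
    yr = y01 - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)
    scale0 = float(np.abs(X).max()) or 1.0
    a_eff = 0
    for a in range(n_components):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale0:
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= (1e-12 * scale0) ** 2:
            break
        pa = Xr.T @ t / tt
        qa = float(yr @ t) / tt
        Xr -= np.outer(t, pa)
        yr = yr - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        ssy[a] = qa * qa * tt
        a_eff = a + 1
    return (W[:, :a_eff], P[:, :a_eff], q[:a_eff], T[:, :a_eff],
            ssy[:a_eff], y_mean, a_eff)


def encode_labels(labels, positive=None) -> tuple[np.ndarray, tuple]:
    """Map two-class labels to a 0/1 dummy.

    ``positive`` names the class coded 1; by default the lexicographically
    larger class.  Returns (y01, (negative_class, positive_class)).
    """
    labels = np.asarray(labels)
    classes = sorted(map(str, np.unique(labels.astype(str))))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA requires exactly 2 classes, got {classes}")
    if positive is None:
        positive = classes[1]
    positive = str(positive)
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among {classes}")
    negative = classes[0] if classes[1] == positive else classes[1]
    y01 = (labels.astype(str) == positive).astype(float)
    return y01, (negative, positive)


def plsda_fit(X, labels, n_components: int, positive=None,
              scale: bool = True) -> PLSModel:
    """Fit a two-class PLS-DA model.

    Parameters
    ----------
    X:
        Raw samples x features matrix.  With ``scale=True`` it is
        autoscaled internally; with ``scale=False`` it is only
        mean-centered (centering is intrinsic to PLS).
    labels:
        Two-class label vector.
    n_components:
        Number of latent variables A; must not exceed the rank of the
        (scaled, centered) training matrix.
    positive:
        Class coded as 1 (defaults to the lexicographically larger label).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    y01, classes = encode_labels(labels, positive)
    X = np.asarray(X, dtype=float)
    scaler = Autoscaler()
    if scale:
        scaler.fit(X)
    else:
        # centering is mandatory for PLS; scale=False skips only the
        # unit-variance scaling
        scaler.centers = X.mean(axis=0)
        scaler.scales = np.ones(X.shape[1])
    Xs = scaler.transform(X)
    W, P, q, T, ssy, y_mean, a_eff = _nipals_pls1(Xs, y01, n_components)
    if a_eff < n_components:
        raise ValueError(
            f"requested {n_components} components but X supports only {a_eff} "
            "(rank exhausted)")
    return PLSModel(classes, W, P, q, T, ssy, y_mean, scaler)


def _predict_scores_path(model: PLSModel, Xs: np.ndarray) -> np.ndarray:
    """Predicted dummy after 1..A components (n x A), nested."""
    W, P, q = model.weights, model.x_loadings, model.y_loadings
    n, A = Xs.shape[0], W.shape[1]
    Xr = Xs.copy()
    yhat = np.zeros((n, A))
    acc = np.full(n, model.y_mean)
    for a in range(A):
        t = Xr @ W[:, a]
        Xr -= np.outer(t, P[:, a])
        acc = acc + q[a] * t
        yhat[:, a] = acc
    return yhat


def plsda_predict(model: PLSModel, X_new, n_components: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Predict class labels and continuous dummy scores for new rows.

    The training transform (if any) is applied to ``X_new``; predictions
    use the first ``n_components`` latent variables (default: all).  The
    class rule is positive iff the predicted dummy >= the model threshold
    (ties at the threshold go to the positive class).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2:
        raise ValueError("X_new must be 2-D")
    Xs = model.scaler.transform(X_new) if model.scaler is not None else X_new
    if Xs.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature count mismatch: {Xs.shape[1]} vs {model.weights.shape[0]}")
    A = model.n_components if n_components is None else n_components
    if not 1 <= A <= model.n_components:
        raise ValueError(f"n_components must be in [1, {model.n_components}]")
    yhat = _predict_scores_path(model, Xs)[:, A - 1]
    neg, pos = model.classes
    labels = np.where(yhat >= model.threshold, pos, neg)
    return labels, yhat


def save_model(model: PLSModel, path) -> None:
    """Serialize a fitted PLS-DA model (weights, loadings, transform,
    class coding) to JSON; :func:`load_model` restores it exactly."""
    import json

    doc = {
        "classes": list(model.classes),
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "scores": model.scores.tolist(),
        "ssy": model.ssy.tolist(),
        "y_mean": model.y_mean,
        "threshold": model.threshold,
        "centers": None if model.scaler is None else model.scaler.centers.tolist(),
        "scales": None if model.scaler is None else model.scaler.scales.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> PLSModel:
    """Restore a PLS-DA model written by :func:`save_model`."""
    import json

    with open(path) as fh:
        doc = json.load(fh)
    scaler = None
    if doc["centers"] is not None:
        scaler = Autoscaler(np.asarray(doc["centers"], dtype=float),
                            np.asarray(doc["scales"], dtype=float))
    return PLSModel(
        classes=tuple(doc["classes"]),
        weights=np.asarray(doc["weights"], dtype=float),
        x_loadings=np.asarray(doc["x_loadings"], dtype=float),
        y_loadings=np.asarray(doc["y_loadings"], dtype=float),
        scores=np.asarray(doc["scores"], dtype=float),
        ssy=np.asarray(doc["ssy"], dtype=float),
        y_mean=float(doc["y_mean"]),
        scaler=scaler,
        threshold=float(doc["threshold"]),
    )


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection for every feature."""
    W, ssy = model.weights, model.ssy
    total = ssy.sum()
    if total <= 0:
        raise ValueError("zero explained response sum of squares; VIP undefined")
    p = W.shape[0]
    wnorm2 = (W ** 2) / np.maximum((W ** 2).sum(axis=0), _EPS)
    return np.sqrt(p * (wnorm2 @ ssy) / total)


# ---------------------------------------------------------------------------
# figures of merit
# ---------------------------------------------------------------------------

@dataclass
class FiguresOfMerit:
    """Classification accuracy / sensitivity / specificity in percent."""

    accuracy: float
    sensitivity: float
    specificity: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def classification_metrics(y_true, y_pred, positive_class) -> FiguresOfMerit:
    """Accuracy, sensitivity (recall of the positive class) and specificity.

    All three are percentages; ``y_true`` must contain both classes.
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = str(positive_class)
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true contains a single class; metrics undefined")
    is_pos = y_true == pos
    pred_pos = y_pred == pos
    tp = int(np.sum(is_pos & pred_pos))
    fn = int(np.sum(is_pos & ~pred_pos))
    tn = int(np.sum(~is_pos & ~pred_pos))
    fp = int(np.sum(~is_pos & pred_pos))
    n = tp + fn + tn + fp
    return FiguresOfMerit(
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )
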