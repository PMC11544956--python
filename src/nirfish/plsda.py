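"""Two-class PLS-DA: NIPALS latent variables, prediction, VIP scores, metrics.

PLS-DA here is PLS1 regression of a {0, 1} class membership vector on the
(autoscaled) spectral matrix, thresholded at 0.5.  Each latent variable is
the direction of maximal covariance between the deflated X block and the
response; X is deflated by its rank-1 reconstruction after every component,
which makes successive score vectors orthogonal.  With as many components
as the data support, the fit collapses to ordinary least squares — a useful
oracle, exploited by the test suite.

VIP (variable importance in projection) for wavelength j over A components:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    SSY_a = q_a^2 t_a' t_a,

so that mean_j VIP_j^2 = 1 — scores above 1 flag wavelengths carrying more
than an average share of the explained class variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import AutoscaleParams, autoscale_apply, autoscale_fit

#: control -> 0, treated -> 1; a fitted response at or above 0.5 is called treated.
CLASS_CODES = {"control": 0, "treated": 1}
THRESHOLD = 0.5


@dataclass
class PLSDAModel:
    """Fitted PLS-DA classifier (PLS1 + 0.5 threshold)."""

    n_components: int
    weights: np.ndarray        # W, p x A
    x_loadings: np.ndarray     # P, p x A
    y_loadings: np.ndarray     # q, A
    scores: np.ndarray         # T, n x A (training scores)
    coef: np.ndarray           # b, p — collapsed regression vector in autoscaled space
    intercept: float
    autoscale: AutoscaleParams | None
    fitted_response: np.ndarray = field(repr=False)
    threshold: float = THRESHOLD

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]

    def coefficients_for(self, a: int) -> tuple[np.ndarray, float]:
        """Collapsed (b, intercept) using only the first ``a`` components.

        Components are nested, so one fit serves every a <= A.
        """
        W, P, q = self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
        b = W @ np.linalg.solve(P.T @ W, q)
        return b, self.intercept

    def to_json(self) -> str:
        d = {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "autoscale": None if self.autoscale is None else json.loads(self.autoscale.to_json()),
            "fitted_response": self.fitted_response.tolist(),
            "threshold": self.threshold,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "PLSDAModel":
        d = json.loads(text)
        auto = d["autoscale"]
        return cls(
            n_components=d["n_components"],
            weights=np.array(d["weights"], dtype=float),
            x_loadings=np.array(d["x_loadings"], dtype=float),
            y_loadings=np.array(d["y_loadings"], dtype=float),
            scores=np.array(d["scores"], dtype=float),
            coef=np.array(d["coef"], dtype=float),
            intercept=d["intercept"],
            autoscale=None if auto is None else AutoscaleParams(
                np.array(auto["means"], dtype=float), np.array(auto["sds"], dtype=float)
            ),
            fitted_response=np.array(d["fitted_response"], dtype=float),
            threshold=d["threshold"],
        )


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int, autoscale: bool = True) -> PLSDAModel:
    """Fit a PLS1 discriminant model of ``y`` (0/1 classes) on ``X``.

    Columns are always mean-centred (PLS works on the centred block);
    ``autoscale=True`` additionally divides by the column sd.  The centring
    and scaling constants are stored in the model and re-applied by
    :func:`predict`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size}")
    if np.unique(y).size < 2:
        raise ValueError("y contains a single class")
    A = int(n_components)
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"n_components must be in 1..min(n-1, p) = {min(n - 1, p)}, got {A}")

    if autoscale:
        params = autoscale_fit(X)
    else:
        params = AutoscaleParams(means=X.mean(axis=0), sds=np.ones(p))
    Xa = autoscale_apply(X, params)
    if not np.any(Xa.std(axis=0) > 0):
        raise ValueError("X has no variance")

    y_mean = y.mean()
    E = Xa - 0.0  # deflated X block; Xa kept for fitted values
    f = y - y_mean
    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    q = np.empty(A)
    for a in range(A):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(f"X-y covariance exhausted after {a} components; reduce n_components")
        w /= norm
        t = E @ w
        tt = t @ t
        if tt < 1e-12:
            raise ValueError(f"rank exhausted after {a} components; reduce n_components")
        p_a = E.T @ t / tt
        q_a = f @ t / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a

    b = W @ np.linalg.solve(P.T @ W, q)
    fitted = y_mean + Xa @ b
    return PLSDAModel(
        n_components=A, weights=W, x_loadings=P, y_loadings=q, scores=T,
        coef=b, intercept=y_mean, autoscale=params, fitted_response=fitted,
    )


def predict(model: PLSDAModel, X_new: np.ndarray, n_components: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Continuous response and 0/1 classes for new rows.

    A response exactly at the threshold is classified treated.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.n_variables:
        raise ValueError(f"expected {model.n_variables} columns, got {X_new.shape}")
    Xa = autoscale_apply(X_new, model.autoscale) if model.autoscale is not None else X_new
    if n_components is None:
        b = model.coef
    else:
        b, _ = model.coefficients_for(n_components)
    y_hat = model.intercept + Xa @ b
    return y_hat, (y_hat >= model.threshold).astype(int)


def transform(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Latent-variable scores of new rows (for score plots)."""
    X_new = np.asarray(X_new, dtype=float)
    Xa = autoscale_apply(X_new, model.autoscale) if model.autoscale is not None else X_new
    # t = X W (P'W)^-1 gives scores consistent with the deflation
    return Xa @ (model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights))


def vip_scores(model: PLSDAModel, n_components: int | None = None) -> np.ndarray:
    """VIP per wavelength; mean squared VIP is 1 by construction."""
    a = model.n_components if n_components is None else n_components
    W = model.weights[:, :a]
    T = model.scores[:, :a]
    q = model.y_loadings[:a]
    p = W.shape[0]
    ssy = q**2 * np.einsum("ij,ij->j", T, T)  # explained-Y sum of squares per LV
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * wnorm2 @ ssy / ssy.sum())


def coefficients(model: PLSDAModel) -> tuple[np.ndarray, float]:
    """Collapsed regression vector (autoscaled-pretreated space) and intercept."""
    return model.coef.copy(), model.intercept


@dataclass
class ClassificationMetrics:
    """Accuracy% and non-error rate (mean class sensitivity, %)."""

    accuracy: float
    ner: float
    confusion: np.ndarray  # rows true (0, 1), cols predicted (0, 1)


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> ClassificationMetrics:
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.size != y_pred.size:
        raise ValueError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    bad = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not bad <= {0, 1}:
        raise ValueError(f"labels must be 0/1, got {sorted(bad)}")
    conf = np.zeros((2, 2), dtype=int)
    for t, p_ in zip(y_true.astype(int), y_pred.astype(int)):
        conf[t, p_] += 1
    accuracy = 100.0 * np.trace(conf) / conf.sum()
    sens = [conf[c, c] / conf[c].sum() for c in (0, 1) if conf[c].sum() > 0]
    ner = 100.0 * float(np.mean(sens))
    return ClassificationMetrics(accuracy=accuracy, ner=ner, confusion=conf)
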