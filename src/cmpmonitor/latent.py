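"""Latent-variable core: unit-variance scaling, PCA, and PLS1.

All multivariate monitoring models decompose a (scaled) data matrix as
X = Σ_i t_i p_iᵀ + E; PCA chooses loadings p to maximize captured variance,
PLS1 chooses weights to maximize covariance between the X-scores t and a
single response y (here: batch maturity, i.e. time).

Everything is deterministic: PCA runs on an SVD, PLS1 on NIPALS with the
response vector as the fixed starting point, and every component's loading /
weight vector is sign-normalized so its largest-magnitude entry is positive.
Zero-variance columns (fluxes pinned to a bound across all training rows)
are dropped by the scaler rather than jittered, and new data is always
scaled with the training statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

PCA = "pca"
PLS1 = "pls1"

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


@dataclass
class Scaler:
    """Column centering/unit-variance scaling with zero-variance drop."""

    means: np.ndarray
    sds: np.ndarray                 # for retained columns only
    retained: np.ndarray            # indices of retained columns
    dropped_columns: list[int] = field(default_factory=list)
    n_columns: int = 0

    @staticmethod
    def fit(X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("scaler needs a 2-D matrix with at least 2 rows")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        retained = np.flatnonzero(sds > 0)
        dropped = [int(j) for j in np.flatnonzero(sds == 0)]
        return Scaler(means=means[retained], sds=sds[retained], retained=retained,
                      dropped_columns=dropped, n_columns=X.shape[1])

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_columns:
            raise ValueError(
                f"expected {self.n_columns} columns (training layout), got {X.shape[1]}")
        return (X[:, self.retained] - self.means) / self.sds


def _sign_fix(vec: np.ndarray) -> float:
    """Sign making the largest-|entry| of ``vec`` positive (ties: first)."""
    j = int(np.argmax(np.abs(vec)))
    return -1.0 if vec[j] < 0 else 1.0


@dataclass
class LatentModel:
    """A fitted PCA or PLS1 model on scaled data.

    ``loadings`` P and (for PLS1) ``weights`` W and ``y_loadings`` q are
    stored column-per-component.  ``explained`` is per-component captured
    variance (PCA) or squared score covariance with y (PLS1).
    """

    kind: str
    loadings: np.ndarray                 # (p_retained, A)
    n_components: int
    scaler: Scaler
    explained: np.ndarray
    scores_train: np.ndarray             # (n, A)
    weights: np.ndarray | None = None    # PLS1 only
    y_loadings: np.ndarray | None = None  # PLS1 only
    y_mean: float = 0.0
    y_sd: float = 1.0

    def _rotation(self) -> np.ndarray:
        if self.kind == PCA:
            return self.loadings
        # Deflation-consistent projection: R = W (PᵀW)⁻¹
        W, P = self.weights, self.loadings
        return W @ np.linalg.inv(P.T @ W)

    def project(self, X_new: np.ndarray) -> np.ndarray:
        """Scores of new rows (training column layout, pre-drop)."""
        return self.scaler.apply(X_new) @ self._rotation()

    def predict_y(self, X_new: np.ndarray) -> np.ndarray:
        """PLS1 response prediction on the original y scale."""
        if self.kind != PLS1:
            raise ValueError("predict_y is defined for PLS1 models only")
        t = self.project(X_new)
        return (t @ self.y_loadings) * self.y_sd + self.y_mean


def fit_scaler(X: np.ndarray) -> Scaler:
    return Scaler.fit(X)


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    return scaler.apply(X)


def fit_pca(X: np.ndarray, n_components: int) -> LatentModel:
    """PCA of the unit-variance-scaled matrix via SVD."""
    scaler = Scaler.fit(X)
    Xs = scaler.apply(X)
    n, p = Xs.shape
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise ValueError(f"n_components must be in [1, {max_a}], got {n_components}")
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    signs = np.array([_sign_fix(Vt[i]) for i in range(n_components)])
    P = (Vt[:n_components].T * signs)
    T = U[:, :n_components] * s[:n_components] * signs
    explained = (s[:n_components] ** 2) / (n - 1)
    return LatentModel(kind=PCA, loadings=P, n_components=n_components,
                       scaler=scaler, explained=explained, scores_train=T)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> LatentModel:
    """Single-response PLS by NIPALS with X (and y) deflation.

    y is centered and scaled to unit variance; the first weight vector is
    proportional to Xᵀy, subsequent ones follow from deflated data.
    """
    y = np.asarray(y, dtype=float).ravel()
    scaler = Scaler.fit(X)
    Xs = scaler.apply(X)
    n, p = Xs.shape
    if y.size != n:
        raise ValueError("y length must match the number of rows of X")
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    if y_sd == 0:
        raise ValueError("y has zero variance")
    ys = (y - y_mean) / y_sd
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise ValueError(f"n_components must be in [1, {max_a}], got {n_components}")

    W = np.zeros((Xs.shape[1], n_components))
    P = np.zeros_like(W)
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd, yd = Xs.copy(), ys.copy()
    for a in range(n_components):
        u = yd.copy()
        w = np.zeros(Xs.shape[1])
        for it in range(NIPALS_MAX_ITER):
            w_new = Xd.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ArithmeticError(f"PLS1 component {a + 1}: X is exhausted (zero weight)")
            w_new /= norm
            t = Xd @ w_new
            qa = float(yd @ t / (t @ t))
            u_new = yd * 1.0  # single response: u stays proportional to y
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w, u = w_new, u_new
        else:
            raise ArithmeticError(f"PLS1 NIPALS did not converge on component {a + 1}")
        w *= _sign_fix(w)
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ArithmeticError(f"PLS1 component {a + 1}: zero score vector")
        pvec = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t
    explained = (q * np.sqrt(np.sum(T**2, axis=0))) ** 2
    return LatentModel(kind=PLS1, loadings=P, n_components=n_components, scaler=scaler,
                       explained=explained, scores_train=T, weights=W, y_loadings=q,
                       y_mean=y_mean, y_sd=y_sd)


def project_scores(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    return model.project(X_new)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def model_to_dict(model: LatentModel) -> dict:
    data = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "n_components": model.n_components,
        "loadings": model.loadings.tolist(),
        "explained": model.explained.tolist(),
        "scores_train": model.scores_train.tolist(),
        "scaler": {
            "means": model.scaler.means.tolist(),
            "sds": model.scaler.sds.tolist(),
            "retained": model.scaler.retained.tolist(),
            "dropped_columns": model.scaler.dropped_columns,
            "n_columns": model.scaler.n_columns,
        },
    }
    if model.kind == PLS1:
        data.update(weights=model.weights.tolist(), y_loadings=model.y_loadings.tolist(),
                    y_mean=model.y_mean, y_sd=model.y_sd)
    return data


def model_from_dict(data: dict) -> LatentModel:
    if data.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {data.get('format_version')}")
    sc = data["scaler"]
    scaler = Scaler(means=np.array(sc["means"]), sds=np.array(sc["sds"]),
                    retained=np.array(sc["retained"], dtype=int),
                    dropped_columns=list(sc["dropped_columns"]),
                    n_columns=int(sc["n_columns"]))
    kind = data["kind"]
    return LatentModel(
        kind=kind,
        loadings=np.array(data["loadings"]),
        n_components=int(data["n_components"]),
        scaler=scaler,
        explained=np.array(data["explained"]),
        scores_train=np.array(data["scores_train"]),
        weights=np.array(data["weights"]) if kind == PLS1 else None,
        y_loadings=np.array(data["y_loadings"]) if kind == PLS1 else None,
        y_mean=float(data.get("y_mean", 0.0)),
        y_sd=float(data.get("y_sd", 1.0)),
    )


def save_model(model: LatentModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> LatentModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
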