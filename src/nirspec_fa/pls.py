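"""NIPALS partial least squares regression with Hotelling outlier screening.

Implements PLS1 (single response) by the classical NIPALS deflation: X and y
are column-mean-centered, and per factor a weight vector ``w`` maximising
covariance with the residual response is extracted, scores ``t = X w``
computed, and X and y deflated by the rank-one fits.  No unit-variance
scaling is applied to X; that is the usual choice for absorbance spectra,
whose variance structure is itself informative.

The regression coefficient vector in the original (centered) X space is
``b = W (P'W)^{-1} q``, so prediction is a single matrix-vector product.

The Hotelling statistic of a sample is its squared Mahalanobis-type distance
in score space, ``H = sum_k t_k^2 / var(t_k)``, with the score variances
taken from the calibration set (sample variance, n-1 denominator).  Samples
with H above a cutoff (10 by default) are treated as spectral outliers and
the model is refitted once without them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, DegenerateTargetError

logger = logging.getLogger(__name__)

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model.

    Attributes
    ----------
    n_factors : number of latent factors F.
    x_mean, y_mean : centering vectors from the calibration set.
    weights : (p, F) NIPALS weight vectors W.
    x_loadings : (p, F) X loadings P.
    y_loadings : (F,) y loadings q.
    rotation : (p, F) matrix R = W (P'W)^{-1}; scores of any X are
        (X - x_mean) @ R.
    score_variances : (F,) sample variances of the calibration scores.
    coef : (p,) regression vector b in centered X space.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    rotation: np.ndarray
    score_variances: np.ndarray
    coef: np.ndarray
    n_samples: int
    meta: dict = field(default_factory=dict)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Predict the response: ``y_mean + (X_new - x_mean) @ coef``."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"X has {X_new.shape[1]} wavelengths, model expects {self.x_mean.size}"
            )
        return self.y_mean + (X_new - self.x_mean) @ self.coef

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Latent scores of samples under the fitted rotation."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.rotation

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_factors": int(self.n_factors),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "rotation": self.rotation.tolist(),
            "score_variances": self.score_variances.tolist(),
            "coef": self.coef.tolist(),
            "n_samples": int(self.n_samples),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_factors=int(d["n_factors"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            rotation=np.asarray(d["rotation"], dtype=float),
            score_variances=np.asarray(d["score_variances"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            n_samples=int(d["n_samples"]),
            meta=dict(d.get("meta", {})),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "PLSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """Run NIPALS deflation; returns W, P, q and calibration scores T."""
    n, p = Xc.shape
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    T = np.empty((n, n_factors))
    X = Xc.copy()
    y = yc.copy()
    k_done = 0
    for k in range(n_factors):
        cov = X.T @ y
        norm = np.linalg.norm(cov)
        if norm < 1e-13 * max(1.0, np.linalg.norm(Xc) * np.linalg.norm(yc)):
            break  # residual response fully explained; stop early
        w = cov / norm
        # For a single response the weight update is stationary after one
        # pass; the loop is kept for the defined convergence contract.
        for _ in range(_NIPALS_MAX_ITER):
            t = X @ w
            tt = t @ t
            if tt == 0:
                raise ConvergenceError("zero score vector in NIPALS")
            qk = (y @ t) / tt
            cov = X.T @ (y * 1.0)
            w_new = cov / np.linalg.norm(cov)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        else:
            raise ConvergenceError(
                f"NIPALS factor {k + 1} did not converge in {_NIPALS_MAX_ITER} iterations"
            )
        t = X @ w
        tt = t @ t
        pk = X.T @ t / tt
        qk = (y @ t) / tt
        X = X - np.outer(t, pk)
        y = y - qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t
        k_done += 1
    if k_done == 0:
        raise DegenerateTargetError("response carries no covariance with X")
    return W[:, :k_done], P[:, :k_done], q[:k_done], T[:, :k_done]


def fit_pls(X: np.ndarray, y: np.ndarray, n_factors: int, meta: dict | None = None) -> PLSModel:
    """Fit a NIPALS PLS1 model with *n_factors* latent factors.

    X and y are centered internally.  Raises
    :class:`~nirspec_fa.errors.DegenerateTargetError` for a constant y.
    If the response is exhausted before *n_factors* factors (exactly
    collinear data), the model keeps the factors actually extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have different numbers of samples")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors > min(n - 1, p):
        raise ValueError(
            f"n_factors={n_factors} exceeds min(n_samples-1, n_wavelengths)="
            f"{min(n - 1, p)}"
        )
    if n < n_factors + 2:
        raise ValueError("need at least n_factors + 2 samples")
    if np.var(y) == 0:
        raise DegenerateTargetError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals(X - x_mean, y - y_mean, n_factors)
    F = W.shape[1]
    if F < n_factors:
        logger.info("NIPALS stopped early at %d of %d factors", F, n_factors)
    rotation = W @ np.linalg.inv(P.T @ W)
    coef = rotation @ q
    score_var = T.var(axis=0, ddof=1)
    return PLSModel(
        n_factors=F,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        rotation=rotation,
        score_variances=score_var,
        coef=coef,
        n_samples=n,
        meta=meta or {},
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`PLSModel.predict`."""
    return model.predict(X_new)


def _cv_predictions(X, y, F_max, folds, seed):
    """Cross-validated predictions for every factor count 1..F_max.

    Venetian-blind folds on a seeded permutation of the samples.  Returns an
    (F_max, n) array of out-of-fold predictions.
    """
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    preds = np.full((F_max, n), np.nan)
    for f in range(folds):
        test = fold_of == f
        train = ~test
        Xtr, ytr = X[train], y[train]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        F_fit = min(F_max, Xtr.shape[0] - 1)
        W, P, q, _ = _nipals(Xtr - xm, ytr - ym, F_fit)
        Xc_test = X[test] - xm
        # Nested models: coefficients for every truncation share one run.
        for F in range(1, W.shape[1] + 1):
            R = W[:, :F] @ np.linalg.inv(P[:, :F].T @ W[:, :F])
            b = R @ q[:F]
            preds[F - 1, test] = ym + Xc_test @ b
        for F in range(W.shape[1] + 1, F_max + 1):
            preds[F - 1, test] = preds[W.shape[1] - 1, test]
    return preds


def cross_val_r2(X, y, F_max, folds=10, seed=0) -> np.ndarray:
    """Cross-validated squared correlation for each factor count 1..F_max."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    preds = _cv_predictions(X, y, F_max, folds, seed)
    out = np.zeros(F_max)
    for F in range(F_max):
        p = preds[F]
        if np.std(p) == 0 or np.std(y) == 0:
            out[F] = 0.0
        else:
            r = np.corrcoef(y, p)[0, 1]
            # guard against anti-correlated CV predictions inflating R^2
            out[F] = max(r, 0.0) ** 2
    return out


def select_factors(X, y, F_max, folds=10, seed=0) -> int:
    """Pick the factor count by venetian-blind cross-validation.

    Uses the one-standard-error rule on the cross-validated squared error:
    the smallest F whose CV MSE lies within one standard error of the best
    is returned, so statistically indistinguishable candidates resolve to
    the simplest model (pure-noise targets return 1) while genuine latent
    structure is resolved exactly (a noiseless rank-r system returns r).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    preds = _cv_predictions(X, y, F_max, folds, seed)
    sq_err = (preds - y[None, :]) ** 2
    mse = sq_err.mean(axis=1)
    best = int(np.argmin(mse))
    se_best = sq_err[best].std(ddof=1) / np.sqrt(y.size)
    for F in range(F_max):
        if mse[F] <= mse[best] + se_best:
            return F + 1
    return best + 1  # pragma: no cover


@dataclass
class HotellingResult:
    """Per-sample Hotelling statistics against a fitted model."""

    h: np.ndarray
    threshold: float
    outlier_flags: np.ndarray

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())


def hotelling_h(model: PLSModel, X: np.ndarray, threshold: float = 10.0) -> HotellingResult:
    """Hotelling statistic ``H = sum_k t_k^2 / var_k`` per sample.

    A sample at the calibration centroid has H = 0; over the calibration set
    the mean H equals F (n-1)/n by the variance identity of centered scores.
    """
    T = model.scores(X)
    h = np.sum(T**2 / model.score_variances, axis=1)
    return HotellingResult(h=h, threshold=threshold, outlier_flags=h > threshold)


def remove_outliers_refit(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    threshold: float = 10.0,
) -> tuple[PLSModel, np.ndarray]:
    """Fit, flag H > threshold, drop flagged samples and refit once.

    Returns the refitted model and the integer indices of removed samples.
    If removal would leave fewer than ``n_factors + 2`` samples the original
    model is returned with a warning and nothing is removed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    model = fit_pls(X, y, n_factors)
    res = hotelling_h(model, X, threshold=threshold)
    removed = np.nonzero(res.outlier_flags)[0]
    if removed.size == 0:
        return model, removed
    keep = ~res.outlier_flags
    if keep.sum() < n_factors + 2:
        warnings.warn(
            "outlier removal would leave too few samples; keeping original model",
            stacklevel=2,
        )
        return model, np.array([], dtype=int)
    refit = fit_pls(X[keep], y[keep], n_factors, meta=model.meta)
    return refit, removed
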