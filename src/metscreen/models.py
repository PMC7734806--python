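"""Two-group classifiers: Fisher discriminant with a KDE boundary, logistic.

The Fisher direction maximizes J = (tbar1 - tbar2)^2 / (s1^2 + s2^2), the
squared gap between projected group means over the summed projected sample
variances.  The decision boundary sits on the score axis at the one-sided
``confidence`` quantile of a Gaussian KDE fit to the positive-group scores;
scores at or below the boundary are labeled positive (case).

Both fitters z-score the inputs with pooled training mean/sd; raw
abundances span several orders of magnitude across features and an
unstandardized fit would be dominated by the large-scale ones.  Held-out
samples must be transformed with the training constants only.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from metscreen.cohort import CASE_LABEL, CONTROL_LABEL

DEFAULT_CONFIDENCE = 0.975
CONFIDENCE_GRID = np.round(np.arange(0.50, 1.00, 0.01), 2)
SCATTER_RIDGE = 1e-6
LOGISTIC_RIDGE = 1e-4


class ModelError(ValueError):
    """Raised for invalid model inputs."""


# -- standardization -----------------------------------------------------------


def _pooled_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0.0, 1.0, sd)
    return mu, sd


# -- Fisher discriminant -------------------------------------------------------


@dataclass
class FdaModel:
    """A fitted Fisher discriminant with its score-axis decision boundary."""

    direction: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    t1_bar: float
    t2_bar: float
    s1_sq: float
    s2_sq: float
    j_value: float
    boundary: float
    confidence: float
    positive_group: str = CASE_LABEL

    def scores(self, X: Sequence[Sequence[float]]) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.direction.size:
            raise ModelError(
                f"expected {self.direction.size} features, got {X.shape[1]}"
            )
        return ((X - self.mu) / self.sigma) @ self.direction

    def to_json(self) -> str:
        d = {
            "kind": "fda",
            "direction": self.direction.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "t1_bar": self.t1_bar,
            "t2_bar": self.t2_bar,
            "s1_sq": self.s1_sq,
            "s2_sq": self.s2_sq,
            "j_value": self.j_value,
            "boundary": self.boundary,
            "confidence": self.confidence,
            "positive_group": self.positive_group,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "FdaModel":
        d = json.loads(text)
        if d.pop("kind") != "fda":
            raise ModelError("not a Fisher-discriminant model export")
        for k in ("direction", "mu", "sigma"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def fda_fit(
    X_case: Sequence[Sequence[float]],
    X_control: Sequence[Sequence[float]],
    confidence: float = DEFAULT_CONFIDENCE,
    standardize: bool = True,
    place_boundary: bool = True,
) -> FdaModel:
    """Fit the Fisher direction and place the KDE boundary.

    The direction solves the pooled within-group scatter system
    ``Sw p = (m1 - m2)`` (ridge-stabilized when singular), is normalized to
    unit length and signed so the case group sits on the lower-score side.
    """
    Xc = np.atleast_2d(np.asarray(X_case, dtype=float))
    Xt = np.atleast_2d(np.asarray(X_control, dtype=float))
    if Xc.shape[0] < 2 or Xt.shape[0] < 2:
        raise ModelError("each group needs at least 2 rows")
    if Xc.shape[1] != Xt.shape[1]:
        raise ModelError("group matrices have different feature counts")
    if standardize:
        mu, sigma = _pooled_standardizer(np.vstack([Xc, Xt]))
    else:
        mu = np.zeros(Xc.shape[1])
        sigma = np.ones(Xc.shape[1])
    Zc = (Xc - mu) / sigma
    Zt = (Xt - mu) / sigma
    dmean = Zc.mean(axis=0) - Zt.mean(axis=0)
    if not np.any(dmean):
        # degenerate: identical group means -> J = 0, any direction admissible
        direction = np.zeros(Zc.shape[1])
        direction[0] = 1.0
    else:
        n1, n2 = Zc.shape[0], Zt.shape[0]
        Sw = (n1 - 1) * np.cov(Zc, rowvar=False, ddof=1) + (n2 - 1) * np.cov(
            Zt, rowvar=False, ddof=1
        )
        Sw = np.atleast_2d(Sw)
        try:
            direction = np.linalg.solve(Sw, dmean)
        except np.linalg.LinAlgError:
            ridge = SCATTER_RIDGE * np.trace(Sw)
            if ridge == 0.0:
                ridge = SCATTER_RIDGE
            direction = np.linalg.solve(Sw + ridge * np.eye(Sw.shape[0]), dmean)
        direction = direction / np.linalg.norm(direction)
    tc = Zc @ direction
    tt = Zt @ direction
    if tc.mean() > tt.mean():
        direction = -direction
        tc, tt = -tc, -tt
    s1_sq = float(tc.var(ddof=1))
    s2_sq = float(tt.var(ddof=1))
    denom = s1_sq + s2_sq
    j = float((tc.mean() - tt.mean()) ** 2 / denom) if denom > 0 else 0.0
    # callers that immediately re-balance the confidence (e.g. LOOCV folds)
    # can skip the initial boundary placement
    boundary = kde_boundary(tc, confidence) if place_boundary else math.nan
    return FdaModel(
        direction=direction,
        mu=mu,
        sigma=sigma,
        t1_bar=float(tc.mean()),
        t2_bar=float(tt.mean()),
        s1_sq=s1_sq,
        s2_sq=s2_sq,
        j_value=j,
        boundary=boundary,
        confidence=confidence,
    )


def fisher_objective(X_case: np.ndarray, X_control: np.ndarray, direction: np.ndarray) -> float:
    """J for an arbitrary direction (used by optimality spot checks)."""
    p = np.asarray(direction, dtype=float)
    p = p / np.linalg.norm(p)
    tc = np.atleast_2d(X_case) @ p
    tt = np.atleast_2d(X_control) @ p
    denom = tc.var(ddof=1) + tt.var(ddof=1)
    return float((tc.mean() - tt.mean()) ** 2 / denom) if denom > 0 else 0.0


# -- KDE decision boundary -----------------------------------------------------

_GRID_POINTS = 2048


def kde_thresholds(scores: Sequence[float], confidences: Sequence[float]) -> np.ndarray:
    """Score thresholds at one-sided KDE mass levels (vectorized).

    Gaussian kernel, Silverman bandwidth, numerically integrated on a
    2048-point grid spanning 4 bandwidths beyond the score range.
    """
    s = np.asarray(scores, dtype=float)
    conf = np.asarray(confidences, dtype=float)
    if s.size < 5:
        raise ModelError("KDE boundary needs at least 5 scores")
    if np.any(conf < 0.5) or np.any(conf >= 1.0):
        raise ModelError("confidence must lie in [0.5, 1)")
    if np.ptp(s) == 0.0:
        return np.full(conf.shape, s[0])
    kde = stats.gaussian_kde(s, bw_method="silverman")
    bw = kde.factor * s.std(ddof=1)
    grid = np.linspace(s.min() - 4 * bw, s.max() + 4 * bw, _GRID_POINTS)
    pdf = kde(grid)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0 * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(conf, cdf, grid)


def kde_boundary(case_scores: Sequence[float], confidence: float) -> float:
    """The score below which a KDE of the case scores holds ``confidence`` mass.

    The case group occupies the lower-score side, so this is the upper
    one-sided quantile of the positive-group score density.
    """
    return float(kde_thresholds(case_scores, [confidence])[0])


def _training_errors(model: FdaModel, tc: np.ndarray, tt: np.ndarray, boundary: float):
    type1 = float(np.mean(tt <= boundary))  # controls labeled case
    type2 = float(np.mean(tc > boundary))  # cases labeled control
    return type1, type2


def balance_confidence(
    model: FdaModel,
    X_case: Sequence[Sequence[float]],
    X_control: Sequence[Sequence[float]],
) -> FdaModel:
    """Pick the boundary confidence that balances type I and type II errors.

    Grid search over {0.50, 0.51, ..., 0.99}; minimizes |typeI - typeII| on
    the training data, ties broken toward smaller total error, then smaller
    confidence.
    """
    tc = model.scores(X_case)
    tt = model.scores(X_control)
    if np.ptp(tc) == 0.0:
        return replace(model, boundary=float(tc[0]), confidence=float(CONFIDENCE_GRID[0]))
    thresholds = kde_thresholds(tc, CONFIDENCE_GRID)
    best = None
    for conf, thr in zip(CONFIDENCE_GRID, thresholds):
        t1, t2 = _training_errors(model, tc, tt, thr)
        key = (abs(t1 - t2), t1 + t2, conf)
        if best is None or key < best[0]:
            best = (key, conf, thr)
    _, conf, thr = best
    return replace(model, boundary=float(thr), confidence=float(conf))


# -- logistic regression -------------------------------------------------------


@dataclass
class LogisticModel:
    """A fitted binary logistic regression (case = positive class)."""

    coefficients: np.ndarray  # per retained feature, standardized scale
    intercept: float
    mu: np.ndarray
    sigma: np.ndarray
    kept: np.ndarray  # indices of retained (non-constant) features
    n_features: int
    ridged: bool = False
    positive_group: str = CASE_LABEL

    def predict_proba(self, X: Sequence[Sequence[float]]) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ModelError(f"expected {self.n_features} features, got {X.shape[1]}")
        Z = (X[:, self.kept] - self.mu) / self.sigma
        eta = np.clip(self.intercept + Z @ self.coefficients, -700, 700)
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "logistic",
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "mu": self.mu.tolist(),
                "sigma": self.sigma.tolist(),
                "kept": self.kept.tolist(),
                "n_features": self.n_features,
                "ridged": self.ridged,
                "positive_group": self.positive_group,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        if d.pop("kind") != "logistic":
            raise ModelError("not a logistic model export")
        for k in ("coefficients", "mu", "sigma"):
            d[k] = np.asarray(d[k], dtype=float)
        d["kept"] = np.asarray(d["kept"], dtype=int)
        return cls(**d)


def _penalized_nll(X1: np.ndarray, y: np.ndarray, beta: np.ndarray, penalty: np.ndarray) -> float:
    eta = X1 @ beta
    # log(1 + e^eta) - y*eta, computed stably
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(penalty * beta**2))


def _irls(Z: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 100) -> np.ndarray | None:
    """Damped Newton/IRLS for logistic MLE; returns None on failure."""
    X1 = np.column_stack([np.ones(Z.shape[0]), Z])
    beta = np.zeros(X1.shape[1])
    penalty = np.full(X1.shape[1], ridge)
    penalty[0] = 0.0  # never penalize the intercept
    nll = _penalized_nll(X1, y, beta, penalty)
    for _ in range(max_iter):
        eta = np.clip(X1 @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-12)
        H = X1.T @ (X1 * w[:, None]) + np.diag(penalty)
        g = X1.T @ (y - p) - penalty * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        # step halving keeps the penalized deviance monotone
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            cand_nll = _penalized_nll(X1, y, candidate, penalty)
            if cand_nll <= nll + 1e-12:
                break
            scale *= 0.5
        else:
            return beta if np.max(np.abs(g)) < 1e-6 else None
        beta, nll = candidate, cand_nll
        if np.max(np.abs(scale * step)) < 1e-10 or np.max(np.abs(g)) < 1e-10:
            return beta
        if ridge == 0.0:
            # MLE does not exist once the groups are cleanly pushed apart
            eta_new = X1 @ beta
            if np.max(np.abs(beta)) > 5e2 or (
                eta_new[y == 1].min() > 10.0 and eta_new[y == 0].max() < -10.0
            ):
                return None
    return beta if np.max(np.abs(g)) < 1e-6 else None


def logistic_fit(
    X: Sequence[Sequence[float]],
    labels: Sequence[str] | Sequence[int],
    positive_group: str = CASE_LABEL,
) -> LogisticModel:
    """Maximum-likelihood logistic fit for mixed continuous/binary predictors.

    Constant features are dropped with a warning.  If the MLE does not
    exist (perfect or quasi separation) the fit falls back to a small L2
    ridge and the model is flagged ``ridged``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub":
        y = labels.astype(float)
    else:
        y = (labels == positive_group).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ModelError("each group needs at least 2 participants")
    sd = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(kept.tolist()))
        warnings.warn(f"constant feature column(s) dropped from logistic fit: {dropped}")
    mu, sigma = _pooled_standardizer(X[:, kept]) if kept.size else (np.empty(0), np.empty(0))
    Z = (X[:, kept] - mu) / sigma if kept.size else np.empty((X.shape[0], 0))
    beta = _irls(Z, y, ridge=0.0)
    ridged = False
    if beta is None:
        beta = _irls(Z, y, ridge=LOGISTIC_RIDGE)
        ridged = True
        if beta is None:
            raise ModelError("logistic fit failed to converge even with ridge fallback")
    return LogisticModel(
        coefficients=beta[1:],
        intercept=float(beta[0]),
        mu=mu,
        sigma=sigma,
        kept=kept,
        n_features=X.shape[1],
        ridged=ridged,
        positive_group=positive_group,
    )


# -- prediction ----------------------------------------------------------------


def classify(model: FdaModel | LogisticModel, x: Sequence[float]) -> tuple[str, float]:
    """(label, score-or-probability) for one feature vector.

    Fisher models label the sample positive iff its score is at or below
    the boundary.  Logistic models take the higher-probability group; an
    exact 0.5 tie goes to the negative (control) group.
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if isinstance(model, FdaModel):
        score = float(model.scores(x)[0])
        label = model.positive_group if score <= model.boundary else CONTROL_LABEL
        return label, score
    if isinstance(model, LogisticModel):
        p = float(model.predict_proba(x)[0])
        label = model.positive_group if p > 0.5 else CONTROL_LABEL
        return label, p
    raise ModelError(f"unknown model type {type(model).__name__}")
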