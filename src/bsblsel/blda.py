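"""Bayesian linear discriminant analysis (BLDA).

The standard ERP classifier: Bayesian linear regression onto class-balanced
targets ``+N/N1`` / ``-N/N2`` with a zero-mean Gaussian weight prior, where
the prior precision ``alpha`` and noise precision ``beta`` are estimated by
evidence maximisation (MacKay fixed-point updates).  Equivalent to an
automatically regularised ridge discriminant; there is nothing to tune and
fitting is deterministic.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = ["BLDA", "blda_fit", "blda_score"]


class BLDA(ClassifierMixin, BaseEstimator):
    """Evidence-maximised Bayesian LDA.

    Parameters
    ----------
    prior : {'isotropic', 'per_feature'}
        One shared prior precision, or an ARD-style precision per weight.
    alpha, beta : float, optional
        Fix the prior/noise precisions instead of estimating them (the
        model then reduces to ridge regression with penalty alpha/beta).
    tol : float
        Relative fixed-point tolerance on (alpha, beta).
    max_iter : int
        Maximum fixed-point iterations.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Discriminant weights.
    intercept_ : float
        Bias term.
    alpha_ : float or ndarray
        Converged prior precision(s).
    beta_ : float
        Converged noise precision.
    """

    def __init__(self, prior: str = "isotropic", tol: float = 1e-6,
                 max_iter: int = 500, alpha: float | None = None,
                 beta: float | None = None):
        self.prior = prior
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha
        self.beta = beta

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"BLDA needs exactly two classes, got {classes}")
        self.classes_ = classes
        n = y.size
        pos = y == classes[1]
        n1, n2 = int(pos.sum()), int((~pos).sum())
        t = np.where(pos, n / n1, -n / n2).astype(float)

        Phi = np.hstack([X, np.ones((n, 1))])
        d = Phi.shape[1]
        if self.alpha is not None and self.beta is not None:
            # fixed hyperparameters: plain MAP / ridge solution
            A = self.beta * (Phi.T @ Phi) + self.alpha * np.eye(d)
            w = self.beta * np.linalg.solve(A, Phi.T @ t)
            alpha, beta, n_iter = float(self.alpha), float(self.beta), 0
        elif self.prior == "isotropic":
            w, alpha, beta, n_iter = self._fit_isotropic(Phi, t)
        elif self.prior == "per_feature":
            w, alpha, beta, n_iter = self._fit_ard(Phi, t)
        else:
            raise ValueError("prior must be 'isotropic' or 'per_feature'")
        self.coef_ = w[:-1]
        self.intercept_ = float(w[-1])
        self.alpha_ = alpha
        self.beta_ = float(beta)
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_isotropic(self, Phi, t):
        n, d = Phi.shape
        # eigenbasis of Phi'Phi lets every fixed-point step reuse one eigh
        lam, V = np.linalg.eigh(Phi.T @ Phi)
        lam = np.maximum(lam, 0.0)
        Pt = V.T @ (Phi.T @ t)
        tt = float(t @ t)
        alpha, beta = 1.0, 1.0
        w_eig = Pt * 0.0
        for it in range(self.max_iter):
            w_eig = beta * Pt / (beta * lam + alpha)
            gamma_eff = float(np.sum(beta * lam / (beta * lam + alpha)))
            w_norm2 = float(w_eig @ w_eig)
            sse = tt - 2 * float(w_eig @ Pt) + float((w_eig * lam) @ w_eig)
            # caps keep the fixed point finite on perfectly separable data,
            # where the residual collapses and beta would diverge
            sse = max(sse, 1e-12 * max(tt, 1.0))
            alpha_new = float(np.clip(gamma_eff / max(w_norm2, 1e-300),
                                      1e-12, 1e12))
            beta_new = float(np.clip(max(n - gamma_eff, 1e-10) / sse,
                                     1e-12, 1e10))
            if (abs(alpha_new - alpha) <= self.tol * abs(alpha)
                    and abs(beta_new - beta) <= self.tol * abs(beta)):
                alpha, beta = alpha_new, beta_new
                break
            alpha, beta = alpha_new, beta_new
        w = V @ (beta * Pt / (beta * lam + alpha))
        return w, float(alpha), float(beta), it + 1

    def _fit_ard(self, Phi, t):
        n, d = Phi.shape
        G = Phi.T @ Phi
        Pt = Phi.T @ t
        alpha = np.ones(d)
        beta = 1.0
        w = np.zeros(d)
        for it in range(self.max_iter):
            A = beta * G + np.diag(alpha)
            Sigma = np.linalg.inv(A)
            w = beta * Sigma @ Pt
            gam = 1.0 - alpha * np.diag(Sigma)
            alpha_new = gam / np.maximum(w ** 2, 1e-300)
            alpha_new = np.minimum(alpha_new, 1e12)
            sse = float(np.sum((t - Phi @ w) ** 2))
            beta_new = max(n - float(gam.sum()), 1e-10) / max(sse, 1e-300)
            if (np.all(np.abs(alpha_new - alpha) <= self.tol * np.abs(alpha))
                    and abs(beta_new - beta) <= self.tol * abs(beta)):
                alpha, beta = alpha_new, beta_new
                break
            alpha, beta = alpha_new, beta_new
        return w, alpha, float(beta), it + 1

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape}")
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores >= 0, self.classes_[1], self.classes_[0])


def blda_fit(features, labels, prior: str = "isotropic") -> BLDA:
    """Fit a BLDA model (thin wrapper over the estimator)."""
    return BLDA(prior=prior).fit(features, labels)


def blda_score(model: BLDA, features) -> np.ndarray:
    """Affine decision score per row; higher means more target-like."""
    return model.decision_function(features)
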