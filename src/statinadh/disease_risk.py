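"""Multi-outcome disease-risk model with cross-validated out-of-fold scores.

Hospitalization outcomes (MI, stroke, CAD, kidney disease within a horizon)
are rare and related, so the per-outcome logistic coefficient vectors are
shrunk toward a shared across-outcome mean: outcome g has coefficients
beta_g = mu + delta_g with ridge penalties on both the deviations delta_g
and the mean mu (intercepts are unpenalized). As the deviation penalty grows
the outcomes coalesce onto one common model; as both penalties vanish the
fit decouples into independent logistic regressions. Risk scores are always
out-of-fold: each patient's predicted probabilities come from a model whose
training folds excluded that patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import KFold

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["RiskModel", "HierLogistic", "fit_risk", "risk_tertile_km",
           "TertileKM"]


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class HierLogistic:
    """Penalized multi-outcome logistic fit with a shared coefficient mean.

    Minimizes sum_g [logistic deviance of outcome g] +
    lam_dev * sum_g ||delta_g||^2 + lam_mean * ||mu||^2 over intercepts a_g,
    shared mean mu and deviations delta_g, with beta_g = mu + delta_g.
    Features are standardized internally with training statistics.
    """

    def __init__(self, lam_dev: float = 1.0, lam_mean: float = 0.1,
                 max_iter: int = 200):
        self.lam_dev = lam_dev
        self.lam_mean = lam_mean
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "HierLogistic":
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        G = Y.shape[1]
        self._mu_x = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd_x = sd
        Z = (X - self._mu_x) / sd

        def unpack(w):
            a = w[:G]
            mu = w[G:G + p]
            D = w[G + p:].reshape(G, p)
            return a, mu, D

        def objective(w):
            a, mu, D = unpack(w)
            B = mu[None, :] + D                      # (G, p)
            eta = Z @ B.T + a[None, :]               # (n, G)
            # stable logistic deviance: sum log(1+exp(eta)) - y*eta
            loss = np.logaddexp(0.0, eta).sum() - (Y * eta).sum()
            loss += self.lam_dev * (D ** 2).sum() + self.lam_mean * (mu ** 2).sum()
            pr = _sigmoid(eta)
            R = pr - Y                               # (n, G)
            ga = R.sum(axis=0)
            GB = R.T @ Z                             # (G, p) grad wrt beta_g
            gmu = GB.sum(axis=0) + 2 * self.lam_mean * mu
            gD = GB + 2 * self.lam_dev * D
            return loss, np.concatenate([ga, gmu, gD.ravel()])

        w0 = np.zeros(G + p + G * p)
        res = minimize(objective, w0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter})
        self.intercepts_, self.mu_, self.deltas_ = unpack(res.x)
        self.coefs_ = self.mu_[None, :] + self.deltas_   # standardized scale
        self.n_outcomes_ = G
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self._mu_x) / self._sd_x
        return _sigmoid(Z @ self.coefs_.T + self.intercepts_[None, :])

    def raw_coefs(self) -> np.ndarray:
        """Coefficients on the original (unstandardized) feature scale."""
        return self.coefs_ / self._sd_x[None, :]


@dataclass
class RiskModel:
    outcome_names: list
    fold_assignment: np.ndarray          # fold index per patient row
    oof_probs: pd.DataFrame              # per-outcome out-of-fold probabilities
    composite_risk: pd.Series            # P(any event) = 1 - prod(1 - p_g)
    lam_per_fold: list
    models: list


def _log_loss(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _select_lambda(X, Y, grid, seed, inner_folds=5, max_iter=80):
    """Pick (lam_dev, lam_mean) by inner-CV mean log-loss."""
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    best, best_loss = grid[0], np.inf
    for lam in grid:
        losses = []
        for tr, te in kf.split(X):
            m = HierLogistic(*lam, max_iter=max_iter).fit(X[tr], Y[tr])
            p = m.predict_proba(X[te])
            losses.append(np.mean([_log_loss(Y[te][:, g], p[:, g])
                                   for g in range(Y.shape[1])]))
        loss = float(np.mean(losses))
        if loss < best_loss:
            best, best_loss = lam, loss
    return best


DEFAULT_LAMBDA_GRID = ((0.5, 0.05), (5.0, 0.5), (50.0, 5.0))


def fit_risk(X, Y, n_folds: int = 30, seed: int = 0,
             lambda_grid=DEFAULT_LAMBDA_GRID, fixed_lambda=None,
             patient_ids=None) -> RiskModel:
    """Cross-validated multi-outcome risk fit with out-of-fold probabilities.

    Parameters
    ----------
    X : (n, p) design (DataFrame or array); missing values not allowed.
    Y : (n, G) binary labels, one column per diagnosis group (G >= 2).
    n_folds : patient-level CV folds (default 30).
    lambda_grid : candidate (lam_dev, lam_mean) pairs, selected per training
        fold by 5-fold inner CV on log-loss; pass ``fixed_lambda`` to skip
        the inner search.
    """
    if isinstance(Y, pd.DataFrame):
        outcome_names = list(Y.columns)
        Yv = Y.to_numpy(float)
    else:
        Yv = np.asarray(Y, float)
        outcome_names = [f"outcome_{g}" for g in range(Yv.shape[1])]
    if Yv.ndim != 2 or Yv.shape[1] < 2:
        raise ValueError("need at least 2 outcomes to borrow strength across")
    if not np.isin(Yv, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if np.isnan(Xv).any():
        raise ValueError("design matrix contains missing values; impute first")
    n = Xv.shape[0]
    if patient_ids is None:
        patient_ids = np.arange(n)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full((n, Yv.shape[1]), np.nan)
    fold_of = np.full(n, -1, int)
    lams, models = [], []
    for fold, (tr, te) in enumerate(kf.split(Xv)):
        lam = fixed_lambda if fixed_lambda is not None else _select_lambda(
            Xv[tr], Yv[tr], lambda_grid, seed=seed + fold)
        m = HierLogistic(*lam).fit(Xv[tr], Yv[tr])
        oof[te] = m.predict_proba(Xv[te])
        fold_of[te] = fold
        lams.append(lam)
        models.append(m)
    oof_df = pd.DataFrame(oof, index=pd.Index(patient_ids, name="patient_id"),
                          columns=outcome_names)
    composite = 1.0 - (1.0 - oof_df).prod(axis=1)
    composite.name = "composite_risk"
    return RiskModel(outcome_names=outcome_names, fold_assignment=fold_of,
                     oof_probs=oof_df, composite_risk=composite,
                     lam_per_fold=lams, models=models)


@dataclass
class TertileKM:
    cutpoints: tuple
    tertile: np.ndarray                  # 0 (lowest) .. 2 (highest score)
    curves: dict                         # tertile -> survival DataFrame
    logrank_p: float | None
    note: str | None = None


def risk_tertile_km(scores, time_days, event) -> TertileKM:
    """Kaplan-Meier curves by score tertile with a 2-df log-rank test.

    Tertile cutpoints are the empirical 1/3 and 2/3 quantiles of ``scores``;
    fewer than three distinct score values is an error. With no events at
    all the curves are identically 1 and the log-rank test is reported as
    not computable.
    """
    scores = np.asarray(scores, float)
    time_days = np.asarray(time_days, float)
    event = np.asarray(event, bool)
    if len(np.unique(scores)) < 3:
        raise ValueError("need at least 3 distinct score values for tertiles")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    tert = np.digitize(scores, [q1, q2])
    curves = {}
    note = None
    for g in range(3):
        sel = tert == g
        if not sel.any():
            # heavy score ties can empty a tertile; report it rather than fail
            curves[g] = None
            note = "empty tertile (tied scores)"
            continue
        km = KaplanMeierFitter()
        km.fit(time_days[sel], event[sel], label=f"tertile_{g}")
        curves[g] = km.survival_function_
    if not event.any():
        return TertileKM(cutpoints=(float(q1), float(q2)), tertile=tert,
                         curves=curves, logrank_p=None,
                         note="no events; log-rank not computable")
    res = multivariate_logrank_test(time_days, tert, event)
    return TertileKM(cutpoints=(float(q1), float(q2)), tertile=tert,
                     curves=curves, logrank_p=float(res.p_value), note=note)
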