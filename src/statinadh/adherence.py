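"""Random-forest prediction of statin adherence (PDC > 80%).

A forest is trained per cross-validation fold on baseline patient/statin
characteristics, interaction counts, predicted disease risk and the NMF
factor scores; pooled out-of-fold probabilities give the cross-validated
ROC and c-statistic. Variable importance is leave-one-covariate-out with a
full CV refit (the change in AUC when a variable, or variable group, is
withheld). A per-factor covariate-adjusted logistic association quantifies
each factor's direction of effect on adherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold
import statsmodels.api as sm

__all__ = ["AdherenceModelSpec", "AdherenceFit", "fit_adherence",
           "c_statistic", "variable_importance", "factor_association"]


@dataclass
class AdherenceModelSpec:
    n_trees: int = 500
    n_folds: int = 30
    seed: int = 0
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 1     # raise (e.g. 25) for smoother probabilities
    include_first_refill: bool = False   # caller must then supply the
    #                                     follow-up-window PDC label


@dataclass
class AdherenceFit:
    oof_prob: pd.Series
    auc: float
    roc: pd.DataFrame                    # fpr/tpr points of the pooled ROC
    fold_assignment: np.ndarray
    spec: AdherenceModelSpec
    feature_names: list = field(default_factory=list)


def c_statistic(y, score) -> float:
    """AUC via the Mann-Whitney rank statistic (ties get midranks)."""
    y = np.asarray(y, bool)
    score = np.asarray(score, float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    r = rankdata(score)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _impute_train_test(Xtr: pd.DataFrame, Xte: pd.DataFrame):
    """Training-fold median imputation plus missingness indicator columns."""
    med = Xtr.median(numeric_only=True)
    out = []
    for X in (Xtr, Xte):
        Xi = X.copy()
        extra = {}
        for col in X.columns:
            if X[col].isna().any() or Xtr[col].isna().any():
                extra[f"{col}__missing"] = X[col].isna().astype(float)
                Xi[col] = X[col].fillna(med.get(col, 0.0))
        for k, v in extra.items():
            Xi[k] = v
        out.append(Xi.to_numpy(float))
    return out


def fit_adherence(X: pd.DataFrame, y, spec: AdherenceModelSpec | None = None,
                  ) -> AdherenceFit:
    """Cross-validated forest with pooled out-of-fold probabilities.

    ``X`` may contain missing numeric values (labs, prior PDC); they are
    imputed per training fold by the median, with a missingness indicator
    appended. ``y`` must contain both classes and no missing labels.
    """
    spec = spec or AdherenceModelSpec()
    y = np.asarray(y, bool)
    if y.all() or not y.any():
        raise ValueError("labels are single-class; cannot fit a classifier")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    n = len(y)
    kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    oof = np.full(n, np.nan)
    fold_of = np.full(n, -1, int)
    for fold, (tr, te) in enumerate(kf.split(X)):
        Xtr, Xte = _impute_train_test(X.iloc[tr], X.iloc[te])
        rf = RandomForestClassifier(n_estimators=spec.n_trees,
                                    max_features=spec.max_features,
                                    min_samples_leaf=spec.min_samples_leaf,
                                    random_state=spec.seed + fold, n_jobs=1)
        rf.fit(Xtr, y[tr])
        oof[te] = rf.predict_proba(Xte)[:, list(rf.classes_).index(True)]
        fold_of[te] = fold
    auc = c_statistic(y, oof)
    fpr, tpr, _ = roc_curve(y, oof)
    idx = X.index if X.index.name == "patient_id" else pd.RangeIndex(n)
    return AdherenceFit(oof_prob=pd.Series(oof, index=idx, name="p_adherent"),
                        auc=auc, roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
                        fold_assignment=fold_of, spec=spec,
                        feature_names=list(X.columns))


def variable_importance(X: pd.DataFrame, y, spec: AdherenceModelSpec | None = None,
                        groups: dict | None = None,
                        baseline: AdherenceFit | None = None) -> pd.DataFrame:
    """Leave-one-covariate-out change in cross-validated AUC.

    For every variable (or named group of columns in ``groups``) the full CV
    pipeline is refit without it; ``delta_auc = AUC(all) - AUC(without)``.
    Returns a table sorted by delta_auc descending.
    """
    spec = spec or AdherenceModelSpec()
    if baseline is None:
        baseline = fit_adherence(X, y, spec)
    units = groups if groups is not None else {c: [c] for c in X.columns}
    rows = []
    for name, cols in units.items():
        reduced = X.drop(columns=list(cols))
        if reduced.shape[1] == 0:
            raise ValueError(f"cannot withhold all columns ({name})")
        fit = fit_adherence(reduced, y, spec)
        rows.append({"variable": name, "auc_without": fit.auc,
                     "delta_auc": baseline.auc - fit.auc})
    out = pd.DataFrame(rows).sort_values("delta_auc", ascending=False)
    return out.reset_index(drop=True)


def factor_association(y, factor_scores: pd.DataFrame,
                       covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-factor adjusted logistic association with adherence.

    One logistic regression per factor: adherence ~ factor score + all
    patient/statin covariates (which should include the composite disease
    risk). Returns factor, coefficient, direction (higher/lower adherence)
    and Wald p-value; degenerate designs are flagged not estimable.
    """
    y = np.asarray(y, float)
    cov = covariates.reset_index(drop=True).astype(float)
    rows = []
    for col in factor_scores.columns:
        design = cov.copy()
        design["factor"] = factor_scores[col].to_numpy(float)
        design = sm.add_constant(design, has_constant="add")
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            coef = float(fit.params["factor"])
            p = float(fit.pvalues["factor"])
            if not np.isfinite(p):
                raise ValueError("non-finite p")
            rows.append({"factor": col, "coef": coef,
                         "direction": "higher" if coef > 0 else "lower",
                         "p_value": p, "estimable": True})
        except Exception:
            rows.append({"factor": col, "coef": np.nan, "direction": "na",
                         "p_value": np.nan, "estimable": False})
    return pd.DataFrame(rows)
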