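"""Nonnegative matrix factorization of the baseline count matrix.

The patients x variables count matrix X is factored as X ~ S @ L.T with
nonnegative per-patient scores S (patients x K) and loadings L
(variables x K), by minimizing the squared Frobenius reconstruction error
with the classic multiplicative updates from a seeded random start. The
per-iteration objective is recorded (it is non-increasing); after
convergence each loading column is scaled to unit L2 norm and the final
scores are the nonnegative least-squares projection of each patient row
onto those fixed loadings, so scoring new patients and re-scoring the
training data use the identical operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .features import CountMatrix

__all__ = ["FactorModel", "fit_nmf", "score_patients", "top_loadings"]

_EPS = 1e-12


@dataclass
class FactorModel:
    loadings: np.ndarray            # (n_variables, K), columns unit L2 norm
    scores: np.ndarray              # (n_patients, K), nonnegative
    k: int
    objective: list = field(default_factory=list)  # per-iteration ||X - S L'||_F^2
    seed: int = 0
    variables: pd.DataFrame | None = None          # name/kind, row-aligned
    patient_ids: np.ndarray | None = None

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"factor_{j}" for j in range(self.k)]
        idx = self.variables["name"] if self.variables is not None else None
        return pd.DataFrame(self.loadings, index=idx, columns=cols)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"factor_{j}" for j in range(self.k)]
        return pd.DataFrame(self.scores, index=self.patient_ids, columns=cols)


def _as_array(counts) -> tuple:
    if isinstance(counts, CountMatrix):
        return counts.X.astype(float), counts.variables, counts.patient_ids
    X = np.asarray(counts, float)
    return X, None, None


def _nnls_scores(X: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    S = np.empty((X.shape[0], loadings.shape[1]))
    for i in range(X.shape[0]):
        S[i], _ = nnls(loadings, X[i])
    return S


def fit_nmf(counts, k: int, max_iter: int = 500, tol: float = 1e-5,
            seed: int = 0, log1p: bool = False) -> FactorModel:
    """Factor a nonnegative count matrix into ``k`` nonnegative factors.

    Parameters
    ----------
    counts : CountMatrix or 2-D nonnegative array (patients x variables).
    k : number of factors; must satisfy 0 < k < min(n, p).
    max_iter, tol : stop after ``max_iter`` multiplicative updates or when the
        relative objective decrease falls below ``tol``.
    log1p : factor log(1 + X) instead of raw counts (off by default; raw
        counts are the canonical input, the transform tames heavy skew).
    """
    X, variables, pids = _as_array(counts)
    if k <= 0:
        raise ValueError("k must be positive")
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.any(X > 0):
        raise ValueError("cannot factor an all-zero matrix")
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be < min(n_patients, n_variables)={min(X.shape)}")
    if log1p:
        X = np.log1p(X)

    n, p = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k)
    S = rng.uniform(0.0, 1.0, size=(n, k)) * scale + _EPS
    L = rng.uniform(0.0, 1.0, size=(p, k)) * scale + _EPS

    objective = [float(np.linalg.norm(X - S @ L.T, "fro") ** 2)]
    for _ in range(max_iter):
        # multiplicative updates for min ||X - S L'||_F^2, S,L >= 0
        S *= (X @ L) / np.maximum(S @ (L.T @ L), _EPS)
        L *= (X.T @ S) / np.maximum(L @ (S.T @ S), _EPS)
        obj = float(np.linalg.norm(X - S @ L.T, "fro") ** 2)
        objective.append(obj)
        prev = objective[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break

    norms = np.linalg.norm(L, axis=0)
    norms[norms == 0] = 1.0
    L = L / norms
    S = _nnls_scores(X, L)
    objective.append(float(np.linalg.norm(X - S @ L.T, "fro") ** 2))
    return FactorModel(loadings=L, scores=S, k=k, objective=objective,
                       seed=seed, variables=variables, patient_ids=pids)


def score_patients(model: FactorModel, counts, log1p: bool = False) -> np.ndarray:
    """Project new patients' count rows onto the fitted loadings (NNLS).

    ``counts`` may be a CountMatrix or array; when it is a CountMatrix its
    variables are aligned to the model's by name, with variables unknown to
    the model ignored and model variables absent from the input treated as
    zero counts. Raises if the two variable sets are disjoint.
    """
    if isinstance(counts, CountMatrix) and model.variables is not None:
        model_vars = model.variables["name"].tolist()
        pos = {v: j for j, v in enumerate(counts.variables["name"])}
        overlap = [v for v in model_vars if v in pos]
        if not overlap:
            raise ValueError("no overlap between input variables and model variables")
        X = np.zeros((counts.X.shape[0], len(model_vars)))
        for j, v in enumerate(model_vars):
            if v in pos:
                X[:, j] = counts.X[:, pos[v]]
    else:
        X, _, _ = _as_array(counts)
        if X.shape[1] != model.loadings.shape[0]:
            raise ValueError("column count does not match model variables")
    if log1p:
        X = np.log1p(X)
    return _nnls_scores(X, model.loadings)


def top_loadings(model: FactorModel, n: int = 10) -> dict:
    """Per-factor list of the n variables with largest loading, descending.

    Zero-loading variables are omitted; ties break lexicographically by
    variable name, so the ranking is deterministic across runs.
    """
    if model.variables is not None:
        names = model.variables["name"].to_numpy()
    else:
        names = np.array([f"v{i}" for i in range(model.loadings.shape[0])])
    out = {}
    for j in range(model.k):
        col = model.loadings[:, j]
        order = sorted(range(len(col)), key=lambda i: (-col[i], names[i]))
        ranked = [(str(names[i]), float(col[i])) for i in order if col[i] > 0]
        out[f"factor_{j}"] = ranked[:n]
    return out
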