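"""Hybrid feature selection: random-forest importance ∩ forward stepwise.

Two independent rankings are produced — mean impurity-decrease importance
from a 500-tree random forest, and the entry order of a forward stepwise
logistic regression governed by AIC — and the selected set is the
intersection of the two top-n prefixes (n = 40 by default).  The
intersection keeps only features that both a non-linear, interaction-aware
ranker and an additive likelihood-based ranker agree on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .encode import group_census

#: number of top-score candidates refitted exactly at each stepwise step
_SCREEN = 8


@dataclass(frozen=True)
class FeatureSelectionResult:
    rf_ranking: tuple[str, ...]        # best first
    stepwise_ranking: tuple[str, ...]  # entry order
    top_n: int
    selected: tuple[str, ...]          # encoder column order
    group_census: dict[str, int]
    fallback_used: bool = False

    def to_frame(self) -> pd.DataFrame:
        rf_rank = {f: i + 1 for i, f in enumerate(self.rf_ranking)}
        sw_rank = {f: i + 1 for i, f in enumerate(self.stepwise_ranking)}
        feats = list(self.rf_ranking)
        sel = set(self.selected)
        return pd.DataFrame({
            "feature": feats,
            "group": [f.split(":", 1)[0] for f in feats],
            "rf_rank": [rf_rank[f] for f in feats],
            "sw_rank": [sw_rank.get(f, 0) for f in feats],
            "selected": [f in sel for f in feats],
        })


def _check_inputs(features: pd.DataFrame, labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if len(y) != len(features):
        raise ValueError("features and labels differ in length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; selection undefined")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return y


def rank_rf(features: pd.DataFrame, labels, seed: int = 0,
            n_trees: int = 500) -> list[str]:
    """Features ordered by decreasing mean impurity-decrease importance.

    Uses a 500-tree forest (matching the ensemble's forest size); ties —
    including the trailing zero-importance block — are broken by feature
    name so the ordering is deterministic.
    """
    y = _check_inputs(features, labels)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(features.to_numpy(), y)
    imp = forest.feature_importances_
    names = list(features.columns)
    order = sorted(range(len(names)), key=lambda i: (-imp[i], names[i]))
    return [names[i] for i in order]


def _logit_aic(X: np.ndarray, y: np.ndarray) -> float:
    """AIC of a logistic fit with intercept; penalized fallback never aborts.

    Perfect separation (routine on strongly separable synthetic data) makes
    the unpenalized MLE diverge; the fallback is an L2-penalized fit whose
    penalized log-likelihood feeds the AIC, which still orders candidates
    sensibly (separating features reach near-zero deviance either way).
    """
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
            if np.isfinite(res.llf):
                return float(res.aic)
        except Exception:
            pass
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(X, y)
    p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    llf -= 0.5 * float(np.sum(clf.coef_ ** 2))  # penalty term of the fallback
    return 2 * (X.shape[1] + 1) - 2 * llf


def _fit_probs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitted probabilities of the current model (penalized on separation)."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
            if np.isfinite(res.llf):
                return np.clip(res.predict(Xc), 1e-9, 1 - 1e-9)
        except Exception:
            pass
    clf = LogisticRegression(C=1.0, max_iter=1000)
    if X.shape[1] == 0:
        return np.full(len(y), y.mean())
    clf.fit(X, y)
    return np.clip(clf.predict_proba(X)[:, 1], 1e-9, 1 - 1e-9)


def _score_statistics(X_cur: np.ndarray, p: np.ndarray, y: np.ndarray,
                      C: np.ndarray) -> np.ndarray:
    """Rao score statistic for adding each candidate column of C.

    Vectorized over candidates: for current design X (with intercept) and
    fitted probabilities p, the statistic for candidate x is
    U^2 / V with U = x'(y-p) and V the efficient information of x after
    projecting out X.  Larger means a bigger one-step likelihood gain.
    """
    n = len(y)
    Xc = np.column_stack([np.ones(n), X_cur])
    w = p * (1 - p)
    r = y - p
    U = C.T @ r
    WC = C * w[:, None]
    XtWX = Xc.T @ (Xc * w[:, None])
    XtWC = Xc.T @ WC
    solve = np.linalg.solve(XtWX + 1e-10 * np.eye(XtWX.shape[0]), XtWC)
    V = np.einsum("ij,ij->j", C, WC) - np.einsum("ij,ij->j", XtWC, solve)
    V = np.maximum(V, 1e-12)
    return (U ** 2) / V


def rank_stepwise(features: pd.DataFrame, labels, top_n: int = 40) -> list[str]:
    """Forward stepwise logistic regression ranked by entry order.

    At each step the candidates are screened by the Rao score test
    (vectorized over all remaining columns); the top-scoring few are refit
    exactly and the best one by AIC enters if it improves the current AIC.
    The walk stops at ``top_n`` entries or when no addition improves AIC;
    any remaining rank slots are filled by single-feature (marginal) AIC
    order so the ranking always has ``top_n`` entries when possible.
    """
    if top_n == 0:
        return []
    y = _check_inputs(features, labels)
    names = list(features.columns)
    Xall = features.to_numpy(dtype=float)
    entered: list[int] = []
    remaining = list(range(len(names)))
    cur_aic = _logit_aic(Xall[:, []], y)

    while remaining and len(entered) < top_n:
        X_cur = Xall[:, entered]
        p = _fit_probs(X_cur, y)
        stats = _score_statistics(X_cur, p, y, Xall[:, remaining])
        k = min(_SCREEN, len(remaining))
        top_idx = np.argpartition(-stats, k - 1)[:k]
        best_j, best_aic = None, cur_aic
        for t in sorted(top_idx, key=lambda t: (-stats[t], names[remaining[t]])):
            j = remaining[t]
            aic = _logit_aic(Xall[:, entered + [j]], y)
            if aic < best_aic - 1e-9:
                best_j, best_aic = j, aic
                break  # screened order ~ likelihood order; first improver wins
        if best_j is None:
            break
        entered.append(best_j)
        remaining.remove(best_j)
        cur_aic = best_aic

    ranking = [names[j] for j in entered]
    if len(ranking) < top_n and remaining:
        marginal = {j: _logit_aic(Xall[:, [j]], y) for j in remaining}
        filler = sorted(remaining, key=lambda j: (marginal[j], names[j]))
        ranking += [names[j] for j in filler[: top_n - len(ranking)]]
    return ranking[:top_n]


def hybrid_select(features: pd.DataFrame, labels, top_n: int = 40,
                  seed: int = 0) -> FeatureSelectionResult:
    """Intersect the top-n features of the forest and stepwise rankings.

    The selected set is returned in the encoder's fixed column order.  If
    the two arms share nothing (a pathological case), the union of the two
    top-(n/2) prefixes is used instead, with a warning.
    """
    rf_ranking = rank_rf(features, labels, seed=seed)
    sw_ranking = rank_stepwise(features, labels, top_n=top_n)
    rf_top = set(rf_ranking[:top_n])
    sw_top = set(sw_ranking[:top_n])
    chosen = rf_top & sw_top
    fallback = False
    if not chosen and top_n > 0:
        warnings.warn(
            "empty intersection of top-n rankings; falling back to the union "
            "of the two top-n/2 prefixes",
            stacklevel=2,
        )
        chosen = set(rf_ranking[: top_n // 2]) | set(sw_ranking[: top_n // 2])
        fallback = True
    selected = tuple(f for f in features.columns if f in chosen)
    return FeatureSelectionResult(
        rf_ranking=tuple(rf_ranking),
        stepwise_ranking=tuple(sw_ranking),
        top_n=top_n,
        selected=selected,
        group_census=group_census(selected),
        fallback_used=fallback,
    )
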