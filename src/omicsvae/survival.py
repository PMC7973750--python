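"""Latent-feature survival pipeline.

Three stages, applied to the LF matrix learned by the VAE / MMD-VAE:

1. *Screening*: a univariate Cox proportional-hazards model per LF; LFs whose
   model is significant (likelihood-ratio p < 0.05 by default) are the
   clinically relevant LFs (CRLFs).
2. *Subgroup inference*: K chosen by majority vote over internal validity
   indices, then seeded K-means on the CRLF matrix.
3. *Subgroup transfer*: a tuned SVM predicts inferred subgroup labels for a
   held-out 40% split; multivariate Cox models (clinical covariates only
   vs. clinical + subgroup) are compared by Harrell's C-index, IPCW Brier
   score and Kaplan-Meier log-rank tests.

Cox fits use lifelines (Efron tie handling); the censoring-weighted Brier
score uses scikit-survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.cluster import KMeans
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.svm import SVC

__all__ = [
    "SurvivalTable", "CRLFSelection", "SubgroupResult",
    "cox_univariate_per_lf", "choose_k", "infer_subgroups", "predict_subgroups",
    "cox_multivariate", "concordance_index", "brier_score", "km_logrank",
    "run_survival_pipeline",
]


@dataclass
class SurvivalTable:
    """Right-censored outcome plus the three clinical covariates.

    os_time is overall survival in days (> 0), os_event 1 for death, 0 for
    censoring; stage and grade are ordinal integers; subtype is an optional
    transcriptional-subtype code.
    """

    data: pd.DataFrame  # columns: sample_id, os_time, os_event, age, stage, grade[, subtype]

    REQUIRED = ("sample_id", "os_time", "os_event", "age", "stage", "grade")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing column(s): {missing}")
        if (self.data["os_time"] <= 0).any():
            raise ValueError("os_time must be strictly positive")
        if not self.data["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0/1")

    def __len__(self):
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["os_time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["os_event"].to_numpy(int)

    def subset(self, idx) -> "SurvivalTable":
        return SurvivalTable(self.data.iloc[idx].reset_index(drop=True))


@dataclass
class CRLFSelection:
    """Univariate Cox screening result over all LFs."""

    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    p_values: np.ndarray
    selected: List[int]
    failed: List[int] = field(default_factory=list)
    threshold: float = 0.05


@dataclass
class SubgroupResult:
    K: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    inferred_labels: np.ndarray  # over training samples
    predicted_labels: np.ndarray  # over test samples
    metrics: Dict[str, float] = field(default_factory=dict)


def _check_survival(survival: SurvivalTable):
    if survival.event.sum() < 2:
        raise ValueError("need at least 2 events for Cox regression")


def cox_univariate_per_lf(lfs: np.ndarray, survival: SurvivalTable,
                          threshold: float = 0.05,
                          bh_correct: bool = False) -> CRLFSelection:
    """One Cox PH fit per LF column; select LFs with significant models.

    The per-LF p-value is the model's likelihood-ratio p, equivalent to the
    score (log-rank) test for a single covariate.  Non-converging LFs are
    flagged and excluded rather than fatal.  ``bh_correct`` optionally applies
    Benjamini-Hochberg across LFs (off by default).
    """
    lfs = np.asarray(lfs, float)
    _check_survival(survival)
    if lfs.shape[0] != len(survival):
        raise ValueError("LF matrix and survival table have different sample counts")
    p = lfs.shape[1]
    coefs = np.full(p, np.nan)
    pvals = np.ones(p)
    failed = []
    base = pd.DataFrame({"os_time": survival.time, "os_event": survival.event})
    for j in range(p):
        df = base.copy()
        df["lf"] = lfs[:, j]
        if np.ptp(lfs[:, j]) == 0:
            failed.append(j)
            continue
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="os_time", event_col="os_event")
            coefs[j] = cph.params_["lf"]
            pvals[j] = cph.log_likelihood_ratio_test().p_value
        except Exception:
            failed.append(j)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        ok = ~np.isnan(coefs)
        adj = np.ones(p)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        pvals = adj
    selected = [j for j in range(p)
                if j not in failed and pvals[j] < threshold]
    return CRLFSelection(coefficients=coefs, hazard_ratios=np.exp(coefs),
                         p_values=pvals, selected=selected, failed=failed,
                         threshold=threshold)


def _dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    from scipy.spatial.distance import cdist
    clusters = [X[labels == c] for c in np.unique(labels)]
    diam = max(cdist(c, c).max() for c in clusters)
    sep = min(cdist(a, b).min()
              for i, a in enumerate(clusters) for b in clusters[i + 1:])
    return sep / diam if diam > 0 else 0.0


def _gap_statistic(X: np.ndarray, ks: Sequence[int], seed: int, n_ref: int = 10):
    """Gap statistic against uniform reference in the bounding box."""
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data, k):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(data)
        return np.log(max(km.inertia_, 1e-12))

    gaps = {}
    for k in ks:
        ref = np.mean([log_wk(rng.uniform(lo, hi, X.shape), k)
                       for _ in range(n_ref)])
        gaps[k] = ref - log_wk(X, k)
    return gaps


def choose_k(X: np.ndarray, candidate_range: Sequence[int] = range(2, 7),
             seed: int = 0) -> int:
    """Majority vote of five internal validity indices over candidate K.

    Indices: silhouette, Calinski-Harabasz, Dunn (maximize), Davies-Bouldin
    (minimize) and the gap statistic.  Ties break toward the smaller K.
    """
    ks = [k for k in candidate_range if 2 <= k <= len(X) - 1]
    if not ks:
        raise ValueError("empty candidate range for K")
    labelings = {k: KMeans(n_clusters=k, n_init=10, random_state=seed)
                 .fit_predict(X) for k in ks}
    votes = []
    votes.append(max(ks, key=lambda k: silhouette_score(X, labelings[k])))
    votes.append(max(ks, key=lambda k: calinski_harabasz_score(X, labelings[k])))
    votes.append(min(ks, key=lambda k: davies_bouldin_score(X, labelings[k])))
    votes.append(max(ks, key=lambda k: _dunn_index(X, labelings[k])))
    gaps = _gap_statistic(X, ks, seed)
    votes.append(max(ks, key=lambda k: gaps[k]))
    counts = {k: votes.count(k) for k in ks}
    best = max(counts.values())
    return min(k for k, c in counts.items() if c == best)


def infer_subgroups(X: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """Seeded K-means; labels renumbered 0..K-1 by decreasing cluster size."""
    X = np.asarray(X, float)
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > len(np.unique(X, axis=0)):
        raise ValueError("K exceeds the number of distinct points")
    raw = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(X)
    order = np.argsort(-np.bincount(raw, minlength=K), kind="stable")
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(K)
    return remap[raw]


def predict_subgroups(X: np.ndarray, labels: np.ndarray, test_size: float = 0.4,
                      seed: int = 0) -> Tuple[np.ndarray, np.ndarray, np.ndarray, SVC]:
    """Stratified 60/40 split; SVM tuned by 5-fold grid search on the training part.

    Returns (train_idx, test_idx, predicted test labels, fitted classifier).
    """
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, random_state=seed, stratify=labels)
    if len(np.unique(labels[train_idx])) < 2:
        raise ValueError("a subgroup is absent from the training split")
    grid = GridSearchCV(
        SVC(kernel="rbf", random_state=seed),
        {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1, 1.0]},
        cv=5, n_jobs=1)
    grid.fit(X[train_idx], labels[train_idx])
    predicted = grid.best_estimator_.predict(X[test_idx])
    return train_idx, test_idx, predicted, grid.best_estimator_


def cox_multivariate(covariates: pd.DataFrame, survival: SurvivalTable,
                     formula: str = "clinical") -> Tuple[CoxPHFitter, float]:
    """Multivariate Cox fit; formula 'clinical' uses age+stage+grade,
    'combined' adds the subgroup column.  Returns (fit, likelihood-ratio p)."""
    _check_survival(survival)
    cols = ["age", "stage", "grade"]
    if formula == "combined":
        cols = cols + ["subgroup"]
    elif formula != "clinical":
        raise ValueError("formula must be 'clinical' or 'combined'")
    df = covariates[cols].reset_index(drop=True).astype(float)
    # Drop constant/collinear covariates rather than failing.
    keep = [c for c in cols if df[c].nunique() > 1]
    dropped = sorted(set(cols) - set(keep))
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}")
    df = df[keep]
    df["os_time"] = survival.time
    df["os_event"] = survival.event
    cph = CoxPHFitter(penalizer=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="os_time", event_col="os_event")
    return cph, float(cph.log_likelihood_ratio_test().p_value)


def concordance_index(risk_scores: np.ndarray, survival: SurvivalTable) -> float:
    """Harrell's C over censoring-comparable pairs; risk ties count 0.5.

    Higher risk should pair with shorter survival; perfectly anti-ordered
    risks give 1.0.
    """
    risk_scores = np.asarray(risk_scores, float)
    # lifelines scores "predicted survival time"; negate risk to match.
    c = _lifelines_cindex(survival.time, -risk_scores, survival.event)
    return float(c)


def _censoring_survival(table: SurvivalTable):
    """KM estimate G of the censoring distribution, carried flat beyond follow-up."""
    km = KaplanMeierFitter()
    km.fit(table.time, 1 - table.event)
    grid = km.survival_function_.index.to_numpy(float)
    vals = km.survival_function_.iloc[:, 0].to_numpy(float)

    def G(t, left: bool = False):
        t = np.atleast_1d(np.asarray(t, float))
        query = t - 1e-9 if left else t
        idx = np.searchsorted(grid, query, side="right") - 1
        out = np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])
        return np.maximum(out, 1e-8)

    return G


def brier_score(surv_probs: np.ndarray, eval_times: np.ndarray,
                survival_test: SurvivalTable,
                survival_train: Optional[SurvivalTable] = None) -> float:
    """Integrated IPCW Brier score of predicted survival probabilities.

    ``surv_probs[i, j]`` is subject i's predicted probability of surviving
    beyond ``eval_times[j]``.  At time t the score is

        (1/n) sum_i [ S_i(t)^2 1{T_i <= t, d_i = 1} / G(T_i^-)
                      + (1 - S_i(t))^2 1{T_i > t} / G(t) ]

    with G the Kaplan-Meier estimate of the censoring distribution (fit on
    ``survival_train``, defaulting to the test set).  Multiple times are
    averaged by trapezoidal integration over the grid; a single time returns
    that time's score.  Without censoring, oracle predictions score 0.
    """
    surv_probs = np.atleast_2d(np.asarray(surv_probs, float))
    eval_times = np.atleast_1d(np.asarray(eval_times, float))
    t_max = survival_test.time.max()
    if np.any(eval_times > t_max):
        raise ValueError("evaluation times beyond observed follow-up")
    if surv_probs.shape != (len(survival_test), len(eval_times)):
        raise ValueError(
            f"surv_probs shape {surv_probs.shape} must be "
            f"(n_test={len(survival_test)}, n_times={len(eval_times)})")
    G = _censoring_survival(survival_train if survival_train is not None
                            else survival_test)
    T, d = survival_test.time, survival_test.event
    inv_g_event = np.where(d == 1, 1.0 / G(T, left=True), 0.0)
    scores = np.empty(len(eval_times))
    for j, t in enumerate(eval_times):
        S = surv_probs[:, j]
        died_by_t = (T <= t) & (d == 1)
        still_alive = T > t
        scores[j] = np.mean(S**2 * died_by_t * inv_g_event
                            + (1.0 - S) ** 2 * still_alive / G(t))
    if len(eval_times) == 1:
        return float(scores[0])
    return float(np.trapezoid(scores, eval_times) / (eval_times[-1] - eval_times[0]))


def km_logrank(groups: np.ndarray, survival: SurvivalTable):
    """Kaplan-Meier fit per group plus the two-sided log-rank test.

    Returns (dict group -> fitted KaplanMeierFitter, test statistic, p-value).
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    fits = {}
    for g in uniq:
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g}")
        km = KaplanMeierFitter()
        km.fit(survival.time[mask], survival.event[mask], label=str(g))
        fits[g] = km
    res = multivariate_logrank_test(survival.time, groups, survival.event)
    return fits, float(res.test_statistic), float(res.p_value)


def default_brier_grid(survival: SurvivalTable) -> np.ndarray:
    """Deciles of observed test times up to the last event."""
    event_times = survival.time[survival.event == 1]
    upper = event_times.max() if len(event_times) else survival.time.max()
    times = survival.time[survival.time <= upper]
    grid = np.unique(np.quantile(times, np.linspace(0.1, 0.9, 9)))
    return grid


def run_survival_pipeline(lfs: np.ndarray, survival: SurvivalTable,
                          seed: int = 0, threshold: float = 0.05,
                          K: Optional[int] = None) -> SubgroupResult:
    """CRLF screening -> (choose K) -> K-means -> SVM transfer -> evaluation.

    Falls back to all LFs (with a warning) when fewer than 2 CRLFs survive
    screening.  Metrics cover train/test C-index and Brier for the
    clinical-only and combined Cox models, plus the test-set KM log-rank p.
    """
    selection = cox_univariate_per_lf(lfs, survival, threshold=threshold)
    if len(selection.selected) >= 2:
        crlf = lfs[:, selection.selected]
    else:
        warnings.warn("fewer than 2 CRLFs passed screening; using all LFs")
        crlf = lfs
    if K is None:
        K = choose_k(crlf, seed=seed)
    inferred = infer_subgroups(crlf, K, seed=seed)
    train_idx, test_idx, predicted, _ = predict_subgroups(crlf, inferred, seed=seed)

    clin_cols = ["age", "stage", "grade"]
    cov_train = survival.data.iloc[train_idx][clin_cols].copy()
    cov_train["subgroup"] = inferred[train_idx]
    cov_test = survival.data.iloc[test_idx][clin_cols].copy()
    cov_test["subgroup"] = predicted
    surv_train = survival.subset(train_idx)
    surv_test = survival.subset(test_idx)

    metrics: Dict[str, float] = {}
    grid = default_brier_grid(surv_test)
    for formula in ("clinical", "combined"):
        fit, model_p = cox_multivariate(cov_train, surv_train, formula=formula)
        metrics[f"cox_p_{formula}"] = model_p
        for name, cov, surv in (("train", cov_train, surv_train),
                                ("test", cov_test, surv_test)):
            cols = [c for c in fit.params_.index]
            risk = fit.predict_partial_hazard(cov[cols].astype(float)).to_numpy()
            metrics[f"cindex_{formula}_{name}"] = concordance_index(risk, surv)
        sf = fit.predict_survival_function(
            cov_test[[c for c in fit.params_.index]].astype(float), times=grid)
        metrics[f"brier_{formula}_test"] = brier_score(
            sf.to_numpy().T, grid, surv_test, survival_train=surv_train)
    if len(np.unique(predicted)) >= 2:
        _, stat, p = km_logrank(predicted, surv_test)
    else:  # degenerate transfer: one predicted subgroup, no separation shown
        stat, p = 0.0, 1.0
    metrics["logrank_stat_test"] = stat
    metrics["logrank_p_test"] = p
    return SubgroupResult(K=K, train_idx=train_idx, test_idx=test_idx,
                          inferred_labels=inferred[train_idx],
                          predicted_labels=predicted, metrics=metrics)
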