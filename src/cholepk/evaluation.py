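"""Metrics, cross-validation regimes, similarity diagnostics, statistics.

Three CV regimes probe how much a cholestasis model depends on the
structural overlap between training and test compounds:

* repeated random k-fold (the standard 20-repeated 5-fold),
* similarity-cluster CV — agglomerative clustering of fingerprints under
  Jaccard distance into five clusters, each fold testing one whole
  cluster,
* ATC-group CV — each fold tests the compounds of one of the five most
  represented level-2 ATC therapeutic classes.

Metrics are sensitivity, specificity, accuracy, Matthews correlation and
ROC AUC; metrics undefined on a degenerate fold (single-class truth) are
reported as missing and excluded from means rather than zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import RepeatedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "MetricsReport",
    "SimilarityReport",
    "DEFAULT_ATC_CODES",
    "compute_metrics",
    "repeated_kfold_scheme",
    "similarity_cluster_scheme",
    "atc_group_scheme",
    "similarity_report",
    "run_cv",
    "lipinski_ttest",
    "anova_two_way",
]

#: The five most represented level-2 ATC therapeutic classes.
DEFAULT_ATC_CODES = ("J01", "N05", "L01", "C01", "N02")

METRIC_NAMES = ("S", "SP", "A", "MCC", "AUC")


@dataclass
class CVScheme:
    """Fold definitions plus provenance of how they were built.

    ``folds`` holds (train_indices, test_indices) pairs into the eligible
    index array; ``eligible`` maps back to the caller's positions when a
    scheme restricts the compound set (ATC CV does).
    """

    kind: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    eligible: np.ndarray
    provenance: dict = field(default_factory=dict)
    seed: int | None = None
    folds_per_pass: int | None = None

    def n_folds(self) -> int:
        return len(self.folds)


def compute_metrics(y_true, y_pred, scores=None) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, MCC and ROC AUC for one fold.

    ``S = TP/(TP+FN)``, ``SP = TN/(TN+FP)``, ``A = (TP+TN)/n``; MCC uses
    its determinant form; AUC is the rank statistic over ``scores``
    (midrank ties). Metrics undefined for the fold come back as NaN.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    pos = y_true == 1
    neg = y_true == 0
    out: dict[str, float] = {}
    out["S"] = float(y_pred[pos].mean()) if pos.any() else np.nan
    out["SP"] = float(1 - y_pred[neg].mean()) if neg.any() else np.nan
    out["A"] = float((y_pred == y_true).mean())
    if pos.any() and neg.any():
        out["MCC"] = float(matthews_corrcoef(y_true, y_pred))
        s = y_pred if scores is None else np.asarray(scores, dtype=float)
        out["AUC"] = float(roc_auc_score(y_true, s))
    else:
        out["MCC"] = np.nan
        out["AUC"] = np.nan
    return out


def repeated_kfold_scheme(n: int, k: int = 5, repeats: int = 20,
                          seed: int = 0) -> CVScheme:
    """Seed-deterministic repeated random k-fold over ``n`` compounds."""
    if k > n:
        raise ValueError(f"k={k} exceeds the number of compounds {n}")
    splitter = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    folds = [(tr.copy(), te.copy()) for tr, te in splitter.split(np.arange(n))]
    return CVScheme(kind="repeated_random", folds=folds,
                    eligible=np.arange(n),
                    provenance={"k": k, "repeats": repeats},
                    seed=seed, folds_per_pass=k)


def jaccard_distance_matrix(fingerprints: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distance of binary fingerprints (square form)."""
    fp = np.asarray(fingerprints, dtype=bool)
    return squareform(pdist(fp, metric="jaccard"))


def similarity_cluster_scheme(fingerprints: np.ndarray, n_clusters: int = 5,
                              linkage: str = "average") -> CVScheme:
    """Hierarchical-clustering CV: each fold tests one structural cluster.

    Agglomerative clustering on pairwise Jaccard distances, cut at
    ``n_clusters``; fold i trains on all other clusters. Deterministic
    given the fingerprints (no randomness in average-linkage merging).
    """
    fp = np.asarray(fingerprints)
    n = len(fp)
    if n_clusters > n:
        raise ValueError("n_clusters exceeds the number of compounds")
    dist = jaccard_distance_matrix(fp)
    labels = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage=linkage,
    ).fit_predict(dist)
    folds = []
    for c in range(n_clusters):
        test = np.flatnonzero(labels == c)
        train = np.flatnonzero(labels != c)
        folds.append((train, test))
    sizes = {int(c): int((labels == c).sum()) for c in range(n_clusters)}
    return CVScheme(kind="similarity_cluster", folds=folds,
                    eligible=np.arange(n),
                    provenance={"linkage": linkage, "cluster_sizes": sizes,
                                "labels": labels},
                    folds_per_pass=n_clusters)


def atc_group_scheme(atc_codes: Sequence[Sequence[str]],
                     top_codes: Sequence[str] = DEFAULT_ATC_CODES
                     ) -> CVScheme:
    """Therapeutic-class CV: each fold tests one level-2 ATC group.

    Only compounds carrying at least one of ``top_codes`` are eligible.
    A compound matching several listed codes is assigned to the code with
    the fewest compounds, preserving group balance.
    """
    matches = [[c for c in top_codes if c in set(codes)]
               for codes in atc_codes]
    counts = {c: sum(1 for m in matches if c in m) for c in top_codes}
    assigned: dict[int, str] = {}
    for i, m in enumerate(matches):
        if not m:
            continue
        if len(m) == 1:
            assigned[i] = m[0]
        else:
            code = min(m, key=lambda c: (counts[c], top_codes.index(c)))
            assigned[i] = code
            logger.info("compound %d carries %s; assigned to %s", i, m, code)
    empty = [c for c in top_codes if c not in assigned.values()]
    if empty:
        raise ValueError(f"ATC code group(s) with no compounds: {empty}")
    eligible = np.array(sorted(assigned), dtype=int)
    pos_of = {idx: j for j, idx in enumerate(eligible)}
    folds = []
    for code in top_codes:
        test = np.array([pos_of[i] for i in eligible if assigned[i] == code])
        train = np.array([pos_of[i] for i in eligible if assigned[i] != code])
        folds.append((train, test))
    return CVScheme(kind="atc_group", folds=folds, eligible=eligible,
                    provenance={"codes": list(top_codes),
                                "group_sizes": {c: int(sum(
                                    1 for v in assigned.values() if v == c))
                                    for c in top_codes}},
                    folds_per_pass=len(top_codes))


@dataclass
class SimilarityReport:
    """Group x group mean top-k Tanimoto similarity."""

    matrix: pd.DataFrame
    group_sizes: dict
    k: int = 3
    flagged: list = field(default_factory=list)

    def intra(self, g) -> float:
        return float(self.matrix.loc[g, g])

    def inter(self, g1, g2) -> float:
        return float(self.matrix.loc[g1, g2])


def similarity_report(fingerprints: np.ndarray, groups: Sequence,
                      k: int = 3) -> SimilarityReport:
    """Mean Tanimoto similarity of each compound's k nearest neighbours.

    For cell (i, j): for every compound in group i, take the mean
    Tanimoto similarity to its k most similar compounds of group j (self
    excluded when i == j), then average over the group. Groups with too
    few members for k neighbours use all available and are flagged.
    """
    fp = np.asarray(fingerprints, dtype=bool)
    groups = np.asarray(groups)
    sim = 1.0 - jaccard_distance_matrix(fp)
    labels = pd.unique(groups)
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    flagged = []
    for gi in labels:
        idx_i = np.flatnonzero(groups == gi)
        for gj in labels:
            idx_j = np.flatnonzero(groups == gj)
            vals = []
            for i in idx_i:
                cand = idx_j[idx_j != i] if gi == gj else idx_j
                if len(cand) == 0:
                    continue
                kk = min(k, len(cand))
                if kk < k and (gi, gj) not in flagged:
                    flagged.append((gi, gj))
                top = np.sort(sim[i, cand])[-kk:]
                vals.append(top.mean())
            mat.loc[gi, gj] = float(np.mean(vals)) if vals else np.nan
    sizes = {g: int((groups == g).sum()) for g in labels}
    return SimilarityReport(matrix=mat, group_sizes=sizes, k=k,
                            flagged=flagged)


@dataclass
class MetricsReport:
    """Per-fold metric table with mean/std summary.

    ``per_fold`` has one row per fold with columns S, SP, A, MCC, AUC;
    NaN marks metrics undefined on that fold. ``summary`` aggregates with
    NaN-exclusion; ``n_excluded`` counts folds excluded per metric.
    """

    per_fold: pd.DataFrame
    scheme_kind: str = ""

    @property
    def summary(self) -> pd.DataFrame:
        rows = {}
        for m in METRIC_NAMES:
            col = self.per_fold[m]
            rows[m] = {"mean": col.mean(), "std": col.std(),
                       "n_excluded": int(col.isna().sum())}
        return pd.DataFrame(rows).T

    def mean(self, metric: str) -> float:
        return float(self.per_fold[metric].mean())


def run_cv(model_factory: Callable[[], object], scheme: CVScheme,
           X, y, score_mode: str = "margin") -> MetricsReport:
    """Fit/predict a fresh estimator per fold and aggregate metrics.

    The factory must yield objects with ``fit(X, y)`` and ``predict(X)``;
    continuous scores come from ``decision_function`` or
    ``predict_proba`` when available. ``score_mode="binary"`` computes
    AUC from the predicted labels instead of the margins (the two-point
    ROC, equal to (S+SP)/2).
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    Xe, ye = X[scheme.eligible], y[scheme.eligible]
    rows = []
    for f, (train, test) in enumerate(scheme.folds):
        est = model_factory()
        est.fit(Xe[train], ye[train])
        pred = np.asarray(est.predict(Xe[test]), dtype=int)
        if score_mode == "binary":
            scores = pred.astype(float)
        elif hasattr(est, "decision_function"):
            scores = np.asarray(est.decision_function(Xe[test]), dtype=float)
        elif hasattr(est, "predict_proba"):
            scores = est.predict_proba(Xe[test])[:, 1]
        else:
            scores = pred.astype(float)
        row = compute_metrics(ye[test], pred, scores)
        row["fold"] = f
        rows.append(row)
    per_fold = pd.DataFrame(rows).set_index("fold")
    return MetricsReport(per_fold=per_fold, scheme_kind=scheme.kind)


def lipinski_ttest(descriptors: pd.DataFrame, labels: Sequence[int],
                   columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Two-sample t-test per descriptor between the two label classes.

    Returns a table with t statistic, two-sided p-value and group means;
    significance is conventionally read at the 95% confidence level.
    """
    y = np.asarray(labels, dtype=int)
    pos = descriptors.loc[y == 1]
    neg = descriptors.loc[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 members for a t-test")
    cols = list(columns) if columns is not None else list(descriptors.columns)
    rows = []
    for c in cols:
        t, p = stats.ttest_ind(pos[c], neg[c])
        rows.append({"descriptor": c, "t": float(t), "p_value": float(p),
                     "mean_pos": float(pos[c].mean()),
                     "mean_neg": float(neg[c].mean())})
    return pd.DataFrame(rows).set_index("descriptor")


def anova_two_way(values, factor_transporter, factor_class,
                  interaction: bool = False) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA of a response (e.g. pIEOD50).

    Factors are the transporter and the cholestasis class. Returns the
    type-II ANOVA table (F and p per main effect, plus the interaction
    when requested).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "transporter": pd.Categorical(factor_transporter),
        "klass": pd.Categorical(factor_class),
    })
    for name in ("transporter", "klass"):
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name} needs at least 2 levels")
    if interaction:
        cells = df.groupby(["transporter", "klass"], observed=True).size()
        full = df["transporter"].nunique() * df["klass"].nunique()
        if len(cells) < full:
            raise ValueError("empty factor cell; rerun without interaction")
        formula = "value ~ C(transporter) * C(klass)"
    else:
        formula = "value ~ C(transporter) + C(klass)"
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return table
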