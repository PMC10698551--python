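"""Model-bank evaluation and the two-stage ranking/fusion workflow.

The workflow mirrors how a radiologist reads a multi-sequence breast MRI
exam: first every sequence is screened on its own — all (selector,
classifier) base models are cross-validated per sequence and the sequences
are ranked by their best AUC (the best single-sequence model is the "Rss"
model) — then the top four sequences are fused in every combination of two,
three or four (11 subsets), each combination again evaluated under the full
base-model bank, and the best fused model is the "R_FF" model. With the
default banks this is 10 x 15 = 150 base models per sequence and
11 x 150 = 1650 fused evaluations.

All fitting (standardization, feature selection, fusion) happens inside
training folds only; stratified ten-fold cross-validation is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._seeds import subseed
from .fusion import ViewStack, apply_fusion, enumerate_combinations, fit_fusion
from .metrics import ComparisonResult, auc_score, threshold_metrics, wilcoxon_paired
from .selectors import SelectorSpec, default_selector_bank, run_selector

TASKS = ("HR+vsHR-", "TNBCvsHEBC", "TNBCvsNonTNBC")

_CLASSIFIERS = (
    "logistic", "lda", "knn", "gaussian_nb", "decision_tree",
    "random_forest", "svm_linear", "svm_rbf", "gboost_stumps", "ridge",
)


def default_classifier_bank() -> tuple[str, ...]:
    """Ten classifiers; logistic regression is the mandatory member."""
    return _CLASSIFIERS


def make_classifier(name: str, seed: int = 0):
    if name == "logistic":
        return LogisticRegression(max_iter=500)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=60, random_state=seed)
    if name == "svm_linear":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    if name == "gboost_stumps":
        return GradientBoostingClassifier(n_estimators=50, max_depth=1, random_state=seed)
    if name == "ridge":
        return RidgeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def _predict_proba(model, X) -> np.ndarray:
    """Probability of the positive class; decision scores are squashed."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    z = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class BaseModelSpec:
    selector: SelectorSpec
    classifier: str
    k_selected: int | None = None

    @property
    def name(self) -> str:
        return f"{self.classifier}+{self.selector.name}"


def default_model_bank(selectors=None, classifiers=None,
                       k_selected: int | None = None) -> list[BaseModelSpec]:
    """Cross-product bank; defaults give the canonical 150 base models."""
    selectors = selectors if selectors is not None else default_selector_bank()
    classifiers = classifiers if classifiers is not None else default_classifier_bank()
    return [BaseModelSpec(selector=s, classifier=c, k_selected=k_selected)
            for c in classifiers for s in selectors]


@dataclass
class CVResult:
    auc: float
    acc: float
    sen: float
    spe: float
    fold_auc: list[float]
    fold_acc: list[float]
    n_folds: int
    task: str = ""
    input_name: str = ""
    model_name: str = ""
    pooled_auc: float = float("nan")


def binary_task_labels(labels, task: str) -> tuple[np.ndarray, np.ndarray]:
    """Binary encoding of a classification task.

    Returns ``(row_mask, y)``: which cohort rows participate and the 0/1
    label (1 = the stated positive class) for those rows. Positive classes:
    HR- for HR+vsHR-, TNBC for the other two tasks.
    """
    labels = np.asarray(labels)
    if task == "HR+vsHR-":
        mask = np.ones(len(labels), dtype=bool)
        y = (labels != "HR+").astype(int)
    elif task == "TNBCvsHEBC":
        mask = np.isin(labels, ["TNBC", "HEBC"])
        y = (labels[mask] == "TNBC").astype(int)
    elif task == "TNBCvsNonTNBC":
        mask = np.ones(len(labels), dtype=bool)
        y = (labels == "TNBC").astype(int)
    else:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"task {task!r} has an empty arm")
    return mask, y


def _fit_predict(model: BaseModelSpec, X_tr, y_tr, X_te, seed: int) -> np.ndarray:
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X_tr = (X_tr - mu) / sd
    X_te = (X_te - mu) / sd
    sel = run_selector(model.selector, X_tr, y_tr, k=model.k_selected, seed=seed)
    idx = sel.selected_indices
    clf = make_classifier(model.classifier, seed=seed)
    clf.fit(X_tr[:, idx], y_tr)
    return _predict_proba(clf, X_te[:, idx])


def cross_validate(model: BaseModelSpec, X, y, n_folds: int = 10, seed: int = 0,
                   n_repeats: int = 1, task: str = "", input_name: str = "") -> CVResult:
    """Stratified k-fold CV of one base model; selector fit per training fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError("every class needs at least n_folds members for stratification")
    fold_auc, fold_acc, fold_sen, fold_spe = [], [], [], []
    pooled_prob = np.zeros(len(y))
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=subseed(seed, "cv", rep))
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            prob = _fit_predict(model, X[tr], y[tr], X[te],
                                seed=subseed(seed, "fold", rep, fold))
            if rep == 0:
                pooled_prob[te] = prob
            fold_auc.append(auc_score(y[te], prob))
            m = threshold_metrics(y[te], prob)
            fold_acc.append(m["acc"])
            fold_sen.append(m["sen"])
            fold_spe.append(m["spe"])
    return CVResult(
        auc=float(np.mean(fold_auc)), acc=float(np.mean(fold_acc)),
        sen=float(np.mean(fold_sen)), spe=float(np.mean(fold_spe)),
        fold_auc=fold_auc, fold_acc=fold_acc, n_folds=n_folds,
        task=task, input_name=input_name, model_name=model.name,
        pooled_auc=auc_score(y, pooled_prob),
    )


def cross_validate_fused(tables: dict[str, pd.DataFrame], channels, model: BaseModelSpec,
                         task: str, n_folds: int = 10, seed: int = 0, n_repeats: int = 1,
                         strategy: str = "featurewise", combination: str = "sum") -> CVResult:
    """CV of a base model on fused features; fusion fit inside each fold."""
    first = tables[channels[0]]
    mask, y = binary_task_labels(first["class"].to_numpy(), task)
    feats = [c for c in first.columns if c != "class"]
    views = {ch: tables[ch].loc[mask, feats].to_numpy(dtype=float) for ch in channels}
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError("every class needs at least n_folds members for stratification")
    fold_auc, fold_acc, fold_sen, fold_spe = [], [], [], []
    pooled_prob = np.zeros(len(y))
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=subseed(seed, "cv", rep))
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            stack_tr = ViewStack(views={ch: v[tr] for ch, v in views.items()},
                                 labels=y[tr], feature_names=tuple(feats))
            transform = fit_fusion(stack_tr, strategy=strategy, combination=combination)
            stack_te = ViewStack(views={ch: v[te] for ch, v in views.items()},
                                 labels=y[te], feature_names=tuple(feats))
            F_tr = apply_fusion(transform, stack_tr)
            F_te = apply_fusion(transform, stack_te)
            prob = _fit_predict(model, F_tr, y[tr], F_te,
                                seed=subseed(seed, "fold", rep, fold))
            if rep == 0:
                pooled_prob[te] = prob
            fold_auc.append(auc_score(y[te], prob))
            m = threshold_metrics(y[te], prob)
            fold_acc.append(m["acc"])
            fold_sen.append(m["sen"])
            fold_spe.append(m["spe"])
    return CVResult(
        auc=float(np.mean(fold_auc)), acc=float(np.mean(fold_acc)),
        sen=float(np.mean(fold_sen)), spe=float(np.mean(fold_spe)),
        fold_auc=fold_auc, fold_acc=fold_acc, n_folds=n_folds,
        task=task, input_name="+".join(channels), model_name=model.name,
        pooled_auc=auc_score(y, pooled_prob),
    )


@dataclass
class RankingTable:
    """Per-channel best base model, ordered by descending AUC."""

    rows: pd.DataFrame          # channel, model, auc, acc, sen, spe
    results: dict[str, CVResult]
    n_evaluations: int

    @property
    def channels(self) -> list[str]:
        return list(self.rows["channel"])


def rank_sequences(tables: dict[str, pd.DataFrame], task: str,
                   bank: list[BaseModelSpec] | None = None,
                   n_folds: int = 10, seed: int = 0) -> RankingTable:
    """Evaluate every base model on every channel; keep each channel's best."""
    if len(tables) < 2:
        raise ValueError("need at least 2 channels to rank")
    bank = bank if bank is not None else default_model_bank()
    best: dict[str, CVResult] = {}
    n_eval = 0
    for ch in sorted(tables):
        df = tables[ch]
        if df.empty:
            raise ValueError(f"channel {ch!r} table is empty")
        mask, y = binary_task_labels(df["class"].to_numpy(), task)
        X = df.loc[mask, [c for c in df.columns if c != "class"]].to_numpy(dtype=float)
        for model in bank:
            res = cross_validate(model, X, y, n_folds=n_folds,
                                 seed=subseed(seed, "rank", ch, model.name),
                                 task=task, input_name=ch)
            n_eval += 1
            cur = best.get(ch)
            # argmax by AUC, then ACC, then lexicographically first model name
            if cur is None or (res.auc, res.acc) > (cur.auc, cur.acc) or (
                    (res.auc, res.acc) == (cur.auc, cur.acc)
                    and res.model_name < cur.model_name):
                best[ch] = res
    rows = pd.DataFrame(
        [{"channel": ch, "model": r.model_name, "auc": r.auc, "acc": r.acc,
          "sen": r.sen, "spe": r.spe} for ch, r in best.items()]
    ).sort_values(by=["auc", "acc", "channel"], ascending=[False, False, True],
                  kind="stable").reset_index(drop=True)
    return RankingTable(rows=rows, results=best, n_evaluations=n_eval)


@dataclass
class FusionSearchResult:
    best: CVResult
    best_channels: tuple[str, ...]
    per_combination: pd.DataFrame
    n_evaluations: int


def rff_search(tables: dict[str, pd.DataFrame], ranking: RankingTable, task: str,
               bank: list[BaseModelSpec] | None = None, n_folds: int = 10,
               seed: int = 0, top_k: int = 4,
               strategy: str = "featurewise", combination: str = "sum") -> FusionSearchResult:
    """Search all fusion combinations of the top-ranked channels.

    Takes the top ``top_k`` channels from the ranking, enumerates all
    subsets of size >= 2 and evaluates the full bank on each subset's fused
    features; returns the argmax-AUC result (ties: higher ACC, then the
    smaller subset, then lexicographic).
    """
    if len(ranking.channels) < top_k:
        raise ValueError(f"ranking must cover at least {top_k} channels")
    bank = bank if bank is not None else default_model_bank()
    top = ranking.channels[:top_k]
    subsets = enumerate_combinations(top)
    records = []
    best: CVResult | None = None
    best_subset: tuple[str, ...] = ()
    n_eval = 0
    for subset in subsets:
        for model in bank:
            res = cross_validate_fused(tables, subset, model, task, n_folds=n_folds,
                                       seed=subseed(seed, "rff", "+".join(subset), model.name),
                                       strategy=strategy, combination=combination)
            n_eval += 1
            records.append({"channels": "+".join(subset), "model": model.name,
                            "auc": res.auc, "acc": res.acc})
            # argmax by AUC, then ACC, then smaller subset, then lexicographic
            key = (res.auc, res.acc, -len(subset), "+".join(subset), res.model_name)
            if best is None:
                take = True
            else:
                cur = (best.auc, best.acc, -len(best_subset), "+".join(best_subset),
                       best.model_name)
                take = (key[0], key[1], key[2]) > (cur[0], cur[1], cur[2]) or (
                    (key[0], key[1], key[2]) == (cur[0], cur[1], cur[2])
                    and (key[3], key[4]) < (cur[3], cur[4]))
            if take:
                best = res
                best_subset = subset
    return FusionSearchResult(best=best, best_channels=best_subset,
                              per_combination=pd.DataFrame(records), n_evaluations=n_eval)


def evaluate_holdout(rss_channel: str, rss_model: BaseModelSpec,
                     rff_channels, rff_model: BaseModelSpec,
                     train_tables: dict[str, pd.DataFrame],
                     test_tables: dict[str, pd.DataFrame], task: str,
                     seed: int = 0, strategy: str = "featurewise",
                     combination: str = "sum") -> dict[str, dict[str, float]]:
    """Refit the best Rss and R_FF models on training data, evaluate once on test."""
    train_ids = set(next(iter(train_tables.values())).index)
    test_ids = set(next(iter(test_tables.values())).index)
    if train_ids & test_ids:
        raise ValueError("train and test cohorts share lesion ids (leakage)")

    def _labels(tables):
        df = next(iter(tables.values()))
        return df["class"].to_numpy()

    mask_tr, y_tr = binary_task_labels(_labels(train_tables), task)
    mask_te, y_te = binary_task_labels(_labels(test_tables), task)
    if len(np.unique(y_te)) < 2:
        raise ValueError("test cohort is single-class for this task")
    feats = [c for c in next(iter(train_tables.values())).columns if c != "class"]

    out: dict[str, dict[str, float]] = {}

    X_tr = train_tables[rss_channel].loc[mask_tr, feats].to_numpy(dtype=float)
    X_te = test_tables[rss_channel].loc[mask_te, feats].to_numpy(dtype=float)
    prob = _fit_predict(rss_model, X_tr, y_tr, X_te, seed=subseed(seed, "holdout", "rss"))
    out["rss"] = {"auc": auc_score(y_te, prob), **threshold_metrics(y_te, prob),
                  "channel": rss_channel, "model": rss_model.name}

    views_tr = {ch: train_tables[ch].loc[mask_tr, feats].to_numpy(dtype=float)
                for ch in rff_channels}
    views_te = {ch: test_tables[ch].loc[mask_te, feats].to_numpy(dtype=float)
                for ch in rff_channels}
    stack_tr = ViewStack(views=views_tr, labels=y_tr, feature_names=tuple(feats))
    transform = fit_fusion(stack_tr, strategy=strategy, combination=combination)
    F_tr = apply_fusion(transform, stack_tr)
    F_te = apply_fusion(transform, ViewStack(views=views_te, labels=y_te,
                                             feature_names=tuple(feats)))
    prob = _fit_predict(rff_model, F_tr, y_tr, F_te, seed=subseed(seed, "holdout", "rff"))
    out["rff"] = {"auc": auc_score(y_te, prob), **threshold_metrics(y_te, prob),
                  "channels": "+".join(rff_channels), "model": rff_model.name}
    return out


def compare_cv_results(a: CVResult, b: CVResult) -> ComparisonResult:
    """Paired Wilcoxon signed-rank comparison of per-fold AUCs."""
    return wilcoxon_paired(a.fold_auc, b.fold_auc,
                           name_a=f"{a.input_name}:{a.model_name}",
                           name_b=f"{b.input_name}:{b.model_name}")


def table3_summary(fused: pd.DataFrame, y, top_k: int = 5,
                   selection_counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Mean-threshold summary of the top-ranked fused features.

    For each feature: a two-sided rank-sum p-value between the classes, the
    threshold (mean of the two class means) and the percentage of each class
    below/above it. ``selection_counts`` — how often each feature was
    selected across base models with AUC > 0.6 — orders the features when
    given, otherwise ascending p-value is used.
    """
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("binary task required")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("empty class arm")
    feats = [c for c in fused.columns if c != "class"]
    rows = []
    for name in feats:
        v = fused[name].to_numpy(dtype=float)
        v0, v1 = v[y == 0], v[y == 1]
        p = stats.ranksums(v1, v0).pvalue
        thr = (v0.mean() + v1.mean()) / 2.0
        rows.append({
            "feature": name, "p_value": float(p), "mean_threshold": float(thr),
            "pos_below_pct": 100.0 * float((v1 < thr).mean()),
            "pos_above_pct": 100.0 * float((v1 >= thr).mean()),
            "neg_below_pct": 100.0 * float((v0 < thr).mean()),
            "neg_above_pct": 100.0 * float((v0 >= thr).mean()),
            "selection_count": (selection_counts or {}).get(name, 0),
        })
    df = pd.DataFrame(rows)
    if selection_counts:
        df = df.sort_values(["selection_count", "p_value"], ascending=[False, True],
                            kind="stable")
    else:
        df = df.sort_values("p_value", kind="stable")
    return df.head(top_k).reset_index(drop=True)


def count_selection_frequency(results: list[tuple[float, list[str]]],
                              auc_threshold: float = 0.6) -> dict[str, int]:
    """Occurrence count of selected features across base models with AUC above threshold."""
    counts: dict[str, int] = {}
    for auc, selected in results:
        if auc > auc_threshold:
            for name in selected:
                counts[name] = counts.get(name, 0) + 1
    return counts
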