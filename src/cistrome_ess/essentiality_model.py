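"""SVM prediction of binding-site essentiality with GA feature selection.

Sites are labeled from screen results — essential when the negative-selection
rank is under a threshold, nonessential when clearly unselected (permutation
p above 0.5 and |LFC| under 0.1) — and the classes are balanced by seeded
downsampling to a ratio within [0.85, 1.1].  Feature subsets are searched by
a genetic algorithm whose fitness is the validation-set AUROC of an SVM
(RBF kernel on standardised features); the final model is evaluated with
stratified k-fold cross-validation on pooled out-of-fold decision scores,
compared against single-feature baselines, and applied to unseen sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._rng import stream


@dataclass
class GAParams:
    population: int = 24
    iterations: int = 25
    elite_frac: float = 0.25
    init_include_prob: float = 0.4
    validation_frac: float = 0.3


@dataclass
class ModelSpec:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"


@dataclass
class FittedModel:
    features: list[str]
    pipeline: Pipeline


@dataclass
class ModelResult:
    selected_features: list[str]
    cv_auc: float
    cv_aupr: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    pr_points: np.ndarray  # (recall, precision) rows
    per_site_score: pd.Series
    single_feature_aucs: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# labeling


def label_sites(
    results: pd.DataFrame,
    rank_threshold: int = 300,
    null_p: float = 0.5,
    max_abs_lfc: float = 0.1,
    ratio_bounds: tuple[float, float] = (0.85, 1.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Essential/nonessential labels from screen results, class-balanced.

    Essential: ``neg_rank < rank_threshold``.  Nonessential: permutation
    ``p_value > null_p`` and ``|lfc| < max_abs_lfc`` (and not essential).
    The larger class is downsampled uniformly (seeded) until the
    essential-to-nonessential ratio falls within ``ratio_bounds``.
    Pass ``rank_threshold="auto"`` to scale the cut as 5% of the site count
    for libraries much smaller than a full cistrome screen.
    """
    if rank_threshold == "auto":
        rank_threshold = max(2, int(round(0.05 * len(results))))
    ess = results[results["neg_rank"] < int(rank_threshold)]
    non = results[
        (results["p_value"] > null_p)
        & (results["lfc"].abs() < max_abs_lfc)
        & ~results["site_id"].isin(ess["site_id"])
    ]
    if ess.empty:
        raise ValueError(
            f"no essential sites under rule neg_rank < {rank_threshold}"
        )
    if non.empty:
        raise ValueError(
            f"no nonessential sites under rule p > {null_p} and |lfc| < {max_abs_lfc}"
        )
    rng = stream(seed, "label_sites")
    e_ids = ess["site_id"].to_numpy()
    n_ids = non["site_id"].to_numpy()
    lo, hi = ratio_bounds
    ratio = len(e_ids) / len(n_ids)
    if ratio > hi:
        e_ids = rng.choice(e_ids, size=int(len(n_ids) * hi), replace=False)
    elif ratio < lo:
        # floor keeps the ratio at or above lo; never exceeds 1 <= hi
        n_ids = rng.choice(n_ids, size=max(1, int(len(e_ids) / lo)), replace=False)
    out = pd.concat(
        [
            pd.DataFrame(
                {"site_id": e_ids, "label": "essential", "source_rule": f"neg_rank<{rank_threshold}"}
            ),
            pd.DataFrame(
                {
                    "site_id": n_ids,
                    "label": "nonessential",
                    "source_rule": f"p>{null_p}&|lfc|<{max_abs_lfc}",
                }
            ),
        ],
        ignore_index=True,
    )
    r = (out["label"] == "essential").sum() / (out["label"] == "nonessential").sum()
    assert lo <= r <= hi, f"balancing failed: ratio {r:.3f}"
    return out


def _labels_to_binary(labels: pd.DataFrame) -> pd.Series:
    return pd.Series(
        (labels["label"] == "essential").astype(int).to_numpy(),
        index=labels["site_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# GA-SVM feature selection


def _make_svm(spec: ModelSpec) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=spec.kernel, C=spec.C, gamma=spec.gamma)),
        ]
    )


def _fitness(
    mask: tuple[bool, ...],
    X: np.ndarray,
    y: np.ndarray,
    split: tuple[np.ndarray, np.ndarray],
    spec: ModelSpec,
    cache: dict,
) -> float:
    if mask in cache:
        return cache[mask]
    cols = np.flatnonzero(mask)
    tr, va = split
    model = _make_svm(spec)
    model.fit(X[np.ix_(tr, cols)], y[tr])
    score = model.decision_function(X[np.ix_(va, cols)])
    fpr, tpr, _ = roc_curve(y[va], score)
    val = float(auc(fpr, tpr))
    cache[mask] = val
    return val


def _mutate(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly add, remove or swap one feature, keeping >= 1 active."""
    m = mask.copy()
    on = np.flatnonzero(m)
    off = np.flatnonzero(~m)
    moves = []
    if off.size:
        moves.append("add")
    if on.size > 1:
        moves.append("remove")
    if on.size and off.size:
        moves.append("change")
    mv = moves[int(rng.integers(len(moves)))]
    if mv == "add":
        m[off[int(rng.integers(off.size))]] = True
    elif mv == "remove":
        m[on[int(rng.integers(on.size))]] = False
    else:
        m[on[int(rng.integers(on.size))]] = False
        m[off[int(rng.integers(off.size))]] = True
    return m


def ga_svm_select(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    ga_params: GAParams | None = None,
    seed: int = 0,
    model_spec: ModelSpec | None = None,
) -> tuple[list[str], list[float]]:
    """Genetic-algorithm search for the feature subset with best AUROC.

    Each generation keeps an elite fraction of subsets and fills the rest
    with single-feature mutations (add/remove/change) of parents sampled
    with rank-proportional probability.  Fitness is the AUROC of the SVM on
    a fixed, seeded 70/30 train/validation split held out from fitness
    evaluation.  Returns the best subset seen and the best-so-far fitness
    trace (one entry per generation, non-decreasing).
    """
    params = ga_params or GAParams()
    spec = model_spec or ModelSpec()
    if features.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    y = _labels_to_binary(labels)
    X = features.loc[y.index].to_numpy(dtype=float)
    yv = y.to_numpy()
    rng = stream(seed, "ga_svm_select")
    idx = np.arange(len(yv))
    tr, va = train_test_split(
        idx,
        test_size=params.validation_frac,
        stratify=yv,
        random_state=int(rng.integers(2**31)),
    )
    split = (tr, va)
    nf = features.shape[1]
    cache: dict = {}

    pop = []
    while len(pop) < params.population:
        m = rng.random(nf) < params.init_include_prob
        if not m.any():
            m[int(rng.integers(nf))] = True
        pop.append(m)

    def score_pop(pop):
        return np.array(
            [_fitness(tuple(m.tolist()), X, yv, split, spec, cache) for m in pop]
        )

    fits = score_pop(pop)
    best_i = int(np.argmax(fits))
    best_mask, best_fit = pop[best_i].copy(), float(fits[best_i])
    trace = [best_fit]

    n_elite = max(1, int(round(params.elite_frac * params.population)))
    for _ in range(params.iterations):
        order = np.argsort(-fits)
        elite = [pop[i] for i in order[:n_elite]]
        # rank-proportional parent sampling over the whole population
        ranks = np.empty(len(pop))
        ranks[order] = np.arange(len(pop), 0, -1)
        pprob = ranks / ranks.sum()
        children = []
        while len(children) < params.population - n_elite:
            parent = pop[int(rng.choice(len(pop), p=pprob))]
            children.append(_mutate(parent, rng))
        pop = elite + children
        fits = score_pop(pop)
        i = int(np.argmax(fits))
        if fits[i] > best_fit:
            best_fit, best_mask = float(fits[i]), pop[i].copy()
        trace.append(best_fit)

    selected = [f for f, on in zip(features.columns, best_mask) if on]
    return selected, trace


# ---------------------------------------------------------------------------
# cross-validation and prediction


def cross_validate(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    model_spec: ModelSpec | None = None,
    folds: int = 5,
    seed: int = 0,
    compare_single_features: bool = True,
) -> ModelResult:
    """Stratified k-fold CV; ROC/PR from pooled out-of-fold decision scores.

    Single-feature baselines rank sites by the feature value itself
    (orientation-free: the reported AUC is max(a, 1-a)).
    """
    spec = model_spec or ModelSpec()
    y = _labels_to_binary(labels)
    X = features.loc[y.index]
    yv = y.to_numpy()
    if min((yv == 0).sum(), (yv == 1).sum()) < folds:
        raise ValueError("too few members of a class for stratified folds")
    rng = stream(seed, "cross_validate")
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    scores = np.empty(len(yv))
    for tr, te in skf.split(X, yv):
        model = _make_svm(spec)
        model.fit(X.iloc[tr], yv[tr])
        scores[te] = model.decision_function(X.iloc[te])
    fpr, tpr, _ = roc_curve(yv, scores)
    prec, rec, _ = precision_recall_curve(yv, scores)
    cv_auc = float(auc(fpr, tpr))
    cv_aupr = float(auc(rec[::-1], prec[::-1]))

    single = {}
    if compare_single_features:
        for f in features.columns:
            x = X[f].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                single[f] = 0.5
                continue
            ffpr, ftpr, _ = roc_curve(yv, x)
            a = auc(ffpr, ftpr)
            single[f] = float(max(a, 1.0 - a))

    return ModelResult(
        selected_features=list(features.columns),
        cv_auc=cv_auc,
        cv_aupr=cv_aupr,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec, prec]),
        per_site_score=pd.Series(scores, index=y.index, name="score"),
        single_feature_aucs=single,
    )


def fit_model(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    model_spec: ModelSpec | None = None,
) -> FittedModel:
    """Fit the SVM on the full labeled set for downstream scoring."""
    spec = model_spec or ModelSpec()
    y = _labels_to_binary(labels)
    model = _make_svm(spec)
    model.fit(features.loc[y.index], y.to_numpy())
    return FittedModel(features=list(features.columns), pipeline=model)


def predict_scores(model: FittedModel, new_rows: pd.DataFrame) -> pd.Series:
    """Decision scores for unseen sites; schema must match training."""
    missing = [f for f in model.features if f not in new_rows.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    X = new_rows[model.features]
    return pd.Series(
        model.pipeline.decision_function(X), index=new_rows.index, name="score"
    )


def error_analysis(
    scores: pd.Series,
    labels: pd.DataFrame,
    features: pd.DataFrame,
    threshold: float | None = None,
) -> dict:
    """Feature profiles of the classifier's confusion groups.

    The predicted-essential threshold defaults to the score quantile that
    matches the labeled prevalence.  Reports per-feature medians for
    TP/FP/TN/FN plus Mann-Whitney p-values for the FP-vs-TN and FN-vs-TP
    contrasts; empty groups are listed under ``skipped``.
    """
    y = _labels_to_binary(labels)
    s = scores.reindex(y.index)
    if threshold is None:
        prevalence = y.mean()
        threshold = float(s.quantile(1.0 - prevalence))
    pred = (s >= threshold).astype(int)
    groups = {
        "TP": y.index[(y == 1) & (pred == 1)],
        "FP": y.index[(y == 0) & (pred == 1)],
        "TN": y.index[(y == 0) & (pred == 0)],
        "FN": y.index[(y == 1) & (pred == 0)],
    }
    skipped = [g for g, ids in groups.items() if len(ids) == 0]
    medians = {
        g: features.loc[ids].median().to_dict()
        for g, ids in groups.items()
        if len(ids)
    }
    contrasts = {}
    for name, (g1, g2) in {"FP_vs_TN": ("FP", "TN"), "FN_vs_TP": ("FN", "TP")}.items():
        if len(groups[g1]) >= 2 and len(groups[g2]) >= 2:
            contrasts[name] = {
                f: float(
                    stats.mannwhitneyu(
                        features.loc[groups[g1], f],
                        features.loc[groups[g2], f],
                        alternative="two-sided",
                    ).pvalue
                )
                for f in features.columns
            }
    return {
        "threshold": threshold,
        "medians": medians,
        "contrasts": contrasts,
        "skipped": skipped,
    }
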