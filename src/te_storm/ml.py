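"""Entropy prefiltering, Boruta all-relevant selection, and RF evaluation.

Feature screening ranks loci by the Shannon entropy of their expression
distribution (log2(x+1)-transformed values binned into equal-width bins)
and keeps the most informative ones.  Boruta then compares each real
feature's random-forest importance against the best of the shuffled
"shadow" copies over repeated fits, confirming or rejecting features by a
Bonferroni-corrected binomial test on the hit counts.  The final model is
a random forest evaluated on a held-out split with the area under the ROC
curve computed as the midrank (Mann-Whitney) statistic.

Samples from the same subject (a converter's pre and post draws) are never
split across the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import UsageError


def shannon_entropy(values, n_bins: int = 10) -> float:
    """Entropy (bits) of the binned log2(x+1) expression distribution.

    Values are transformed to log2(x+1) and histogrammed into ``n_bins``
    equal-width bins over the observed range; H = -sum p log2 p over
    non-empty bins.  A constant vector has a single occupied bin and H = 0.
    """
    if n_bins < 2:
        raise UsageError(f"n_bins must be >= 2, got {n_bins}")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UsageError("entropy needs at least 2 samples")
    t = np.log2(v + 1.0)
    lo, hi = float(t.min()), float(t.max())
    if hi <= lo:
        return 0.0
    hist, _ = np.histogram(t, bins=n_bins, range=(lo, hi))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_prefilter(
    matrix: pd.DataFrame, top_k: int = 10_000, n_bins: int = 10
) -> list[str]:
    """Loci ranked by expression entropy, descending; first top_k retained.

    Ties are broken by locus id (lexicographic) so the retained set is
    deterministic.
    """
    if top_k < 1:
        raise UsageError("top_k must be >= 1")
    H = matrix.apply(lambda row: shannon_entropy(row.to_numpy(), n_bins), axis=1)
    order = sorted(H.index, key=lambda lid: (-H[lid], lid))
    return order[: min(top_k, len(order))]


@dataclass
class BorutaDecision:
    locus_id: str
    status: str  # confirmed | rejected | tentative
    hit_count: int
    n_iterations: int


@dataclass
class BorutaResult:
    decisions: list[BorutaDecision]
    n_iterations: int

    def by_status(self, status: str) -> list[str]:
        return [d.locus_id for d in self.decisions if d.status == status]

    @property
    def confirmed(self) -> list[str]:
        return self.by_status("confirmed")

    @property
    def rejected(self) -> list[str]:
        return self.by_status("rejected")

    @property
    def tentative(self) -> list[str]:
        return self.by_status("tentative")


def boruta_select(
    X: pd.DataFrame,
    y,
    p_value: float = 0.05,
    n_tree: int = 10_000,
    max_runs: int = 100,
    seed: int = 0,
    importance: str = "impurity",
) -> BorutaResult:
    """Shadow-feature all-relevant selection.

    Per iteration every still-active feature gets a shuffled shadow copy;
    a random forest of ``n_tree`` trees is fit on real + shadow columns and
    a feature scores a hit when its importance exceeds the maximum shadow
    importance.  After each iteration a two-sided binomial test (success
    probability 0.5, Bonferroni-corrected over the currently undecided
    features) confirms or rejects; undecided features at ``max_runs`` stay
    tentative.  ``importance`` is impurity (mean decrease) or
    ``oob_permutation`` (per-tree out-of-bag accuracy drop).
    """
    y = np.asarray(y)
    labels = np.unique(y)
    if len(labels) < 2:
        raise UsageError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise UsageError("each class needs at least 2 samples")
    if importance not in ("impurity", "oob_permutation"):
        raise UsageError(f"unknown importance {importance!r}")
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    status = {f: "tentative" for f in features}
    hits = {f: 0 for f in features}
    decided_at = {}
    n_iter = 0
    Xv = X.to_numpy(dtype=float)
    for run in range(1, max_runs + 1):
        active = [f for f in features if status[f] != "rejected"]
        undecided = [f for f in features if status[f] == "tentative"]
        if not undecided:
            break
        n_iter = run
        cols = [features.index(f) for f in active]
        real = Xv[:, cols]
        shadow = real.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        # pad shadows so the max-shadow reference never rests on <5 columns
        while shadow.shape[1] < 5:
            extra = real[:, rng.integers(0, real.shape[1])].copy()
            rng.shuffle(extra)
            shadow = np.column_stack([shadow, extra])
        Xfull = np.column_stack([real, shadow])
        imp = _forest_importance(
            Xfull, y, n_tree=n_tree,
            seed=int(rng.integers(0, 2**31 - 1)), kind=importance,
        )
        real_imp = imp[: len(cols)]
        shadow_max = imp[len(cols):].max()
        for f, v in zip(active, real_imp):
            if status[f] == "tentative" and v > shadow_max:
                hits[f] += 1
        k = len(undecided)
        for f in undecided:
            upper = stats.binom.sf(hits[f] - 1, run, 0.5)
            lower = stats.binom.cdf(hits[f], run, 0.5)
            if upper * k < p_value:
                status[f] = "confirmed"
                decided_at[f] = run
            elif lower * k < p_value:
                status[f] = "rejected"
                decided_at[f] = run
    decisions = [
        BorutaDecision(locus_id=f, status=status[f], hit_count=hits[f],
                       n_iterations=decided_at.get(f, n_iter))
        for f in features
    ]
    return BorutaResult(decisions=decisions, n_iterations=n_iter)


def _forest_importance(X, y, n_tree: int, seed: int, kind: str) -> np.ndarray:
    if kind == "impurity":
        rf = RandomForestClassifier(
            n_estimators=n_tree, max_features="sqrt", random_state=seed, n_jobs=1
        )
        rf.fit(X, y)
        return rf.feature_importances_
    return _oob_permutation_importance(X, y, n_tree, seed)


def _oob_permutation_importance(X, y, n_tree: int, seed: int) -> np.ndarray:
    """Z-score of the out-of-bag accuracy drop per feature (mean/sd over trees)."""
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(seed)
    n, F = X.shape
    y = np.asarray(y)
    drops = np.zeros((n_tree, F))
    used = np.zeros(n_tree, dtype=bool)
    for t in range(n_tree):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0:
            continue
        used[t] = True
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        Xo = X[oob]
        base = (tree.predict(Xo) == y[oob]).mean()
        # one stacked prediction for all per-feature permutations
        big = np.tile(Xo, (F, 1))
        m = len(oob)
        for f in range(F):
            perm = rng.permutation(m)
            big[f * m:(f + 1) * m, f] = Xo[perm, f]
        pred = tree.predict(big).reshape(F, m)
        acc = (pred == y[oob][None, :]).mean(axis=1)
        drops[t] = base - acc
    d = drops[used]
    if not len(d):
        return np.zeros(F)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1) if len(d) > 1 else np.ones(F)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, mean / sd, 0.0)


def mann_whitney_auc(scores, labels) -> float:
    """Midrank AUC: probability a random positive outranks a random negative."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    n1, n0 = int(lab.sum()), int((~lab).sum())
    if n1 == 0 or n0 == 0:
        raise UsageError("AUC needs both classes in the evaluation set")
    ranks = stats.rankdata(s)
    return float((ranks[lab].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (FPR, TPR) over all score thresholds."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    order = np.argsort(-s, kind="mergesort")
    tps = np.cumsum(lab[order])
    fps = np.cumsum(~lab[order])
    tpr = np.concatenate([[0], tps / max(lab.sum(), 1)])
    fpr = np.concatenate([[0], fps / max((~lab).sum(), 1)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def paired_aware_split(
    meta: pd.DataFrame, train_frac: float = 0.70, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Subject-level train/test split: a subject's samples stay together.

    Subjects are stratified by their label profile (e.g. paired converters
    vs single-sample controls) so both sides keep both classes.  Reduces to
    a stratified sample-level split when every subject has one sample.
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    profiles = meta.groupby("subject_id")["group"].apply(
        lambda g: ",".join(sorted(set(g))))
    for _, subjects in profiles.groupby(profiles):
        ids = sorted(subjects.index)
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        chosen = {ids[i] for i in perm[:n_train]}
        for subj in ids:
            samples = meta.loc[meta["subject_id"] == subj, "sample_id"].tolist()
            (train if subj in chosen else test).extend(samples)
    return sorted(train), sorted(test)


@dataclass
class ModelReport:
    features: list[str]
    train_samples: list[str]
    test_samples: list[str]
    cv_folds: int
    cv_accuracy: float
    auc: float
    accuracy: float
    confusion: pd.DataFrame
    roc: pd.DataFrame
    params: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_features": len(self.features), "auc": self.auc,
            "accuracy": self.accuracy, "cv_accuracy": self.cv_accuracy,
            "n_train": len(self.train_samples), "n_test": len(self.test_samples),
        }


def train_evaluate(
    X: pd.DataFrame,
    y: pd.Series,
    features: list[str],
    meta: pd.DataFrame | None = None,
    train_frac: float = 0.70,
    cv_folds: int = 5,
    downsample: bool = True,
    n_tree: int = 10_000,
    seed: int = 0,
) -> ModelReport:
    """Random-forest evaluation with a held-out split.

    Rows of ``X`` are samples.  The split is subject-aware when ``meta``
    (with subject_id) is given.  The training set is optionally
    down-sampled to class balance; a ``cv_folds``-fold cross-validation
    accuracy on the training set is reported as a sanity check; ROC/AUC
    are computed on the held-out test set from predicted class
    probabilities by the midrank statistic.
    """
    if not features:
        raise UsageError("feature list is empty")
    rng = np.random.default_rng(seed)
    if meta is not None:
        train_ids, test_ids = paired_aware_split(meta, train_frac, seed)
        train_ids = [s for s in train_ids if s in X.index]
        test_ids = [s for s in test_ids if s in X.index]
    else:
        idx = np.array(X.index)
        train_ids, test_ids = [], []
        for cls in np.unique(y):
            ids = idx[np.asarray(y) == cls]
            perm = rng.permutation(len(ids))
            n_train = int(round(train_frac * len(ids)))
            train_ids += list(ids[perm[:n_train]])
            test_ids += list(ids[perm[n_train:]])
        train_ids, test_ids = sorted(train_ids), sorted(test_ids)
    y_train = y.loc[train_ids]
    y_test = y.loc[test_ids]
    for name, ys in (("train", y_train), ("test", y_test)):
        if ys.nunique() < 2:
            raise UsageError(f"a class is absent from the {name} set; re-split")
    X_train = X.loc[train_ids, features]
    X_test = X.loc[test_ids, features]
    if downsample:
        n_min = y_train.value_counts().min()
        keep = []
        for cls, grp in y_train.groupby(y_train):
            ids = np.array(grp.index)
            keep += list(ids[rng.permutation(len(ids))[:n_min]])
        keep = sorted(keep)
        X_train, y_train = X_train.loc[keep], y_train.loc[keep]
    classes = sorted(y_train.unique())
    pos = classes[-1]
    folds = min(cv_folds, int(y_train.value_counts().min()))
    cv_acc = np.nan
    if folds >= 2:
        accs = []
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        for tr, va in skf.split(X_train, y_train):
            rf = RandomForestClassifier(
                n_estimators=n_tree, max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1)
            rf.fit(X_train.iloc[tr], y_train.iloc[tr])
            accs.append((rf.predict(X_train.iloc[va]) == y_train.iloc[va]).mean())
        cv_acc = float(np.mean(accs))
    rf = RandomForestClassifier(
        n_estimators=n_tree, max_features="sqrt",
        random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1)
    rf.fit(X_train, y_train)
    prob = rf.predict_proba(X_test)[:, list(rf.classes_).index(pos)]
    is_pos = (y_test == pos).to_numpy()
    auc = mann_whitney_auc(prob, is_pos)
    pred = rf.predict(X_test)
    accuracy = float((pred == y_test).mean())
    confusion = pd.crosstab(
        pd.Series(y_test.to_numpy(), name="truth"),
        pd.Series(pred, name="predicted"),
    )
    return ModelReport(
        features=list(features), train_samples=list(train_ids),
        test_samples=list(test_ids), cv_folds=folds, cv_accuracy=cv_acc,
        auc=auc, accuracy=accuracy, confusion=confusion,
        roc=roc_points(prob, is_pos),
        params={"n_tree": n_tree, "downsample": downsample, "seed": seed,
                "train_frac": train_frac, "positive_class": str(pos)},
    )
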