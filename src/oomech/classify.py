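"""Usable-blastocyst prediction from oocyte mechanics and maternal factors.

Feature tables combine fitted mechanical parameters (k0, k1, eta0, eta1,
tau) with maternal factors (patient age, number of retrieved mature MII
oocytes).  All features are log2 transformed and standardized with
parameters learned on training rows only.  Train/test splitting and
cross-validation folds are grouped by patient so no patient straddles a
boundary.  The classifier is an RBF support-vector machine whose
hyperparameters and features are chosen by greedy forward selection
maximising mean 10-fold cross-validated ROC AUC on the training set.
Inter-rater agreement between embryologists is summarised with Fleiss'
kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from statsmodels.stats import inter_rater

MECHANICAL_FEATURES = ["k0", "k1", "eta0", "eta1", "tau"]
MATERNAL_FEATURES = ["patient_age", "mii_count"]
FEATURE_SETS = {
    "mechanical": MECHANICAL_FEATURES,
    "maternal": MATERNAL_FEATURES,
    "mixed": MECHANICAL_FEATURES + MATERNAL_FEATURES,
}

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_FACTORS = (0.1, 1.0, 10.0)

__all__ = [
    "FeatureTable",
    "SplitAssignment",
    "ConfusionMetrics",
    "TrainedClassifier",
    "assemble_features",
    "split_by_patient",
    "train_test_target_sizes",
    "forward_select_and_train",
    "evaluate",
    "confusion_metrics",
    "fleiss_kappa",
    "compare_predictors",
    "FEATURE_SETS",
]


@dataclass
class FeatureTable:
    """Per-oocyte features (log2 scale), labels and patient grouping.

    ``X`` holds the log2-transformed raw features; standardization
    parameters are learned from a set of training rows via
    :meth:`fit_scaler` and applied with :meth:`transform`, keeping the
    transform state with the table so test rows can never influence it.
    """

    X: pd.DataFrame
    y: pd.Series
    patient_id: pd.Series
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)
    mean_: pd.Series | None = None
    std_: pd.Series | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def fit_scaler(self, train_index) -> None:
        """Learn per-column mean/std on the given (training) rows; drops
        zero-variance columns with a warning."""
        Xt = self.X.loc[train_index]
        std = Xt.std(ddof=0)
        dead = std[std < 1e-12].index.tolist()
        if dead:
            warnings.warn(f"dropping zero-variance feature(s): {dead}")
            self.X = self.X.drop(columns=dead)
            Xt = self.X.loc[train_index]
            std = Xt.std(ddof=0)
        self.mean_ = Xt.mean()
        self.std_ = std

    def transform(self, index=None) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted; call fit_scaler first")
        X = self.X if index is None else self.X.loc[index]
        return (X - self.mean_) / self.std_


@dataclass(frozen=True)
class SplitAssignment:
    train_patients: frozenset
    test_patients: frozenset
    train_index: np.ndarray
    test_index: np.ndarray

    def __post_init__(self) -> None:
        if self.train_patients & self.test_patients:
            raise ValueError("train and test patient sets overlap")


class DataError(ValueError):
    pass


def assemble_features(cohort: pd.DataFrame, fits: pd.DataFrame,
                      feature_set: str = "mechanical",
                      fertilized_only: bool = False) -> FeatureTable:
    """Join fitted mechanics onto the cohort and build the feature table.

    ``fits`` carries one row per oocyte_id with columns k0, k1, eta0,
    eta1 (tau derived if absent) and optionally ``converged``.  Measured
    oocytes without a converged fit are excluded with a logged reason
    (the poor-video-quality pathway); the exclusions are kept on the
    returned table.  All features are log2 transformed here; a
    non-positive feature value is a data error naming the row.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    cols = FEATURE_SETS[feature_set]

    df = cohort[cohort["arm"] == "measured"].copy()
    exclusions = []
    if "excluded" in df.columns:
        for oid in df.loc[df["excluded"], "oocyte_id"]:
            exclusions.append((oid, "poor video quality"))
        df = df[~df["excluded"]]

    fits = fits.copy()
    if "tau" not in fits.columns and {"k0", "k1", "eta0"} <= set(fits.columns):
        fits["tau"] = fits["eta0"] * (fits["k0"] + fits["k1"]) / (fits["k0"] * fits["k1"])
    df = df.merge(fits, on="oocyte_id", how="left", suffixes=("", "_fit"))
    need_mech = any(c in MECHANICAL_FEATURES for c in cols)
    if need_mech:
        missing = df["k0"].isna() if "k0" in df.columns else pd.Series(True, index=df.index)
        for oid in df.loc[missing, "oocyte_id"]:
            exclusions.append((oid, "no fit available"))
        df = df[~missing]
        if "converged" in df.columns:
            bad = ~df["converged"].astype(bool)
            for oid in df.loc[bad, "oocyte_id"]:
                exclusions.append((oid, "fit did not converge"))
            df = df[~bad]
    if fertilized_only:
        df = df[df["fertilized"].astype(bool)]

    X = df.set_index("oocyte_id")[cols].astype(float)
    nonpos = X[(X <= 0).any(axis=1)]
    if len(nonpos):
        raise DataError(f"non-positive feature before log2 for rows "
                        f"{nonpos.index.tolist()[:5]}")
    if X.isna().any().any():
        raise DataError("missing feature values after assembly")
    return FeatureTable(
        X=np.log2(X),
        y=df.set_index("oocyte_id")["usable_blastocyst"].astype(bool),
        patient_id=df.set_index("oocyte_id")["patient_id"],
        excluded=pd.DataFrame(exclusions, columns=["oocyte_id", "reason"]),
    )


def train_test_target_sizes(n_oocytes: int, train_fraction: float = 0.70):
    """Target oocyte counts under oocyte-count rounding: a ~70/30 split
    of n oocytes aims at round(0.7 n) training rows."""
    n_train = int(round(train_fraction * n_oocytes))
    return n_train, n_oocytes - n_train


def split_by_patient(table_or_cohort, train_fraction: float = 0.70,
                     seed: int = 0) -> SplitAssignment:
    """Assign whole patients to train/test, targeting ~70% of oocytes.

    Patients are shuffled by ``seed`` and added to the training set
    greedily while that moves the train oocyte count closer to
    round(train_fraction * n).  Accepts a FeatureTable or a cohort
    DataFrame with patient_id/oocyte_id columns.
    """
    if isinstance(table_or_cohort, FeatureTable):
        pid = table_or_cohort.patient_id
    else:
        pid = table_or_cohort.set_index("oocyte_id")["patient_id"]
    patients = pid.unique()
    if len(patients) < 2:
        raise ValueError("need >= 2 patients to split by patient")
    sizes = pid.value_counts()
    target, _ = train_test_target_sizes(len(pid), train_fraction)
    rng = np.random.default_rng(seed)
    order = rng.permutation(patients)
    train, count = [], 0
    for p in order:
        if abs(count + sizes[p] - target) <= abs(count - target):
            train.append(p)
            count += sizes[p]
    if not train:        # degenerate tiny cohorts
        train = [order[0]]
    if len(train) == len(patients):
        train = train[:-1]
    train_set = frozenset(train)
    test_set = frozenset(patients) - train_set
    mask = pid.isin(train_set).to_numpy()
    return SplitAssignment(train_patients=train_set, test_patients=test_set,
                           train_index=pid.index[mask].to_numpy(),
                           test_index=pid.index[~mask].to_numpy())


def _grouped_folds(groups: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Patient-grouped folds: shuffle patients, then greedily balance
    fold oocyte counts.  Returns per-fold boolean row masks."""
    uniq, counts = np.unique(groups, return_counts=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    n_folds = min(n_folds, len(uniq))
    fold_of = {}
    load = np.zeros(n_folds)
    for i in order[np.argsort(-counts[order], kind="stable")]:
        f = int(np.argmin(load))
        fold_of[uniq[i]] = f
        load[f] += counts[i]
    assign = np.array([fold_of[g] for g in groups])
    return [assign == f for f in range(n_folds)]


def _cv_auc(X: pd.DataFrame, y: np.ndarray, folds: list[np.ndarray],
            C: float, gamma) -> float:
    aucs = []
    for test_mask in folds:
        tr, te = ~test_mask, test_mask
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue
        mu, sd = X[tr].mean(), X[tr].std(ddof=0).replace(0.0, 1.0)
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit((X[tr] - mu) / sd, y[tr])
        scores = clf.decision_function((X[te] - mu) / sd)
        aucs.append(roc_auc_score(y[te], scores))
    return float(np.mean(aucs)) if aucs else 0.5


@dataclass
class TrainedClassifier:
    model: SVC
    features: list[str]
    table: FeatureTable
    cv_report: dict
    seed: int

    def predict(self, index=None) -> np.ndarray:
        Xs = self.table.transform(index)[self.features]
        return self.model.predict(Xs).astype(bool)


def forward_select_and_train(table: FeatureTable, split: SplitAssignment,
                             seed: int = 0, n_folds: int = 10,
                             C_grid=DEFAULT_C_GRID,
                             gamma_factors=DEFAULT_GAMMA_FACTORS,
                             tol: float = 1e-6) -> TrainedClassifier:
    """Greedy forward feature selection wrapped around an RBF SVM.

    At each step the candidate feature whose addition maximises the mean
    patient-grouped 10-fold CV AUC (with the SVM's C and kernel width
    grid-searched inside the same folds) is added; selection stops at
    the first non-improving addition.  Standardization inside each fold
    uses that fold's training rows only.  The final model is refitted on
    all training rows with the winning features and hyperparameters.
    """
    y_all = table.y.loc[split.train_index].to_numpy()
    if len(np.unique(y_all)) < 2:
        raise ValueError("training rows contain a single class")
    X_all = table.X.loc[split.train_index]
    groups = table.patient_id.loc[split.train_index].to_numpy()
    folds = _grouped_folds(groups, n_folds, seed)
    n_train_rows = len(X_all)
    gamma_grid = lambda k: [f * (1.0 / k) for f in gamma_factors]  # 'scale'-like base

    selected: list[str] = []
    best_auc, best_hp = -np.inf, (1.0, "scale")
    history = []
    remaining = list(X_all.columns)
    while remaining:
        step = []
        for feat in remaining:
            cand = selected + [feat]
            for C in C_grid:
                for g in gamma_grid(len(cand)):
                    auc = _cv_auc(X_all[cand], y_all, folds, C, g)
                    step.append((auc, feat, (C, g)))
        auc, feat, hp = max(step, key=lambda s: (s[0], s[1]))
        if auc <= best_auc + tol:
            break
        selected.append(feat)
        remaining.remove(feat)
        best_auc, best_hp = auc, hp
        history.append({"added": feat, "cv_auc": auc, "C": hp[0], "gamma": hp[1]})
    if not selected:  # nothing beats nothing: fall back to best single step
        auc, feat, hp = max(step, key=lambda s: (s[0], s[1]))
        selected, best_auc, best_hp = [feat], auc, hp
        history.append({"added": feat, "cv_auc": auc, "C": hp[0], "gamma": hp[1]})

    table.fit_scaler(split.train_index)
    selected = [f for f in selected if f in table.X.columns]
    Xs = table.transform(split.train_index)[selected]
    model = SVC(C=best_hp[0], gamma=best_hp[1], kernel="rbf")
    model.fit(Xs, table.y.loc[split.train_index].to_numpy())
    report = {"selected": list(selected), "cv_auc": best_auc,
              "C": best_hp[0], "gamma": best_hp[1], "steps": history,
              "n_folds": len(folds), "seed": seed,
              "n_train_rows": n_train_rows}
    return TrainedClassifier(model=model, features=selected, table=table,
                             cv_report=report, seed=seed)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts plus the five derived rates, in percent; a rate whose
    denominator is empty is NaN and listed in ``undefined``."""

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def acc(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def sen(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def spe(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def undefined(self) -> list[str]:
        import math
        return [k for k in ("acc", "ppv", "npv", "sen", "spe")
                if math.isnan(getattr(self, k))]

    def as_dict(self, rounded: bool = False) -> dict:
        vals = {k: getattr(self, k) for k in ("acc", "ppv", "npv", "sen", "spe")}
        if rounded:
            vals = {k: (round(v) if v == v else v) for k, v in vals.items()}
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn, **vals}


def confusion_metrics(y_true, y_pred) -> ConfusionMetrics:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("labels and predictions must be matched and non-empty")
    return ConfusionMetrics(
        tp=int(np.sum(y_pred & y_true)), fp=int(np.sum(y_pred & ~y_true)),
        tn=int(np.sum(~y_pred & ~y_true)), fn=int(np.sum(~y_pred & y_true)))


def evaluate(classifier: TrainedClassifier, split: SplitAssignment) -> ConfusionMetrics:
    """Confusion metrics of the trained classifier on the held-out
    (test-patient) rows."""
    if len(split.test_index) == 0:
        raise ValueError("test set is empty")
    y_true = classifier.table.y.loc[split.test_index].to_numpy()
    y_pred = classifier.predict(split.test_index)
    return confusion_metrics(y_true, y_pred)


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for a subjects x raters matrix of categorical
    ratings: (Pbar - Pe) / (1 - Pe) with subject-wise agreement
    proportions and squared marginal category shares."""
    R = pd.DataFrame(ratings)
    if R.isna().any().any():
        raise ValueError("rating matrix must be complete")
    if R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    counts, _ = inter_rater.aggregate_raters(R.to_numpy())
    if counts.shape[1] < 2:
        raise ValueError("degenerate agreement: every rating identical (Pe = 1)")
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def compare_predictors(variants: dict, rater_predictions: pd.DataFrame | None = None,
                       y_true: pd.Series | None = None) -> pd.DataFrame:
    """One metrics row per classifier variant and per human rater.

    ``variants`` maps a name to a (TrainedClassifier, SplitAssignment)
    pair; all variants must share the same test rows.  ``rater_predictions``
    is a test-subjects x raters table of usable/unusable predictions
    scored against ``y_true``.  A ``mean_rater`` summary row averages the
    rater metrics (at full precision; display rounding is the caller's
    concern).
    """
    rows, ref_index = [], None
    for name, (clf, split) in variants.items():
        idx = pd.Index(split.test_index)
        if ref_index is None:
            ref_index = idx
        elif not ref_index.equals(idx):
            raise ValueError("variants evaluated on different test rows")
        m = evaluate(clf, split)
        rows.append({"predictor": name, **m.as_dict()})
    if rater_predictions is not None:
        if y_true is None:
            raise ValueError("rater predictions need y_true to score against")
        accs = []
        for rater in rater_predictions.columns:
            m = confusion_metrics(y_true.loc[rater_predictions.index],
                                  rater_predictions[rater])
            accs.append(m.acc)
            rows.append({"predictor": str(rater), **m.as_dict()})
        rows.append({"predictor": "mean_rater", "acc": float(np.mean(accs))})
    return pd.DataFrame(rows)
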