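"""Training and evaluation of the stress classifiers.

Feature-table rows are flattened into one fixed-order vector per
subject-trial (region channels x modes x 3 descriptors), standardized with
training-set statistics only, and classified with a multilayer perceptron
(3 hidden layers of 10 ReLU units, Adam, learning rate 1e-3, L2 alpha
1e-4, 200 iterations) or an RBF-kernel SVM (C = 0.90, gamma = 0.02,
iteration cap 100, tolerance 1e-3).  Splits are at the *subject* level —
all rows of a subject stay on one side — under either a stratified
70/10/20 train/validation/test split or stratified 10-fold cross
validation with pooled fold predictions.

Reported metrics: sensitivity, specificity and accuracy in percent, the F1
measure, and Cohen's kappa (observed minus chance agreement over one minus
chance agreement).  The stressed class ("B") is the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import channel_group

POSITIVE_LABEL = "B"   # stressed performers

MODE_GROUPS = {"m1_4": (1, 2, 3, 4), "m5_8": (5, 6, 7, 8),
               "m1_8": (1, 2, 3, 4, 5, 6, 7, 8)}


@dataclass
class MLPParams:
    hidden_layers: int = 3
    neurons_per_layer: int = 10
    activation: str = "relu"
    alpha_reg: float = 1e-4
    max_iter: int = 200
    optimizer: str = "adam"
    learning_rate: float = 1e-3


@dataclass
class SVMParams:
    C: float = 0.90
    epsilon: float = 0.1       # regression-style parameter; inert for classification
    kernel: str = "rbf"
    gamma_g: float = 0.02
    iteration_limit: int = 100
    tolerance: float = 1e-3


@dataclass
class ClassifierConfig:
    kind: str = "mlp"          # "mlp" or "svm"
    mlp: MLPParams = field(default_factory=MLPParams)
    svm: SVMParams = field(default_factory=SVMParams)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("mlp", "svm"):
            raise ValueError(f"kind must be 'mlp' or 'svm', got {self.kind!r}")


@dataclass
class SplitConfig:
    mode: str = "percentage"   # "percentage" or "kfold"
    fractions: tuple = (0.70, 0.10, 0.20)
    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("percentage", "kfold"):
            raise ValueError(f"mode must be 'percentage' or 'kfold', got {self.mode!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class SubsetSpec:
    region: str = "all"            # channel-group name
    mode_group: str = "m1_8"
    comparison: str = "good_vs_bad"  # or good_vs_bad_female / good_vs_bad_male

    def __post_init__(self):
        if self.mode_group not in MODE_GROUPS:
            raise ValueError(f"unknown mode group {self.mode_group!r}")
        if self.comparison not in (
            "good_vs_bad", "good_vs_bad_female", "good_vs_bad_male"
        ):
            raise ValueError(f"unknown comparison {self.comparison!r}")

    @property
    def modes(self) -> tuple:
        return MODE_GROUPS[self.mode_group]


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None
    kappa: float | None
    n_instances: int
    split_mode: str
    classifier: str
    flags: list[str] = field(default_factory=list)
    validation_accuracy: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Sensitivity/specificity/accuracy (percent) and F1 from counts.

    A rate whose denominator is zero is reported as None and flagged, never
    silently coerced to 0.
    """
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    flags = []
    total = tp + tn + fp + fn
    sen = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spe = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    acc = 100.0 * (tp + tn) / total if total > 0 else None
    f1 = tp / (tp + (fp + fn) / 2.0) if (tp + (fp + fn) / 2.0) > 0 else None
    if sen is None:
        flags.append("sensitivity undefined (no positive instances)")
    if spe is None:
        flags.append("specificity undefined (no negative instances)")
    if acc is None:
        flags.append("accuracy undefined (no instances)")
    if f1 is None:
        flags.append("f1 undefined (no predicted or actual positives)")
    return {
        "sensitivity": sen,
        "specificity": spe,
        "accuracy": acc,
        "f1": f1,
        "flags": flags,
    }


def kappa(observed_agreement: float, expected_agreement: float) -> float:
    """Chance-corrected agreement (observed - expected) / (1 - expected)."""
    if not (0 <= observed_agreement <= 1 and 0 <= expected_agreement <= 1):
        raise ValueError("agreements must be fractions in [0, 1]")
    if expected_agreement >= 1:
        raise ValueError("kappa undefined when expected agreement is 1")
    return (observed_agreement - expected_agreement) / (1.0 - expected_agreement)


def kappa_from_confusion(tp: int, tn: int, fp: int, fn: int) -> float | None:
    """Cohen's kappa with chance agreement from the marginal products."""
    n = tp + tn + fp + fn
    if n == 0:
        return None
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if pe >= 1:
        return None
    return kappa(po, pe)


def _subject_frame(table: pd.DataFrame) -> pd.DataFrame:
    sub = table[["subject_id", "label"]].drop_duplicates("subject_id")
    return sub.sort_values("subject_id", kind="mergesort").reset_index(drop=True)


def split(table: pd.DataFrame, cfg: SplitConfig):
    """Subject-level stratified partitioning.

    percentage mode → one ``(train, val, test)`` triple of subject-id arrays
    honoring ``cfg.fractions``; kfold mode → list of ``(train, test)``
    subject-id pairs.  Deterministic under ``cfg.seed``.
    """
    subs = _subject_frame(table)
    ids = subs["subject_id"].to_numpy()
    y = subs["label"].to_numpy()
    strat = y if cfg.stratified else None
    if cfg.mode == "percentage":
        if min(np.bincount(pd.factorize(y)[0])) < 2:
            raise ValueError("need at least 2 subjects per class to split")
        f_train, f_val, f_test = cfg.fractions
        n = ids.size
        n_train = int(round(f_train * n))
        n_val = int(round(f_val * n))
        train, rest = train_test_split(
            ids, train_size=n_train, stratify=strat, random_state=cfg.seed
        )
        rest_y = y[np.isin(ids, rest)] if cfg.stratified else None
        val, test = train_test_split(
            rest, train_size=n_val, stratify=rest_y, random_state=cfg.seed
        )
        return np.sort(train), np.sort(val), np.sort(test)
    # kfold
    counts = pd.Series(y).value_counts()
    if (counts < cfg.k).any():
        raise ValueError(
            f"every class needs >= k={cfg.k} subjects for k-fold; have {dict(counts)}"
        )
    skf = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
    return [
        (np.sort(ids[tr]), np.sort(ids[te]))
        for tr, te in skf.split(ids, y)
    ]


def _vectorize(table: pd.DataFrame, subset: SubsetSpec):
    """Flatten descriptor rows into one fixed-order vector per subject-trial."""
    montage = sorted(table["channel"].unique())
    region = channel_group(montage, subset.region)
    sel = table[
        table["channel"].isin(region.members) & table["mode"].isin(subset.modes)
    ]
    if sel.empty:
        raise ValueError(
            f"empty subset: region={subset.region!r}, modes={subset.mode_group!r}"
        )
    wide = sel.pivot_table(
        index=["subject_id", "trial"],
        columns=["channel", "mode"],
        values=list(("area", "m", "ctm")),
        sort=True,
    )
    wide = wide.sort_index(axis=1).sort_index(axis=0)
    if wide.isna().any().any():
        raise ValueError("missing (channel, mode) cells in feature table")
    label_of = sel.drop_duplicates("subject_id").set_index("subject_id")["label"]
    subjects = wide.index.get_level_values("subject_id")
    X = wide.to_numpy()
    y = (label_of.loc[subjects].to_numpy() == POSITIVE_LABEL).astype(int)
    return X, y, subjects.to_numpy()


def _make_estimator(cfg: ClassifierConfig):
    if cfg.kind == "mlp":
        p = cfg.mlp
        return MLPClassifier(
            hidden_layer_sizes=(p.neurons_per_layer,) * p.hidden_layers,
            activation=p.activation,
            alpha=p.alpha_reg,
            max_iter=p.max_iter,
            solver=p.optimizer,
            learning_rate_init=p.learning_rate,
            random_state=cfg.seed,
        )
    p = cfg.svm
    return SVC(
        C=p.C,
        kernel=p.kernel,
        gamma=p.gamma_g,
        max_iter=p.iteration_limit,
        tol=p.tolerance,
        random_state=cfg.seed,
    )


def _fit_predict(X_tr, y_tr, X_te, cfg: ClassifierConfig, flags: list[str]):
    scaler = StandardScaler().fit(X_tr)
    est = _make_estimator(cfg)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(scaler.transform(X_tr), y_tr)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        flags.append(f"{cfg.kind} did not converge within its iteration limit")
    return est, scaler, est.predict(scaler.transform(X_te))


def _confusion(y_true, y_pred):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def evaluate(
    table: pd.DataFrame,
    subset: SubsetSpec,
    clf: ClassifierConfig,
    split_cfg: SplitConfig,
    genders: dict | None = None,
) -> EvalReport:
    """Train and score one classifier on one (region, mode-group) subset.

    Percentage mode scores the held-out 20% test partition (the 10%
    validation partition is scored as a monitoring diagnostic only); kfold
    mode pools predictions over all folds so every instance is scored
    exactly once.
    """
    if subset.comparison.endswith(("female", "male")):
        if genders is None:
            raise ValueError("gender comparison requested but no genders given")
        want = "F" if subset.comparison.endswith("female") else "M"
        keep = {s for s, g in genders.items() if str(g).upper().startswith(want)}
        table = table[table["subject_id"].isin(keep)]
        if table.empty:
            raise ValueError(f"no subjects of gender {want!r} in table")

    X, y, subjects = _vectorize(table, subset)
    flags: list[str] = []
    sub_table = pd.DataFrame({"subject_id": subjects, "label": y}).drop_duplicates(
        "subject_id"
    )
    sub_table["label"] = np.where(sub_table["label"] == 1, "B", "G")

    if split_cfg.mode == "percentage":
        train, val, test = split(sub_table, split_cfg)
        tr_m, va_m, te_m = (np.isin(subjects, s) for s in (train, val, test))
        est, scaler, y_pred = _fit_predict(X[tr_m], y[tr_m], X[te_m], clf, flags)
        val_acc = None
        if va_m.any():
            val_pred = est.predict(scaler.transform(X[va_m]))
            val_acc = float(np.mean(val_pred == y[va_m]))
        tp, tn, fp, fn = _confusion(y[te_m], y_pred)
        n_eval = int(te_m.sum())
    else:
        y_pred = np.empty_like(y)
        for train, test in split(sub_table, split_cfg):
            tr_m, te_m = np.isin(subjects, train), np.isin(subjects, test)
            _, _, pred = _fit_predict(X[tr_m], y[tr_m], X[te_m], clf, flags)
            y_pred[te_m] = pred
        tp, tn, fp, fn = _confusion(y, y_pred)
        n_eval = y.size
        val_acc = None

    m = confusion_metrics(tp, tn, fp, fn)
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
        f1=m["f1"],
        kappa=kappa_from_confusion(tp, tn, fp, fn),
        n_instances=n_eval,
        split_mode=split_cfg.mode,
        classifier=clf.kind,
        flags=flags + m["flags"],
        validation_accuracy=val_acc,
    )
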