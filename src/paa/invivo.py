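"""Analysis of in vivo activity-sensor reporter matrices.

Activity-based nanosensors release mass-encoded urinary reporters upon
proteolytic cleavage in vivo; quantifying the reporters yields an
n samples x k reporters concentration matrix with a class label per sample
(e.g. tumor-bearing vs control mice). This module covers the downstream
analysis of such matrices:

* normalization (per-sample relative abundance, optionally scaled by each
  reporter's across-sample mean);
* differential enrichment between two classes (two-sided Mann-Whitney U by
  default, Welch t-test optional) with Benjamini-Hochberg adjustment and a
  volcano-plot-ready table;
* PCA with a fixed sign convention (per component, the largest-magnitude
  loading is made positive) so outputs are comparable across runs;
* binary classification with stratified k-fold cross-validated ROC/AUC,
  multiclass evaluation with out-of-fold confusion matrices, and recursive
  feature elimination for reporter panel reduction.

All stochastic steps (fold shuffling, forest construction) are driven by an
explicit integer seed; identical inputs and seed give identical reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, PaaError, ValidationError

__all__ = [
    "ReporterDataset",
    "NormalizationMethod",
    "DifferentialResult",
    "PcaResult",
    "ClassifierReport",
    "RfeResult",
    "read_reporter_csv",
    "normalize_reporters",
    "differential_enrichment",
    "pca",
    "train_classifier",
    "evaluate_multiclass",
    "recursive_feature_elimination",
    "volcano_table",
    "plot_volcano",
    "plot_pca",
    "plot_roc",
    "plot_confusion",
]


@dataclass
class ReporterDataset:
    """Sample x reporter concentration matrix with class labels.

    ``values`` rows are samples (index = sample ids), columns are reporter
    ids; concentrations must be nonnegative. ``class_labels`` aligns with
    the rows; ``group_labels`` (e.g. time point) is optional.
    """

    values: pd.DataFrame
    class_labels: pd.Series
    group_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.values.astype(float)
        if vals.columns.duplicated().any():
            dup = vals.columns[vals.columns.duplicated()][0]
            raise ValidationError(f"duplicate reporter id {dup!r}")
        if (vals.to_numpy() < 0).any():
            raise ValidationError("reporter concentrations must be nonnegative")
        labels = pd.Series(self.class_labels)
        if len(labels) != len(vals):
            raise ValidationError(
                f"{len(labels)} class labels for {len(vals)} samples"
            )
        labels.index = vals.index
        if self.group_labels is not None:
            groups = pd.Series(self.group_labels)
            if len(groups) != len(vals):
                raise ValidationError("group labels must align with samples")
            groups.index = vals.index
            self.group_labels = groups
        self.values = vals
        self.class_labels = labels

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def reporter_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_labels.unique())

    def subset(self, classes: Sequence[str] | None = None) -> "ReporterDataset":
        if classes is None:
            return self
        mask = self.class_labels.isin(classes)
        return ReporterDataset(
            values=self.values[mask],
            class_labels=self.class_labels[mask],
            group_labels=self.group_labels[mask] if self.group_labels is not None else None,
        )


def read_reporter_csv(path: str | Path, *, delimiter: str = ",") -> ReporterDataset:
    """Read the reporter CSV layout: sample_id, class label, optional
    ``group`` column, then one column per reporter. Header row required."""
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: expected sample_id, class and >=1 reporter column")
    sample_col, class_col = df.columns[0], df.columns[1]
    rest = list(df.columns[2:])
    group = None
    if rest and rest[0].strip().casefold() in {"group", "timepoint", "time_point", "week"}:
        group = df[rest[0]].astype(str)
        rest = rest[1:]
    values = df[rest].apply(pd.to_numeric)
    values.index = df[sample_col].astype(str)
    ds = ReporterDataset(
        values=values,
        class_labels=df[class_col].astype(str).set_axis(values.index),
        group_labels=group.set_axis(values.index) if group is not None else None,
    )
    return ds


class NormalizationMethod(str, enum.Enum):
    sample_relative = "sample_relative"
    reporter_mean = "reporter_mean"
    none = "none"


def normalize_reporters(
    ds: ReporterDataset,
    method: NormalizationMethod | str = NormalizationMethod.sample_relative,
) -> ReporterDataset:
    """Normalize a reporter matrix.

    ``sample_relative`` divides each sample's reporters by that sample's
    total, making rows sum to 1 (removes per-animal differences in urine
    concentration and injected dose). ``reporter_mean`` additionally
    divides each reporter by its across-sample mean (removes per-reporter
    scale differences, e.g. ionization efficiency).
    """
    method = NormalizationMethod(method)
    if method is NormalizationMethod.none:
        return ds
    totals = ds.values.sum(axis=1)
    zero = totals[totals == 0]
    if not zero.empty:
        raise DegenerateInputError(
            f"sample {zero.index[0]!r} has all-zero reporters; cannot normalize"
        )
    rel = ds.values.div(totals, axis=0)
    if method is NormalizationMethod.reporter_mean:
        rel = rel.div(rel.mean(axis=0), axis=1)
    return ReporterDataset(values=rel, class_labels=ds.class_labels, group_labels=ds.group_labels)


# ---------------------------------------------------------------------------
# differential enrichment
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-reporter two-group comparison with multiplicity adjustment."""

    class_a: str
    class_b: str
    test: str
    fdr: float
    table: pd.DataFrame  # index reporter; mean_fold_change, log2_fold_change, p_raw, p_adjusted, significant

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def differential_enrichment(
    ds: ReporterDataset,
    class_a: str,
    class_b: str,
    test: str = "mann_whitney",
    fdr: float = 0.05,
    correction: str = "fdr_bh",
) -> DifferentialResult:
    """Two-sided per-reporter test of class A vs class B with BH adjustment.

    The fold change is the ratio of class means (A over B). The default
    test is the two-sided Mann-Whitney U (exact null for small groups
    without ties, normal approximation with tie correction otherwise);
    ``test="t_test"`` switches to Welch's t-test. ``correction`` may be
    ``"fdr_bh"`` (default) or ``"bonferroni"``.
    """
    for cls in (class_a, class_b):
        if cls not in set(ds.class_labels):
            raise ValueError(f"class {cls!r} not present in dataset (has {ds.classes})")
    a = ds.values[ds.class_labels == class_a].to_numpy(dtype=float)
    b = ds.values[ds.class_labels == class_b].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both classes need >= 2 samples")
    if test == "mann_whitney":
        # exact null for small groups without ties; otherwise the normal
        # approximation with tie correction (no continuity correction, which
        # over-conservatively shifts small-sample p-values)
        pooled = np.vstack([a, b])
        has_ties = any(
            len(np.unique(pooled[:, j])) < pooled.shape[0] for j in range(pooled.shape[1])
        )
        if max(len(a), len(b)) <= 8 and not has_ties:
            method, extra = "exact", {}
        else:
            method, extra = "asymptotic", {"use_continuity": False}
        res = scipy.stats.mannwhitneyu(
            a, b, axis=0, alternative="two-sided", method=method, **extra
        )
        p_raw = np.atleast_1d(res.pvalue)
    elif test == "t_test":
        res = scipy.stats.ttest_ind(a, b, axis=0, equal_var=False)
        p_raw = np.atleast_1d(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
        log2fc = np.log2(fc)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=fdr, method=correction)[:4]
    table = pd.DataFrame(
        {
            "mean_fold_change": fc,
            "log2_fold_change": log2fc,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": reject,
        },
        index=ds.reporter_ids,
    )
    return DifferentialResult(class_a=class_a, class_b=class_b, test=test, fdr=fdr, table=table)


def volcano_table(diff: DifferentialResult) -> pd.DataFrame:
    """Plot-ready volcano table: log2 fold change, -log10 adjusted p,
    significance flag (consistent with the differential result)."""
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(diff.table["p_adjusted"].to_numpy())
    return pd.DataFrame(
        {
            "log2_fold_change": diff.table["log2_fold_change"],
            "neg_log10_p_adjusted": neg_log10,
            "significant": diff.table["significant"],
        },
        index=diff.table.index,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame  # n x c
    loadings: pd.DataFrame  # k x c
    explained_variance_ratio: np.ndarray


def pca(ds: ReporterDataset, n_components: int = 2, standardize: bool = False) -> PcaResult:
    """Principal component analysis of the reporter matrix.

    Deterministic (full SVD) with a fixed sign convention: within each
    component the largest-magnitude loading is made positive. With
    ``standardize=True`` reporters are z-scored first (correlation PCA).
    """
    X = ds.values.to_numpy(dtype=float)
    n, k = X.shape
    if not 1 <= n_components <= min(n, k):
        raise ValueError(f"n_components must be in [1, {min(n, k)}], got {n_components}")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # k x c
    for c in range(n_components):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=ds.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=ds.reporter_ids, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class Algorithm(str, enum.Enum):
    svm = "svm"
    random_forest = "random_forest"
    linear_model = "linear_model"


def _make_estimator(algorithm: Algorithm | str, seed: int, kernel: str = "linear"):
    """Estimator factory. SVM and the linear model are standardized within
    each training fold; the random forest is scale-free and is not."""
    algorithm = Algorithm(algorithm)
    if algorithm is Algorithm.svm:
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel=kernel, random_state=seed)),
            ]
        )
    elif algorithm is Algorithm.random_forest:
        est = RandomForestClassifier(n_estimators=200, random_state=seed)
    else:
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
            ]
        )
    return est


def _decision_scores(est, X: np.ndarray, positive_idx: int) -> np.ndarray:
    if hasattr(est, "decision_function"):
        s = est.decision_function(X)
        if s.ndim == 1:
            return s
        return s[:, positive_idx]
    return est.predict_proba(X)[:, positive_idx]


@dataclass
class ClassifierReport:
    """Cross-validated classification results.

    For binary problems ``mean_auc`` averages the per-fold held-out ROC
    AUCs and ``roc_points`` holds one (fpr, tpr) pair of arrays per fold.
    For multiclass problems ``confusion`` aggregates out-of-fold
    predictions (rows = true class, columns = predicted) and
    ``per_class`` holds precision/recall per class.
    """

    algorithm: str
    cv_scheme: str
    seed: int
    fold_aucs: list[float] = field(default_factory=list)
    mean_auc: float | None = None
    roc_points: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    confusion: pd.DataFrame | None = None
    per_class: pd.DataFrame | None = None


def _check_cv(n_splits: int, counts: pd.Series) -> None:
    if n_splits < 2:
        raise ValueError("cross-validation needs >= 2 folds")
    if n_splits > counts.min():
        raise ValueError(
            f"{n_splits}-fold CV impossible: smallest class has {counts.min()} samples"
        )


def train_classifier(
    ds: ReporterDataset,
    algorithm: Algorithm | str = Algorithm.svm,
    positive_class: str | None = None,
    n_splits: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Binary classification with stratified k-fold cross-validation.

    Per fold, the model is fit on the training split and scored on the
    held-out split; the ROC AUC of the held-out decision scores is
    recorded and the fold AUCs averaged. All randomness (fold shuffling,
    forest construction) derives from ``seed``.
    """
    classes = ds.classes
    if len(classes) != 2:
        raise ValueError(f"binary classifier needs exactly 2 classes, got {classes}")
    positive_class = positive_class or classes[-1]
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not in {classes}")
    y = (ds.class_labels == positive_class).astype(int).to_numpy()
    X = ds.values.to_numpy(dtype=float)
    counts = ds.class_labels.value_counts()
    _check_cv(n_splits, counts)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    report = ClassifierReport(
        algorithm=Algorithm(algorithm).value,
        cv_scheme=f"stratified {n_splits}-fold, shuffled",
        seed=seed,
    )
    for train, test in skf.split(X, y):
        est = _make_estimator(algorithm, seed)
        est.fit(X[train], y[train])
        scores = _decision_scores(est, X[test], positive_idx=1)
        report.fold_aucs.append(float(roc_auc_score(y[test], scores)))
        fpr, tpr, _ = roc_curve(y[test], scores)
        report.roc_points.append((fpr, tpr))
    report.mean_auc = float(np.mean(report.fold_aucs))
    return report


def evaluate_multiclass(
    ds: ReporterDataset,
    algorithm: Algorithm | str = Algorithm.svm,
    n_splits: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Multiclass evaluation: out-of-fold predictions aggregated into a
    confusion matrix (rows = true class), plus per-class precision/recall."""
    classes = ds.classes
    if len(classes) < 3:
        raise ValueError(
            f"multiclass evaluation needs >= 3 classes, got {classes}; "
            "use train_classifier for binary problems"
        )
    y = ds.class_labels.to_numpy()
    X = ds.values.to_numpy(dtype=float)
    counts = ds.class_labels.value_counts()
    _check_cv(n_splits, counts)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for train, test in skf.split(X, y):
        est = _make_estimator(algorithm, seed)
        est.fit(X[train], y[train])
        pred[test] = est.predict(X[test])
    cm = _sk_confusion(y, pred.astype(str), labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    with np.errstate(invalid="ignore"):
        recall = np.diag(cm) / cm.sum(axis=1)
        precision = np.diag(cm) / np.where(cm.sum(axis=0) == 0, np.nan, cm.sum(axis=0))
    per_class = pd.DataFrame({"precision": precision, "recall": recall}, index=classes)
    return ClassifierReport(
        algorithm=Algorithm(algorithm).value,
        cv_scheme=f"stratified {n_splits}-fold, shuffled",
        seed=seed,
        confusion=confusion,
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# recursive feature elimination
# ---------------------------------------------------------------------------

@dataclass
class RfeResult:
    """Reporter ranking by reverse elimination order plus the
    performance-vs-panel-size curve."""

    ranking: list[str]  # rank 1 first (last eliminated / most important)
    curve: pd.DataFrame  # index n_features; column mean_auc
    seed: int


def _importances(est, algorithm: Algorithm) -> np.ndarray:
    if algorithm is Algorithm.random_forest:
        return est.feature_importances_
    coef = est.named_steps["clf"].coef_
    return np.abs(coef).mean(axis=0)


def recursive_feature_elimination(
    ds: ReporterDataset,
    algorithm: Algorithm | str = Algorithm.svm,
    n_keep: int = 1,
    positive_class: str | None = None,
    n_splits: int = 5,
    seed: int = 0,
) -> RfeResult:
    """Iteratively drop the lowest-importance reporter and refit.

    At each panel size the cross-validated AUC is recorded (binary
    problems). Importance is |linear weight| for SVM / linear model and
    impurity importance for the random forest; RBF-kernel SVMs expose no
    per-feature importance and are rejected. The final ranking is the
    reverse elimination order: the last surviving reporter has rank 1.
    """
    algorithm = Algorithm(algorithm)
    if not 1 <= n_keep <= len(ds.reporter_ids):
        raise ValueError(f"n_keep must be in [1, {len(ds.reporter_ids)}]")
    features = list(ds.reporter_ids)
    eliminated: list[str] = []
    curve_sizes: list[int] = []
    curve_aucs: list[float] = []
    while True:
        sub = ReporterDataset(
            values=ds.values[features],
            class_labels=ds.class_labels,
            group_labels=ds.group_labels,
        )
        rep = train_classifier(
            sub, algorithm=algorithm, positive_class=positive_class, n_splits=n_splits, seed=seed
        )
        curve_sizes.append(len(features))
        curve_aucs.append(rep.mean_auc)
        if len(features) <= n_keep:
            break
        est = _make_estimator(algorithm, seed)
        y = ds.class_labels.to_numpy()
        est.fit(ds.values[features].to_numpy(dtype=float), y)
        imp = _importances(est, algorithm)
        drop = features[int(np.argmin(imp))]  # ties: first (stable) index
        features.remove(drop)
        eliminated.append(drop)
    # survivors ranked by final-model importance, then the eliminated in
    # reverse order of removal
    if len(features) > 1:
        est = _make_estimator(algorithm, seed)
        est.fit(ds.values[features].to_numpy(dtype=float), ds.class_labels.to_numpy())
        imp = _importances(est, algorithm)
        survivors = [f for _, f in sorted(zip(-imp, features))]
    else:
        survivors = list(features)
    ranking = survivors + list(reversed(eliminated))
    curve = pd.DataFrame({"mean_auc": curve_aucs}, index=pd.Index(curve_sizes, name="n_features"))
    return RfeResult(ranking=ranking, curve=curve, seed=seed)


# ---------------------------------------------------------------------------
# plotting (presentation only)
# ---------------------------------------------------------------------------

def _agg_plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_volcano(diff: DifferentialResult, path: str | Path) -> Path:
    plt = _agg_plt()
    tab = volcano_table(diff)
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = tab["significant"]
    ax.scatter(tab["log2_fold_change"][~sig], tab["neg_log10_p_adjusted"][~sig], c="grey", s=16)
    ax.scatter(tab["log2_fold_change"][sig], tab["neg_log10_p_adjusted"][sig], c="crimson", s=20)
    for rid in tab.index[sig]:
        ax.annotate(rid, (tab.at[rid, "log2_fold_change"], tab.at[rid, "neg_log10_p_adjusted"]), fontsize=6)
    ax.axhline(-np.log10(diff.fdr), color="grey", ls="--", lw=0.7)
    ax.set_xlabel(f"log2 fold change ({diff.class_a} / {diff.class_b})")
    ax.set_ylabel("-log10 adjusted p")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_pca(res: PcaResult, class_labels: pd.Series, path: str | Path) -> Path:
    plt = _agg_plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in sorted(class_labels.unique()):
        mask = (class_labels == cls).to_numpy()
        ax.scatter(res.scores.iloc[mask, 0], res.scores.iloc[mask, 1], label=str(cls), s=24)
    evr = res.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    if res.scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    ax.legend()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_roc(report: ClassifierReport, path: str | Path) -> Path:
    plt = _agg_plt()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for i, (fpr, tpr) in enumerate(report.roc_points, start=1):
        ax.plot(fpr, tpr, lw=1, alpha=0.7, label=f"fold {i} (AUC {report.fold_aucs[i-1]:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{report.algorithm}: mean AUC {report.mean_auc:.3f}")
    ax.legend(fontsize=6)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_confusion(report: ClassifierReport, path: str | Path) -> Path:
    plt = _agg_plt()
    if report.confusion is None:
        raise ValueError("report has no confusion matrix (binary report?)")
    cm = report.confusion
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(cm.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(cm.columns)), list(cm.columns), rotation=45)
    ax.set_yticks(range(len(cm.index)), list(cm.index))
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm.iat[i, j]), ha="center", va="center", fontsize=8)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
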