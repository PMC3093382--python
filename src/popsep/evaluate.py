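"""Hold-out evaluation, ROC curves and sliding-window classifier scans.

All supervised scans share one stratified train/hold-out split across
windows, so per-window accuracies form a comparable spectrum, and per-window
normalization statistics are fitted on the training rows only and applied to
the hold-out rows — the hold-out set never influences training in any way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import (
    EnsembleResult,
    TrainConfig,
    ann_ensemble,
    svm_decision,
    svm_train,
)
from .genotypes import GenotypeMatrix, LabelSet, subset_window, window_ranges
from .simulate import split_null
from .structure import (
    PcaWindowRecord,
    apply_normalizer,
    fit_normalizer,
    pca_window_scan,
)

__all__ = [
    "SplitSpec",
    "SplitError",
    "ROCCurve",
    "WindowScanResult",
    "NullSplitReport",
    "holdout_split",
    "accuracy_percent",
    "roc_curve",
    "classifier_window_scan",
    "window_convergence_experiment",
    "null_split_test",
]


class SplitError(ValueError):
    pass


@dataclass
class SplitSpec:
    """Stratified train/hold-out split specification (default 4:1)."""

    train_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise SplitError(f"train_fraction must be in (0,1), got {self.train_fraction}")


def holdout_split(
    labels: LabelSet, spec: SplitSpec, rng: np.random.Generator | None = None
) -> tuple[list[str], list[str]]:
    """Stratified random split of the labelled ids.

    Within each class, ``ceil(train_fraction * n)`` samples (rounding toward
    the training side) are drawn for training; the rest are held out.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    hold: list[str] = []
    for cls in (0, 1):
        ids = [s for s, c in labels.labels.items() if c == cls]
        if len(ids) < 2:
            raise SplitError(f"class {cls} has fewer than 2 samples")
        n_train = int(np.ceil(spec.train_fraction * len(ids)))
        if n_train >= len(ids):
            n_train = len(ids) - 1
        if n_train < 1:
            raise SplitError(f"class {cls}: split would empty one side")
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        hold += [ids[i] for i in perm[n_train:]]
    return train, hold


def accuracy_percent(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Percent agreement; 100 is a perfect classifier, 50 is chance level
    for balanced two-class data."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return 100.0 * float((p == t).mean())


@dataclass
class ROCCurve:
    """TPR vs FPR over descending decision thresholds; AUC by trapezoid."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> ROCCurve:
    """Receiver operating characteristic of a score that ranks class 1 high.

    Thresholds sweep the sorted unique scores (ties share one step) with a
    leading sentinel so the curve starts at (0,0); it always ends at (1,1).
    The area equals the Mann-Whitney U statistic scaled to [0,1].
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    if s.shape != t.shape:
        raise ValueError("scores and truth misaligned")
    n1 = int((t == 1).sum())
    n0 = int((t == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present in the truth labels")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    distinct = np.flatnonzero(np.diff(s_sorted)) if s.size > 1 else np.array([], int)
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(t_sorted == 1)[idx]
    fps = np.cumsum(t_sorted == 0)[idx]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class WindowScanResult:
    """Per-window hold-out classification spectrum.

    ``sigma`` is the ensemble standard deviation for the network (0 for the
    deterministic SVM); ``scores`` holds each window's hold-out decision
    values (class-1 probability for the network, signed margin for the SVM)
    for downstream ROC analysis.
    """

    method: str
    window_size: int
    starts: np.ndarray
    stops: np.ndarray
    mean_accuracy: np.ndarray
    sigma: np.ndarray
    scores: list[np.ndarray]
    train_ids: list[str]
    holdout_ids: list[str]
    holdout_truth: np.ndarray
    ensembles: list[EnsembleResult] | None = None


def _window_features(
    gm: GenotypeMatrix, start: int, stop: int, train_rows: np.ndarray, hold_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized train/hold-out feature blocks for one window; frequency
    statistics come from the training rows only."""
    win = subset_window(gm, start, stop - start)
    train_gm = GenotypeMatrix(
        [gm.sample_ids[i] for i in train_rows], win.snps, win.dosages[train_rows]
    )
    stats = fit_normalizer(train_gm)
    if not stats.keep.any():
        raise ValueError(f"window [{start}, {stop}): all SNPs monomorphic in training data")
    hold_gm = GenotypeMatrix(
        [gm.sample_ids[i] for i in hold_rows], win.snps, win.dosages[hold_rows]
    )
    return apply_normalizer(train_gm, stats), apply_normalizer(hold_gm, stats)


def classifier_window_scan(
    gm: GenotypeMatrix,
    labels: LabelSet,
    window_size: int,
    method: str = "ann",
    train_config: TrainConfig | None = None,
    C: float = 1.0,
    split_spec: SplitSpec | None = None,
    split: tuple[list[str], list[str]] | None = None,
    keep_ensembles: bool = False,
) -> WindowScanResult:
    """Hold-out classification accuracy per non-overlapping SNP window.

    One stratified split is drawn once and reused for every window; an
    explicit ``split`` (train ids, hold-out ids) may be injected instead,
    e.g. to share a split across several scans.  ``method`` is ``"ann"``
    (restart ensemble, mean +/- sigma) or ``"svm"`` (deterministic, single
    accuracy).
    """
    if method not in ("ann", "svm"):
        raise ValueError(f"unknown method {method!r}")
    labels.validate_against(gm)
    split_spec = split_spec or SplitSpec()
    train_config = train_config or TrainConfig()
    train_ids, hold_ids = split if split is not None else holdout_split(labels, split_spec)
    row_of = {s: i for i, s in enumerate(gm.sample_ids)}
    train_rows = np.array([row_of[s] for s in train_ids])
    hold_rows = np.array([row_of[s] for s in hold_ids])
    y_train = np.array([labels.labels[s] for s in train_ids])
    y_hold = np.array([labels.labels[s] for s in hold_ids])

    ranges = window_ranges(gm.n_snps, window_size)
    means = np.empty(len(ranges))
    sigmas = np.zeros(len(ranges))
    scores: list[np.ndarray] = []
    ensembles: list[EnsembleResult] = []
    for k, (start, stop) in enumerate(ranges):
        try:
            x_train, x_hold = _window_features(gm, start, stop, train_rows, hold_rows)
            if method == "ann":
                res = ann_ensemble(x_train, y_train, x_hold, y_hold, train_config)
                means[k] = res.mean_accuracy
                sigmas[k] = res.sigma
                scores.append(res.per_sample_mean_probability)
                if keep_ensembles:
                    ensembles.append(res)
            else:
                model = svm_train(x_train, y_train, C=C)
                dec = svm_decision(model, x_hold)
                pred = (dec >= 0.0).astype(int)
                means[k] = accuracy_percent(pred, y_hold)
                scores.append(dec)
        except ValueError as exc:
            raise ValueError(f"window [{start}, {stop}): {exc}") from exc
    starts = np.array([r[0] for r in ranges])
    stops = np.array([r[1] for r in ranges])
    return WindowScanResult(
        method=method,
        window_size=window_size,
        starts=starts,
        stops=stops,
        mean_accuracy=means,
        sigma=sigmas,
        scores=scores,
        train_ids=train_ids,
        holdout_ids=hold_ids,
        holdout_truth=y_hold,
        ensembles=ensembles if keep_ensembles else None,
    )


@dataclass
class ConvergenceComparison:
    """One large window against its constituent smallest-size windows."""

    size: int
    start: int
    stop: int
    accuracy: float
    sigma: float
    best_constituent_accuracy: float
    best_constituent_sigma: float
    mean_constituent_accuracy: float


def window_convergence_experiment(
    gm: GenotypeMatrix,
    labels: LabelSet,
    sizes: tuple[int, ...] = (20, 50, 100),
    method: str = "ann",
    train_config: TrainConfig | None = None,
    C: float = 1.0,
    split_spec: SplitSpec | None = None,
) -> tuple[dict[int, WindowScanResult], list[ConvergenceComparison]]:
    """Repeat the window scan at several window sizes with one shared split.

    For each window of every larger size, reports its accuracy next to the
    max and mean accuracy of the smallest-size windows it contains — the
    diagnostic for whether enlarging a window converges to the best or the
    worst constituent rate.
    """
    sizes = tuple(sizes)
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    split_spec = split_spec or SplitSpec()
    results = {
        w: classifier_window_scan(
            gm, labels, w, method=method, train_config=train_config, C=C,
            split_spec=split_spec,
        )
        for w in sizes
    }
    base = results[sizes[0]]
    comparisons: list[ConvergenceComparison] = []
    for w in sizes[1:]:
        res = results[w]
        for k in range(len(res.starts)):
            inside = (base.starts >= res.starts[k]) & (base.stops <= res.stops[k])
            if not inside.any():
                continue
            accs = base.mean_accuracy[inside]
            best = int(np.argmax(accs))
            comparisons.append(
                ConvergenceComparison(
                    size=w,
                    start=int(res.starts[k]),
                    stop=int(res.stops[k]),
                    accuracy=float(res.mean_accuracy[k]),
                    sigma=float(res.sigma[k]),
                    best_constituent_accuracy=float(accs[best]),
                    best_constituent_sigma=float(base.sigma[inside][best]),
                    mean_constituent_accuracy=float(accs.mean()),
                )
            )
    return results, comparisons


@dataclass
class NullSplitReport:
    """Homogeneity check of one population under a random split."""

    labels: LabelSet
    pca_records: list[PcaWindowRecord]
    scan: WindowScanResult
    flagged_accuracy_windows: list[int]
    flagged_pca_windows: list[int]
    alpha: float
    bonferroni_level: float


def null_split_test(
    gm: GenotypeMatrix,
    n_a: int,
    n_b: int,
    window_size: int = 50,
    k_axes: int = 10,
    method: str = "ann",
    train_config: TrainConfig | None = None,
    C: float = 1.0,
    split_spec: SplitSpec | None = None,
    alpha: float = 0.01,
    seed: int = 0,
) -> NullSplitReport:
    """Split one population into two random subsets and run both arms.

    Flags any window whose hold-out accuracy exceeds 50 by more than 3 sigma
    (ensemble spread) or whose structure-test p-value falls below the
    Bonferroni-corrected ``alpha`` — either indicates the 'homogeneous'
    population is not."""
    rng = np.random.default_rng(seed)
    labels = split_null(gm, n_a, n_b, rng)
    pca_records = pca_window_scan(gm, labels, window_size, k_axes=k_axes)
    scan = classifier_window_scan(
        gm, labels, window_size, method=method, train_config=train_config, C=C,
        split_spec=split_spec or SplitSpec(seed=seed),
    )
    n_windows = len(pca_records)
    level = alpha / max(n_windows, 1)
    flagged_acc = [
        k
        for k in range(len(scan.starts))
        if scan.mean_accuracy[k] - 50.0 > 3.0 * scan.sigma[k]
    ]
    flagged_pca = [
        k
        for k, rec in enumerate(pca_records)
        if rec.test is not None and rec.test.p_value < level
    ]
    return NullSplitReport(
        labels=labels,
        pca_records=pca_records,
        scan=scan,
        flagged_accuracy_windows=flagged_acc,
        flagged_pca_windows=flagged_pca,
        alpha=alpha,
        bonferroni_level=level,
    )
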