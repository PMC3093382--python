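"""Unsupervised population-structure detection: PCA, F_ST, BBP threshold.

The pipeline mirrors the standard eigenanalysis workflow for SNP data:

* per-SNP normalization with a shrunk allele-frequency estimate
  ``p = (1 + sum d) / (2 + 2 n_called)`` and scaling by ``sqrt(p (1 - p))``;
* PCA via eigendecomposition of the M x M sample covariance;
* the Hudson/Reich ratio-of-sums F_ST estimator (biased low in finite
  samples and allowed to go negative) with a delete-one-SNP jackknife SE;
* the spiked-eigenvalue (BBP) critical divergence ``F_crit = 1/sqrt(N M)``
  below which PCA cannot detect two equal-size populations;
* a structure test summing per-axis one-way ANOVA F statistics between the
  two labelled groups, referred to a chi-square with one degree of freedom
  per axis.

A sliding non-overlapping window scan stitches these into per-window records
comparing the estimated F_ST against the window's critical value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .genotypes import MISSING, GenotypeMatrix, LabelSet, subset_window, window_ranges

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationStats",
    "PCAResult",
    "FstEstimate",
    "StructureTest",
    "PcaWindowRecord",
    "fit_normalizer",
    "apply_normalizer",
    "normalize",
    "run_pca",
    "fst_hudson",
    "fst_critical",
    "anova_structure_test",
    "pca_window_scan",
]


@dataclass
class NormalizationStats:
    """Frozen per-SNP statistics so hold-out data can be normalized with
    training-set frequencies (no leakage)."""

    p_hat: np.ndarray  # shrunk frequency per kept SNP
    keep: np.ndarray  # boolean mask over the original SNP axis


def fit_normalizer(gm: GenotypeMatrix, shrinkage: bool = True) -> NormalizationStats:
    """Estimate per-SNP frequencies and the kept-SNP mask.

    With ``shrinkage`` (default) the frequency is ``(1 + sum d)/(2 + 2 n)``,
    never exactly 0 or 1; otherwise the plain MLE ``sum d / (2 n)`` is used.
    Monomorphic SNPs — only one allele observed (all non-missing dosages 0,
    or all 2) — are dropped with a log notice.
    """
    if gm.n_snps == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    d = gm.dosages
    miss = d == MISSING
    n_called = (~miss).sum(axis=0)
    if (n_called == 0).any():
        j = int(np.argmax(n_called == 0))
        raise ValueError(f"SNP {gm.snps[j].snp_id}: no non-missing calls")
    counts = np.where(miss, 0, d).sum(axis=0)
    keep = ~((counts == 0) | (counts == 2 * n_called))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("normalize: dropped %d monomorphic SNP(s)", n_dropped)
    if shrinkage:
        p_hat = (1.0 + counts[keep]) / (2.0 + 2.0 * n_called[keep])
    else:
        p_hat = counts[keep] / (2.0 * n_called[keep])
    return NormalizationStats(p_hat=p_hat, keep=keep)


def apply_normalizer(gm: GenotypeMatrix, stats_: NormalizationStats) -> np.ndarray:
    """Centered, variance-scaled real matrix; missing entries become 0
    (the column mean) after centering."""
    d = gm.dosages[:, stats_.keep].astype(float)
    miss = gm.dosages[:, stats_.keep] == MISSING
    p = stats_.p_hat
    x = (d - 2.0 * p[None, :]) / np.sqrt(p * (1.0 - p))[None, :]
    x[miss] = 0.0
    return x


def normalize(gm: GenotypeMatrix, shrinkage: bool = True) -> np.ndarray:
    """Fit-and-apply normalization on one matrix (the common PCA entry)."""
    return apply_normalizer(gm, fit_normalizer(gm, shrinkage=shrinkage))


@dataclass
class PCAResult:
    """Top-k eigenpairs of the sample covariance of normalized genotypes.

    ``projections`` are sample scores (left singular vectors scaled by the
    singular values); columns are mutually orthogonal.
    """

    eigenvalues: np.ndarray  # (k,), non-increasing
    projections: np.ndarray  # (M, k)
    n_axes: int
    sample_ids: list[str] | None = None


def run_pca(norm_matrix: np.ndarray, k: int) -> PCAResult:
    """Eigendecomposition of ``C = X X^T / N`` for normalized rows ``X``.

    Signs are fixed so each axis's largest-magnitude loading is positive,
    making results deterministic across LAPACK backends.
    """
    x = np.asarray(norm_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("normalized matrix must be 2-dimensional")
    m, n = x.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} out of range for a {m}x{n} matrix")
    if not np.isfinite(x).all():
        raise ValueError("normalized matrix contains non-finite entries")
    cov = x @ x.T / n
    evals, evecs = linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip[None, :]
    projections = evecs * np.sqrt(evals * n)[None, :]
    return PCAResult(eigenvalues=evals, projections=projections, n_axes=k)


@dataclass
class FstEstimate:
    """Ratio-of-sums F_ST estimate with a delete-one-SNP jackknife SE."""

    fst_hat: float
    se: float
    n_snps_used: int
    n1: int
    n2: int


def _hudson_terms(
    gm: GenotypeMatrix, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP numerator/denominator of the Hudson/Reich estimator plus the
    usable-SNP mask (both classes >= 2 called individuals, denominator > 0)."""
    d = gm.dosages
    miss = d == MISSING
    out_n = []
    out_d = []
    for g in (0, 1):
        rows = y == g
        dg = d[rows]
        mg = miss[rows]
        called = (~mg).sum(axis=0)
        alleles = 2.0 * called
        count = np.where(mg, 0, dg).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(alleles > 0, count / alleles, np.nan)
            corr = np.where(alleles > 1, p * (1.0 - p) / (alleles - 1.0), np.nan)
        out_n.append((p, corr, called))
        out_d.append(p)
    (p1, c1, called1), (p2, c2, called2) = out_n
    num = (p1 - p2) ** 2 - c1 - c2
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    usable = (called1 >= 2) & (called2 >= 2) & np.isfinite(num) & (den > 0)
    return num, den, usable


def fst_hudson(gm: GenotypeMatrix, labels: LabelSet) -> FstEstimate:
    """Hudson/Reich ratio-of-sums F_ST between the two labelled groups.

    Per SNP, with sample allele frequencies ``p1, p2`` over ``n`` called
    allele copies per group::

        num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    and the estimate is ``sum(num) / sum(den)`` over usable SNPs (``den > 0``,
    both groups with >= 2 called individuals).  The numerator's variance
    corrections make the estimator unbiased-in-numerator, so it can be
    negative in finite samples.
    """
    labels.validate_against(gm)
    y = labels.y_for(gm)
    n1_ind = int((y == 0).sum())
    n2_ind = int((y == 1).sum())
    num, den, usable = _hudson_terms(gm, y)
    if not usable.any():
        raise ValueError("no usable SNPs for F_ST estimation after filtering")
    ns, ds = num[usable], den[usable]
    total_n, total_d = ns.sum(), ds.sum()
    fst_hat = float(total_n / total_d)
    j = ns.size
    if j > 1:
        loo = (total_n - ns) / (total_d - ds)
        se = float(np.sqrt((j - 1) / j * ((loo - loo.mean()) ** 2).sum()))
    else:
        se = 0.0
    return FstEstimate(fst_hat=fst_hat, se=se, n_snps_used=j, n1=n1_ind, n2=n2_ind)


def fst_critical(n_snps: int, n_individuals: int) -> float:
    """BBP critical divergence ``1 / sqrt(N M)`` for two equal-size
    populations: below it, PCA carries no detectable structure."""
    if n_snps < 1 or n_individuals < 2:
        raise ValueError("need n_snps >= 1 and n_individuals >= 2")
    return 1.0 / math.sqrt(n_snps * n_individuals)


@dataclass
class StructureTest:
    """Per-axis ANOVA F statistics and the global chi-square summary."""

    axis_stats: np.ndarray  # (k,)
    global_stat: float
    dof: int
    p_value: float


def _two_group_f(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F between two groups, per column of ``values``.

    Degenerate columns (zero between-group sum of squares) give F = 0; zero
    within-group variance with real separation gives +inf.
    """
    a = values[y == 0]
    b = values[y == 1]
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each class needs >= 2 members for the ANOVA")
    grand = values[y >= 0].mean(axis=0)
    ssb = na * (a.mean(axis=0) - grand) ** 2 + nb * (b.mean(axis=0) - grand) ** 2
    ssw = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    dfw = na + nb - 2
    f = np.zeros_like(ssb)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ssb > 0, ssb / np.where(ssw > 0, ssw / dfw, np.nan), 0.0)
    f = np.where((ssb > 0) & (ssw == 0), np.inf, f)
    return f


def anova_structure_test(
    pca: PCAResult, labels: LabelSet, k_axes: int | None = None, gm: GenotypeMatrix | None = None
) -> StructureTest:
    """Between-group ANOVA along principal axes, summed into a global
    chi-square statistic with one degree of freedom per axis.

    ``pca.sample_ids`` (or an explicit ``gm``) provides the row ordering used
    to align labels with projections.
    """
    sample_ids = pca.sample_ids if pca.sample_ids is not None else (
        gm.sample_ids if gm is not None else None
    )
    if sample_ids is None:
        raise ValueError("PCAResult lacks sample_ids; pass the genotype matrix")
    k = pca.n_axes if k_axes is None else k_axes
    if not 1 <= k <= pca.n_axes:
        raise ValueError(f"k_axes={k} out of range (have {pca.n_axes})")
    y = np.array([labels.labels.get(s, -1) for s in sample_ids])
    proj = pca.projections[y >= 0, :k]
    yy = y[y >= 0]
    axis_f = _two_group_f(proj, yy)
    global_stat = float(axis_f.sum())
    p_value = float(stats.chi2.sf(global_stat, df=k))
    return StructureTest(axis_stats=axis_f, global_stat=global_stat, dof=k, p_value=p_value)


@dataclass
class PcaWindowRecord:
    """One window of the unsupervised scan."""

    start: int
    stop: int
    fst: FstEstimate | None
    fst_crit: float
    test: StructureTest | None
    degenerate: bool = False


def pca_window_scan(
    gm: GenotypeMatrix,
    labels: LabelSet,
    window_size: int,
    k_axes: int = 10,
) -> list[PcaWindowRecord]:
    """Non-overlapping window scan: normalize -> PCA -> F_ST -> structure test.

    Only labelled samples enter the scan.  Windows in which every SNP is
    monomorphic in the pooled sample yield a flagged degenerate record.
    """
    labels.validate_against(gm)
    y_all = labels.y_for(gm)
    rows = np.flatnonzero(y_all >= 0)
    sub = GenotypeMatrix(
        [gm.sample_ids[i] for i in rows], list(gm.snps), gm.dosages[rows, :]
    )
    m = sub.n_samples
    records: list[PcaWindowRecord] = []
    for start, stop in window_ranges(gm.n_snps, window_size):
        crit = fst_critical(window_size, m)
        win = subset_window(sub, start, stop - start)
        norm_stats = fit_normalizer(win)
        if not norm_stats.keep.any():
            records.append(
                PcaWindowRecord(start, stop, None, crit, None, degenerate=True)
            )
            continue
        try:
            x = apply_normalizer(win, norm_stats)
            k = min(k_axes, m - 1, x.shape[1])
            pca = run_pca(x, k)
            pca.sample_ids = sub.sample_ids
            fst = fst_hudson(win, labels)
            test = anova_structure_test(pca, labels, k)
        except ValueError as exc:
            raise ValueError(f"window [{start}, {stop}): {exc}") from exc
        records.append(PcaWindowRecord(start, stop, fst, crit, test))
    return records
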