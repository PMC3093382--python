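"""PCA, the Hudson/Reich F_ST estimator, BBP threshold and structure test."""

import numpy as np
import pytest
from scipy import stats

from popsep.genotypes import MISSING, GenotypeMatrix, LabelSet
from popsep.simulate import SimSpec, BlockSpec, simulate_blocks, simulate_pair
from popsep.structure import (
    anova_structure_test,
    apply_normalizer,
    fit_normalizer,
    fst_critical,
    fst_hudson,
    normalize,
    pca_window_scan,
    run_pca,
)

from .conftest import make_matrix, two_class_labels


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_normalize_all_heterozygous_column_retained():
    """Shrunk frequency (1+4)/(2+8)=0.5 centers an all-het column to zeros;
    both alleles are observed, so the column is kept."""
    gm = make_matrix([[1], [1], [1], [1]])
    x = normalize(gm)
    assert x.shape == (4, 1)
    assert np.allclose(x, 0.0)


def test_normalize_drops_fixed_columns():
    gm = make_matrix([[0, 1, 2], [0, 0, 2], [0, 1, 2]])
    stats_ = fit_normalizer(gm)
    assert list(stats_.keep) == [False, True, False]
    x = apply_normalizer(gm, stats_)
    assert x.shape == (3, 1)


def test_normalize_centers_and_missing_to_zero():
    gm = make_matrix([[0, 2], [2, 0], [1, 1], [1, MISSING]])
    x = normalize(gm)
    # no-missing column approximately centered (shrinkage keeps it near 0)
    assert abs(x[:, 0].mean()) < 0.15
    assert x[3, 1] == 0.0  # missing -> column mean after centering


def test_normalize_row_permutation_equivariance(rng):
    gm, _ = simulate_pair(SimSpec(fst=0.02, n_snps=30, n_per_pop=(5, 5), seed=2))
    x = normalize(gm)
    perm = rng.permutation(gm.n_samples)
    gm_p = GenotypeMatrix(
        [gm.sample_ids[i] for i in perm], gm.snps, gm.dosages[perm]
    )
    assert np.allclose(normalize(gm_p), x[perm])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_run_pca_matches_svd_oracle(rng):
    """Eigenpairs of X X^T / N agree with an independent SVD route."""
    x = rng.normal(size=(20, 50))
    res = run_pca(x, 10)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    assert np.allclose(res.eigenvalues, (s**2 / 50)[:10], atol=1e-8)
    scores = u * s
    for k in range(10):
        dot = res.projections[:, k] @ scores[:, k]
        assert abs(abs(dot) - scores[:, k] @ scores[:, k]) < 1e-6  # same axis up to sign
    # orthogonality of projections
    g = res.projections.T @ res.projections
    assert np.allclose(g - np.diag(np.diag(g)), 0.0, atol=1e-8)


def test_run_pca_rank_one_and_trace(rng):
    x = np.outer(rng.normal(size=8), rng.normal(size=30))
    res = run_pca(x, 8)
    assert res.eigenvalues[0] > 0
    assert np.allclose(res.eigenvalues[1:], 0.0, atol=1e-10)
    assert res.eigenvalues.sum() == pytest.approx(np.trace(x @ x.T / 30))
    with pytest.raises(ValueError):
        run_pca(x, 31)


# ---------------------------------------------------------------------------
# F_ST estimator
# ---------------------------------------------------------------------------

def test_fst_fixed_difference_is_one():
    gm = make_matrix([[2], [2], [0], [0]])
    lab = two_class_labels(gm, 2)
    est = fst_hudson(gm, lab)
    assert est.fst_hat == pytest.approx(1.0)


def test_fst_symmetric_heterozygotes_negative_third():
    """p1 = p2 = 0.5 with n = 4 allele copies per group: num = -1/6,
    den = 1/2, ratio exactly -1/3 (the estimator may go negative)."""
    gm = make_matrix([[1], [1], [1], [1]])
    lab = two_class_labels(gm, 2)
    est = fst_hudson(gm, lab)
    assert est.fst_hat == pytest.approx(-1.0 / 3.0)


def _fst_bruteforce(gm, lab):
    """Independent per-SNP re-implementation (explicit loops)."""
    y = lab.y_for(gm)
    num_sum = den_sum = 0.0
    used = 0
    for j in range(gm.n_snps):
        terms = {}
        ok = True
        for g in (0, 1):
            vals = [
                int(gm.dosages[i, j])
                for i in range(gm.n_samples)
                if y[i] == g and gm.dosages[i, j] != MISSING
            ]
            if len(vals) < 2:
                ok = False
                break
            n = 2 * len(vals)
            p = sum(vals) / n
            terms[g] = (p, p * (1 - p) / (n - 1))
        if not ok:
            continue
        (p1, c1), (p2, c2) = terms[0], terms[1]
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den <= 0:
            continue
        num_sum += (p1 - p2) ** 2 - c1 - c2
        den_sum += den
        used += 1
    return num_sum / den_sum, used


def test_fst_matches_bruteforce_oracle():
    rng = np.random.default_rng(99)
    for trial in range(50):
        m = int(rng.integers(6, 16))
        n = int(rng.integers(3, 12))
        n0 = int(rng.integers(2, m - 1))
        d = rng.integers(0, 3, size=(m, n)).astype(np.int8)
        miss = rng.random(size=d.shape) < 0.1
        d[miss] = MISSING
        gm = make_matrix(d)
        lab = two_class_labels(gm, n0)
        try:
            est = fst_hudson(gm, lab)
        except ValueError:
            continue  # no usable SNPs in this draw
        oracle, used = _fst_bruteforce(gm, lab)
        assert est.n_snps_used == used
        assert est.fst_hat == pytest.approx(oracle, abs=1e-12)


def test_fst_null_distribution_and_sign():
    """Under the null the estimator is centered at ~0 with frequent negative
    draws (the numerator is unbiased for zero; only a tiny ratio bias
    remains), never exceeding 1."""
    vals = []
    for s in range(200):
        gm, lab = simulate_pair(SimSpec(fst=0.0, n_snps=50, n_per_pop=(20, 20), seed=7000 + s))
        vals.append(fst_hudson(gm, lab).fst_hat)
    vals = np.array(vals)
    assert (vals < 0).mean() > 0.3  # negativity is common, not exotic
    assert abs(vals.mean()) < 4 * vals.std() / np.sqrt(vals.size)
    assert (vals <= 1).all()


def test_fst_jackknife_se_tracks_replicate_spread():
    """Delete-one-SNP jackknife SE approximates the across-replicate sd."""
    ests = [
        fst_hudson(*simulate_pair(SimSpec(fst=0.01, n_snps=1000, n_per_pop=(100, 100), seed=s)))
        for s in range(12)
    ]
    ses = np.array([e.se for e in ests])
    spread = np.std([e.fst_hat for e in ests], ddof=1)
    assert 0.3 * spread < ses.mean() < 3 * spread


# ---------------------------------------------------------------------------
# Critical threshold
# ---------------------------------------------------------------------------

def test_fst_critical_values():
    assert fst_critical(500, 400) == pytest.approx(2.236e-3, rel=1e-3)
    assert fst_critical(5739, 400) == pytest.approx(6.60e-4, rel=1e-2)
    # inverse-square-root scaling: quadrupling N halves the threshold
    assert fst_critical(2000, 400) == pytest.approx(fst_critical(500, 400) / 2)
    with pytest.raises(ValueError):
        fst_critical(0, 400)


# ---------------------------------------------------------------------------
# ANOVA structure test
# ---------------------------------------------------------------------------

def test_anova_matches_textbook_oracle():
    """Per-axis F equals a one-way ANOVA on a small printed table."""
    proj = np.array([[1.0], [2.0], [3.0], [6.0], [7.0], [8.0]])
    from popsep.structure import PCAResult

    pca = PCAResult(
        eigenvalues=np.array([1.0]),
        projections=proj,
        n_axes=1,
        sample_ids=[f"s{i}" for i in range(6)],
    )
    lab = LabelSet({f"s{i}": int(i >= 3) for i in range(6)})
    res = anova_structure_test(pca, lab, 1)
    f_scipy, _ = stats.f_oneway(proj[:3, 0], proj[3:, 0])
    assert res.axis_stats[0] == pytest.approx(f_scipy)
    assert res.global_stat == pytest.approx(res.axis_stats.sum())
    assert res.dof == 1
    assert res.p_value == pytest.approx(float(stats.chi2.sf(f_scipy, 1)))


def test_anova_identical_groups_give_zero():
    proj = np.tile(np.array([[1.0, -2.0]]), (6, 1))
    from popsep.structure import PCAResult

    pca = PCAResult(np.array([1.0, 0.5]), proj, 2, [f"s{i}" for i in range(6)])
    lab = LabelSet({f"s{i}": int(i % 2) for i in range(6)})
    res = anova_structure_test(pca, lab, 2)
    assert np.allclose(res.axis_stats, 0.0)
    assert res.p_value == pytest.approx(1.0)


def test_anova_null_pvalues_roughly_uniform():
    """Exact-null global p-values pass a KS sanity bound (chi-square
    reference is asymptotic, so only approximate uniformity is claimed)."""
    ps = []
    for s in range(200):
        gm, lab = simulate_pair(SimSpec(fst=0.0, n_snps=60, n_per_pop=(20, 20), seed=5000 + s))
        x = normalize(gm)
        pca = run_pca(x, 5)
        pca.sample_ids = gm.sample_ids
        ps.append(anova_structure_test(pca, lab, 5).p_value)
    stat, _ = stats.kstest(ps, "uniform")
    assert stat < 1.63 / np.sqrt(len(ps))  # KS 1% critical value
    assert all(0.0 <= p <= 1.0 for p in ps)


# ---------------------------------------------------------------------------
# Window scan
# ---------------------------------------------------------------------------

def test_pca_window_scan_null_windows_mostly_subcritical():
    gm, lab = simulate_pair(SimSpec(fst=0.0, n_snps=500, n_per_pop=(200, 200), seed=21))
    recs = pca_window_scan(gm, lab, 50)
    assert len(recs) == 10
    fsts = np.array([r.fst.fst_hat for r in recs])
    crit = recs[0].fst_crit
    assert (fsts < crit).sum() >= 8  # F-hat fluctuates ~crit/1.4 under null
    assert np.abs(fsts).mean() < crit


def test_pca_window_scan_localises_divergent_block():
    bs = BlockSpec(blocks=[(50, 0.05), (450, 0.0)], n_per_pop=(200, 200), seed=6)
    gm, lab = simulate_blocks(bs)
    recs = pca_window_scan(gm, lab, 50)
    assert recs[0].fst.fst_hat > recs[0].fst_crit
    assert recs[0].test.p_value < 1e-6
    others = [r.fst.fst_hat for r in recs[1:]]
    assert max(others) < recs[0].fst.fst_hat / 5


def test_pca_window_scan_counts_and_coordinates():
    gm, lab = simulate_pair(SimSpec(fst=0.01, n_snps=230, n_per_pop=(20, 20), seed=1))
    recs = pca_window_scan(gm, lab, 100, k_axes=5)
    assert [(r.start, r.stop) for r in recs] == [(0, 100), (100, 200)]
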