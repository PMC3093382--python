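"""Two-population genotype simulation under the Balding-Nichols model.

The simulator stands in for real cohort pairs: each SNP draws an ancestral
frequency ``p`` uniformly from a stated interval, then per-population
frequencies from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` whose mean is ``p`` and
variance ``F p(1-p)`` — so the divergence parameter ``F`` is the expected
F_ST between the populations.  Genotypes are independent Binomial(2, p_pop)
draws (unlinked SNPs, mirroring LD-pruned panels).  ``F = 0`` is handled
exactly (both populations share the ancestral frequency), so null datasets
carry no between-population structure by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, LabelSet, SNPRecord

__all__ = [
    "SimSpec",
    "BlockSpec",
    "draw_population_freqs",
    "simulate_pair",
    "simulate_blocks",
    "split_null",
]


@dataclass
class SimSpec:
    """Parameters of one two-population dataset.

    fst: target divergence (0 <= fst < 1); n_snps: number of unlinked SNPs;
    n_per_pop: individuals per population; ancestral_freq_range: support of
    the uniform ancestral-frequency draw; maf_floor: SNPs with pooled
    empirical minor-allele frequency below this are redrawn; seed: RNG seed.
    """

    fst: float
    n_snps: int
    n_per_pop: tuple[int, int] = (200, 200)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    maf_floor: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"ancestral_freq_range must be ordered within (0,1), got {self.ancestral_freq_range}")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        n1, n2 = self.n_per_pop
        if n1 < 2 or n2 < 2:
            raise ValueError("need >= 2 individuals per population")


@dataclass
class BlockSpec:
    """Concatenation of SNP blocks with per-block divergence, over one shared
    pair of populations (e.g. one divergent region embedded in a null
    background)."""

    blocks: list[tuple[int, float]]
    n_per_pop: tuple[int, int] = (200, 200)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    maf_floor: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("block list must be non-empty")
        for k, (n, f) in enumerate(self.blocks):
            if n < 1:
                raise ValueError(f"block {k}: n_snps must be >= 1")
            if not 0.0 <= f < 1.0:
                raise ValueError(f"block {k}: fst must be in [0, 1)")


def draw_population_freqs(
    p_anc: float | np.ndarray, fst: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-population allele frequencies for one (or a vector of) SNP(s).

    ``fst = 0`` short-circuits to the ancestral frequency exactly; otherwise
    two independent Beta draws with mean ``p_anc`` and variance
    ``fst * p_anc * (1 - p_anc)``.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError(f"fst must be in [0, 1), got {fst}")
    p = np.asarray(p_anc, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("p_anc must lie strictly within (0, 1)")
    if fst == 0.0:
        return p.copy(), p.copy()
    scale = (1.0 - fst) / fst
    a, b = p * scale, (1.0 - p) * scale
    eps = 1e-12
    p1 = np.clip(rng.beta(a, b), eps, 1.0 - eps)
    p2 = np.clip(rng.beta(a, b), eps, 1.0 - eps)
    return p1, p2


def _draw_block(
    rng: np.random.Generator,
    n_snps: int,
    fst: float,
    n1: int,
    n2: int,
    freq_range: tuple[float, float],
    maf_floor: float,
) -> np.ndarray:
    """Dosage block (n1+n2 x n_snps); SNPs failing the MAF floor are redrawn."""
    m = n1 + n2
    out = np.empty((m, n_snps), dtype=np.int8)
    todo = np.arange(n_snps)
    lo, hi = freq_range
    for _ in range(1000):
        k = todo.size
        if k == 0:
            return out
        p_anc = rng.uniform(lo, hi, size=k)
        p1, p2 = draw_population_freqs(p_anc, fst, rng)
        g = np.empty((m, k), dtype=np.int8)
        g[:n1] = rng.binomial(2, p1, size=(n1, k))
        g[n1:] = rng.binomial(2, p2, size=(n2, k))
        pooled = g.sum(axis=0) / (2.0 * m)
        ok = np.minimum(pooled, 1.0 - pooled) >= maf_floor
        out[:, todo[ok]] = g[:, ok]
        todo = todo[~ok]
    raise RuntimeError(
        f"MAF floor {maf_floor} not met for {todo.size} SNPs after 1000 redraw rounds"
    )


def _make_matrix(dosages: np.ndarray, n1: int, n2: int) -> tuple[GenotypeMatrix, LabelSet]:
    m, n = dosages.shape
    sample_ids = [f"P1_{i + 1:04d}" for i in range(n1)] + [
        f"P2_{i + 1:04d}" for i in range(n2)
    ]
    snps = [
        SNPRecord(f"snp{j + 1:06d}", "1", j + 1, allele_a="A", allele_b="B")
        for j in range(n)
    ]
    labels = LabelSet(
        {sid: (0 if i < n1 else 1) for i, sid in enumerate(sample_ids)},
        class_names=("pop1", "pop2"),
    )
    return GenotypeMatrix(sample_ids, snps, dosages), labels


def simulate_pair(spec: SimSpec) -> tuple[GenotypeMatrix, LabelSet]:
    """Simulate two labelled populations at divergence ``spec.fst``.

    Deterministic given ``spec.seed``; no missing data is generated.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_pop
    dosages = _draw_block(
        rng, spec.n_snps, spec.fst, n1, n2, spec.ancestral_freq_range, spec.maf_floor
    )
    return _make_matrix(dosages, n1, n2)


def simulate_blocks(blocks: BlockSpec) -> tuple[GenotypeMatrix, LabelSet]:
    """Concatenate per-block simulations over the same individuals.

    Block ``k`` uses seed ``blocks.seed + k``, so a single block reproduces
    :func:`simulate_pair` with the same parameters and seed exactly.  SNP ids
    and positions are assigned consecutively across the concatenation.
    """
    blocks.validate()
    n1, n2 = blocks.n_per_pop
    parts = []
    for k, (n_snps, fst) in enumerate(blocks.blocks):
        rng = np.random.default_rng(blocks.seed + k)
        parts.append(
            _draw_block(
                rng, n_snps, fst, n1, n2, blocks.ancestral_freq_range, blocks.maf_floor
            )
        )
    return _make_matrix(np.concatenate(parts, axis=1), n1, n2)


def split_null(
    gm: GenotypeMatrix, n_a: int, n_b: int, rng: np.random.Generator
) -> LabelSet:
    """Random disjoint two-subset labelling of one population (null split).

    Draws ``n_a + n_b`` samples uniformly without replacement; the first
    ``n_a`` form class 0.  Remaining samples stay unlabelled.
    """
    if n_a + n_b > gm.n_samples:
        raise ValueError(
            f"n_a + n_b = {n_a + n_b} exceeds number of samples {gm.n_samples}"
        )
    chosen = rng.choice(gm.n_samples, size=n_a + n_b, replace=False)
    labels = {gm.sample_ids[i]: 0 for i in chosen[:n_a]}
    labels.update({gm.sample_ids[i]: 1 for i in chosen[n_a:]})
    return LabelSet(labels, class_names=("splitA", "splitB"))
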