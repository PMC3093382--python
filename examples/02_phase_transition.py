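"""The BBP phase transition seen through the structure test.

For 500 SNPs and 400 individuals the critical divergence is
F_crit = 1/sqrt(500*400) ~ 0.00224.  Simulating pairs at a grid of
divergences around it shows the global ANOVA p-value collapsing by many
orders of magnitude once F_ST crosses the threshold, while the estimated
F_ST tracks the target throughout.
"""

import numpy as np

from popsep import SimSpec, anova_structure_test, fst_critical, fst_hudson, normalize, run_pca, simulate_pair

N, (n1, n2) = 500, (200, 200)
crit = fst_critical(N, n1 + n2)
print(f"F_crit = {crit:.5f}\n")
print(f"{'F_target/F_crit':>16} {'fst_hat':>10} {'p_value':>12}")
for mult in (0.2, 0.5, 1.0, 2.0, 5.0):
    gm, labels = simulate_pair(SimSpec(fst=mult * crit, n_snps=N, n_per_pop=(n1, n2), seed=7))
    x = normalize(gm)
    pca = run_pca(x, 10)
    pca.sample_ids = gm.sample_ids
    test = anova_structure_test(pca, labels)
    est = fst_hudson(gm, labels)
    print(f"{mult:>16.1f} {est.fst_hat:>10.5f} {test.p_value:>12.3g}")
# Expect p-values of order 0.01-1 below the threshold and a collapse towards
# zero (p << 1e-6) by the time F_ST reaches a few times F_crit.
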