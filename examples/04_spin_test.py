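"""Spin-permutation test of association between two cortical-like maps.

Two spatially smooth fields are generated independently on an icosphere
(a stand-in for a spherical cortical registration). A naive permutation
test would reject independence far too often because smooth maps have
few effective degrees of freedom; the spin test preserves the spatial
structure in its null and stays calibrated.
"""

import numpy as np
from scipy.stats import spearmanr

import gradmap as gm

sphere = gm.make_icosphere(subdivisions=3)  # 642 vertices
map_a = gm.smooth_field(sphere, n_smooth=10, seed=1)
map_b = gm.smooth_field(sphere, n_smooth=10, seed=2)

observed = spearmanr(map_a.values, map_b.values).statistic
print(f"observed Spearman rho between the two maps: {observed:+.4f}")

ens = gm.spin_permutation(map_a, sphere, n_perm=1000, rng=42)
nulls = np.array([spearmanr(z, map_b.values).statistic for z in ens])
p = gm.empirical_pvalue(observed, nulls, tail="two")
print(f"spin-null two-tailed p = {p:.4f}  (n_perm = {ens.n_perm})")
# the two maps are independent by construction, so p is typically
# unremarkable; naive i.i.d. permutations would often report p < 0.001
# for the same |rho| because they ignore spatial autocorrelation.
print(f"null sd of rho under spins: {nulls.std():.4f} "
      "(vs ~0.04 under naive permutation)")
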