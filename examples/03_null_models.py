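"""Benchmark an observed network against the three null models.

A strongly modular toy network is compared with fixed-marginal
(Patefield), connectance-preserving abundance-weighted (Vazquez) and
weight-shuffling nulls. Specialization collapses under the first two;
Shannon diversity is untouched by the shuffle null, which only moves the
existing weights around.
"""

import numpy as np

from woodweb import InteractionMatrix, h2prime, null_ensemble, shannon_entries

rng = np.random.default_rng(0)
W = np.kron(np.eye(4), np.ones((1, 3))) * 15 + (rng.random((4, 12)) < 0.4)
M = InteractionMatrix(W)

print(f"observed: H2' = {h2prime(M):.3f}, Shannon = {shannon_entries(M):.3f}")
for method in ("patefield", "vazquez", "shuffle"):
    ens = null_ensemble(M, method, n=50, seed=1)
    d = ens.index_distributions
    print(f"{method:9s}: H2' = {d['h2prime'].mean():.3f} "
          f"(sd {d['h2prime'].std():.3f}), "
          f"Shannon = {d['shannon'].mean():.3f} (sd {d['shannon'].std():.3f})")
print()
print("observed H2' far above the Patefield/Vazquez null distributions")
print("indicates real specialization; the shuffle Shannon sd of 0 shows why")
print("diversity indices cannot be tested against that null.")
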