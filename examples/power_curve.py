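"""How the detectable signal grows with the trait-geometry coupling beta.

For each beta the study is regenerated a few times; the mean total
co-inertia and the rejection rate of the global L-R permutation test show
the method's power rising from the null.
"""

import numpy as np

from patchtraits import SimulationConfig, generate_study, permutation_test, rlq

N_REP = 4
print(f"{'beta':>5} {'mean sum(lambda)':>17} {'global L-R p (per rep)':>30}")
for beta in (0.0, 0.5, 1.0, 2.0):
    lams, ps = [], []
    for seed in range(N_REP):
        study = generate_study(SimulationConfig(seed=seed, beta=beta))
        lams.append(rlq(study.tables).total_inertia)
        ps.append(permutation_test(study.tables, 2, n_perm=499, seed=seed).global_test.p)
    print(f"{beta:>5.1f} {np.mean(lams):>17.3f}   {np.round(ps, 3)}")

print(
    "\nsum(lambda) is the co-inertia shared by traits and spatial "
    "configuration; it should be near zero at beta=0 and grow with beta, "
    "while the permutation p-values fall toward their minimum."
)
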