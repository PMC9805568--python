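"""Heterozygote concordance versus simulated coverage.

Thins held-out targets at several coverages, imputes each against the
panel, and reports mean heterozygote concordance with and without the GP
post-imputation filter at threshold 0.8.
"""

import numpy as np

from lsimpute import (
    CheckpointPlan,
    HMMParameters,
    SimulationConfig,
    concordance,
    make_synthetic_panel,
    run_forward_backward,
    thin_genotypes,
)

data = make_synthetic_panel(20, 800, seed=6, n_targets=5)
params = HMMParameters.from_panel(data.panel)

print("coverage   het concordance   het concordance   evaluated fraction")
print("           (no filter)       (GP >= 0.8)       (GP >= 0.8)")
for c in (0.05, 0.2, 0.5, 1.0):
    raw, filt, frac = [], [], []
    for t in range(data.n_targets):
        lik = thin_genotypes(
            data.truth_genotypes[t], SimulationConfig(coverage=c, seed=100 * t + 1)
        )
        res = run_forward_backward(
            data.panel, lik, params, plan=CheckpointPlan("two_level")
        )
        truth = data.truth_genotypes[t]
        raw.append(concordance(res.gp, truth, het_only=True, threshold=0.0).concordance)
        rep = concordance(res.gp, truth, het_only=True, threshold=0.8)
        filt.append(rep.concordance)
        frac.append(rep.evaluated_fraction)
    print(f"  {c:4.2f}       {np.mean(raw):.3f}             {np.mean(filt):.3f}"
          f"             {np.mean(frac):.3f}")
print()
print("concordance rises with coverage. At moderate-to-high coverage the GP")
print("filter trades evaluated sites for accuracy; at very low coverage few")
print("truth-heterozygous sites reach GP 0.8 at all, and the ones that do")
print("are dominated by confident (wrong) homozygous calls - the reason")
print("filtered and unfiltered concordance are both reported.")
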