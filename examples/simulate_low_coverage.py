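"""Thin truth genotypes into single-read genotype likelihoods.

Shows the read-sampling law (P(alt read) = delta, 0.5, 1-delta for the
three genotypes) and the GATK-style single-read likelihood triplets,
including the literal 0.3333 uniform triplet at unsampled sites.
"""

import numpy as np

from lsimpute import SimulationConfig, thin_genotypes
from lsimpute.simulate import read_likelihoods

delta = 0.03
print(f"single-read likelihood triplets at delta={delta}:")
print(f"  ref read sampled: {read_likelihoods(0, delta)}")
print(f"  alt read sampled: {read_likelihoods(1, delta)}")
print(f"  no read:          {read_likelihoods(None, delta)}")
print()

rng = np.random.default_rng(0)
truth = rng.integers(0, 3, size=20_000)
config = SimulationConfig(coverage=0.3, delta=0.001, seed=42)
lik = thin_genotypes(truth, config)
print(f"thinned {truth.size} sites at target coverage {config.coverage}:")
print(f"  observed fraction: {lik.observed.mean():.4f} (expected ~{config.p})")
for g, label in enumerate(("hom-ref", "het", "hom-alt")):
    sel = lik.observed & (truth == g)
    alt = (lik.likelihoods[sel, 2] > lik.likelihoods[sel, 0]).mean()
    print(f"  alt-read fraction given {label:8s}: {alt:.4f}")
print()
print("the alt-read fractions follow the sampling law delta / 0.5 / 1-delta;")
print("unobserved rows carry the uniform 0.3333 triplet.")
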