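# Methods

## Model

`lsimpute` implements genotype imputation for a single diploid target
sample under the haplotype-copying (Li & Stephens) model, driven by
genotype likelihoods rather than called genotypes. Given `H` phased
reference haplotypes over `M` biallelic SNPs, the hidden state at site `j`
is an **ordered** pair `X_j = (x1, x2)` of reference-haplotype indices —
which haplotype each of the sample's two chromosomes currently copies —
for `H²` states in total. The chain starts uniform over states
(`P(X_1) = 1/H²`).

**Transitions.** Between consecutive sites each chromosome independently
either stays on its template (probability `1−θ_j`) or switches, landing on
a uniformly chosen haplotype (probability `θ_j`, including landing back on
the same one). The diploid transition therefore factorizes into two
per-chromosome factors `(1−θ) + θ/H` (same template) and `θ/H` (different),
whose products give the familiar three-regime form by switch count:

    P(X_j | X_{j−1}) = θ²/H²                                (2 switches)
                       (1−θ)θ/H + θ²/H²                     (1 switch)
                       (1−θ)² + 2(θ−θ²)/H + θ²/H²           (0 switches)

The per-interval switch probability is derived from genetic-map distance
as `θ_j = 1 − exp(−4·Ne·d_j/H)` with `d_j` in Morgans. `Ne` defaults to
11418, the HapMap-era effective-size constant used across the imputation
literature; it is a run parameter, never hard-coded in the engine. Without
a genetic map, physical distance is converted at 1 cM/Mb (the genome-wide
human average).

**Emissions.** The observed datum at site `j` is a genotype-likelihood
triplet `Y_j = (L(0), L(1), L(2))`. A 3×3 observation matrix `O[g_obs,
g_imp]` with error parameter `ε_j` relates the latent genotype to the
genotype implied by the state (the sum of the two template alleles); each
column sums to 1. Integrating the latent genotype gives the emission
weight `w(X_j) = Σ_g O[g, G(X_j)] · L_j(g)`, which depends on the state
only through its implied genotype — so emissions per site are a 3-vector
lookup, not an `H²` computation. `ε` defaults to a constant 0.01;
a per-site vector is accepted as a hook for position-dependent error
models (e.g. ancient-DNA damage), none of which is shipped. Unobserved
sites carry a uniform triplet and contribute a constant factor per site.

**Posteriors.** The forward–backward algorithm with per-site rescaling
(each vector normalized to sum 1, log normalizers accumulated into the
data log-likelihood) yields state posteriors `P(X_j | Y)`. Reported
outputs per site are

* `GP(g) = Σ_X P(X_j|Y) · O[g, G(X_j)]·L_j(g) / w(X_j)` — the posterior of
  the latent genotype given **all** data, including the local likelihood
  term (default). The panel-only predictive mixture
  `Σ_X P(X_j|Y)·O[g, G(X_j)]` is available as `gp_mode="predictive"` for
  comparison; the two differ exactly by the local data term.
* dosage `DS = GP(1) + 2·GP(2)`;
* a phased haplotype pair taken from the per-site max-posterior state
  (ties broken toward the smallest linear state index, a deterministic and
  testable rule). Per-site argmax phasing can produce switch-inconsistent
  haplotypes across sites; no joint (Viterbi) path is computed, by design.

## Collapsed propagation

The dense transition multiply is `O(H⁴)` per site. Because the transition
matrix is the Kronecker square of the per-chromosome matrix
`T = (1−θ)I + (θ/H)J`, the product collapses to two rank-one corrections:
per chromosome slot, `v' = (1−θ)·v + (θ/H)·(marginal over that slot)`,
applied to the `H×H` reshaped state vector once per slot — `O(H²)` total
and *exact* (verified against the dense multiply to 1e-12). The matrix is
symmetric, so the same operation serves the backward recursion.

## Checkpointing

Storing all `M` forward vectors costs `O(M·H²)` memory. Two checkpointed
schedules trade recomputation for memory, changing nothing in the result
(agreement verified to 1e-10, including block sizes that do not divide
`M`):

| mode      | stored vectors (peak)  | forward updates |
|-----------|------------------------|-----------------|
| full      | `M`                    | `M`             |
| one_level | `M/k₁ + k₁`            | `≈ 2M`          |
| two_level | `M/k₁ + k₁/k₂ + k₂`    | `≈ 3M`          |

Defaults `k₁ = ⌈M^(2/3)⌉`, `k₂ = ⌈M^(1/3)⌉` make two-level memory scale
with the cube root of `M`. The backward sweep regenerates forward vectors
per block from the stored checkpoints; emission weights are recomputed on
demand (they are `O(H²)` and already paid once per update). Measured at
`M = 10 000`: 2.95 updates per site for two-level, 2.00 for one-level.

Rescaling rather than log-space recursion is deliberate: the collapsed
update is a linear operation that log-space arithmetic would break; the
per-site normalization with accumulated log factors is the standard remedy
and keeps every vector in a safe floating-point range.

Degenerate inputs: a site where every state has zero emission weight is
only possible at `ε = 0` combined with contradictory one-hot likelihoods;
it raises an error naming the site. `ε = 0` itself is supported for
exactness tests but not recommended for data.

## Read-thinning simulator

The simulator emulates shallow shotgun sequencing of coverage `c ≤ 1` from
known truth genotypes: each site independently receives one read with
probability `p = c` (one read per sampled site, so the sampling
probability equals the coverage directly). The read is the alternative
allele with probability `δ`, `0.5`, `1−δ` for truth genotypes 0, 1, 2, with
`δ` the constant per-base error rate (default 0.001, Illumina-like, always
configurable). A sampled read `X` (other allele `Y`) becomes the
GATK-style single-read triplet `L(XX) = 1−δ`, `L(XY) = 0.5·δ/3 +
0.5·(1−δ)`, `L(YY) = δ/3`; unsampled sites carry the literal triplet
`(0.3333, 0.3333, 0.3333)`. In the emitted VCF the GL field is log10-scaled
as the VCF specification requires (writing linear values would corrupt
observed rows on round-trip through any compliant reader); the in-memory
matrix keeps the literal constant, and equal GL values round-trip to an
exactly uniform row — downstream inference is invariant to positive row
rescaling in any case.

A consequence worth stating: at `c = 1, δ = 0` a heterozygous site is
*not* fully informative — its single read gives `L = (1, 0.5, 0)` (or
mirrored), which favors a homozygous explanation two-fold. When the panel
contains near-duplicates of a copied haplotype, the posterior at such a
site can tip to a homozygous call even for a target that is an exact panel
pair; one such effective tie (GP 0.507 vs 0.493) appeared in ~7600
heterozygous fixture sites. Perfect concordance in this limit is a
property of one-hot likelihoods (where the local term forces the GP),
not of single-read data.

## Synthetic fixtures

`make_synthetic_panel` builds a self-contained study set: per-site allele
frequencies drawn uniformly on `[maf_floor, 1−maf_floor]`; a small founder
set (default `max(4, H/5)` haplotypes) drawn from them; panel haplotypes
as recombinant mosaics of the founders (per-interval switch probability
0.01, the same order as `θ` at the default `Ne` and site spacing of 1 kb at
1 cM/Mb); the minor-allele count is then forced up to the MAF floor
(default 0.05) at any violating site. Held-out targets are fresh mosaics
of the *panel* haplotypes — never panel members, so the evaluation is
honest out-of-panel imputation; with switch rate 0 a target degenerates to
an exact panel pair. Everything is deterministic given the seed.

What the generator does **not** emulate: realistic allele-frequency
spectra (no rare-variant excess), mutation on target lineages, variable
recombination maps, genotyping batch effects, reference-panel divergence
from the study population, and post-mortem damage. Passing tests
demonstrate the correctness of the inference machinery and the qualitative
coverage–accuracy trade-off, not field performance on empirical panels.

## Evaluation protocol

Concordance is the fraction of evaluated sites where the argmax-GP
genotype equals the gold standard; ties in the argmax break toward the
lower genotype code. "Comparable" sites are those with non-missing truth
overlapping the output (optionally restricted to truth-heterozygous
sites); "evaluated" sites additionally pass the post-imputation filter
`max GP ≥ t`. Both raw counts and the evaluated fraction are reported.
Zero evaluated sites yields a flagged, NaN-concordance report rather than
an error. MAF stratification uses the reference-panel minor allele
frequency with 25 equal-width, right-closed bins on `[0, 0.5]` (MAF 0 in
bin 1, MAF 0.5 in the top bin); equal-width was chosen over
equal-occupancy and the bin count is a parameter.

## Numerical and I/O choices

* Site matching across files is the exact key (chromosome, position, ref,
  alt); allele swaps and strand flips are dropped and counted, never
  reconciled.
* Likelihood rows read from VCF (GL via `10^GL`, PL via `10^(−PL/10)`) are
  rescaled to maximum 1; the model is scale-invariant per row, which is
  tested end-to-end.
* A target VCF defining neither GL nor PL is an error; a matched record
  with a missing value is treated as unobserved (uniform triplet).
* Written GP values use largest-remainder rounding to 3 decimals, so each
  row sums to exactly 1 and each entry is within one unit in the last
  place of the true posterior; DS is computed from the written GP.
* Genetic maps: 3-column HapMap style (cumulative-cM column used) and
  4-column PLINK style are autodetected by column count; interpolation is
  linear in physical position with flanking-rate extrapolation beyond the
  ends, clamped to non-negative rates.

## Problem sizes

Unit and property tests run on instances up to `H = 20, M = 10 000`
(checkpoint accounting) and `H ≤ 3, M ≤ 5` (exhaustive path-enumeration
oracle, (H²)^M paths). The end-to-end recovery study uses `H = 40,
M = 2 000` with 10 held-out targets across coverages
{0.05, 0.2, 0.5, 1.0} — small enough to run in minutes on one CPU while
keeping several hundred heterozygous sites per target for stable
concordance estimates.

## Known limitations

* Single-sample, single-region runs; no windowed chromosome chunking or
  overlap stitching.
* No allele reconciliation (swaps/flips are dropped), no BCF/CRAM, no
  liftover.
* No damage-aware observation model; `ε` is constant by default.
* Per-site argmax phasing is not switch-consistent; no Viterbi path or
  path sampling.
* Coverage is capped at 1× with at most one read per site; multi-read
  pileups are out of scope.
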