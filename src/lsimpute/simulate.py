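"""Low-coverage read thinning and synthetic panel fixtures.

The thinning procedure turns known diploid genotypes into sparse
genotype-likelihood data mimicking shallow shotgun sequencing of coverage
``c <= 1``: each site independently receives a single read with probability
``p = c``; the read's allele follows the true genotype with a constant
per-base error rate ``delta``; the read is then converted into GATK-style
single-read genotype likelihoods.  Sites with no read get the literal
uniform triplet (0.3333, 0.3333, 0.3333).

``make_synthetic_panel`` builds self-contained fixtures: a reference panel
of recombinant founder mosaics plus held-out diploid targets that are fresh
mosaics of the panel haplotypes (never members of it), so imputation is
learnable and evaluable without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel_io import UNIFORM_GL, LikelihoodMatrix, ReferencePanel

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "sample_read",
    "read_likelihoods",
    "thin_genotypes",
    "make_synthetic_panel",
    "synthetic_map_cm",
]

_BASE_CHOICES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Thinning parameters: target coverage, per-base error rate, seed.

    With one read per sampled site, the read-sampling probability ``p``
    equals the coverage ``c`` directly.
    """

    coverage: float
    delta: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if not 0.0 <= self.delta < 0.5:
            raise ValueError("delta must lie in [0, 0.5)")

    @property
    def p(self) -> float:
        return self.coverage


def sample_read(truth_genotype: int, delta: float, rng: np.random.Generator) -> int:
    """Draw one read allele (1 = alternative) given the true genotype.

    P(alt) is 1 - delta for genotype 2 (alt hom), 0.5 for 1 (het), delta
    for 0 (ref hom).
    """
    try:
        p_alt = {2: 1.0 - delta, 1: 0.5, 0: delta}[int(truth_genotype)]
    except KeyError:
        raise ValueError(f"invalid genotype code {truth_genotype!r}") from None
    return int(rng.random() < p_alt)


def read_likelihoods(sampled_allele: int | None, delta: float) -> np.ndarray:
    """Single-read genotype likelihood triplet (L(0), L(1), L(2)).

    With X the sampled and Y the other allele: L(XX) = 1 - delta,
    L(XY) = 0.5*delta/3 + 0.5*(1 - delta), L(YY) = delta/3.  ``None`` means
    no read was sampled and yields the literal uniform triplet.
    """
    if sampled_allele is None:
        return np.full(3, UNIFORM_GL)
    l_same = 1.0 - delta
    l_het = 0.5 * (delta / 3.0) + 0.5 * (1.0 - delta)
    l_other = delta / 3.0
    if sampled_allele == 1:
        return np.array([l_other, l_het, l_same])
    if sampled_allele == 0:
        return np.array([l_same, l_het, l_other])
    raise ValueError(f"invalid allele code {sampled_allele!r}")


def thin_genotypes(truth_genotypes, config: SimulationConfig, rng=None) -> LikelihoodMatrix:
    """Thin a vector of truth genotypes into low-coverage likelihoods.

    Per site: Bernoulli(p) read-sampling decision, then one read and its
    likelihood triplet.  Missing truth genotypes (coded < 0) are emitted as
    unobserved and counted.  Deterministic given the config seed (or an
    explicitly supplied generator).
    """
    truth = np.asarray(truth_genotypes)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    M = truth.shape[0]
    lik = np.full((M, 3), UNIFORM_GL)
    observed = np.zeros(M, dtype=bool)
    missing = truth < 0
    sampled = rng.random(M) < config.p
    alt_read = rng.random(M)  # drawn for every site to keep the stream aligned
    usable = sampled & ~missing
    p_alt = np.select(
        [truth == 2, truth == 1], [1.0 - config.delta, 0.5], default=config.delta
    )
    is_alt = alt_read < p_alt
    row_alt = read_likelihoods(1, config.delta)
    row_ref = read_likelihoods(0, config.delta)
    lik[usable & is_alt] = row_alt
    lik[usable & ~is_alt] = row_ref
    observed[usable] = True
    return LikelihoodMatrix(lik, observed, n_missing_truth=int(missing.sum()))


@dataclass
class SyntheticDataset:
    """A synthetic panel plus held-out diploid targets with known truth."""

    panel: ReferencePanel
    target_haplotypes: np.ndarray  # (n_targets, 2, M) allele codes
    truth_genotypes: np.ndarray  # (n_targets, M) alt-allele counts
    target_names: list[str] = field(default_factory=list)

    @property
    def n_targets(self) -> int:
        return self.truth_genotypes.shape[0]


def _mosaic(source: np.ndarray, switch_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One haplotype copied as a mosaic of the source rows.

    Starts on a uniformly random source row; between consecutive sites the
    template switches to a uniformly random row with probability
    ``switch_rate``.
    """
    n, M = source.shape
    template = np.empty(M, dtype=np.int64)
    template[0] = rng.integers(n)
    switches = rng.random(M - 1) < switch_rate
    draws = rng.integers(n, size=M - 1)
    cur = template[0]
    for j in range(1, M):
        if switches[j - 1]:
            cur = draws[j - 1]
        template[j] = cur
    return source[template, np.arange(M)]


def make_synthetic_panel(
    n_haplotypes: int,
    n_sites: int,
    mosaic_switch_rate: float = 0.01,
    maf_floor: float = 0.05,
    seed: int = 0,
    *,
    n_targets: int = 1,
    n_founders: int | None = None,
    start_pos: int = 10_001,
    spacing_bp: int = 1_000,
    chrom: str = "20",
) -> SyntheticDataset:
    """Build a mosaic reference panel and held-out diploid targets.

    Founder haplotypes are drawn from per-site allele frequencies bounded
    away from 0 and 1; panel haplotypes are recombinant mosaics of the
    founders (creating linkage structure); each held-out target chromosome
    is a fresh mosaic of the *panel* haplotypes, so the panel contains the
    information needed to impute it, while the target haplotypes themselves
    never appear in the panel (with switch rate 0 a target collapses to an
    exact panel haplotype pair).  Panel MAF is forced to at least
    ``maf_floor`` at every site.  Fully deterministic given the seed.
    """
    H, M = n_haplotypes, n_sites
    if H < 4 or M < 10:
        raise ValueError("need n_haplotypes >= 4 and n_sites >= 10")
    if not 0.0 <= maf_floor <= 0.5:
        raise ValueError("maf_floor must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    if n_founders is None:
        n_founders = max(4, H // 5)

    lo = max(maf_floor, 0.05)
    freqs = rng.uniform(lo, 1.0 - lo, size=M)
    founders = (rng.random((n_founders, M)) < freqs).astype(np.uint8)
    panel_haps = np.stack([_mosaic(founders, mosaic_switch_rate, rng) for _ in range(H)])

    # Enforce the MAF floor by flipping majority alleles at violating sites.
    min_count = int(np.ceil(maf_floor * H)) if maf_floor > 0 else 1
    min_count = max(min_count, 1)
    for j in range(M):
        count = int(panel_haps[:, j].sum())
        minor = 1 if count <= H // 2 else 0
        n_minor = count if minor == 1 else H - count
        if n_minor < min_count:
            majority_rows = np.flatnonzero(panel_haps[:, j] != minor)
            flip = rng.choice(majority_rows, size=min_count - n_minor, replace=False)
            panel_haps[flip, j] = minor

    positions = start_pos + spacing_bp * np.arange(M, dtype=np.int64)
    refs = _BASE_CHOICES[rng.integers(4, size=M)]
    alts = np.array(
        [_BASE_CHOICES[(np.flatnonzero(_BASE_CHOICES != r))[rng.integers(3)]] for r in refs]
    )
    panel = ReferencePanel(
        chrom=chrom,
        positions=positions,
        ref_alleles=refs,
        alt_alleles=alts,
        haplotypes=panel_haps,
    )

    targets = np.empty((n_targets, 2, M), dtype=np.uint8)
    for t in range(n_targets):
        if mosaic_switch_rate == 0:
            a, b = rng.choice(H, size=2, replace=False)
            targets[t, 0] = panel_haps[a]
            targets[t, 1] = panel_haps[b]
        else:
            targets[t, 0] = _mosaic(panel_haps, mosaic_switch_rate, rng)
            targets[t, 1] = _mosaic(panel_haps, mosaic_switch_rate, rng)
    truth = targets.sum(axis=1).astype(np.int8)
    names = [f"TARGET{t:02d}" for t in range(n_targets)]
    return SyntheticDataset(panel, targets, truth, names)


def synthetic_map_cm(panel: ReferencePanel, cm_per_mb: float = 1.0) -> np.ndarray:
    """Cumulative cM for a synthetic panel at a constant recombination rate."""
    return (panel.positions - panel.positions[0]) * cm_per_mb * 1e-6
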