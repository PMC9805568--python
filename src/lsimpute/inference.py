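"""Collapsed forward-backward inference over the diploid copying HMM.

The state space has ``S = H**2`` ordered haplotype pairs.  A naive
transition step costs O(S**2); because the transition factorizes into one
per-chromosome factor ((1-theta) stay + theta/H uniform re-draw), the exact
matrix-vector product collapses to O(S): per chromosome slot, mix the vector
with its marginal over that slot.

Memory is controlled by checkpointing the forward sweep:

* ``full``        — keep all M forward vectors (one sweep, O(M) memory);
* ``one_level``   — keep every k1-th vector, recompute inside each block
  during the backward sweep (~2x forward work, O(M/k1 + k1) memory);
* ``two_level``   — keep every k1-th vector, rebuild every k2-th vector
  inside the active block, then rebuild sub-blocks (~3x forward work,
  O(M/k1 + k1/k2 + k2) memory; with the default k1 = M^(2/3),
  k2 = M^(1/3) this is cube-root memory).

All three modes produce identical posteriors up to floating-point noise;
per-site rescaling with accumulated log scale factors keeps the recursion
stable (the collapsed update is linear, so log-space recursions are not an
option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import HMMParameters, observation_matrix
from .panel_io import LikelihoodMatrix, ReferencePanel

__all__ = [
    "CheckpointPlan",
    "PosteriorResult",
    "ZeroEmissionError",
    "collapsed_propagate",
    "forward_pass",
    "backward_pass",
    "run_forward_backward",
]


class ZeroEmissionError(ValueError):
    """Raised when every hidden state has zero emission weight at a site.

    Only possible with epsilon = 0 and contradictory one-hot likelihoods;
    any epsilon > 0 makes all emission weights strictly positive.
    """

    def __init__(self, site: int):
        super().__init__(
            f"all hidden states have zero emission weight at site index {site}; "
            "use epsilon > 0 or fix the likelihood input"
        )
        self.site = site


@dataclass
class CheckpointPlan:
    """Forward-vector storage policy for the backward sweep."""

    mode: str = "full"  # "full" | "one_level" | "two_level"
    k1: int | None = None
    k2: int | None = None

    def resolve(self, n_sites: int) -> "CheckpointPlan":
        """Fill in default block sizes for a concrete problem size."""
        if self.mode not in ("full", "one_level", "two_level"):
            raise ValueError(f"unknown checkpoint mode {self.mode!r}")
        M = n_sites
        k1 = self.k1 if self.k1 is not None else min(max(math.ceil(M ** (2.0 / 3.0)), 1), M)
        k2 = self.k2 if self.k2 is not None else min(max(math.ceil(M ** (1.0 / 3.0)), 1), k1)
        if not (1 <= k2 <= k1 <= M):
            raise ValueError(f"invalid block sizes k1={k1}, k2={k2} for M={M}")
        return CheckpointPlan(self.mode, k1, k2)


@dataclass
class PosteriorResult:
    """Everything the forward-backward sweep reports for one target sample."""

    gp: np.ndarray  # (M, 3) genotype posteriors, rows sum to 1
    dosage: np.ndarray  # (M,) expected alt-allele count, GP(1) + 2 GP(2)
    haplotypes: np.ndarray  # (2, M) phased allele codes from the max-posterior state
    map_state: np.ndarray  # (M,) linear index of the max-posterior state
    map_state_prob: np.ndarray  # (M,) posterior probability of that state
    log_likelihood: float
    n_forward_updates: int = 0
    peak_stored_vectors: int = 0
    genotype_group_posterior: np.ndarray | None = None  # (M, 3) sum of state
    # posteriors grouped by implied genotype (the panel-only predictive mix)


def collapsed_propagate(state_vector: np.ndarray, theta: float, n_haplotypes: int) -> np.ndarray:
    """Exact transition-matrix product in O(H^2).

    Equivalent to multiplying by the dense S x S transition matrix: per
    chromosome slot the new vector is ``(1-theta) * v + (theta/H) *
    (marginal over that slot)``, applied to each slot in turn.  Preserves
    total mass; theta = 0 is the identity, theta = 1 spreads the mass
    uniformly.
    """
    H = n_haplotypes
    v = np.asarray(state_vector, dtype=float)
    A = v.reshape(H, H)
    out = (1.0 - theta) * A + (theta / H) * A.sum(axis=0, keepdims=True)
    out = (1.0 - theta) * out + (theta / H) * out.sum(axis=1, keepdims=True)
    return out.reshape(v.shape)


class _Engine:
    """Shared per-run state: emission lookup, update counter."""

    def __init__(self, panel: ReferencePanel, likelihoods, params: HMMParameters):
        if isinstance(likelihoods, LikelihoodMatrix):
            lik = likelihoods.likelihoods
        else:
            lik = np.asarray(likelihoods, dtype=float)
        if lik.shape != (panel.n_sites, 3):
            raise ValueError("likelihoods must be (M, 3) aligned with the panel")
        if params.n_haplotypes != panel.n_haplotypes:
            raise ValueError("parameter H does not match the panel")
        if params.epsilon.shape[0] != panel.n_sites:
            raise ValueError("per-site epsilon must match the panel size")
        if params.theta.shape[0] < panel.n_sites - 1:
            raise ValueError("theta must cover all M-1 intervals")
        self.panel = panel
        self.lik = lik
        self.params = params
        self.H = panel.n_haplotypes
        self.S = self.H * self.H
        self.M = panel.n_sites
        # w[j, k] = sum_g O_j[g, k] * L_j(g): emission weight by implied genotype
        self.weights = np.empty((self.M, 3))
        eps = params.epsilon
        if np.all(eps == eps[0]):
            O = observation_matrix(eps[0])
            self.weights[:] = lik @ O
        else:
            for j in range(self.M):
                self.weights[j] = observation_matrix(eps[j]).T @ lik[j]
        self.hap = panel.haplotypes
        self.n_forward_updates = 0

    def emission(self, j: int) -> np.ndarray:
        col = self.hap[:, j]
        gimp = col[:, None] + col[None, :]
        return self.weights[j][gimp].reshape(self.S)

    def implied_genotypes(self, j: int) -> np.ndarray:
        col = self.hap[:, j]
        return (col[:, None] + col[None, :]).reshape(self.S)

    def forward_step(self, prev: np.ndarray | None, j: int) -> tuple[np.ndarray, float]:
        """One normalized forward update; returns (alpha_j, log scale)."""
        e = self.emission(j)
        if j == 0 or prev is None:
            a = e / self.S  # uniform initial state distribution
        else:
            a = e * collapsed_propagate(prev, self.params.theta[j - 1], self.H)
        total = a.sum()
        if total <= 0.0 or not np.isfinite(total):
            raise ZeroEmissionError(j)
        self.n_forward_updates += 1
        return a / total, float(np.log(total))

    def backward_step(self, beta_next: np.ndarray, j: int) -> tuple[np.ndarray, float]:
        """beta_j from beta_{j+1}; the transition matrix is symmetric, so the
        collapsed propagation is reused unchanged."""
        b = collapsed_propagate(self.emission(j + 1) * beta_next, self.params.theta[j], self.H)
        total = b.sum()
        if total <= 0.0 or not np.isfinite(total):
            raise ZeroEmissionError(j + 1)
        return b / total, float(np.log(total))


def forward_pass(panel, likelihoods, params: HMMParameters):
    """Full (uncheckpointed) forward sweep.

    Returns ``(alphas, log_scales)`` where ``alphas`` is (M, S) with each row
    normalized to sum 1 and ``log_scales`` accumulates the per-site
    normalizers; ``log_scales.sum()`` is the data log-likelihood.
    """
    eng = _Engine(panel, likelihoods, params)
    alphas = np.empty((eng.M, eng.S))
    scales = np.empty(eng.M)
    prev = None
    for j in range(eng.M):
        prev, scales[j] = eng.forward_step(prev, j)
        alphas[j] = prev
    return alphas, scales


def backward_pass(panel, likelihoods, params: HMMParameters):
    """Full backward sweep; returns ``(betas, log_scales)``, rows sum to 1."""
    eng = _Engine(panel, likelihoods, params)
    betas = np.empty((eng.M, eng.S))
    scales = np.zeros(eng.M)
    betas[-1] = 1.0 / eng.S
    scales[-1] = np.log(eng.S)  # beta_M is the all-ones vector, stored normalized
    for j in range(eng.M - 2, -1, -1):
        betas[j], scales[j] = eng.backward_step(betas[j + 1], j)
    return betas, scales


def _site_outputs(eng: _Engine, alpha, beta, j, gp_mode, out):
    post = alpha * beta
    total = post.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise ZeroEmissionError(j)
    post /= total
    gimp = eng.implied_genotypes(j)
    q = np.bincount(gimp, weights=post, minlength=3)
    if gp_mode == "posterior":
        # true genotype posterior: includes the local likelihood term
        w = eng.weights[j]
        ratio = np.where(w > 0, q / np.where(w > 0, w, 1.0), 0.0)
        O = observation_matrix(eng.params.epsilon[j])
        gp = (O * eng.lik[j][:, None]) @ ratio
    elif gp_mode == "predictive":
        # panel-only predictive mix sum_X P(X|Y) P(g|X)
        gp = observation_matrix(eng.params.epsilon[j]) @ q
    else:
        raise ValueError(f"unknown gp_mode {gp_mode!r}")
    gp_total = gp.sum()
    if gp_total <= 0:
        raise ZeroEmissionError(j)
    gp /= gp_total
    idx = int(np.argmax(post))  # ties break to the smallest linear index
    x1, x2 = idx // eng.H, idx % eng.H
    out.gp[j] = gp
    out.genotype_group_posterior[j] = q
    out.map_state[j] = idx
    out.map_state_prob[j] = post[idx]
    out.haplotypes[0, j] = eng.hap[x1, j]
    out.haplotypes[1, j] = eng.hap[x2, j]


def run_forward_backward(
    panel: ReferencePanel,
    likelihoods,
    params: HMMParameters,
    plan: CheckpointPlan | None = None,
    gp_mode: str = "posterior",
) -> PosteriorResult:
    """Posterior genotype probabilities, dosage and phasing for one sample.

    ``gp_mode='posterior'`` (default) reports the posterior of the latent
    genotype given all data, including the local likelihood term;
    ``'predictive'`` reports the panel-only mixture over implied genotypes.
    The checkpoint plan changes memory and work, never the result.
    """
    plan = (plan or CheckpointPlan()).resolve(panel.n_sites)
    eng = _Engine(panel, likelihoods, params)
    M, S, H = eng.M, eng.S, eng.H

    out = PosteriorResult(
        gp=np.empty((M, 3)),
        dosage=np.empty(M),
        haplotypes=np.empty((2, M), dtype=np.uint8),
        map_state=np.empty(M, dtype=np.int64),
        map_state_prob=np.empty(M),
        log_likelihood=0.0,
        genotype_group_posterior=np.empty((M, 3)),
    )

    k1 = plan.k1 if plan.mode != "full" else M
    # Forward sweep: store everything (full) or level-1 checkpoints only.
    loglik = 0.0
    stored: dict[int, np.ndarray] = {}
    prev = None
    for j in range(M):
        prev, logc = eng.forward_step(prev, j)
        loglik += logc
        if plan.mode == "full" or j % k1 == 0:
            stored[j] = prev
    out.log_likelihood = loglik
    peak = len(stored)

    # Backward sweep, emitting per-site outputs as beta becomes available.
    beta = np.full(S, 1.0 / S)
    if plan.mode == "full":
        for j in range(M - 1, -1, -1):
            _site_outputs(eng, stored[j], beta, j, gp_mode, out)
            if j > 0:
                beta, _ = eng.backward_step(beta, j - 1)
    else:
        for start in range(((M - 1) // k1) * k1, -1, -k1):
            end = min(start + k1, M)
            if plan.mode == "one_level":
                buf = [stored[start]]
                for j in range(start + 1, end):
                    a, _ = eng.forward_step(buf[-1], j)
                    buf.append(a)
                peak = max(peak, len(stored) + len(buf))
                for j in range(end - 1, start - 1, -1):
                    _site_outputs(eng, buf[j - start], beta, j, gp_mode, out)
                    if j > 0:
                        beta, _ = eng.backward_step(beta, j - 1)
            else:  # two_level
                k2 = plan.k2
                level2 = {start: stored[start]}
                a = stored[start]
                for j in range(start + 1, end):
                    a, _ = eng.forward_step(a, j)
                    if (j - start) % k2 == 0:
                        level2[j] = a
                peak = max(peak, len(stored) + len(level2))
                for sub in range(start + ((end - 1 - start) // k2) * k2, start - 1, -k2):
                    sub_end = min(sub + k2, end)
                    buf = [level2[sub]]
                    for j in range(sub + 1, sub_end):
                        a, _ = eng.forward_step(buf[-1], j)
                        buf.append(a)
                    peak = max(peak, len(stored) + len(level2) + len(buf))
                    for j in range(sub_end - 1, sub - 1, -1):
                        _site_outputs(eng, buf[j - sub], beta, j, gp_mode, out)
                        if j > 0:
                            beta, _ = eng.backward_step(beta, j - 1)
                    del level2[sub]
            del stored[start]

    out.dosage = out.gp[:, 1] + 2.0 * out.gp[:, 2]
    out.n_forward_updates = eng.n_forward_updates
    out.peak_stored_vectors = peak
    return out
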