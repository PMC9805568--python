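"""Brute-force oracle: exhaustive enumeration over all hidden-state paths.

Computes state posteriors, genotype posteriors and the data likelihood by
summing the joint probability over every one of the (H^2)^M paths, using
only the local probability definitions (switch-count transitions, the 3x3
observation matrix, likelihood-integrated emissions).  Deliberately
independent of the collapsed forward-backward implementation it validates;
feasible for H <= 3, M <= 5.
"""

from __future__ import annotations

import numpy as np

from lsimpute.model import observation_matrix


def brute_force_posteriors(haplotypes, likelihoods, theta, epsilon):
    """Exact posteriors by path enumeration.

    Parameters: ``haplotypes`` (H, M) allele codes; ``likelihoods`` (M, 3)
    linear-scale rows; ``theta`` length M-1; ``epsilon`` scalar or length M.

    Returns a dict with ``state_posteriors`` (M, S), ``gp`` (M, 3) including
    the local likelihood term, ``gp_predictive`` (M, 3) panel-only mixture,
    and ``log_likelihood``.
    """
    hap = np.asarray(haplotypes)
    lik = np.asarray(likelihoods, dtype=float)
    H, M = hap.shape
    S = H * H
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), (M,))

    idx = np.arange(S)
    x1, x2 = idx // H, idx % H
    gimp = np.stack([hap[x1, j] + hap[x2, j] for j in range(M)])  # (M, S)

    obs = [observation_matrix(eps[j]) for j in range(M)]
    # per-site emission weight by state: w_j[s] = sum_g O_j[g, gimp] L_j(g)
    emis = np.stack([(obs[j].T @ lik[j])[gimp[j]] for j in range(M)])

    trans = []
    for j in range(M - 1):
        t = theta[j]
        same1 = (x1[:, None] == x1[None, :]).astype(float)
        same2 = (x2[:, None] == x2[None, :]).astype(float)
        f1 = (1 - t) * same1 + t / H
        f2 = (1 - t) * same2 + t / H
        trans.append(f1 * f2)

    paths = np.indices((S,) * M).reshape(M, -1)  # (M, S**M)
    prob = np.full(paths.shape[1], 1.0 / S)
    for j in range(1, M):
        prob = prob * trans[j - 1][paths[j - 1], paths[j]]
    for j in range(M):
        prob = prob * emis[j][paths[j]]
    total = prob.sum()

    state_post = np.stack(
        [np.bincount(paths[j], weights=prob, minlength=S) / total for j in range(M)]
    )

    gp = np.empty((M, 3))
    gp_pred = np.empty((M, 3))
    for j in range(M):
        O = obs[j]
        w_state = emis[j][paths[j]]
        for g in range(3):
            local = O[g, gimp[j][paths[j]]] * lik[j, g] / w_state
            gp[j, g] = np.sum(prob * local) / total
        q = np.bincount(gimp[j], weights=state_post[j], minlength=3)
        gp_pred[j] = O @ q
        gp_pred[j] /= gp_pred[j].sum()

    return {
        "state_posteriors": state_post,
        "gp": gp,
        "gp_predictive": gp_pred,
        "log_likelihood": float(np.log(total)),
    }


def random_instance(rng, n_haplotypes=None, n_sites=None, allow_unobserved=True):
    """A small random panel + likelihood instance for oracle comparisons."""
    H = n_haplotypes if n_haplotypes is not None else int(rng.integers(2, 4))
    M = n_sites if n_sites is not None else int(rng.integers(1, 6))
    hap = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
    # avoid monomorphic-everywhere panels so posteriors stay interesting
    hap[0, 0] = 1 - hap[1, 0]
    lik = rng.uniform(0.01, 1.0, size=(M, 3))
    if allow_unobserved and M > 1:
        j = int(rng.integers(M))
        lik[j] = 1.0 / 3.0
    theta = rng.uniform(0.0, 0.6, size=max(M - 1, 0))
    eps = float(rng.uniform(0.001, 0.2))
    return hap, lik, theta, eps
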