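"""Local probabilities of the diploid haplotype-copying HMM.

The model treats a diploid target sample as an imperfect mosaic of ``H``
phased reference haplotypes.  The hidden state at site ``j`` is an ordered
pair ``X_j = (x1, x2)`` of reference-haplotype indices — which haplotype
each of the sample's two chromosomes is currently copying — giving ``H**2``
states.  Between consecutive sites each chromosome switches template with
probability ``theta_j`` (derived from genetic-map distance), landing on a
uniformly chosen haplotype; this yields the classic three-regime transition
probabilities by number of template switches.  Emissions integrate a
per-site error parameter ``epsilon_j`` (genotype observation matrix) against
the target's genotype likelihoods ``L(0), L(1), L(2)``.

All haplotype and state indices are 0-based internally; genotypes are coded
as the count of alternative alleles, ``g in {0, 1, 2}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_NE",
    "DEFAULT_EPSILON",
    "HMMParameters",
    "recombination_fraction",
    "state_transition_prob",
    "haplotype_transition_prob",
    "dense_transition_matrix",
    "observation_matrix",
    "observation_prob",
    "implied_genotype",
    "implied_genotype_matrix",
    "emission_weight",
    "emission_field",
]

#: HapMap-era effective population size used to scale recombination rates.
DEFAULT_NE = 11418.0

#: Default per-site error/mutation parameter of the observation model.
DEFAULT_EPSILON = 0.01


def recombination_fraction(delta_cm, ne: float, n_haplotypes: int):
    """Per-interval template-switch probability from genetic distance.

    theta = 1 - exp(-4 * Ne * d / H) with ``d`` the distance in Morgans
    (``delta_cm / 100``).  Returns a scalar for scalar input, an array for
    array input; theta is 0 iff the distance is 0 and approaches 1 for
    large distances.
    """
    d = np.asarray(delta_cm, dtype=float) / 100.0
    if np.any(d < 0):
        raise ValueError("genetic distances must be non-negative")
    theta = -np.expm1(-4.0 * ne * d / n_haplotypes)
    if np.ndim(delta_cm) == 0:
        return float(theta)
    return theta


def state_transition_prob(theta: float, n_haplotypes: int, n_switch: int) -> float:
    """Diploid state transition probability by number of template switches.

    ``n_switch`` counts how many of the two copying chromosomes change
    template haplotype between the two sites (0, 1 or 2).
    """
    H = n_haplotypes
    if n_switch == 2:
        return theta**2 / H**2
    if n_switch == 1:
        return (1.0 - theta) * theta / H + theta**2 / H**2
    if n_switch == 0:
        return (1.0 - theta) ** 2 + 2.0 * (theta - theta**2) / H + theta**2 / H**2
    raise ValueError(f"n_switch must be 0, 1 or 2, got {n_switch}")


def haplotype_transition_prob(theta: float, n_haplotypes: int, same: bool) -> float:
    """Per-chromosome transition factor.

    The diploid transition probability factorizes as the product of one such
    factor per chromosome; this factorization is what makes the collapsed
    O(H^2) propagation exact.
    """
    if same:
        return (1.0 - theta) + theta / n_haplotypes
    return theta / n_haplotypes


def dense_transition_matrix(theta: float, n_haplotypes: int) -> np.ndarray:
    """Explicit H^2 x H^2 transition matrix, built from switch counts.

    Intended for validation and tiny problems only; the inference engine
    never materializes it.  States are ordered pairs in row-major order:
    linear index ``s = x1 * H + x2``.
    """
    H = n_haplotypes
    idx = np.arange(H * H)
    x1, x2 = idx // H, idx % H
    n_switch = (x1[:, None] != x1[None, :]).astype(int) + (
        x2[:, None] != x2[None, :]
    ).astype(int)
    probs = np.array([state_transition_prob(theta, H, k) for k in range(3)])
    return probs[n_switch]


def observation_matrix(epsilon: float) -> np.ndarray:
    """3x3 genotype observation matrix ``O[g_obs, g_implied]``.

    Each column (fixed implied genotype) sums to 1.  With epsilon = 0 the
    matrix is the identity.
    """
    e = float(epsilon)
    if not 0.0 <= e < 0.5:
        raise ValueError(f"epsilon must be in [0, 0.5), got {e}")
    return np.array(
        [
            [(1 - e) ** 2, (1 - e) * e, e**2],
            [2 * e * (1 - e), (1 - e) ** 2 + e**2, 2 * e * (1 - e)],
            [e**2, (1 - e) * e, (1 - e) ** 2],
        ]
    )


def observation_prob(g_obs: int, g_implied: int, epsilon: float) -> float:
    """P(observed genotype | genotype implied by the hidden state)."""
    if g_obs not in (0, 1, 2) or g_implied not in (0, 1, 2):
        raise ValueError("genotype codes must be 0, 1 or 2")
    return float(observation_matrix(epsilon)[g_obs, g_implied])


def implied_genotype(state: tuple[int, int], panel, site: int) -> int:
    """Genotype implied by a hidden state: sum of its two template alleles."""
    x1, x2 = state
    return int(panel.haplotypes[x1, site]) + int(panel.haplotypes[x2, site])


def implied_genotype_matrix(panel, site: int) -> np.ndarray:
    """(H, H) matrix of implied genotypes for every ordered state pair."""
    col = panel.haplotypes[:, site].astype(np.int8)
    return col[:, None] + col[None, :]


def emission_weight(
    state: tuple[int, int], likelihood_row, epsilon: float, panel, site: int
) -> float:
    """Likelihood-integrated emission weight sum_g P(g|X) * L(g) for one state."""
    g_imp = implied_genotype(state, panel, site)
    O = observation_matrix(epsilon)
    return float(O[:, g_imp] @ np.asarray(likelihood_row, dtype=float))


def emission_field(panel, site: int, likelihood_row, epsilon: float) -> np.ndarray:
    """(H, H) emission weights over all states at one site.

    The weight depends on the state only through its implied genotype, so the
    field is a 3-vector lookup over the implied-genotype matrix.
    """
    O = observation_matrix(epsilon)
    w = O.T @ np.asarray(likelihood_row, dtype=float)  # w[k] = sum_g O[g,k] L(g)
    return w[implied_genotype_matrix(panel, site)]


@dataclass
class HMMParameters:
    """Per-run parameterization of the copying model.

    Attributes
    ----------
    n_haplotypes
        Number of reference haplotypes H.
    theta
        Per-interval switch probabilities, length M-1 (interval ``i`` lies
        between sites ``i`` and ``i+1``); each in [0, 1).
    epsilon
        Per-site error parameters, length M, each in [0, 0.5).  A constant
        by default; a vector hook exists for position-dependent error models
        (e.g. ancient-DNA damage), none of which is shipped.
    ne
        Effective-size constant used to derive theta (kept for logging).
    """

    n_haplotypes: int
    theta: np.ndarray
    epsilon: np.ndarray
    ne: float = DEFAULT_NE

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 reference haplotypes")
        if np.any(self.theta < 0) or np.any(self.theta >= 1):
            raise ValueError("theta values must lie in [0, 1)")
        if np.any(self.epsilon < 0) or np.any(self.epsilon >= 0.5):
            raise ValueError("epsilon values must lie in [0, 0.5)")

    @property
    def n_sites(self) -> int:
        return self.epsilon.shape[0]

    @classmethod
    def from_panel(
        cls,
        panel,
        genetic_map=None,
        *,
        ne: float = DEFAULT_NE,
        epsilon=DEFAULT_EPSILON,
        cm_per_mb: float = 1.0,
    ) -> "HMMParameters":
        """Derive parameters for a panel.

        With a genetic map, per-site cumulative cM come from linear
        interpolation of the map; without one, physical distance is converted
        at a constant ``cm_per_mb`` (default 1 cM/Mb, the genome-wide human
        average).
        """
        if genetic_map is not None:
            cm = genetic_map.interpolate(panel.positions)
        else:
            cm = panel.positions.astype(float) * cm_per_mb * 1e-6
        delta_cm = np.maximum(np.diff(cm), 0.0)
        theta = recombination_fraction(delta_cm, ne, panel.n_haplotypes)
        eps = np.asarray(epsilon, dtype=float)
        if eps.ndim == 0:
            eps = np.full(panel.n_sites, float(eps))
        elif eps.shape[0] != panel.n_sites:
            raise ValueError("per-site epsilon must have one entry per panel site")
        return cls(
            n_haplotypes=panel.n_haplotypes,
            theta=np.atleast_1d(theta),
            epsilon=eps,
            ne=ne,
        )

    @classmethod
    def constant(
        cls,
        n_haplotypes: int,
        n_sites: int,
        *,
        theta: float,
        epsilon=DEFAULT_EPSILON,
        ne: float = DEFAULT_NE,
    ) -> "HMMParameters":
        """Constant-theta parameters (synthetic data and tests)."""
        eps = np.asarray(epsilon, dtype=float)
        if eps.ndim == 0:
            eps = np.full(n_sites, float(eps))
        return cls(
            n_haplotypes=n_haplotypes,
            theta=np.full(max(n_sites - 1, 0), float(theta)),
            epsilon=eps,
            ne=ne,
        )
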