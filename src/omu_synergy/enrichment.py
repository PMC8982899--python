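"""Enrichment of true synergistic pairs in the top-ranked list.

The prioritized top-k list and an independent random sample of pairs are each
screened for true synergy, giving two (hits, draws) outcomes.  Under the null
hypothesis that the ranking is no better than random sampling, both outcomes
are draws from the same unknown population proportion M of synergistic pairs.
The maximum-likelihood M under a binomial model for both trials is found
numerically (it coincides with the pooled proportion (k1+k2)/(s1+s2)), and
the joint likelihood at that M quantifies how (im)probable the observed split
is under the null.  A finite-population (hypergeometric) variant maximizes
over the integer number of synergistic pairs in a population of N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


def n_pairs(n_drugs: int) -> int:
    """Number of unordered two-drug combinations, n(n-1)/2."""
    if n_drugs < 2:
        raise ValueError("need at least 2 drugs to form a pair")
    return n_drugs * (n_drugs - 1) // 2


@dataclass
class EnrichmentResult:
    k1: int
    s1: int
    k2: int
    s2: int
    m_hat: float
    joint_prob_at_mhat: float
    finite_population: int | None = None
    m_hat_finite: float | None = None
    joint_prob_finite: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _joint_binomial_likelihood(m: float, k1: int, s1: int, k2: int, s2: int) -> float:
    return float(stats.binom.pmf(k1, s1, m) * stats.binom.pmf(k2, s2, m))


def joint_binomial_mle(
    k1: int, s1: int, k2: int, s2: int, finite_population: int | None = None
) -> EnrichmentResult:
    """Proportion M maximizing the joint probability of two (hits, draws) trials.

    The argmax is located numerically over (0, 1); degenerate corners (all
    hits or no hits) are handled exactly.  With ``finite_population=N`` the
    report additionally carries the hypergeometric variant: the integer hit
    count K in {0..N} maximizing the product of the two sampling pmfs,
    reported as the proportion K/N.
    """
    for k, s in ((k1, s1), (k2, s2)):
        if not 0 <= k <= s:
            raise ValueError(f"invalid trial: {k} hits in {s} draws")
    if s1 + s2 == 0:
        raise ValueError("both trials are empty")

    total_k, total_s = k1 + k2, s1 + s2
    if total_k == 0:
        m_hat = 0.0
    elif total_k == total_s:
        m_hat = 1.0
    else:
        res = optimize.minimize_scalar(
            lambda m: -_joint_binomial_likelihood(m, k1, s1, k2, s2),
            bounds=(1e-9, 1 - 1e-9),
            method="bounded",
            options={"xatol": 1e-10},
        )
        m_hat = float(res.x)
    joint = _joint_binomial_likelihood(m_hat, k1, s1, k2, s2)

    result = EnrichmentResult(k1=k1, s1=s1, k2=k2, s2=s2,
                              m_hat=m_hat, joint_prob_at_mhat=joint)
    if finite_population is not None:
        n = int(finite_population)
        if n < max(s1, s2):
            raise ValueError("finite population smaller than a draw")
        ks = np.arange(0, n + 1)
        lik = (stats.hypergeom.pmf(k1, n, ks, s1)
               * stats.hypergeom.pmf(k2, n, ks, s2))
        best = int(ks[np.argmax(lik)])
        result.finite_population = n
        result.m_hat_finite = best / n
        result.joint_prob_finite = float(lik[best])
    return result
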