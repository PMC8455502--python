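"""The delta statistic of phylogenetic signal for categorical traits.

delta measures how strongly a categorical trait (here: the ecological niche
of each taxon on a gene tree) tracks the phylogeny. The chain is:

1. fit the equal-rates Mk transition rate by maximum likelihood;
2. compute marginal ancestral state probabilities for every internal node;
3. reduce each probability vector to its normalized Shannon entropy
   h_i in (0, 1) — low entropy means the trait state at that node is
   well determined by the tips, i.e. the trait is phylogenetically
   structured;
4. model the entropies as i.i.d. Beta(alpha, beta) with independent
   Exponential(lambda0) priors on alpha and beta, sampled by alternating
   Metropolis-Hastings updates;
5. delta is the posterior mean of beta/alpha. Uncertain (high-entropy)
   reconstructions drag delta down; confident ones push it up, so larger
   delta = stronger phylogenetic signal. delta is a positive real with no
   upper bound.

Significance is assessed by a shuffled-trait permutation test: the trait
values are permuted across tips (preserving category counts) and delta is
recomputed for each shuffle; the p-value is the fraction of shuffles whose
delta is greater than or equal to the observed delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .phylo_core import (
    PhyloTree,
    TreeError,
    ancestral_state_table,
    fit_rate,
    trait_states,
    validate_traits,
)

ENTROPY_EPS = 1e-9


@dataclass(frozen=True)
class DeltaParams:
    """MCMC settings for the delta estimate.

    Defaults are the published run settings: exponential prior rate 0.1,
    Metropolis proposal sd 0.5, 10,000 iterations, thinning 10, burn-in 100
    retained-scale samples.
    """

    lambda0: float = 0.1
    proposal_sd: float = 0.5
    n_iter: int = 10_000
    thin: int = 10
    burn: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")
        if self.n_iter <= self.burn * self.thin:
            raise ValueError("n_iter must exceed burn * thin")

    @property
    def n_retained(self) -> int:
        """Retained chain length: samples at iterations i with
        burn*thin < i <= n_iter and i % thin == 0."""
        return self.n_iter // self.thin - self.burn


@dataclass
class DeltaResult:
    delta: float
    alpha_chain: np.ndarray
    beta_chain: np.ndarray
    acceptance_rate_alpha: float
    acceptance_rate_beta: float
    rate: float
    n_internal: int

    @property
    def delta_ratio_of_means(self) -> float:
        """Diagnostic alternative estimator mean(beta)/mean(alpha)."""
        return float(self.beta_chain.mean() / self.alpha_chain.mean())


@dataclass
class PermutationResult:
    real_delta: float
    shuffled_deltas: List[float]
    p_value: float
    shuffle_seeds: List[int]

    @property
    def shuffled_mean(self) -> float:
        return float(np.mean(self.shuffled_deltas))

    @property
    def shuffled_sd(self) -> float:
        return float(np.std(self.shuffled_deltas, ddof=1))

    def p_display(self) -> str:
        """Tabular rendering: a zero count prints as '<0.01'."""
        n = len(self.shuffled_deltas)
        if self.p_value == 0:
            return f"<{1 / n:.2g}"
        return f"{self.p_value:.2g}"


def node_entropies(anc_probs: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropies of ancestral probability vectors.

    h_i = -sum_s p_s ln p_s / ln k with 0 ln 0 := 0; values of exactly 0 or
    1 are nudged into the open interval by 1e-9 so the Beta likelihood is
    finite.
    """
    P = np.asarray(anc_probs, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    k = P.shape[1]
    if k < 2:
        raise ValueError("need k >= 2 states")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    h = -terms.sum(axis=1) / math.log(k)
    return np.clip(h, ENTROPY_EPS, 1.0 - ENTROPY_EPS)


def _sample_beta_params(
    h: np.ndarray, params: DeltaParams, rng: np.random.Generator
):
    """Alternating Metropolis-Hastings on (alpha, beta) for i.i.d. Beta data.

    Log-posterior for alpha given beta (up to a constant):
        (alpha - 1) * sum(log h) - m * logBeta(alpha, beta) - lambda0 * alpha
    and symmetrically for beta with sum(log(1 - h)). Non-positive proposals
    are rejected outright.
    """
    m = h.size
    S = float(np.log(h).sum())
    T = float(np.log1p(-h).sum())
    lgamma = math.lgamma
    lam = params.lambda0
    se = params.proposal_sd

    def logpost(a: float, b: float) -> float:
        lbeta = lgamma(a) + lgamma(b) - lgamma(a + b)
        return (a - 1) * S + (b - 1) * T - m * lbeta - lam * (a + b)

    a, b = 1.0, 1.0
    lp = logpost(a, b)
    n = params.n_iter
    prop = rng.normal(0.0, se, size=(n, 2))
    logu = np.log(rng.random(size=(n, 2)))
    keep_from = params.burn * params.thin
    alphas: List[float] = []
    betas: List[float] = []
    acc_a = acc_b = 0
    for i in range(1, n + 1):
        pa = a + prop[i - 1, 0]
        if pa > 0:
            lp_new = logpost(pa, b)
            if lp_new - lp > logu[i - 1, 0]:
                a, lp = pa, lp_new
                acc_a += 1
        pb = b + prop[i - 1, 1]
        if pb > 0:
            lp_new = logpost(a, pb)
            if lp_new - lp > logu[i - 1, 1]:
                b, lp = pb, lp_new
                acc_b += 1
        if i > keep_from and i % params.thin == 0:
            alphas.append(a)
            betas.append(b)
    return (
        np.array(alphas),
        np.array(betas),
        acc_a / n,
        acc_b / n,
    )


def estimate_delta(
    tree: PhyloTree,
    traits: Mapping[str, str],
    params: Optional[DeltaParams] = None,
) -> DeltaResult:
    """Estimate delta for a tree and a categorical trait.

    Requires >= 4 tips, >= 2 observed categories and >= 2 internal nodes.
    Deterministic given ``params.seed``.
    """
    params = params or DeltaParams()
    validate_traits(tree, traits)
    if tree.n_tips < 4:
        raise TreeError("delta needs >= 4 tips")
    states = trait_states(traits)
    if len(states) < 2:
        raise TreeError("constant trait: delta is undefined")
    r = fit_rate(tree, traits)
    anc = ancestral_state_table(tree, traits, r)
    if anc.shape[0] < 2:
        raise TreeError("delta needs >= 2 internal nodes")
    h = node_entropies(anc)
    rng = np.random.default_rng(params.seed)
    alphas, betas, acc_a, acc_b = _sample_beta_params(h, params, rng)
    delta = float(np.mean(betas / alphas))
    return DeltaResult(
        delta=delta,
        alpha_chain=alphas,
        beta_chain=betas,
        acceptance_rate_alpha=acc_a,
        acceptance_rate_beta=acc_b,
        rate=r,
        n_internal=int(anc.shape[0]),
    )


def shuffle_traits(
    traits: Mapping[str, str], seed: int
) -> Dict[str, str]:
    """Uniform random permutation of trait values over the same tips.

    The multiset of categories is exactly preserved (a shuffle, not a
    resample). Reproducible for a fixed seed.
    """
    if not traits:
        raise ValueError("empty trait table")
    rng = np.random.default_rng(seed)
    tips = list(traits.keys())
    values = [traits[t] for t in tips]
    perm = rng.permutation(len(values))
    return {tip: values[j] for tip, j in zip(tips, perm)}


def _shuffle_seed(master_seed: int, i: int) -> int:
    """Independent per-shuffle seed stream, derived by fixed offset so that
    shuffles can be computed in any order or in parallel."""
    ss = np.random.SeedSequence([master_seed, i])
    return int(ss.generate_state(1)[0] % (2**31))


def permutation_test(
    tree: PhyloTree,
    traits: Mapping[str, str],
    params: Optional[DeltaParams] = None,
    n_shuffles: int = 100,
) -> PermutationResult:
    """Shuffled-trait permutation test of phylogenetic signal.

    Computes delta for the observed trait and for ``n_shuffles`` independent
    trait shuffles; p = (# shuffled delta >= real delta) / n_shuffles (ties
    count against the observed signal, the conservative reading). The full
    shuffled distribution is kept so reports can state its mean and sd.
    """
    params = params or DeltaParams()
    real = estimate_delta(tree, traits, params)
    shuffled: List[float] = []
    seeds: List[int] = []
    for i in range(n_shuffles):
        s = _shuffle_seed(params.seed, i)
        seeds.append(s)
        perm = shuffle_traits(traits, seed=s)
        sub = DeltaParams(
            lambda0=params.lambda0,
            proposal_sd=params.proposal_sd,
            n_iter=params.n_iter,
            thin=params.thin,
            burn=params.burn,
            seed=_shuffle_seed(params.seed, n_shuffles + i),
        )
        shuffled.append(estimate_delta(tree, perm, sub).delta)
    p = sum(d >= real.delta for d in shuffled) / n_shuffles
    return PermutationResult(
        real_delta=real.delta,
        shuffled_deltas=shuffled,
        p_value=p,
        shuffle_seeds=seeds,
    )


def table2_row(
    name: str, tree: PhyloTree, result: PermutationResult
) -> Dict[str, object]:
    """One row of a published-style summary table: tip count, real delta,
    shuffled mean and sd, and the displayed p-value."""
    return {
        "gene": name,
        "tips": tree.n_tips,
        "delta": round(result.real_delta, 3),
        "shuffled_mean": round(result.shuffled_mean, 3),
        "shuffled_sd": round(result.shuffled_sd, 3),
        "p_value": result.p_display(),
        "significant": result.p_value < 0.05,
    }
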