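"""Anchored maximum-entropy sampling of sequence space by Metropolis MCMC.

Given a trained classifier and an anchor sequence x0, the target distribution
over all length-L sequences is

    p(x) = exp(-beta * d(phi(x0), phi(x)) + mu * N(x)) / Z

where d is the weighted Euclidean metric in penultimate-activation space,
N(x) counts G and C nucleotides, mu = log(c / (1 - c)) encodes genome GC
content c, and beta is the Lagrange multiplier that sets how tightly samples
reproduce the anchor's hidden representation.  This is the distribution
closest (in KL divergence) to the i.i.d. background q subject to a
constraint on the mean activation distance to the anchor.

Sampling uses single-site Metropolis: a position is chosen uniformly, a
replacement nucleotide is drawn uniformly from the three alternatives, and
the move is accepted with probability
min(1, exp(-beta * (d' - d) + mu * (N' - N))).  The proposal kernel is
symmetric, so the chain's stationary distribution is exactly p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .network import (
    ALPHABET,
    EncodedSequence,
    MetricWeights,
    weighted_distance,
)

__all__ = [
    "BackgroundModel",
    "SamplerConfig",
    "SampleSet",
    "mu_from_gc",
    "metropolis_acceptance",
    "run_chains",
    "select_beta",
]

_IS_GC = np.array([0, 1, 1, 0], dtype=np.int64)  # A,C,G,T


@dataclass(frozen=True)
class BackgroundModel:
    """i.i.d. per-position background q with P(G)=P(C)=c/2, P(A)=P(T)=(1-c)/2."""

    gc_content: float

    def __post_init__(self):
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly in (0, 1)")

    @property
    def probs(self) -> np.ndarray:
        """Per-nucleotide probabilities in A,C,G,T order."""
        c = self.gc_content
        return np.array([(1 - c) / 2, c / 2, c / 2, (1 - c) / 2])

    @property
    def mu(self) -> float:
        return mu_from_gc(self.gc_content)

    def sample(self, length: int, n: int, rng: np.random.Generator) -> list[str]:
        idx = rng.choice(4, size=(n, length), p=self.probs)
        return ["".join(ALPHABET[i] for i in row) for row in idx]


def mu_from_gc(c: float) -> float:
    """GC offset mu = log(c / (1 - c)), natural log."""
    if not 0.0 < c < 1.0:
        raise ValueError(f"GC content must lie strictly in (0, 1); got {c}")
    return math.log(c / (1.0 - c))


def metropolis_acceptance(
    d_current: float, d_proposed: float, delta_gc: int, beta: float, mu: float
) -> float:
    """Metropolis acceptance probability for a single-site proposal."""
    log_ratio = -beta * (d_proposed - d_current) + mu * delta_gc
    if log_ratio >= 0.0:
        return 1.0
    return math.exp(log_ratio)


@dataclass(frozen=True)
class SamplerConfig:
    beta: float
    mu: float = 0.0
    n_chains: int = 50
    proposals_per_chain: int = 100
    thin: int = 1
    seed: int = 0
    record_initial: bool = False
    burn_in: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.n_chains < 1 or self.proposals_per_chain < 1:
            raise ValueError("n_chains and proposals_per_chain must be positive")
        if not 1 <= self.thin <= self.proposals_per_chain:
            raise ValueError("thin must satisfy 1 <= thin <= proposals_per_chain")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")


@dataclass
class SampleSet:
    """Pooled MCMC output for one anchor."""

    anchor: EncodedSequence
    samples: list[str]
    acceptance_rate: float
    mean_distance: float
    config: SamplerConfig
    per_chain_acceptance: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _chain_rng(seed: int, chain: int) -> np.random.Generator:
    # Chain streams are derived from the master seed by spawn key, so adding
    # chains never reshuffles the streams of existing chains.
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(chain,)))
    )


def run_chains(model, weights: MetricWeights, anchor: EncodedSequence, config: SamplerConfig) -> SampleSet:
    """Run independent Metropolis chains initialized at the anchor.

    States are recorded every ``thin`` proposals (after ``burn_in`` unrecorded
    proposals), pooled over chains.  Returns per-chain and pooled acceptance
    rates and the Monte-Carlo estimate of the mean anchor distance D.
    """
    if model.input_length is not None and anchor.length != model.input_length:
        raise ValueError("anchor length does not match model input length")
    W = np.asarray(weights.W, dtype=float)
    phi0 = np.asarray(model.phi(anchor), dtype=float)
    if W.shape != phi0.shape:
        raise ValueError("metric weight length does not match penultimate size")

    rows = anchor.row_table()
    anchor_idx = anchor.indices
    L = anchor.length

    samples: list[str] = []
    distances: list[float] = []
    acc_per_chain = np.zeros(config.n_chains)
    total_steps = config.burn_in + config.proposals_per_chain

    for chain in range(config.n_chains):
        rng = _chain_rng(config.seed, chain)
        idx = anchor_idx.copy()
        enc = rows[idx].copy()
        d_cur = 0.0
        accepted = 0

        positions = rng.integers(0, L, size=total_steps)
        alt_draws = rng.integers(0, 3, size=total_steps)
        unif = rng.random(total_steps)

        if config.record_initial:
            samples.append(anchor.bases)
            distances.append(0.0)

        for t in range(total_steps):
            pos = positions[t]
            old = idx[pos]
            new = alt_draws[t]
            if new >= old:
                new += 1  # uniform over the 3 alternatives
            enc[pos] = rows[new]
            phi_prop = model.phi(enc)
            diff = phi0 - phi_prop
            d_prop = float(np.sqrt(np.sum((W * diff) ** 2)))
            delta_gc = int(_IS_GC[new] - _IS_GC[old])
            log_ratio = -config.beta * (d_prop - d_cur) + config.mu * delta_gc
            if log_ratio >= 0.0 or unif[t] < math.exp(log_ratio):
                idx[pos] = new
                d_cur = d_prop
                accepted += 1
            else:
                enc[pos] = rows[old]
            rec = t - config.burn_in + 1
            if rec > 0 and rec % config.thin == 0:
                samples.append("".join(ALPHABET[i] for i in idx))
                distances.append(d_cur)

        acc_per_chain[chain] = accepted / total_steps

    return SampleSet(
        anchor=anchor,
        samples=samples,
        acceptance_rate=float(acc_per_chain.mean()),
        mean_distance=float(np.mean(distances)) if distances else 0.0,
        config=config,
        per_chain_acceptance=acc_per_chain,
    )


def select_beta(model, weights: MetricWeights, anchors, R: float, epsilon: float) -> float:
    """Choose beta from nearest-neighbor distances among anchor activations.

    For each anchor x_i, let D_i = max(d(phi(x_i), phi(x_NN)), epsilon) with
    x_NN its nearest neighbor among the supplied anchors.  Solving
    exp(-beta_i * D_i) = R gives beta_i = -ln(R) / D_i; the returned beta is
    the mean over anchors.  R sets how far the sampled mass has decayed at
    the nearest-neighbor scale; epsilon guards against duplicate activations.
    """
    anchors = list(anchors)
    if len(anchors) < 2:
        raise ValueError("select_beta needs at least 2 anchors for nearest neighbors")
    if not 0.0 < R < 1.0:
        raise ValueError("R must lie strictly in (0, 1)")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    phis = np.array([model.phi(a) for a in anchors], dtype=float)
    W = np.asarray(weights.W, dtype=float)
    scaled = phis * W[None, :]
    diff = scaled[:, None, :] - scaled[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    D = np.maximum(nn, epsilon)
    betas = -math.log(R) / D
    return float(betas.mean())
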