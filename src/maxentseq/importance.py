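"""Input-wide feature importance from MaxEnt samples.

An input-wide feature V maps a sequence to a weighted sum of per-position
nucleotide indicator variables, V(x) = sum_i c_i I_i(x_i) (its value on a
sequence is the "concordance").  The importance of V to the network's
representation of an anchor is scored by

    delta = 1 / s^2  -  1 / sigma^2

where s^2 is the variance of V over the anchored MaxEnt samples and sigma^2
its variance under the i.i.d. background q (available in closed form).  A
feature the network constrains has s^2 << sigma^2 and hence large delta
(approximately 1/s^2 in that regime); an unconstrained feature has delta
near 0.  Significance is assessed against "dummy" features whose indicator
set at each position is a random unordered nucleotide pair; feature
discovery uses the lowest-variance principal components of the sample
indicator tracks, since Var(V) = c^T S c is minimized over unit-norm weight
vectors c by the bottom eigenvectors of the indicator covariance S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import ALPHABET
from .profiles import sequences_to_indices, _sample_list
from .sampler import BackgroundModel, SampleSet

__all__ = [
    "InputWideFeature",
    "ImportanceResult",
    "PCFeatureSet",
    "NUCLEOTIDE_PAIRS",
    "concordance",
    "concordance_many",
    "background_variance",
    "delta_score",
    "dummy_percentile",
    "low_variance_pcs",
]

# The six unordered 2-nucleotide indicator sets used for dummy features.
NUCLEOTIDE_PAIRS = (
    frozenset("GC"),
    frozenset("GA"),
    frozenset("GT"),
    frozenset("CA"),
    frozenset("CT"),
    frozenset("AT"),
)


@dataclass(frozen=True)
class InputWideFeature:
    """V(x) = sum_i c_i I_i(x_i) over a set of positions.

    ``indicator_sets[j]`` is the subset of {A,C,G,T} scoring 1 at
    ``positions[j]``; ``weights[j]`` is the real weight c_j.
    """

    positions: tuple[int, ...]
    indicator_sets: tuple[frozenset, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.positions) == len(self.indicator_sets) == len(self.weights)):
            raise ValueError("positions, indicator_sets and weights must align")
        if len(self.positions) == 0:
            raise ValueError("feature must cover at least one position")
        for s in self.indicator_sets:
            if not 0 < len(s) < 4:
                raise ValueError("indicator sets must be non-empty proper subsets of ACGT")
            if not set(s) <= set(ALPHABET):
                raise ValueError(f"invalid nucleotides in indicator set {set(s)}")
        if min(self.positions) < 0:
            raise ValueError("positions must be non-negative")

    @classmethod
    def gc_content(cls, region: range | tuple[int, int]) -> "InputWideFeature":
        """Unit-weight strong-nucleotide (G/C) feature over a position range."""
        if isinstance(region, tuple):
            region = range(region[0], region[1])
        pos = tuple(region)
        return cls(
            positions=pos,
            indicator_sets=(frozenset("GC"),) * len(pos),
            weights=(1.0,) * len(pos),
        )

    def membership_matrix(self) -> np.ndarray:
        """(n_positions, 4) 0/1 matrix: entry [j, b] = I_j(base b)."""
        m = np.zeros((len(self.positions), 4))
        for j, s in enumerate(self.indicator_sets):
            for b in s:
                m[j, ALPHABET.index(b)] = 1.0
        return m


@dataclass
class ImportanceResult:
    s2: float
    sigma2: float
    delta: float
    percentile: float | None = None


@dataclass
class PCFeatureSet:
    """Eigendecomposition of the per-position indicator covariance S.

    ``pc_vectors`` columns are orthonormal weight vectors c with
    c^T S c = pc_variances (ascending); the lowest-variance columns are the
    discovered input-wide features.
    """

    covariance: np.ndarray
    pc_vectors: np.ndarray
    pc_variances: np.ndarray
    indicator_set: frozenset = frozenset("GC")


def concordance(feature: InputWideFeature, bases: str) -> float:
    """V(x) for a single sequence."""
    if max(feature.positions) >= len(bases):
        raise ValueError(
            f"feature position {max(feature.positions)} out of range for "
            f"length-{len(bases)} sequence"
        )
    total = 0.0
    for pos, s, c in zip(feature.positions, feature.indicator_sets, feature.weights):
        if bases[pos] in s:
            total += c
    return total


def concordance_many(feature: InputWideFeature, samples) -> np.ndarray:
    """Vectorized V(x) over a SampleSet or list of equal-length sequences."""
    seqs = _sample_list(samples)
    idx = sequences_to_indices(seqs)
    if max(feature.positions) >= idx.shape[1]:
        raise ValueError("feature positions out of range for samples")
    sub = idx[:, list(feature.positions)]  # (n, npos)
    memb = feature.membership_matrix()  # (npos, 4)
    hits = memb[np.arange(sub.shape[1])[None, :], sub]  # (n, npos)
    return hits @ np.asarray(feature.weights, dtype=float)


def background_variance(feature: InputWideFeature, background: BackgroundModel) -> float:
    """sigma^2 = sum_i c_i^2 p_i (1 - p_i) under the i.i.d. background."""
    probs = background.probs
    memb = feature.membership_matrix()
    p = memb @ probs
    c = np.asarray(feature.weights, dtype=float)
    return float(np.sum(c**2 * p * (1.0 - p)))


def delta_score(samples, feature: InputWideFeature, background: BackgroundModel) -> ImportanceResult:
    """delta = 1/s^2 - 1/sigma^2 with s^2 the unbiased sample variance of V.

    A feature completely frozen by high-beta sampling has s^2 = 0; delta is
    then reported as the +inf sentinel (a frozen feature outranks any finite
    score) rather than raising.
    """
    v = concordance_many(feature, samples)
    if v.shape[0] < 2:
        raise ValueError("delta_score needs at least 2 samples")
    s2 = float(np.var(v, ddof=1))
    sigma2 = background_variance(feature, background)
    if sigma2 <= 0:
        raise ValueError("background variance is zero; degenerate feature")
    if s2 == 0.0:
        warnings.warn("feature is frozen in samples (zero variance); delta = +inf", stacklevel=2)
        return ImportanceResult(s2=0.0, sigma2=sigma2, delta=np.inf)
    return ImportanceResult(s2=s2, sigma2=sigma2, delta=1.0 / s2 - 1.0 / sigma2)


def _random_dummy(region: tuple[int, ...], rng: np.random.Generator) -> InputWideFeature:
    picks = rng.integers(0, len(NUCLEOTIDE_PAIRS), size=len(region))
    return InputWideFeature(
        positions=region,
        indicator_sets=tuple(NUCLEOTIDE_PAIRS[i] for i in picks),
        weights=(1.0,) * len(region),
    )


def dummy_percentile(
    samples,
    feature: InputWideFeature,
    region,
    background: BackgroundModel,
    n_dummies: int = 300,
    seed: int = 0,
) -> ImportanceResult:
    """Percentile of the feature's delta within a dummy-feature null.

    Dummies carry unit weights over ``region`` with a 2-nucleotide indicator
    set drawn uniformly per position from the six unordered pairs, making
    them exchangeable with a unit-weight target under the background.
    Returns the target's ImportanceResult with ``percentile`` filled in
    (midrank convention for ties).
    """
    if n_dummies < 2:
        raise ValueError("n_dummies must be at least 2")
    region = tuple(region)  # accepts a range or any iterable of positions
    rng = np.random.default_rng(seed)
    result = delta_score(samples, feature, background)
    deltas = np.empty(n_dummies)
    for j in range(n_dummies):
        dummy = _random_dummy(region, rng)
        deltas[j] = delta_score(samples, dummy, background).delta
    less = np.sum(deltas < result.delta)
    equal = np.sum(deltas == result.delta)
    result.percentile = float(100.0 * (less + 0.5 * equal) / n_dummies)
    return result


def low_variance_pcs(samples, indicator_set=frozenset("GC")) -> PCFeatureSet:
    """PCA of per-position indicator tracks, eigenvalues ascending.

    Maps each sample to its L-length binary indicator track (default:
    strong nucleotides), forms the covariance matrix S of the tracks, and
    eigendecomposes it.  The bottom eigenvectors are unit-norm weight
    vectors minimizing Var(V) = c^T S c, i.e. the most tightly constrained
    input-wide features.  Eigenvector signs follow the convention that the
    largest-magnitude entry is positive.
    """
    seqs = _sample_list(samples)
    if not seqs:
        raise ValueError("empty sample set")
    idx = sequences_to_indices(seqs)
    n, L = idx.shape
    if n < L:
        warnings.warn(
            f"only {n} samples for {L} positions; covariance is rank-deficient",
            stacklevel=2,
        )
    memb = np.zeros(4)
    for b in indicator_set:
        memb[ALPHABET.index(b)] = 1.0
    tracks = memb[idx]  # (n, L)
    S = np.cov(tracks, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)  # ascending
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return PCFeatureSet(
        covariance=S,
        pc_vectors=evecs,
        pc_variances=np.maximum(evals, 0.0),
        indicator_set=frozenset(indicator_set),
    )
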