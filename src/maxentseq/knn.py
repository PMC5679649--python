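"""Nearest-neighbor classification with per-exemplar low-variance PC metrics.

Each exemplar summarizes the MaxEnt samples of one anchored sequence by the
element-wise mean of their binary strong/weak indicator tracks together with
the m lowest-variance principal components of those tracks.  The distance
from a test track to an exemplar projects the displacement onto the
exemplar's PC basis and scales each coordinate by the inverse standard
deviation, so directions the network held fixed for that anchor count
heavily while free directions are ignored.  Replacing the learned bases with
random orthonormal bases (QR of a Gaussian matrix) is the control that
verifies any classification signal really lives in the learned directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .importance import PCFeatureSet, low_variance_pcs
from .profiles import _sample_list, sequences_to_indices, ws_track

__all__ = [
    "Exemplar",
    "build_exemplar",
    "pc_distance",
    "knn_classify",
    "classify_tracks",
    "random_orthogonal_basis",
]


@dataclass
class Exemplar:
    mean_track: np.ndarray
    pc_basis: np.ndarray  # (L, m), orthonormal columns
    pc_scales: np.ndarray  # (m,) standard deviations along the basis
    label: int


def build_exemplar(
    samples,
    pcs: PCFeatureSet | None,
    label: int,
    m: int = 5,
    variance_floor: float = 1e-6,
) -> Exemplar:
    """Summarize a SampleSet as an exemplar with an m-dimensional PC metric.

    ``pcs`` should be the PCFeatureSet of the same samples (computed if
    None).  ``variance_floor`` bounds the smallest PC variance away from
    zero before inverse-scaling: at high beta some directions are exactly
    frozen and would otherwise yield infinite distances.
    """
    seqs = _sample_list(samples)
    if pcs is None:
        pcs = low_variance_pcs(samples)
    L = pcs.pc_vectors.shape[0]
    if not 1 <= m <= L:
        raise ValueError(f"m must satisfy 1 <= m <= {L}")
    idx = sequences_to_indices(seqs)
    memb = np.zeros(4)
    from .network import ALPHABET

    for b in pcs.indicator_set:
        memb[ALPHABET.index(b)] = 1.0
    tracks = memb[idx]
    mean_track = tracks.mean(axis=0)
    basis = pcs.pc_vectors[:, :m].copy()
    scales = np.sqrt(np.maximum(pcs.pc_variances[:m], variance_floor))
    return Exemplar(mean_track=mean_track, pc_basis=basis, pc_scales=scales, label=label)


def pc_distance(test_track: np.ndarray, ex: Exemplar) -> float:
    """Scaled Euclidean distance in the exemplar's PC subspace."""
    t = np.asarray(test_track, dtype=float)
    if t.shape != ex.mean_track.shape:
        raise ValueError("test track length does not match exemplar")
    coords = ex.pc_basis.T @ (t - ex.mean_track)
    return float(np.sqrt(np.sum((coords / ex.pc_scales) ** 2)))


def knn_classify(test_track: np.ndarray, exemplars: list[Exemplar], k: int = 10) -> int:
    """Majority vote over the k nearest exemplars.

    Distance ties break by exemplar order (stable sort); vote ties break to
    the lowest class label.
    """
    if not 1 <= k <= len(exemplars):
        raise ValueError(f"k must satisfy 1 <= k <= {len(exemplars)}")
    dists = np.array([pc_distance(test_track, ex) for ex in exemplars])
    order = np.argsort(dists, kind="stable")[:k]
    votes: dict[int, int] = {}
    for i in order:
        votes[exemplars[i].label] = votes.get(exemplars[i].label, 0) + 1
    best = max(votes.values())
    return min(lbl for lbl, n in votes.items() if n == best)


def classify_tracks(tracks: np.ndarray, exemplars: list[Exemplar], k: int = 10) -> np.ndarray:
    """knn_classify applied row-wise to an (n, L) array of test tracks."""
    return np.array([knn_classify(t, exemplars, k=k) for t in np.asarray(tracks, float)])


def random_orthogonal_basis(dim: int, m: int, seed) -> np.ndarray:
    """dim x m orthonormal matrix: QR of an i.i.d. standard-normal matrix.

    ``seed`` may be an int or a numpy Generator.  Column signs are fixed so
    the diagonal of R is positive, making the draw Haar-distributed on the
    Stiefel manifold and reproducible.
    """
    if m > dim:
        raise ValueError("m must not exceed dim")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_normal((dim, m))
    q, r = np.linalg.qr(g)
    q = q * np.sign(np.diag(r))[None, :]
    return q
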