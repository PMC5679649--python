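"""Synthetic data and exactly-constructed networks for the full pipeline.

Three study designs are emulated, matching the classification problems the
interpretation method targets:

* XOR-labeled dinucleotides: class 1 iff exactly one of (position 0 is W,
  position 1 is G) holds, drawn i.i.d. with P(A)=P(T)=0.3, P(G)=P(C)=0.2.
  Both an exact hand-weighted network and a NumPy SGD trainer for the
  2-filter convolutional architecture are provided.
* Motif-implanted positives vs dinucleotide-composition-matched negatives
  (Euler-path shuffles), plus a hand-built PWM-scanner network whose
  decision is a thresholded best-window log-odds score.
* Nucleosome-like sequences with a 10-bp periodic strong/weak preference
  and elevated GC content.

Planted-constraint background samplers (GC-variance-constrained,
direction-constrained, marked-position two-class) provide ground-truthed
inputs for the importance, PCA, and kNN components.

Every generator is seed-deterministic: the same seed yields byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .network import ALPHABET, BASE_INDEX, Conv1D, Dense, Flatten, GlobalMaxPool, SequentialModel
from .sampler import BackgroundModel

__all__ = [
    "xor_label",
    "generate_xor_dataset",
    "build_exact_xor_network",
    "train_xor_models",
    "XorTrainingResult",
    "random_pwm",
    "build_pwm_scanner_network",
    "dinucleotide_shuffle",
    "generate_motif_dataset",
    "MotifDataset",
    "generate_periodic_dataset",
    "PeriodicDataset",
    "sample_background",
    "sample_gc_constrained",
    "sample_direction_constrained",
    "sample_marked_positions",
]

_W_SET = frozenset("AT")


# ---------------------------------------------------------------------------
# XOR toy problem
# ---------------------------------------------------------------------------


def xor_label(dinucleotide: str) -> int:
    """Class 1 iff exactly one holds: position 0 is W (A/T); position 1 is G."""
    if len(dinucleotide) != 2:
        raise ValueError("XOR labels are defined on dinucleotides")
    for pos, b in enumerate(dinucleotide):
        if b not in BASE_INDEX:
            raise ValueError(f"invalid base {b!r} at position {pos}")
    cond1 = dinucleotide[0] in _W_SET
    cond2 = dinucleotide[1] == "G"
    return int(cond1 != cond2)


def generate_xor_dataset(
    n: int = 2000, p_at: float = 0.3, p_gc: float = 0.2, seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """i.i.d. dinucleotides with P(A)=P(T)=p_at, P(G)=P(C)=p_gc, XOR labels."""
    if abs(2 * p_at + 2 * p_gc - 1.0) > 1e-9 or p_at <= 0 or p_gc <= 0:
        raise ValueError("need 2*p_at + 2*p_gc = 1 with positive probabilities")
    rng = np.random.default_rng(seed)
    probs = np.array([p_at, p_gc, p_gc, p_at])  # A,C,G,T
    idx = rng.choice(4, size=(n, 2), p=probs)
    seqs = ["".join(ALPHABET[i] for i in row) for row in idx]
    labels = np.array([xor_label(s) for s in seqs], dtype=np.int64)
    return seqs, labels


def build_exact_xor_network(variant: str = "route_separating") -> SequentialModel:
    """Hand-weighted convolutional network solving the dinucleotide XOR task.

    Convolution (2 width-1 filters): filter 0 detects W, filter 1 detects G,
    at each of the two positions.  Let a = W-at-0 and b = G-at-1 (the other
    two conv activations enter the next layer with weight 0).

    * ``route_separating``: penultimate u1 = ReLU(a - b), u2 = ReLU(b - a);
      the two ways of satisfying the XOR occupy different penultimate units,
      so anchors AA and GG have distinct representations (1,0) and (0,1).
    * ``merged``: u1 = ReLU(a + b - 1) (AND), u2 = a + b (sum); both XOR
      routes map to the same penultimate vector (0,1).

    Output: sigmoid(s * (u1 + u2 - 1/2)) with s = 10 (route-separating), or
    the equivalent XOR readout for the merged variant.  All 16 dinucleotides
    are classified correctly by both variants.
    """
    conv = Conv1D(
        weights=np.array([[[1.0, 0.0, 0.0, 1.0]], [[0.0, 0.0, 1.0, 0.0]]]),
        bias=np.zeros(2),
        activation="relu",
    )
    # flattened conv order: (p0 f0, p0 f1, p1 f0, p1 f1) = (a, G-at-0, W-at-1, b)
    if variant == "route_separating":
        fc = Dense(
            weights=np.array([[1.0, 0.0, 0.0, -1.0], [-1.0, 0.0, 0.0, 1.0]]),
            bias=np.zeros(2),
            activation="relu",
        )
        out = Dense(weights=np.array([[10.0, 10.0]]), bias=np.array([-5.0]), activation="sigmoid")
    elif variant == "merged":
        fc = Dense(
            weights=np.array([[1.0, 0.0, 0.0, 1.0], [1.0, 0.0, 0.0, 1.0]]),
            bias=np.array([-1.0, 0.0]),
            activation="relu",
        )
        out = Dense(weights=np.array([[-20.0, 10.0]]), bias=np.array([-5.0]), activation="sigmoid")
    else:
        raise ValueError("variant must be 'route_separating' or 'merged'")
    return SequentialModel([conv, Flatten(), fc, out], input_length=2)


@dataclass
class XorTrainingResult:
    models: list[SequentialModel]
    accuracies: np.ndarray  # final accuracy on the 16 dinucleotides, per model
    epochs: np.ndarray  # epochs actually trained, per model


def _all_dinucleotides() -> tuple[list[str], np.ndarray, np.ndarray]:
    seqs = [a + b for a in ALPHABET for b in ALPHABET]
    X = np.stack([np.eye(4)[[BASE_INDEX[c] for c in s]] for s in seqs])
    y = np.array([xor_label(s) for s in seqs], dtype=float)
    return seqs, X, y


def train_xor_models(
    n_models: int,
    max_epochs: int = 40,
    lr: float = 5e-3,
    seed: int = 0,
    n_train: int = 2000,
    stability_epochs: int = 0,
) -> XorTrainingResult:
    """Train the 2-filter conv + 2-unit FC + sigmoid XOR architecture by SGD.

    Pure-NumPy trainer: Glorot-uniform initialization, per-sample stochastic
    gradient descent on the binary cross-entropy loss, ReLU hidden
    activations.  Each model draws its own fresh 2000-dinucleotide training
    set.  After every epoch the model is evaluated on the 16 distinct
    dinucleotides; training stops for a model once it classifies all 16
    correctly, or after ``max_epochs``.  ``stability_epochs`` optionally
    continues training converged models that many further epochs (their
    recorded accuracy is re-checked afterwards).

    All models are trained in parallel through vectorized updates, so the
    wall time is nearly independent of ``n_models``.
    """
    if n_models < 1:
        raise ValueError("n_models must be positive")
    rng = np.random.default_rng(seed)
    M = n_models

    def glorot(shape, fan_in, fan_out):
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    # conv: (M, 2 filters, 4 channels) width-1; fc: (M, 2, 4); out: (M, 2)
    Wc = glorot((M, 2, 4), 4, 2)
    bc = np.zeros((M, 2))
    Wf = glorot((M, 2, 4), 4, 2)
    bf = np.zeros((M, 2))
    wo = glorot((M, 2), 2, 1)
    bo = np.zeros(M)

    # fresh training data per model
    data = [generate_xor_dataset(n_train, seed=int(rng.integers(2**31))) for _ in range(M)]
    eye = np.eye(4)
    X_all = np.stack(
        [np.stack([eye[[BASE_INDEX[c] for c in s]] for s in seqs]) for seqs, _ in data]
    )  # (M, n_train, 2, 4)
    y_all = np.stack([labels.astype(float) for _, labels in data])  # (M, n_train)

    _, X16, y16 = _all_dinucleotides()

    def forward(X):  # X: (M, B, 2, 4) -> activations
        z1 = np.einsum("mbpc,mfc->mbpf", X, Wc) + bc[:, None, None, :]
        a1 = np.maximum(z1, 0.0)
        aflat = a1.reshape(M, X.shape[1], 4)  # (p0f0, p0f1, p1f0, p1f1)
        z2 = np.einsum("mbi,mji->mbj", aflat, Wf) + bf[:, None, :]
        h = np.maximum(z2, 0.0)
        logit = np.einsum("mbj,mj->mb", h, wo) + bo[:, None]
        y = 1.0 / (1.0 + np.exp(-logit))
        return a1, aflat, h, y

    def accuracy16():
        X = np.broadcast_to(X16[None], (M, 16, 2, 4))
        *_, y = forward(X)
        pred = (y > 0.5).astype(float)
        return (pred == y16[None, :]).mean(axis=1)

    active = np.ones(M, dtype=bool)
    epochs = np.zeros(M, dtype=np.int64)
    extra = np.zeros(M, dtype=np.int64)  # stability epochs consumed

    for epoch in range(max_epochs + stability_epochs):
        if not active.any() and stability_epochs == 0:
            break
        training = active | (extra < stability_epochs)
        if not training.any():
            break
        perm = np.argsort(rng.random((M, n_train)), axis=1)
        for b in range(n_train):
            sel = perm[:, b]
            X = X_all[np.arange(M), sel][:, None, :, :]  # (M, 1, 2, 4)
            t = y_all[np.arange(M), sel][:, None]  # (M, 1)
            a1, aflat, h, y = forward(X)
            g = (y - t) * training[:, None]  # dL/dlogit, frozen models masked
            dwo = np.einsum("mb,mbj->mj", g, h)
            dbo = g.sum(axis=1)
            dh = g[:, :, None] * wo[:, None, :]
            dh = dh * (h > 0)
            dWf = np.einsum("mbj,mbi->mji", dh, aflat)
            dbf = dh.sum(axis=1)
            daflat = np.einsum("mbj,mji->mbi", dh, Wf)
            da = daflat.reshape(M, 1, 2, 2) * (a1 > 0)
            dWc = np.einsum("mbpf,mbpc->mfc", da, X)
            dbc = da.sum(axis=(1, 2))
            Wc -= lr * dWc
            bc -= lr * dbc
            Wf -= lr * dWf
            bf -= lr * dbf
            wo -= lr * dwo
            bo -= lr * dbo
        acc = accuracy16()
        epochs[training] += 1
        newly_done = active & (acc >= 1.0)
        active &= acc < 1.0
        if stability_epochs:
            extra[~active & (epochs > 0)] += 1
            extra[newly_done] = 0
        if epoch + 1 >= max_epochs and not stability_epochs:
            break

    final_acc = accuracy16()
    models = []
    for m in range(M):
        layers = [
            Conv1D(weights=Wc[m][:, None, :].copy(), bias=bc[m].copy(), activation="relu"),
            Flatten(),
            Dense(weights=Wf[m].copy(), bias=bf[m].copy(), activation="relu"),
            Dense(weights=wo[m][None, :].copy(), bias=bo[m : m + 1].copy(), activation="sigmoid"),
        ]
        models.append(SequentialModel(layers, input_length=2))
    return XorTrainingResult(models=models, accuracies=final_acc, epochs=epochs)


# ---------------------------------------------------------------------------
# Motif scanner problem
# ---------------------------------------------------------------------------


def random_pwm(width: int, seed: int = 0, consensus_prob: float = 0.85) -> np.ndarray:
    """Informative random PWM: one consensus base per column at the given
    probability, remainder spread evenly."""
    if not 0.25 < consensus_prob <= 1.0:
        raise ValueError("consensus_prob must exceed 0.25")
    rng = np.random.default_rng(seed)
    pwm = np.full((width, 4), (1.0 - consensus_prob) / 3.0)
    cons = rng.integers(0, 4, size=width)
    pwm[np.arange(width), cons] = consensus_prob
    return pwm


def build_pwm_scanner_network(pwm: np.ndarray, threshold: float | None = None, gain: float = 1.0) -> SequentialModel:
    """Hand-built network whose decision is a thresholded best-window PWM score.

    A single convolutional filter carries the log-odds PWM (vs uniform
    background); global max pooling extracts the best window score m; the
    penultimate units are u1 = ReLU(gain*(m - threshold)) and
    u2 = ReLU(gain*(threshold - m)); the sigmoid output fires iff m exceeds
    the threshold.  Default threshold: half the consensus score, which
    separates implanted-motif windows from background maxima for informative
    PWMs.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4 or not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pwm must be a (width, 4) matrix with rows summing to 1")
    logodds = np.log(np.clip(pwm, 1e-3, None) / 0.25)
    if threshold is None:
        threshold = 0.5 * float(logodds.max(axis=1).sum())
    conv = Conv1D(weights=logodds[None, :, :], bias=np.zeros(1), activation="linear")
    fc = Dense(
        weights=np.array([[gain], [-gain]]),
        bias=np.array([-gain * threshold, gain * threshold]),
        activation="relu",
    )
    out = Dense(weights=np.array([[4.0, -4.0]]), bias=np.zeros(1), activation="sigmoid")
    # length-agnostic: conv + global max pool work for any L >= pwm width
    return SequentialModel([conv, GlobalMaxPool(), fc, out], input_length=None)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random shuffle preserving exact dinucleotide counts (Euler-path method).

    Treats the sequence as an Eulerian path on the graph whose vertices are
    the distinct bases and whose edges are the observed dinucleotides; picks
    a random "last edge" arborescence into the final base and shuffles the
    remaining out-edges (Altschul-Erickson construction), then rewalks.
    """
    if len(seq) < 3 or len(set(seq)) < 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges.keys() | set(seq))
    last_vertex = seq[-1]

    def reaches_end(last: dict[str, str]) -> bool:
        for v in last:
            cur, hops = v, 0
            while cur != last_vertex and hops <= len(vertices):
                if cur not in last:
                    return False
                cur = last[cur]
                hops += 1
            if cur != last_vertex:
                return False
        return True

    while True:
        last = {
            v: outs[rng.integers(len(outs))]
            for v, outs in edges.items()
            if v != last_vertex
        }
        if reaches_end(last):
            break

    shuffled: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in last:
            rest.remove(last[v])
        rng.shuffle(rest)
        if v in last:
            rest.append(last[v])
        shuffled[v] = rest

    out = [seq[0]]
    ptr = {v: 0 for v in shuffled}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class MotifDataset:
    positives: list[str]
    negatives: list[str]
    offsets: np.ndarray
    pwm: np.ndarray


def generate_motif_dataset(
    n_pos: int,
    n_neg: int,
    L: int = 101,
    pwm: np.ndarray | None = None,
    offset_distribution=None,
    seed: int = 0,
    background: BackgroundModel | None = None,
) -> MotifDataset:
    """Motif-implanted positives and dinucleotide-matched shuffled negatives.

    Positives are background draws with a PWM sample implanted at an offset
    drawn from ``offset_distribution`` (callable rng -> int; default uniform
    over valid offsets).  Negatives are Euler-path shuffles of positives
    (cycling through them when n_neg > n_pos), preserving dinucleotide
    counts exactly.  True offsets are returned for recovery tests.
    """
    rng = np.random.default_rng(seed)
    if pwm is None:
        pwm = random_pwm(19, seed=seed)
    pwm = np.asarray(pwm, dtype=float)
    w = pwm.shape[0]
    if w > L:
        raise ValueError("pwm width exceeds sequence length")
    if background is None:
        background = BackgroundModel(0.46)
    probs = background.probs
    offsets = np.empty(n_pos, dtype=np.int64)
    positives = []
    for i in range(n_pos):
        idx = rng.choice(4, size=L, p=probs)
        off = offset_distribution(rng) if offset_distribution else int(rng.integers(0, L - w + 1))
        offsets[i] = off
        for j in range(w):
            idx[off + j] = rng.choice(4, p=pwm[j])
        positives.append("".join(ALPHABET[k] for k in idx))
    negatives = [dinucleotide_shuffle(positives[i % n_pos], rng) for i in range(n_neg)]
    return MotifDataset(positives=positives, negatives=negatives, offsets=offsets, pwm=pwm)


# ---------------------------------------------------------------------------
# Periodic (nucleosome-like) problem
# ---------------------------------------------------------------------------


@dataclass
class PeriodicDataset:
    positives: list[str]
    negatives: list[str]
    s_prob: np.ndarray  # per-position P(strong) of the positive class


def generate_periodic_dataset(
    n_pos: int,
    n_neg: int,
    L: int = 201,
    period: float = 10.0,
    amplitude: float = 0.1,
    gc_shift: float = 0.1,
    base_gc: float = 0.38,
    seed: int = 0,
) -> PeriodicDataset:
    """Sequences with 10-bp periodic strong/weak preference and elevated GC.

    Positives: P(S at i) = base_gc + gc_shift + amplitude*cos(2*pi*i/period)
    (strong base then G or C equally, weak base then A or T equally).
    Negatives: flat P(S) = base_gc.
    """
    i = np.arange(L)
    p_s = base_gc + gc_shift + amplitude * np.cos(2 * np.pi * i / period)
    if np.any(p_s <= 0) or np.any(p_s >= 1):
        raise ValueError("per-position strong probability leaves (0, 1)")
    rng = np.random.default_rng(seed)

    def draw(p_track, n):
        out = []
        for _ in range(n):
            strong = rng.random(L) < p_track
            gc_pick = rng.random(L) < 0.5
            at_pick = rng.random(L) < 0.5
            bases = np.where(strong, np.where(gc_pick, "G", "C"), np.where(at_pick, "A", "T"))
            out.append("".join(bases))
        return out

    positives = draw(p_s, n_pos)
    negatives = draw(np.full(L, base_gc), n_neg)
    return PeriodicDataset(positives=positives, negatives=negatives, s_prob=p_s)


# ---------------------------------------------------------------------------
# Planted-constraint background samplers
# ---------------------------------------------------------------------------


def sample_background(background: BackgroundModel, L: int, n: int, seed: int = 0) -> list[str]:
    """n i.i.d. draws of length L from the background q."""
    rng = np.random.default_rng(seed)
    return background.sample(L, n, rng)


def sample_gc_constrained(
    background: BackgroundModel,
    L: int,
    positions,
    variance_ratio: float,
    n: int,
    seed: int = 0,
) -> list[str]:
    """Background samples with the GC count over ``positions`` constrained.

    Exact sampler for the Gaussian-tilted distribution
    q(x) * exp(-lambda * (V(x) - E_q V)^2), where V counts strong bases over
    the given positions.  lambda is solved numerically so that the tilted
    variance of V is exactly ``variance_ratio`` times its background value
    sigma^2 = n_pos * c * (1 - c); the marginal of V is then sampled from
    the tilted binomial and sequences are assembled position-exchangeably.
    """
    positions = np.asarray(list(positions), dtype=np.int64)
    npos = len(positions)
    c = background.gc_content
    if not 0 < variance_ratio < 1:
        raise ValueError("variance_ratio must lie in (0, 1)")
    v = np.arange(npos + 1)
    log_binom = gammaln(npos + 1) - gammaln(v + 1) - gammaln(npos - v + 1)
    log_q = log_binom + v * math.log(c) + (npos - v) * math.log(1 - c)
    v0 = npos * c
    sigma2 = npos * c * (1 - c)

    def tilted_var(lam):
        logw = log_q - lam * (v - v0) ** 2
        w = np.exp(logw - logw.max())
        w /= w.sum()
        mean = np.sum(w * v)
        return np.sum(w * (v - mean) ** 2)

    target = variance_ratio * sigma2
    lam = brentq(lambda l: tilted_var(l) - target, 0.0, 1e3, xtol=1e-12)
    logw = log_q - lam * (v - v0) ** 2
    w = np.exp(logw - logw.max())
    w /= w.sum()

    rng = np.random.default_rng(seed)
    counts = rng.choice(npos + 1, size=n, p=w)
    pos_set = set(int(p) for p in positions)
    free = [i for i in range(L) if i not in pos_set]
    probs = background.probs
    out = []
    for k in counts:
        row = np.empty(L, dtype="<U1")
        strong_sites = rng.choice(npos, size=k, replace=False)
        strong_mask = np.zeros(npos, dtype=bool)
        strong_mask[strong_sites] = True
        gc_pick = rng.random(npos) < 0.5
        at_pick = rng.random(npos) < 0.5
        row[positions] = np.where(
            strong_mask, np.where(gc_pick, "G", "C"), np.where(at_pick, "A", "T")
        )
        if free:
            row[free] = [ALPHABET[i] for i in rng.choice(4, size=len(free), p=probs)]
        out.append("".join(row))
    return out


def sample_direction_constrained(
    c_star: np.ndarray,
    background: BackgroundModel,
    strength: float,
    n: int,
    seed: int = 0,
    thin_sweeps: int = 2,
    burn_in_sweeps: int = 10,
) -> list[str]:
    """Background samples with a planted soft linear constraint on the S-track.

    Metropolis sampling of binary strong/weak tracks t under
    q(t) * exp(-strength * (c_star . t - v0)^2), v0 = c_star . (c * 1).
    Strong positions become G or C uniformly, weak positions A or T.  Used
    as ground truth for low-variance PC recovery: the lowest-variance
    principal direction of the sampled tracks should align with c_star.
    """
    c_star = np.asarray(c_star, dtype=float)
    L = c_star.shape[0]
    c = background.gc_content
    v0 = float(c_star.sum() * c)
    log_odds = math.log(c / (1 - c))
    rng = np.random.default_rng(seed)
    t = (rng.random(L) < c).astype(float)
    dot = float(c_star @ t)
    out_tracks = np.empty((n, L))
    total_sweeps = burn_in_sweeps + n * thin_sweeps
    kept = 0
    for sweep in range(total_sweeps):
        sites = rng.integers(0, L, size=L)
        us = rng.random(L)
        for s_i, u in zip(sites, us):
            delta_t = 1.0 - 2.0 * t[s_i]  # +1 if flipping 0->1
            new_dot = dot + delta_t * c_star[s_i]
            dlog = delta_t * log_odds - strength * ((new_dot - v0) ** 2 - (dot - v0) ** 2)
            if dlog >= 0 or u < math.exp(dlog):
                t[s_i] += delta_t
                dot = new_dot
        if sweep >= burn_in_sweeps and (sweep - burn_in_sweeps + 1) % thin_sweeps == 0:
            if kept < n:
                out_tracks[kept] = t
                kept += 1
    gc_pick = rng.random((n, L)) < 0.5
    at_pick = rng.random((n, L)) < 0.5
    seqs = []
    for k in range(n):
        bases = np.where(
            out_tracks[k] > 0.5,
            np.where(gc_pick[k], "G", "C"),
            np.where(at_pick[k], "A", "T"),
        )
        seqs.append("".join(bases))
    return seqs


def sample_marked_positions(
    n: int,
    L: int,
    positions,
    s_prob_at_positions: float,
    background: BackgroundModel,
    seed: int = 0,
) -> list[str]:
    """Background samples with chosen positions biased to strong (or weak) bases.

    Marked positions are strong with probability ``s_prob_at_positions``
    (near 1 plants a strong-base pattern, near 0 a weak-base pattern); all
    other positions follow the background.  Two-class kNN fixtures use one
    pattern per class.
    """
    positions = np.asarray(list(positions), dtype=np.int64)
    rng = np.random.default_rng(seed)
    probs = background.probs
    out = []
    for _ in range(n):
        idx = rng.choice(4, size=L, p=probs)
        strong = rng.random(len(positions)) < s_prob_at_positions
        gc_pick = rng.random(len(positions)) < 0.5
        at_pick = rng.random(len(positions)) < 0.5
        for j, p in enumerate(positions):
            if strong[j]:
                idx[p] = 2 if gc_pick[j] else 1  # G or C
            else:
                idx[p] = 0 if at_pick[j] else 3  # A or T
        out.append("".join(ALPHABET[i] for i in idx))
    return out
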