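"""Feature readouts from MaxEnt samples: frequency profiles, motif calls,
and normalized Fourier periodicity spectra.

Per-position nucleotide frequencies of the samples play the role of a
position-specific scoring matrix: positions whose sample distribution
diverges from the background are the ones the network relies on.  Motif
calling finds the fixed-width window maximizing the mean per-position KL
divergence from a reference distribution.  Periodicity (e.g. the 10-bp
weak/strong alternation characteristic of nucleosomal DNA) is quantified
with discrete Fourier amplitudes normalized to unit Euclidean norm after
removing the zero-frequency component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import ALPHABET, BASE_INDEX
from .sampler import BackgroundModel, SampleSet

__all__ = [
    "NucleotideProfile",
    "MotifCall",
    "FourierSpectrum",
    "nucleotide_frequencies",
    "kl_profile",
    "call_motif",
    "normalized_fourier",
    "mean_spectrum",
    "profile_spectrum",
    "per_sample_spectrum",
    "ws_track",
]

_S_SET = frozenset("GC")


def _sample_list(samples) -> list[str]:
    if isinstance(samples, SampleSet):
        return samples.samples
    return list(samples)


def sequences_to_indices(seqs: list[str]) -> np.ndarray:
    """(n, L) array of base indices (A,C,G,T -> 0..3)."""
    if not seqs:
        raise ValueError("empty sample set")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), len(seqs[0]))
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    idx = lut[arr]
    if np.any(idx < 0):
        raise ValueError("samples contain non-ACGT characters")
    return idx.astype(np.int64)


@dataclass
class NucleotideProfile:
    """L x 4 per-position sample frequencies (rows sum to 1)."""

    freq: np.ndarray
    n_samples: int
    background: BackgroundModel | None = None

    @property
    def length(self) -> int:
        return self.freq.shape[0]


@dataclass
class MotifCall:
    start: int
    width: int
    pssm: np.ndarray
    mean_kl: float


@dataclass
class FourierSpectrum:
    """Amplitudes per period L/k, k = 1..floor(L/2), unit Euclidean norm."""

    periods: np.ndarray
    normalized_amplitude: np.ndarray
    degenerate: bool = False

    def amplitude_at_period(self, period: float) -> float:
        """Amplitude at the spectral period closest to ``period``."""
        i = int(np.argmin(np.abs(self.periods - period)))
        return float(self.normalized_amplitude[i])

    @property
    def peak_period(self) -> float:
        return float(self.periods[int(np.argmax(self.normalized_amplitude))])


def nucleotide_frequencies(samples, background: BackgroundModel | None = None) -> NucleotideProfile:
    """Per-position nucleotide frequencies of a SampleSet (or sequence list)."""
    seqs = _sample_list(samples)
    idx = sequences_to_indices(seqs)
    n, L = idx.shape
    counts = np.zeros((L, 4))
    for b in range(4):
        counts[:, b] = np.sum(idx == b, axis=0)
    return NucleotideProfile(freq=counts / n, n_samples=n, background=background)


def kl_profile(profile: NucleotideProfile, reference=None, alpha: float = 0.5) -> np.ndarray:
    """Per-position KL divergence (nats) of sample frequencies from a reference.

    A pseudocount ``alpha`` is added to each nucleotide count before
    normalization so that positions frozen by high-beta sampling yield a
    finite divergence.  ``reference`` may be a length-4 PMF (broadcast to all
    positions), an (L, 4) per-position PMF, or None for uniform.
    """
    L = profile.length
    if reference is None:
        ref = np.full((L, 4), 0.25)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape == (4,):
            ref = np.broadcast_to(ref, (L, 4)).copy()
        if ref.shape != (L, 4):
            raise ValueError("reference must be a length-4 PMF or an (L, 4) matrix")
        if np.any(ref <= 0) or not np.allclose(ref.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("reference rows must be strictly positive PMFs")
    counts = profile.freq * profile.n_samples + alpha
    p = counts / counts.sum(axis=1, keepdims=True)
    return np.sum(p * np.log(p / ref), axis=1)


def call_motif(kl: np.ndarray, profile: NucleotideProfile, width: int = 19) -> MotifCall:
    """Leftmost fixed-width window with the largest mean KL divergence."""
    kl = np.asarray(kl, dtype=float)
    L = kl.shape[0]
    if not 1 <= width <= L:
        raise ValueError(f"width {width} exceeds profile length {L}")
    window_means = np.convolve(kl, np.ones(width), mode="valid") / width
    start = int(np.argmax(window_means))  # argmax is leftmost on ties
    pssm = profile.freq[start : start + width].copy()
    return MotifCall(start=start, width=width, pssm=pssm, mean_kl=float(window_means[start]))


def normalized_fourier(signal) -> FourierSpectrum:
    """Normalized DFT amplitude spectrum of a real signal.

    The zero-frequency component is set to 0, the remaining (non-negative
    frequency) components are divided by their overall Euclidean norm, and
    the amplitude is reported per period L/k for k = 1..floor(L/2).  For a
    constant signal the norm vanishes; an all-zero spectrum is returned with
    ``degenerate=True`` and a warning.
    """
    x = np.asarray(signal, dtype=float)
    L = x.shape[0]
    if L < 4:
        raise ValueError("signal must have length >= 4")
    X = np.fft.rfft(x)[1:]  # drop zero frequency
    ks = np.arange(1, L // 2 + 1)
    X = X[: len(ks)]
    periods = L / ks
    norm = np.sqrt(np.sum(np.abs(X) ** 2))
    # rfft of a constant leaves O(eps) residuals in the nonzero frequencies
    if norm <= 1e-10 * max(1.0, float(np.max(np.abs(x))) * L):
        warnings.warn("constant signal: Fourier spectrum is degenerate", stacklevel=2)
        return FourierSpectrum(periods=periods, normalized_amplitude=np.zeros(len(ks)), degenerate=True)
    return FourierSpectrum(periods=periods, normalized_amplitude=np.abs(X) / norm)


def mean_spectrum(spectra_or_signals) -> FourierSpectrum:
    """Element-wise mean of normalized amplitude spectra.

    Accepts either FourierSpectrum objects or raw signals (transformed
    individually first).
    """
    items = list(spectra_or_signals)
    if not items:
        raise ValueError("empty input")
    spectra = [
        s if isinstance(s, FourierSpectrum) else normalized_fourier(s) for s in items
    ]
    periods = spectra[0].periods
    for s in spectra[1:]:
        if s.periods.shape != periods.shape or not np.allclose(s.periods, periods):
            raise ValueError("spectra have mismatched period grids")
    amp = np.mean([s.normalized_amplitude for s in spectra], axis=0)
    return FourierSpectrum(
        periods=periods,
        normalized_amplitude=amp,
        degenerate=all(s.degenerate for s in spectra),
    )


def ws_track(bases: str) -> np.ndarray:
    """Binary weak/strong indicator: 1 for G or C (strong), 0 for A or T."""
    return np.array([1.0 if b in _S_SET else 0.0 for b in bases])


def profile_spectrum(profile: NucleotideProfile) -> FourierSpectrum:
    """Profile-level periodicity spectrum.

    The four per-nucleotide frequency tracks are transformed and normalized
    separately and their amplitude spectra averaged, so that a periodic
    preference visible in any nucleotide channel registers regardless of
    which channels carry it.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mean_spectrum([profile.freq[:, b] for b in range(4)])


def per_sample_spectrum(samples, indicator=ws_track) -> FourierSpectrum:
    """Average of per-sample normalized spectra of an indicator track.

    Each sampled sequence is mapped to its indicator track (default:
    weak/strong), transformed separately, and the normalized amplitudes are
    averaged.  Contrasting this with :func:`profile_spectrum` distinguishes a
    periodicity present in individual samples from one that only emerges in
    the ensemble average.
    """
    seqs = _sample_list(samples)
    if not seqs:
        raise ValueError("empty sample set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mean_spectrum([indicator(s) for s in seqs])
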