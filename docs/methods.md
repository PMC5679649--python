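# Methods

## The model

`maxentseq` interprets a trained feed-forward DNA sequence classifier by
asking which sequences the network considers equivalent to a given input.
Let Φ(x) be the penultimate-layer activation vector of a length-L sequence
x, and let x₀ be the anchor — the classified input being interpreted.
Similarity in the network's eyes is measured by a weighted Euclidean metric
in activation space,

    d(Φ(x₀), Φ(x)) = sqrt( Σᵢ Wᵢ² (Φᵢ(x₀) − Φᵢ(x))² ),

with Wᵢ taken from the output layer: for a single-output (or binary)
classifier, the weight row feeding the anchor's output unit; for multiclass,
the difference w_anchor − w_contrast, which weights each penultimate unit by
its leverage on the log-odds between the two classes.  The diagonal form is
used because it is the only reading of the weighted metric under which d is
an actual metric (non-negative, symmetric, triangle inequality); this is
verified by property tests on random triples.

The interpretation distribution is the maximum-entropy distribution over all
4^L sequences that is closest (minimum KL divergence) to an i.i.d.
background q while constraining the mean activation distance to the anchor:

    p(x) = exp( −β d(Φ(x₀), Φ(x)) + μ N(x) ) / Z,

where N(x) counts G+C nucleotides, μ = log(c/(1−c)) encodes the genome GC
content c of the background (μ(0.38) ≈ −0.49), and β is the Lagrange
multiplier of the distance constraint.  β = 0 recovers the background;
β → ∞ concentrates all mass on sequences that exactly reproduce Φ(x₀).
The constraint level D is never set directly: β is the operational knob, and
the realized mean distance is reported as a Monte-Carlo diagnostic.

## Sampling

`run_chains` samples p by single-site Metropolis MCMC: chains start at the
anchor; each proposal picks a position uniformly and a replacement
nucleotide uniformly from the three alternatives, and is accepted with
probability min(1, exp(−β Δd + μ ΔN)).  The proposal kernel is symmetric, so
the stationary distribution is exactly p; this is verified against
brute-force enumeration of the target on small inputs (total variation
< 0.05 at 5×10⁴ pooled samples).

Numerical/sampling choices:

* **No burn-in by default.** Chains are anchored at x₀, which is in the
  high-probability region at the β values of interest; a `burn_in` option
  exists for low-β runs.
* **The initial state is not recorded** unless `record_initial` is set;
  recording it would bias small runs toward the anchor.
* **Chain streams** derive from the master seed by `SeedSequence` spawn
  keys, so increasing `n_chains` never reshuffles existing chains, and
  identical configs give byte-identical sample sets.
* **Default schedule** is 50 chains × 100 proposals, thin 1 (suited to toy
  inputs); motif-scale and long-input work uses 100 × 3×10⁴ (thin 100) and
  1 × 10⁶ (thin 100) respectively, passed explicitly.
* Φ is re-evaluated per proposal (one forward pass); no global memoization,
  keeping memory constant for long chains.

`select_beta` sets β from data: for each anchor, D_i is the distance to its
nearest neighbor among the supplied anchors' activation vectors (floored at
ε to handle duplicate representations), β_i solves e^(−β_i D_i) = R, and the
mean β_i is returned.  R = 0.4, ε = 1.0 are sensible defaults for toy
networks; both are explicit arguments.

## Feature readouts

**Profiles and motifs.** Per-position nucleotide frequencies of the samples
act as a position-specific probability matrix.  Motif calling computes, per
position, the KL divergence (natural log) of the sample distribution from a
reference (uniform by default, optionally the background), then takes the
leftmost width-19 window with the largest mean divergence.  A pseudocount
α = 0.5 per nucleotide count is added before normalization so that frozen
positions (high β) give finite divergence; α is configurable and the
documented closed-form examples hold in the α → 0 limit.

**Periodicity.** Normalized Fourier spectra: DFT, zero-frequency component
removed, remaining components scaled to unit Euclidean norm, amplitude
reported per period L/k.  Two estimators are distinguished deliberately:
the *profile-level* spectrum transforms the four per-nucleotide frequency
tracks separately, normalizes each, and averages amplitudes; the
*per-sample* spectrum maps each sampled sequence to its binary weak/strong
(A/T vs G/C) track, transforms each, and averages.  An ensemble-level
periodicity (different samples covering different phase "hot spots") shows
up strongly in the profile spectrum but weakly in the per-sample spectrum;
the periodic fixture reproduces this ordering.  For a constant signal the
normalization is undefined; an all-zero spectrum is returned with a
degenerate flag (tolerance 1e−10 relative to the signal scale, since the
FFT of a constant is not exactly zero).

**Input-wide importance.** A feature V(x) = Σᵢ cᵢ Iᵢ(xᵢ) sums weighted
nucleotide-set indicators.  Its importance score is δ = 1/s² − 1/σ², where
s² is the unbiased (n−1) sample variance of V over the MaxEnt samples and
σ² = Σᵢ cᵢ² pᵢ(1−pᵢ) its closed-form variance under q.  Unbiased variance is
used because δ is a difference of reciprocals and small-sample bias
propagates nonlinearly.  A fully frozen feature (s² = 0) reports δ = +∞ as a
sentinel rather than an error — freezing is expected at high β and must
outrank any finite score.  Negative δ (s² > σ²) is reported as-is and read
as "unimportant".  When s² ≪ σ², δ ≈ 1/s², which motivates feature
discovery by minimizing variance: Var(V) = cᵀSc over unit-norm c is
minimized by the bottom eigenvectors of the indicator covariance S, so
`low_variance_pcs` eigendecomposes S (covariance, not correlation — the
variance itself is the quantity of interest) with eigenvalues ascending and
a deterministic sign convention (largest-magnitude entry positive).

Significance uses a dummy-feature null: 300 unit-weight features over the
same region, with each position's 2-nucleotide indicator set drawn uniformly
from {G,C}, {G,A}, {G,T}, {C,A}, {C,T}, {A,T}.  Unit weights match the GC
target, making dummies exchangeable with it under q; the reported value is
the percentile (midrank on ties) of the target's δ among the dummies.
The Gaussian reasoning behind δ assumes V is approximately normal under
both distributions; under q this follows from the CLT for features spanning
many positions with comparable weights, and the suite checks it with a
normality test on 100-position unit-weight features (n = 1000, p > 0.001).

## Exemplar kNN

Each interpreted anchor becomes an exemplar: the element-wise mean of its
samples' strong/weak indicator tracks plus the m = 5 lowest-variance PC
vectors with their standard deviations.  Distance from a binary test track
to an exemplar projects the displacement onto the PC basis and scales
coordinate j by 1/σⱼ (inverse standard deviation, taken at face value).
A variance floor of 1e−6 (configurable) is applied before inversion so that
exactly frozen directions yield large finite, not infinite, distances.
Classification is a majority vote over the k = 10 nearest exemplars;
distance ties break by exemplar order and vote ties to the lowest label
(the balanced designs of interest make ties measure-zero events).  The
control replaces each exemplar's PC basis with a QR-orthonormalized
Gaussian matrix (Haar-distributed), which destroys planted-feature
classification down to chance.

## Synthetic study conditions

The fixtures generate every input the pipeline needs, emulating three
designs:

* **XOR dinucleotides**: class 1 iff exactly one of (position 0 ∈ {A,T},
  position 1 = G); i.i.d. draws with P(A) = P(T) = 0.3, P(G) = P(C) = 0.2,
  training sets of 2000.  An exact hand-weighted network ships in two
  variants: *route-separating* (the two XOR routes occupy different
  penultimate units, so anchors AA and GG have distinct representations —
  the behavior seen in trained networks that cleanly separate the logic) and
  *merged* (both routes collapse to one representation).  `train_xor_models`
  trains the same architecture (2 width-1 conv filters, 2-unit fully
  connected layer, sigmoid output, ReLU elsewhere) with a NumPy SGD trainer:
  Glorot-uniform init, per-sample updates (classical SGD; the batch size is
  a design choice here), learning rate 5×10⁻³, binary cross-entropy,
  stopping at 16/16 validation accuracy or 40 epochs.  Only a minority of
  runs reach 100% (≈ 5/50 in the shipped configuration), matching the
  qualitative difficulty of the task; all models are trained in parallel via
  vectorized updates so 50 runs take seconds.
* **Motif design**: positives implant a PWM draw (default: width 19,
  consensus probability 0.85) into i.i.d. background at a random offset;
  negatives are Altschul–Erickson Euler-path shuffles preserving
  dinucleotide counts exactly.  The scanner network scores the best
  convolutional window against the log-odds PWM and thresholds at half the
  consensus score — its decision rule is verifiable by an independent
  sliding-window scorer.
* **Periodic design**: P(strong at i) = base + shift + A·cos(2πi/10) for
  positives (defaults base 0.38, shift 0.1, amplitude 0.1, L = 201), flat
  for negatives — a caricature of the anti-phased 10-bp weak/strong
  preference and GC enrichment of nucleosome-favoring DNA.

Planted-constraint samplers provide exact ground truth for the importance
machinery without a network in the loop: a Gaussian-tilted binomial sampler
constrains the GC count over a region to any target variance (the tilt λ is
solved numerically so the constrained variance is exact, e.g. σ²/10 ⇒
δ = 9/σ²); a Metropolis track sampler plants a soft linear constraint along
an arbitrary unit direction for PC-recovery tests; and a marked-position
generator plants class-specific near-frozen positions (strong or weak with
probability 0.95) for the kNN experiments.

What these fixtures do *not* emulate: trained-network noise and route
ambiguity (real networks may or may not separate logical routes), genomic
dinucleotide structure beyond what the shuffle preserves, motif degeneracy
and multiple occurrences, and the diffuse, correlated nucleosome signals of
real chromatin.  Passing tests therefore demonstrate correctness of the
machinery under controlled conditions, not performance claims on real data.

## Problem sizes

The shipped test and reproduction runs use desk-scale sizes chosen to give
clear statistical margins: 5×10⁴ pooled samples for the sampler-exactness
check (L = 2, enumeration oracle over 16 sequences), 50 anchors × 9,600
proposals for motif recovery, 600 sequences for the periodicity ordering,
6,000 samples for δ calibration, 20 planted + 60 null runs × 300 dummies
for the percentile checks, and 50 exemplars × 250 samples (L = 201) for the
kNN experiment.  All randomness flows from explicit seeds; every generator
and the sampler are reproducible byte-for-byte given the same seed.

## Known limitations

* Per-proposal forward passes make sampling cost linear in network size;
  very deep networks need the chain schedule scaled accordingly (the
  engine is plain NumPy, single-threaded).
* The Metropolis chain explores single-site moves only; at very high β on
  rugged landscapes it can mix slowly between distant equivalence classes
  (visible as chains that never leave the anchor's class — which is also
  the informative regime for interpretation).
* δ's Gaussian rationale degrades for features over few positions or with
  wildly unequal weights; the normality diagnostic should be consulted.
* `select_beta` uses the user-supplied anchor set as the empirical
  activation distribution; subsampling large datasets is the caller's
  responsibility.
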