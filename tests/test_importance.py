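"""Input-wide feature concordance, delta scores, dummy nulls, and
low-variance PCA feature discovery."""

import math

import numpy as np
import pytest
from scipy import stats

from maxentseq import (
    BackgroundModel,
    InputWideFeature,
    background_variance,
    concordance,
    concordance_many,
    delta_score,
    dummy_percentile,
    low_variance_pcs,
)
from maxentseq.fixtures import sample_background, sample_gc_constrained

BG38 = BackgroundModel(0.38)


def gc_feature(n):
    return InputWideFeature.gc_content(range(n))


class TestConcordance:
    def test_all_hits(self):
        assert concordance(gc_feature(4), "GGCC") == 4.0

    def test_no_hits(self):
        assert concordance(gc_feature(4), "AATT") == 0.0

    def test_signed_weights(self):
        feat = InputWideFeature(
            positions=(0, 1),
            indicator_sets=(frozenset("GC"), frozenset("AT")),
            weights=(1.0, -2.0),
        )
        assert concordance(feat, "GA") == -1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            concordance(gc_feature(5), "ACG")

    def test_vectorized_matches_scalar(self, rng):
        feat = InputWideFeature(
            positions=(0, 2, 3),
            indicator_sets=(frozenset("GC"), frozenset("A"), frozenset("CT")),
            weights=(1.5, -1.0, 2.0),
        )
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 5)) for _ in range(40)]
        vec = concordance_many(feat, seqs)
        assert np.allclose(vec, [concordance(feat, s) for s in seqs])

    def test_improper_indicator_sets_rejected(self):
        with pytest.raises(ValueError):
            InputWideFeature(positions=(0,), indicator_sets=(frozenset("ACGT"),), weights=(1.0,))


class TestBackgroundVariance:
    def test_single_position_bernoulli(self):
        feat = gc_feature(1)
        assert background_variance(feat, BackgroundModel(0.5)) == pytest.approx(0.25)

    def test_central_147_bases_closed_form(self):
        feat = gc_feature(147)
        assert background_variance(feat, BG38) == pytest.approx(147 * 0.38 * 0.62)
        assert background_variance(feat, BG38) == pytest.approx(34.6332)

    def test_doubling_weights_quadruples_variance(self):
        feat = gc_feature(10)
        doubled = InputWideFeature(
            positions=feat.positions,
            indicator_sets=feat.indicator_sets,
            weights=tuple(2.0 * w for w in feat.weights),
        )
        assert background_variance(doubled, BG38) == pytest.approx(
            4 * background_variance(feat, BG38)
        )

    def test_matches_empirical_variance_under_background(self):
        feat = gc_feature(60)
        seqs = sample_background(BG38, 60, 4000, seed=3)
        v = concordance_many(feat, seqs)
        emp = np.var(v, ddof=1)
        sigma2 = background_variance(feat, BG38)
        se = sigma2 * math.sqrt(2.0 / (len(v) - 1))
        assert abs(emp - sigma2) < 3 * se


class TestDeltaScore:
    def test_background_samples_give_delta_near_zero(self):
        feat = gc_feature(80)
        seqs = sample_background(BG38, 80, 3000, seed=9)
        res = delta_score(seqs, feat, BG38)
        # bootstrap SE of delta
        v = concordance_many(feat, seqs)
        rng = np.random.default_rng(0)
        boots = [
            1.0 / np.var(rng.choice(v, size=len(v), replace=True), ddof=1) - 1.0 / res.sigma2
            for _ in range(200)
        ]
        assert abs(res.delta) < 3 * np.std(boots)

    def test_frozen_feature_reports_infinite_sentinel(self):
        feat = gc_feature(3)
        with pytest.warns(UserWarning, match="frozen"):
            res = delta_score(["GGG", "GGG", "GGG"], feat, BG38)
        assert res.delta == np.inf
        assert res.s2 == 0.0

    def test_planted_variance_reduction_recovers_delta(self):
        """Constraining Var(V) to sigma^2/10 must give delta = 9/sigma^2."""
        feat = gc_feature(147)
        seqs = sample_gc_constrained(BG38, 147, range(147), variance_ratio=0.1,
                                     n=6000, seed=5)
        res = delta_score(seqs, feat, BG38)
        sigma2 = background_variance(feat, BG38)
        assert res.delta == pytest.approx(9.0 / sigma2, rel=0.10)

    def test_complement_flip_invariance(self):
        """V -> const - V leaves both variances, hence delta, unchanged."""
        feat = gc_feature(40)
        flipped = InputWideFeature(
            positions=feat.positions,
            indicator_sets=tuple(frozenset("ACGT") - s for s in feat.indicator_sets),
            weights=tuple(-w for w in feat.weights),
        )
        seqs = sample_background(BG38, 40, 500, seed=17)
        r1 = delta_score(seqs, feat, BG38)
        r2 = delta_score(seqs, flipped, BG38)
        assert r1.delta == pytest.approx(r2.delta, rel=1e-12)
        assert r1.sigma2 == pytest.approx(r2.sigma2)

    def test_normality_of_concordance_under_background(self):
        """CLT check backing the Gaussian decay approximation: unit-weight
        features over many positions are approximately normal under q."""
        feat = gc_feature(100)
        seqs = sample_background(BG38, 100, 1000, seed=23)
        v = concordance_many(feat, seqs)
        _, p = stats.normaltest(v)
        assert p > 0.001


class TestDummyPercentile:
    def test_target_exceeding_every_dummy_is_100th(self):
        # a near-frozen GC constraint has delta far above every dummy
        seqs = sample_gc_constrained(BG38, 60, range(60), variance_ratio=0.02,
                                     n=800, seed=2)
        feat = gc_feature(60)
        res = dummy_percentile(seqs, feat, range(60), BG38, n_dummies=50, seed=0)
        assert res.percentile == 100.0

    def test_planted_gc_constraint_scores_high(self):
        feat = gc_feature(147)
        seqs = sample_gc_constrained(BG38, 147, range(147), variance_ratio=0.1,
                                     n=1000, seed=31)
        res = dummy_percentile(seqs, feat, range(147), BG38, n_dummies=100, seed=1)
        assert res.percentile > 90.0

    def test_too_few_dummies_rejected(self):
        seqs = sample_background(BG38, 10, 50, seed=0)
        with pytest.raises(ValueError):
            dummy_percentile(seqs, gc_feature(10), range(10), BG38, n_dummies=1)


class TestLowVariancePCA:
    def test_frozen_position_yields_zero_variance_pc(self, rng):
        seqs = []
        for _ in range(200):
            s = list("".join("ACGT"[i] for i in rng.integers(0, 4, 12)))
            s[5] = "G"  # frozen strong position
            seqs.append("".join(s))
        pcs = low_variance_pcs(seqs)
        assert pcs.pc_variances[0] == pytest.approx(0.0, abs=1e-12)
        assert abs(pcs.pc_vectors[5, 0]) == pytest.approx(1.0)

    def test_reconstruction_and_orthonormality(self):
        seqs = sample_background(BG38, 30, 400, seed=41)
        pcs = low_variance_pcs(seqs)
        V, lam = pcs.pc_vectors, pcs.pc_variances
        assert np.allclose(V.T @ V, np.eye(30), atol=1e-8)
        recon = (V * lam[None, :]) @ V.T
        assert np.allclose(recon, pcs.covariance, atol=1e-8)
        # Rayleigh quotient equals the eigenvalue
        assert np.allclose(np.diag(V.T @ pcs.covariance @ V), lam, atol=1e-10)

    def test_matches_sklearn_pca_oracle(self):
        """Independent route: sklearn PCA on the same indicator tracks."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        from maxentseq.profiles import sequences_to_indices

        seqs = sample_background(BG38, 15, 300, seed=43)
        idx = sequences_to_indices(seqs)
        tracks = np.isin(idx, [1, 2]).astype(float)  # C, G
        pcs = low_variance_pcs(seqs)
        sk = sklearn.PCA(n_components=15).fit(tracks)
        assert np.allclose(np.sort(sk.explained_variance_), pcs.pc_variances, atol=1e-8)
        lowest_sk = sk.components_[-1]
        cos = abs(lowest_sk @ pcs.pc_vectors[:, 0])
        assert cos > 0.99

    def test_background_spectrum_is_flat(self):
        """i.i.d. samples show no sharp low-variance drop."""
        seqs = sample_background(BG38, 25, 2000, seed=47)
        pcs = low_variance_pcs(seqs)
        assert pcs.pc_variances[0] > 0.5 * pcs.pc_variances[-1]

    def test_rank_deficiency_warns(self):
        seqs = sample_background(BG38, 50, 20, seed=3)
        with pytest.warns(UserWarning, match="rank-deficient"):
            low_variance_pcs(seqs)
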