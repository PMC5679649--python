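"""Synthetic datasets, exact fixture networks, and planted-constraint samplers."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from maxentseq import BackgroundModel, encode_onehot, predict_class
from maxentseq.fixtures import (
    build_exact_xor_network,
    build_pwm_scanner_network,
    dinucleotide_shuffle,
    generate_motif_dataset,
    generate_periodic_dataset,
    generate_xor_dataset,
    random_pwm,
    sample_gc_constrained,
    sample_marked_positions,
    train_xor_models,
    xor_label,
)

from conftest import ALL_DINUCLEOTIDES


class TestXorLabel:
    @pytest.mark.parametrize("seq,label", [("AA", 1), ("GG", 1), ("AG", 0), ("CC", 0), ("TG", 0)])
    def test_known_cases(self, seq, label):
        assert xor_label(seq) == label

    def test_exhaustive_against_boolean_oracle(self):
        for s in ALL_DINUCLEOTIDES:
            expected = int((s[0] in "AT") ^ (s[1] == "G"))
            assert xor_label(s) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            xor_label("ACG")


class TestXorDataset:
    def test_empty_and_invalid(self):
        seqs, labels = generate_xor_dataset(0, seed=1)
        assert seqs == [] and len(labels) == 0
        with pytest.raises(ValueError):
            generate_xor_dataset(10, p_at=0.4, p_gc=0.4)

    def test_base_frequencies_match_generating_distribution(self):
        seqs, _ = generate_xor_dataset(5000, seed=3)
        counts = Counter("".join(seqs))
        n = 2 * len(seqs)
        for base, p in zip("ACGT", [0.3, 0.2, 0.2, 0.3]):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[base] / n - p) < 3 * se

    def test_class1_fraction_matches_closed_form(self):
        # P(c1) + P(c2) - 2 P(c1) P(c2) with P(c1)=0.6, P(c2)=0.2
        seqs, labels = generate_xor_dataset(5000, seed=5)
        expected = 0.6 + 0.2 - 2 * 0.6 * 0.2
        se = math.sqrt(expected * (1 - expected) / len(labels))
        assert abs(labels.mean() - expected) < 3 * se

    def test_seed_determinism(self):
        a = generate_xor_dataset(100, seed=9)
        b = generate_xor_dataset(100, seed=9)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])


class TestExactXorNetworks:
    @pytest.mark.parametrize("variant", ["route_separating", "merged"])
    def test_all_16_dinucleotides_classified(self, variant):
        net = build_exact_xor_network(variant)
        for s in ALL_DINUCLEOTIDES:
            assert predict_class(net, encode_onehot(s)) == xor_label(s)

    def test_route_separating_penultimate_vectors(self, route_net):
        assert np.allclose(route_net.phi(encode_onehot("AA")), [1.0, 0.0])
        assert np.allclose(route_net.phi(encode_onehot("GG")), [0.0, 1.0])

    def test_merged_variant_collapses_routes(self, merged_net):
        assert np.allclose(
            merged_net.phi(encode_onehot("AA")), merged_net.phi(encode_onehot("GG"))
        )

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_exact_xor_network("bogus")


class TestXorTraining:
    def test_contract_and_determinism(self):
        res = train_xor_models(4, max_epochs=3, seed=7)
        assert len(res.models) == 4
        assert np.all((res.accuracies >= 0) & (res.accuracies <= 1))
        assert np.all(res.epochs <= 3)
        res2 = train_xor_models(4, max_epochs=3, seed=7)
        assert np.array_equal(res.accuracies, res2.accuracies)

    def test_returned_models_reproduce_recorded_accuracy(self):
        res = train_xor_models(2, max_epochs=2, seed=13)
        for model, acc in zip(res.models, res.accuracies):
            got = np.mean(
                [predict_class(model, encode_onehot(s)) == xor_label(s) for s in ALL_DINUCLEOTIDES]
            )
            assert got == pytest.approx(acc)

    def test_training_beats_majority_class(self):
        res = train_xor_models(6, max_epochs=12, seed=21)
        # the 16-dinucleotide validation set has a 10/16 majority class
        assert res.accuracies.max() > 10 / 16


class TestDinucleotideShuffle:
    def _dinuc_counts(self, s):
        return Counter(s[i : i + 2] for i in range(len(s) - 1))

    def test_counts_preserved_exactly(self, rng):
        for _ in range(20):
            L = int(rng.integers(10, 80))
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
            t = dinucleotide_shuffle(s, rng)
            assert self._dinuc_counts(t) == self._dinuc_counts(s)
            assert t[0] == s[0] and t[-1] == s[-1]

    def test_actually_shuffles(self, rng):
        s = "ACGTACGTACGTACGTACGTGGCCAATT" * 3
        outs = {dinucleotide_shuffle(s, rng) for _ in range(10)}
        assert len(outs) > 1


class TestMotifDataset:
    def test_deterministic_pwm_implants_exact_substring(self):
        pwm = np.eye(4)[[2, 0, 3, 3, 1]]  # GATTC, rows one-hot
        ds = generate_motif_dataset(n_pos=20, n_neg=0, L=40, pwm=pwm, seed=3)
        for seq, off in zip(ds.positives, ds.offsets):
            assert seq[off : off + 5] == "GATTC"

    def test_negatives_preserve_dinucleotide_counts(self):
        ds = generate_motif_dataset(n_pos=5, n_neg=5, L=60, seed=11)
        for pos, neg in zip(ds.positives, ds.negatives):
            cp = Counter(pos[i : i + 2] for i in range(len(pos) - 1))
            cn = Counter(neg[i : i + 2] for i in range(len(neg) - 1))
            assert cp == cn

    def test_uniform_pwm_indistinguishable_from_background(self):
        from scipy import stats

        pwm = np.full((8, 4), 0.25)
        bg = BackgroundModel(0.5)
        ds = generate_motif_dataset(n_pos=300, n_neg=0, L=50, pwm=pwm, seed=17, background=bg)
        ref = BackgroundModel(0.5).sample(50, 300, np.random.default_rng(99))
        gc_pos = [s.count("G") + s.count("C") for s in ds.positives]
        gc_ref = [s.count("G") + s.count("C") for s in ref]
        _, p = stats.ks_2samp(gc_pos, gc_ref)
        assert p > 0.01

    def test_pwm_wider_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            generate_motif_dataset(1, 0, L=5, pwm=np.full((10, 4), 0.25))


class TestScannerNetwork:
    def test_decision_matches_independent_pwm_scorer(self, rng):
        """Network classification equals thresholding a hand-rolled
        sliding-window log-odds scan."""
        pwm = random_pwm(6, seed=4)
        net = build_pwm_scanner_network(pwm)
        logodds = np.log(np.clip(pwm, 1e-3, None) / 0.25)
        thresh = 0.5 * logodds.max(axis=1).sum()
        for _ in range(30):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
            best = max(
                sum(logodds[j, "ACGT".index(seq[s + j])] for j in range(6))
                for s in range(25 - 6 + 1)
            )
            assert predict_class(net, encode_onehot(seq)) == int(best > thresh)

    def test_implanted_consensus_is_classified_positive(self):
        pwm = random_pwm(10, seed=8, consensus_prob=0.9)
        net = build_pwm_scanner_network(pwm)
        consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=1))
        seq = "A" * 20 + consensus + "T" * 20
        assert predict_class(net, encode_onehot(seq)) == 1


class TestPeriodicDataset:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_periodic_dataset(1, 1, amplitude=0.5, gc_shift=0.3)

    def test_gc_shift_raises_mean_gc(self):
        ds = generate_periodic_dataset(400, 0, L=200, gc_shift=0.1, amplitude=0.1, seed=5)
        gc = np.mean([(s.count("G") + s.count("C")) / len(s) for s in ds.positives])
        se = math.sqrt(0.48 * 0.52 / (400 * 200))
        assert abs(gc - 0.48) < 4 * se

    def test_zero_signal_matches_negatives_in_distribution(self):
        from scipy import stats

        ds = generate_periodic_dataset(300, 300, L=100, amplitude=0.0, gc_shift=0.0, seed=7)
        gc_pos = [s.count("G") + s.count("C") for s in ds.positives]
        gc_neg = [s.count("G") + s.count("C") for s in ds.negatives]
        _, p = stats.ks_2samp(gc_pos, gc_neg)
        assert p > 0.01

    def test_seed_determinism(self):
        a = generate_periodic_dataset(10, 10, seed=3)
        b = generate_periodic_dataset(10, 10, seed=3)
        assert a.positives == b.positives and a.negatives == b.negatives


class TestPlantedSamplers:
    def test_gc_constrained_variance_hits_target(self):
        bg = BackgroundModel(0.38)
        seqs = sample_gc_constrained(bg, 147, range(147), variance_ratio=0.1, n=5000, seed=1)
        v = np.array([s.count("G") + s.count("C") for s in seqs])
        sigma2 = 147 * 0.38 * 0.62
        assert np.var(v, ddof=1) == pytest.approx(sigma2 / 10, rel=0.1)
        # mean stays at the background mean
        assert v.mean() == pytest.approx(147 * 0.38, abs=3 * math.sqrt(sigma2 / 10 / 5000) * 10)

    def test_marked_positions_bias(self):
        bg = BackgroundModel(0.38)
        seqs = sample_marked_positions(2000, 30, [3, 17], 0.95, bg, seed=2)
        s_freq = np.mean([[b in "GC" for b in s] for s in seqs], axis=0)
        assert abs(s_freq[3] - 0.95) < 0.03
        assert abs(s_freq[17] - 0.95) < 0.03
        unmarked = [i for i in range(30) if i not in (3, 17)]
        assert np.all(np.abs(s_freq[unmarked] - 0.38) < 0.05)

    def test_samplers_are_seed_deterministic(self):
        bg = BackgroundModel(0.4)
        a = sample_gc_constrained(bg, 20, range(20), 0.2, n=10, seed=6)
        b = sample_gc_constrained(bg, 20, range(20), 0.2, n=10, seed=6)
        assert a == b
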