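"""The 12 musical dimensions: worked examples, brute-force cross-checks and
invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melosem.corpus_io import Improvisation, NoteEvent
from melosem.features import (
    DEFAULT_DISSONANCE_RANKS,
    DEFAULT_MODEL,
    FEATURE_NAMES,
    SpectrumModel,
    ambitus,
    articulation,
    attack_time,
    brightness,
    euler_gradus,
    extract_features,
    gradus,
    harmonic_dissonance,
    load_feature_table,
    lowest_note,
    mean_duration,
    mean_velocity,
    melodic_entropy,
    merge_feature_overrides,
    pitch_entropy,
    plomp_levelt_pair,
    roughness,
)


def _note(onset, dur, pitch, vel=64):
    return NoteEvent(onset, onset + dur, pitch, vel)


def _random_piece(seed, n=50):
    rng = np.random.default_rng(seed)
    return [
        _note(float(rng.uniform(0, 15)), float(rng.uniform(0.1, 1.5)),
              int(rng.integers(30, 100)), int(rng.integers(1, 128)))
        for _ in range(n)
    ]


class TestScalarFeatures:
    @pytest.mark.parametrize("pitches,expected", [((60, 60, 60), 0.0), ((60, 72), 12.0)])
    def test_ambitus_examples(self, pitches, expected):
        notes = [_note(i * 0.5, 0.4, p) for i, p in enumerate(pitches)]
        assert ambitus(notes) == expected

    def test_scalar_features_match_brute_force(self):
        notes = _random_piece(3)
        assert ambitus(notes) == max(n.pitch for n in notes) - min(n.pitch for n in notes)
        assert lowest_note(notes) == min(n.pitch for n in notes)
        assert mean_duration(notes) == pytest.approx(
            sum(n.offset - n.onset for n in notes) / len(notes))
        assert mean_velocity(notes) == pytest.approx(
            sum(n.velocity for n in notes) / len(notes))

    def test_attack_time_velocity_map_endpoints(self):
        loud = [_note(0, 1, 60, 127)]
        soft = [_note(0, 1, 60, 1)]
        assert attack_time(loud) == pytest.approx(0.005)
        assert attack_time(soft) == pytest.approx(0.050, abs=5e-4)
        mixed = _random_piece(4)
        expected = np.mean([0.05 - n.velocity / 127 * 0.045 for n in mixed])
        assert attack_time(mixed) == pytest.approx(expected)


class TestArticulation:
    def test_gapless_chain_is_legato_1(self):
        notes = [_note(i * 0.5, 0.5, 60 + i) for i in range(10)]
        assert articulation(notes) == pytest.approx(1.0)

    def test_vanishing_durations_approach_staccato_0(self):
        for eps, bound in ((0.1, 0.11), (0.01, 0.011)):
            notes = [_note(i * 1.0, eps, 60) for i in range(10)]
            assert articulation(notes) == pytest.approx(eps / 1.0)
            assert articulation(notes) < bound

    def test_half_duty_cycle(self):
        notes = [_note(i * 1.0, 0.5, 60) for i in range(8)]
        assert articulation(notes) == pytest.approx(0.5)

    def test_single_attack_is_undefined(self):
        assert math.isnan(articulation([_note(0, 1, 60)]))
        # a chord is still a single attack
        assert math.isnan(articulation([_note(0, 1, 60), _note(0.01, 1, 64)]))

    def test_overlapping_notes_cap_at_one(self):
        notes = [_note(0.0, 2.0, 60), _note(1.0, 1.0, 62)]
        assert articulation(notes) == 1.0


class TestPitchEntropy:
    def test_single_repeated_pitch_is_zero(self):
        notes = [_note(i * 0.4, 0.3, 60) for i in range(40)]
        assert pitch_entropy(notes) == 0.0

    def test_uniform_pitch_classes_reach_log2_12(self):
        notes = [_note(i * 0.3, 0.2, 60 + i) for i in range(12)]
        assert pitch_entropy(notes) == pytest.approx(math.log2(12))

    def test_two_window_piece_matches_per_window_brute_force(self):
        # onsets span 9 s: windows [0,7) and [5,12) with default 7 s / 5 s hop
        notes = [_note(t, 0.2, p) for t, p in
                 [(0.0, 60), (1.0, 62), (6.0, 64), (6.5, 60), (8.0, 65), (9.0, 65)]]
        def window_entropy(pcs):
            counts = np.bincount([p % 12 for p in pcs], minlength=12)
            pr = counts[counts > 0] / counts.sum()
            return float(-(pr * np.log2(pr)).sum())
        w1 = window_entropy([60, 62, 64, 60])           # onsets in [0, 7)
        w2 = window_entropy([64, 60, 65, 65])           # onsets in [5, 12)
        assert pitch_entropy(notes) == pytest.approx((w1 + w2) / 2)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 5000))
    def test_octave_and_time_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        notes = _random_piece(seed, n=30)
        base = pitch_entropy(notes)
        shifted = [
            NoteEvent(n.onset + 3.7, n.offset + 3.7,
                      (n.pitch + 12 if n.pitch <= 96 else n.pitch - 12)
                      if rng.random() < 0.5 else n.pitch,
                      n.velocity)
            for n in notes
        ]
        transposed_only = [
            NoteEvent(n.onset, n.offset, n.pitch - 12 if n.pitch >= 42 else n.pitch + 12,
                      n.velocity)
            for n in notes
        ]
        assert pitch_entropy(transposed_only) == pytest.approx(base)
        assert pitch_entropy(shifted) == pytest.approx(base)

    def test_melodic_entropy_equals_pitch_entropy_on_monophony(self):
        notes = [_note(i * 0.4, 0.3, int(p)) for i, p in
                 enumerate(np.random.default_rng(9).integers(55, 80, size=30))]
        assert melodic_entropy(notes) == pytest.approx(pitch_entropy(notes))

    def test_chords_under_repeated_top_note_have_zero_melodic_entropy(self):
        notes = []
        for i in range(10):
            notes += [_note(i * 0.5, 0.4, 72), _note(i * 0.5, 0.4, 60 + i)]
        assert melodic_entropy(notes) == 0.0


class TestRoughness:
    def test_single_pure_tone_is_zero(self):
        model = SpectrumModel(n_partials=1)
        assert roughness([_note(0, 1, 69)], model) == 0.0

    def test_semitone_rougher_than_octave(self):
        semi = [_note(0, 1, 60), _note(0, 1, 61)]
        octave = [_note(0, 1, 60), _note(0, 1, 72)]
        assert roughness(semi) > roughness(octave)

    def test_close_partials_give_strictly_positive_roughness(self):
        assert roughness([_note(0, 1, 60), _note(0, 1, 61)], SpectrumModel(n_partials=1)) > 0

    def test_three_note_frame_matches_pairwise_brute_force(self):
        notes = [_note(0, 1, p) for p in (48, 55, 62)]
        freqs, amps = [], []
        for p in (48, 55, 62):
            f0 = 440.0 * 2 ** ((p - 69) / 12)
            for k in range(1, 7):
                freqs.append(k * f0)
                amps.append(1.0 / k)
        expected = 0.0
        for i in range(len(freqs)):
            for j in range(i + 1, len(freqs)):
                expected += plomp_levelt_pair(freqs[i], freqs[j], amps[i], amps[j])
        # frames at 0.0 .. 0.95 hold the chord; the final grid point at the
        # last offset is empty under the half-open convention
        assert roughness(notes) == pytest.approx(expected * 20 / 21)

    def test_invariant_under_note_order_permutation(self):
        notes = _random_piece(11, n=20)
        rng = np.random.default_rng(0)
        shuffled = list(notes)
        rng.shuffle(shuffled)
        assert roughness(shuffled) == pytest.approx(roughness(notes))


class TestBrightness:
    def test_all_energy_below_cutoff(self):
        assert brightness([_note(0, 1, 30)], SpectrumModel(n_partials=2)) == 0.0

    def test_all_energy_above_cutoff(self):
        assert brightness([_note(0, 1, 100)], SpectrumModel(n_partials=2)) == 1.0

    def test_mixed_spectrum_matches_energy_ratio(self):
        notes = [_note(0, 1, 69)]  # A4: partials at 440k Hz
        freqs = np.array([440.0 * k for k in range(1, 7)])
        energy = np.array([1.0 / k**2 for k in range(1, 7)])
        expected = energy[freqs > 1500.0].sum() / energy.sum()
        assert brightness(notes) == pytest.approx(expected)


class TestHarmonicDissonance:
    def test_monophonic_piece_scores_zero(self):
        notes = [_note(i * 1.0, 0.8, 60 + i) for i in range(5)]
        assert harmonic_dissonance(notes) == 0.0

    def test_octave_is_most_consonant_class(self):
        octave = [_note(0, 1, 48), _note(0, 1, 60)]
        assert harmonic_dissonance(octave) == 0.0

    def test_minor_second_ranks_above_tritone(self):
        m2 = [_note(0, 1, 60), _note(0, 1, 61)]
        tritone = [_note(0, 1, 60), _note(0, 1, 66)]
        assert harmonic_dissonance(m2) == DEFAULT_DISSONANCE_RANKS[1] == 10
        assert harmonic_dissonance(tritone) == DEFAULT_DISSONANCE_RANKS[6] == 11
        assert harmonic_dissonance(tritone) > harmonic_dissonance(m2)


class TestGradus:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (6, 4), (15, 7), (45, 9)])
    def test_euler_gradus_prime_formula(self, n, expected):
        assert euler_gradus(n) == expected

    @pytest.mark.parametrize("interval,expected", [
        (0, 1),    # unison 1:1 -> gradus(1) = 1
        (12, 2),   # octave 2:1 -> gradus(2) = 2
        (7, 4),    # fifth 3:2 -> gradus(6) = 4
    ])
    def test_melodic_interval_examples(self, interval, expected):
        notes = [_note(i * 0.5, 0.4, 60 + (i % 2) * interval) for i in range(6)]
        assert gradus(notes) == pytest.approx(expected)

    def test_single_attack_is_undefined(self):
        assert math.isnan(gradus([_note(0, 1, 60)]))


class TestExtractFeatures:
    def test_golden_fixture_all_twelve_dimensions(self):
        """Five-note fixture with every dimension computed by hand."""
        notes = (
            NoteEvent(0.0, 1.0, 60, 100),
            NoteEvent(0.0, 1.0, 64, 80),
            NoteEvent(1.0, 1.5, 67, 60),
            NoteEvent(2.0, 2.4, 72, 90),
            NoteEvent(2.4, 3.0, 60, 50),
        )
        imp = Improvisation("p1", "truth", "positive", "logic", notes)
        f = extract_features(imp)
        assert f["ambitus"] == 12.0
        assert f["lowest_note"] == 60.0
        assert f["duration"] == pytest.approx(0.7)
        assert f["velocity"] == pytest.approx(76.0)
        assert f["attack_time"] == pytest.approx(0.05 - 76 * 0.045 / 127)
        # clusters: {60,64}@0, {67}@1, {72}@2, {60}@2.4
        assert f["articulation"] == pytest.approx((1.0 + 0.5 + 1.0) / 3)
        # one 7 s window, pitch classes {0:3, 4:1, 7:1}
        assert f["entropy"] == pytest.approx(
            -(0.6 * math.log2(0.6) + 2 * 0.2 * math.log2(0.2)))
        # skyline 64, 67, 72, 60 -> classes {4:1, 7:1, 0:2}
        assert f["melodic_entropy"] == pytest.approx(1.5)
        # skyline intervals 3, 5, 12 -> gradus(30)=8, gradus(12)=5, gradus(2)=2
        assert f["gradus"] == pytest.approx((8 + 5 + 2) / 3)
        # only the major third sounds simultaneously: rank 3 in every pair
        assert f["dissonance"] == pytest.approx(3.0)
        assert f["roughness"] > 0
        assert 0 <= f["brightness"] <= 1

    def test_corpus_extraction_is_total(self, study_table):
        feats = study_table[FEATURE_NAMES]
        assert len(study_table) == 608
        assert not feats.isna().any().any()
        assert (feats["articulation"].between(0, 1)).all()
        assert (feats["brightness"].between(0, 1)).all()
        assert (feats["entropy"].between(0, math.log2(12) + 1e-9)).all()
        assert (feats[["roughness", "dissonance", "ambitus"]] >= 0).all().all()
        assert (feats["gradus"] >= 1).all()

    def test_velocity_scaling_touches_only_velocity_and_attack(self):
        notes = _random_piece(21, n=25)
        scaled = [NoteEvent(n.onset, n.offset, n.pitch, max(1, n.velocity // 2))
                  for n in notes]
        imp = lambda ns: Improvisation("p", "truth", "positive", "logic",
                                       tuple(sorted(ns, key=lambda n: n.onset)))
        base = extract_features(imp(notes))
        half = extract_features(imp(scaled))
        for name in FEATURE_NAMES:
            if name in ("velocity", "attack_time"):
                assert base[name] != pytest.approx(half[name])
            else:
                assert base[name] == pytest.approx(half[name]), name


class TestExternalFeatureOverride:
    def test_empty_override_is_identity(self, tmp_path, study_table):
        head = study_table.head(10)
        path = tmp_path / "ext.csv"
        head[["file"]].to_csv(path, index=False)
        merged = merge_feature_overrides(head, load_feature_table(path))
        assert merged.equals(head)

    def test_partial_override_changes_only_that_column(self, tmp_path, study_table):
        head = study_table.head(10).reset_index(drop=True)
        ext = head[["file"]].copy()
        ext["roughness"] = 99.0
        path = tmp_path / "ext.csv"
        ext.to_csv(path, index=False)
        merged = merge_feature_overrides(head, load_feature_table(path))
        assert (merged["roughness"] == 99.0).all()
        others = [f for f in FEATURE_NAMES if f != "roughness"]
        assert merged[others].equals(head[others])

    def test_unknown_columns_and_missing_keys_rejected(self, tmp_path, study_table):
        path = tmp_path / "bad.csv"
        path.write_text("file,swagger\na.mid,1\n")
        with pytest.raises(ValueError, match="unknown feature"):
            load_feature_table(path)
        path2 = tmp_path / "missing.csv"
        path2.write_text("file,roughness\nnot_there.mid,1.0\n")
        with pytest.raises(ValueError, match="not in table"):
            merge_feature_overrides(study_table.head(5), load_feature_table(path2))
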