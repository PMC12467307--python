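import numpy as np
import pytest

from aucurve.fixtures import (
    EmotionSpec,
    SyntheticClipRecord,
    analytic_joint,
    base_face,
    au_region,
    load_corpus,
    make_corpus,
    make_records,
    render_clip,
    sample_au_corpus,
)
from aucurve.inventory import AU_INVENTORY


class TestEmotionSpec:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            EmotionSpec("bad", {"AU1": 1.5})

    def test_unknown_au_rejected(self):
        with pytest.raises(ValueError):
            EmotionSpec("bad", {"AU99": 0.5})

    def test_nonpositive_modulator_rejected(self):
        with pytest.raises(ValueError):
            EmotionSpec("bad", {"AU1": 0.5}, modulator_me=0.0)


class TestSampleAuCorpus:
    def test_probability_one_au_always_present(self):
        spec = EmotionSpec("sure", {"AU12": 1.0, "AU4": 0.2})
        corpus = sample_au_corpus(spec, 50, seed=3)
        assert all("AU12" in s for s in corpus)

    def test_seed_determinism(self, happiness_spec):
        a = sample_au_corpus(happiness_spec, 40, seed=7)
        b = sample_au_corpus(happiness_spec, 40, seed=7)
        assert a == b

    def test_sets_never_empty(self, emotion_specs):
        corpus = sample_au_corpus(emotion_specs["neutral"], 200, seed=5)
        assert all(len(s) > 0 for s in corpus)

    def test_marginal_frequency_within_binomial_bound(self):
        # AU1 at probability 1 keeps every set non-empty, so AU4's marginal
        # frequency is an unconditioned Bernoulli(0.3) empirical mean.
        spec = EmotionSpec("m", {"AU1": 1.0, "AU4": 0.3})
        n = 5000
        corpus = sample_au_corpus(spec, n, seed=13)
        freq = sum("AU4" in s for s in corpus) / n
        bound = 3 * np.sqrt(0.3 * 0.7 / n)
        assert abs(freq - 0.3) < bound

    def test_pair_boost_raises_cooccurrence(self):
        base = EmotionSpec("b", {"AU6": 0.5, "AU12": 0.5})
        boosted = EmotionSpec("b+", {"AU6": 0.5, "AU12": 0.5},
                              pair_boost={("AU6", "AU12"): 3.0})
        n = 4000
        both_base = sum({"AU6", "AU12"} <= s for s in sample_au_corpus(base, n, 1)) / n
        both_boost = sum({"AU6", "AU12"} <= s for s in sample_au_corpus(boosted, n, 1)) / n
        assert both_boost > both_base + 0.05

    def test_empirical_matches_analytic_joint(self):
        spec = EmotionSpec("j", {"AU1": 0.6, "AU4": 0.3, "AU12": 0.8},
                           pair_boost={("AU1", "AU4"): 2.0},
                           au_ids=("AU1", "AU4", "AU12"))
        marginal, pair = analytic_joint(spec)
        n = 5000
        corpus = sample_au_corpus(spec, n, seed=2)
        emp = np.array([sum(au in s for s in corpus) / n for au in spec.au_ids])
        assert np.abs(emp - marginal).max() < 0.03


class TestRecordValidation:
    def test_apex_must_sit_strictly_inside(self):
        with pytest.raises(ValueError):
            SyntheticClipRecord("c", "s", "happiness", {"AU12"}, {"AU12": 1.0},
                                onset_frame=4, apex_frame=4, offset_frame=11, n_frames=16)

    def test_normalized_timestamps(self, sample_record):
        assert sample_record.t_start == pytest.approx(4 / 15)
        assert sample_record.t_end == pytest.approx(11 / 15)


class TestRenderClip:
    def test_support_outside_event_is_static(self, sample_record, sample_clip):
        f = sample_clip.frames
        for t in list(range(0, sample_record.onset_frame + 1)) + \
                list(range(sample_record.offset_frame, sample_record.n_frames)):
            np.testing.assert_array_equal(f[t], f[0])

    def test_frames_inside_event_move(self, sample_record, sample_clip):
        f = sample_clip.frames
        for t in range(sample_record.onset_frame + 1, sample_record.offset_frame):
            assert np.abs(f[t] - f[0]).max() > 0

    def test_motion_energy_argmax_near_apex(self, small_records):
        for rec in small_records[:8]:
            clip = render_clip(rec, 48, 48)
            energy = np.abs(np.diff(clip.frames, axis=0)).sum(axis=(1, 2, 3))
            peak = int(np.argmax(energy))  # energy[i] is the step i -> i+1
            assert abs(peak - rec.apex_frame) <= 1 or abs(peak + 1 - rec.apex_frame) <= 1

    def test_only_active_regions_perturbed(self, sample_record):
        clip = render_clip(sample_record, 64, 64)
        delta = np.abs(clip.frames - clip.frames[0]).max(axis=0)[..., 0]
        moved = delta > 1e-9
        mask = np.zeros((64, 64), dtype=bool)
        for au in sample_record.au_set:
            rs, cs = au_region(au, 64, 64)
            mask[rs, cs] = True
        assert moved[mask].any()
        assert not moved[~mask].any()

    def test_min_size_enforced(self, sample_record):
        with pytest.raises(ValueError):
            render_clip(sample_record, 16, 64)

    def test_base_face_regions_disjoint_and_deterministic(self):
        img1 = base_face(64, 64)
        img2 = base_face(64, 64)
        np.testing.assert_array_equal(img1, img2)
        seen = np.zeros((64, 64), dtype=int)
        for au in AU_INVENTORY:
            rs, cs = au_region(au, 64, 64)
            seen[rs, cs] += 1
        assert seen.max() == 1


class TestCorpus:
    def test_counts_and_subjects(self, tmp_path):
        records = make_corpus(tmp_path / "c", n_clips=10, n_subjects=5, seed=42,
                              write_frames=False)
        assert len(records) == 10
        assert len({r.subject_id for r in records}) == 5

    def test_manifest_byte_identical_across_runs(self, tmp_path):
        make_corpus(tmp_path / "a", 8, 4, seed=9, write_frames=False)
        make_corpus(tmp_path / "b", 8, 4, seed=9, write_frames=False)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
            (tmp_path / "b" / "manifest.csv").read_bytes()
        assert (tmp_path / "a" / "labels.json").read_bytes() == \
            (tmp_path / "b" / "labels.json").read_bytes()

    def test_round_trip_reproduces_records(self, tmp_path):
        written = make_corpus(tmp_path / "c", 12, 3, seed=4, write_frames=False)
        loaded = load_corpus(tmp_path / "c")
        assert loaded == written

    def test_requires_enough_clips(self):
        with pytest.raises(ValueError):
            make_records(3, 5)
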