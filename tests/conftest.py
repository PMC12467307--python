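import pytest

from aucurve.fixtures import (
    SyntheticClipRecord,
    default_emotion_specs,
    make_records,
    render_clip,
)


@pytest.fixture(scope="session")
def emotion_specs():
    return default_emotion_specs()


@pytest.fixture(scope="session")
def happiness_spec(emotion_specs):
    return emotion_specs["happiness"]


@pytest.fixture(scope="session")
def sample_record():
    return SyntheticClipRecord(
        clip_id="clip_test", subject_id="subj_0", emotion="happiness",
        au_set=frozenset({"AU6", "AU12"}),
        au_values={"AU6": 0.8, "AU12": 1.0},
        onset_frame=4, apex_frame=8, offset_frame=11, n_frames=16, seed=7)


@pytest.fixture(scope="session")
def sample_clip(sample_record):
    return render_clip(sample_record, 64, 64)


@pytest.fixture(scope="session")
def small_records():
    return make_records(21, 7, seed=11)
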