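import numpy as np
import pytest

import swallowsound as ss


@pytest.fixture(scope="session")
def extractor() -> ss.FeatureExtractor:
    return ss.FeatureExtractor()


@pytest.fixture(scope="session")
def small_teacher() -> ss.TeacherSet:
    """A small, fast teacher set shared by classifier-level tests."""
    return ss.synth_teacher_set(n_clips=16, clip_dur_s=0.6, seed=7)


@pytest.fixture(scope="session")
def small_model(small_teacher: ss.TeacherSet) -> ss.CrackleModel:
    return ss.train(small_teacher, rounds=40, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_decisions(present: np.ndarray, rate: int = 44_100) -> ss.FrameDecisions:
    """Wrap a hand-built presence track in FrameDecisions on the 12-ms grid."""
    present = np.asarray(present, dtype=bool)
    hop = round(0.012 * rate)
    window = round(0.024 * rate)
    grid = ss.FrameGrid(hop_samples=hop, window_samples=window,
                        n_frames=present.size, rate=rate)
    y = np.where(present, 1.0, -1.0)
    return ss.FrameDecisions(grid=grid, y=y, present=present, threshold=0.0)
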