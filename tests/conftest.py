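import pytest

from acumap import gen_face_landmarks, gen_hand_landmarks, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture()
def front_hand():
    return gen_hand_landmarks("front", handedness="right", seed=0)


@pytest.fixture()
def back_hand():
    return gen_hand_landmarks("back", handedness="right", seed=0)


@pytest.fixture()
def center_face():
    return gen_face_landmarks("center", seed=0)
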