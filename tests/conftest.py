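import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_labels():
    """4 samples x 3 labels; co-occurrence worked out by hand in the tests."""
    return np.array([[1, 1, 0],
                     [1, 0, 0],
                     [0, 1, 1],
                     [1, 1, 0]])


@pytest.fixture
def glove_file(tmp_path):
    """Write a small GloVe-style text file and return its path."""
    def _write(lines, name="vectors.txt"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path
    return _write


@pytest.fixture
def toy_manifest(tmp_path, toy_labels):
    """Manifest CSV wrapping the toy label matrix (no real images needed)."""
    frame = pd.DataFrame({
        "image_path": [f"images/img_{i}.png" for i in range(4)],
        "patient_id": ["p0", "p0", "p1", "p1"],
        "eye": ["OD", "OS", "OD", "OS"],
        "a": toy_labels[:, 0],
        "b": toy_labels[:, 1],
        "c": toy_labels[:, 2],
    })
    path = tmp_path / "manifest.csv"
    frame.to_csv(path, index=False)
    return path
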