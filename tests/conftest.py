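import numpy as np
import pytest

from roughpnn.data import DecisionTable


def make_table(features, labels, attrs=None, label_set=None):
    feats = np.asarray(features, dtype=float)
    n, k = feats.shape
    return DecisionTable(
        sample_ids=tuple(f"s{i}" for i in range(n)),
        features=feats,
        attribute_index=tuple(attrs or range(1, k + 1)),
        labels=tuple(labels),
        label_set=tuple(label_set or sorted(set(labels))),
    )


@pytest.fixture
def four_sample_table():
    """1-D table with one mixed granule at delta=0.15 (hand-worked case)."""
    return make_table([[0.0], [0.1], [0.2], [0.7]], ["a", "a", "b", "b"])


@pytest.fixture
def random_table():
    """Reusable 12-sample, 3-attribute table with features in [0,1]."""
    rng = np.random.default_rng(42)
    feats = rng.uniform(size=(12, 3))
    labels = ["a"] * 6 + ["b"] * 6
    return make_table(feats, labels)


def write_wdbc_lines(path, rows):
    """Write a toy file in the 32-field WDBC dialect."""
    with open(path, "w") as fh:
        for rid, diag, feats in rows:
            fh.write(",".join([str(rid), diag] + [f"{v:g}" for v in feats]) + "\n")


@pytest.fixture
def toy_wdbc(tmp_path):
    rng = np.random.default_rng(0)
    rows = [
        (8510426 + i, diag, rng.uniform(0.01, 900.0, size=30))
        for i, diag in enumerate(["M", "B", "B"])
    ]
    path = tmp_path / "toy_wdbc.data"
    write_wdbc_lines(path, rows)
    return path
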