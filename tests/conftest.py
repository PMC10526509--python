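import numpy as np
import pytest

from gradwise.data_io import FeatureTable


@pytest.fixture
def toy_csv(tmp_path):
    """4-row CSV with a binary column, a continuous column and a Grade label."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "A,B,Grade\n"
        "0,1.5,LGG\n"
        "1,2.5,GBM\n"
        "0,3.5,LGG\n"
        "1,4.5,GBM\n"
    )
    return path


def make_table(X, y, kinds=None, names=None):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = tuple(names) if names else tuple(f"f{j}" for j in range(p))
    if kinds is None:
        kinds = tuple(
            "binary" if set(np.unique(X[:, j])) <= {0.0, 1.0} else "continuous"
            for j in range(p)
        )
    return FeatureTable(
        sample_ids=tuple(range(n)),
        feature_names=names,
        feature_kinds=tuple(kinds),
        X=X,
        y=np.asarray(y, dtype=int),
        positive_label="GBM",
    )


@pytest.fixture
def table_factory():
    return make_table
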