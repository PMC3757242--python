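import numpy as np
import pytest

from rbcompare import ExpressionStudy, OrthologPairSet


@pytest.fixture
def tiny_pair_studies():
    """Two small studies (3v3 / 4v3 samples, 6 ortholog pairs) with signal."""
    rng = np.random.default_rng(7)
    n = 6
    ids_a = [f"a{i}" for i in range(n)]
    ids_b = [f"b{i}" for i in range(n)]
    shift = np.array([2.0, -2.0, 2.0, 0.0, 0.0, 0.0])
    mat_a = rng.normal(0, 1, (n, 6))
    mat_a[:, :3] += shift[:, None]
    mat_b = rng.normal(0, 1, (n, 7))
    mat_b[:, :4] += shift[:, None]
    study_a = ExpressionStudy(mat_a, ids_a, ["tumor"] * 3 + ["control"] * 3, "A")
    study_b = ExpressionStudy(mat_b, ids_b, ["tumor"] * 4 + ["control"] * 3, "B")
    pairs = OrthologPairSet(list(zip(ids_a, ids_b)))
    return study_a, study_b, pairs


def make_null_studies(rng, n_features=6, n_a=(3, 3), n_b=(3, 3)):
    ids_a = [f"a{i}" for i in range(n_features)]
    ids_b = [f"b{i}" for i in range(n_features)]
    sa = ExpressionStudy(
        rng.normal(0, 1, (n_features, sum(n_a))), ids_a,
        ["tumor"] * n_a[0] + ["control"] * n_a[1], "A",
    )
    sb = ExpressionStudy(
        rng.normal(0, 1, (n_features, sum(n_b))), ids_b,
        ["tumor"] * n_b[0] + ["control"] * n_b[1], "B",
    )
    return sa, sb, OrthologPairSet(list(zip(ids_a, ids_b)))
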