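import numpy as np
import pytest

from mass_select import EncodedMatrix, PhenotypeMatrix


def make_encoded(values, domain="pm_one", groups=None, feature_ids=None):
    """Wrap a raw array as an EncodedMatrix with singleton groups."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    fids = feature_ids or [f"a{j}" for j in range(m)]
    groups = groups or {f: [j] for j, f in enumerate(fids)}
    prov = {f: (f, None) for f in fids}
    return EncodedMatrix([f"s{i}" for i in range(n)], fids, values, domain, groups, prov)


def random_pm_one(rng, n, m):
    """Random +/-1 matrix avoiding constant columns."""
    while True:
        vals = rng.choice([-1.0, 1.0], size=(n, m))
        if (np.abs(vals.sum(axis=0)) < n).all():
            return make_encoded(vals)


@pytest.fixture
def binary_matrix():
    return PhenotypeMatrix(
        ["s1", "s2", "s3", "s4"],
        ["a", "b"],
        np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0], [0.0, 0.0]]),
    )


@pytest.fixture
def categorical_matrix():
    levels = ["negative", "weak", "positive"]
    vals = np.array(
        [
            ["negative", "positive"],
            ["weak", "negative"],
            ["positive", "weak"],
        ],
        dtype=object,
    )
    return PhenotypeMatrix(["s1", "s2", "s3"], ["c1", "c2"], vals, level_set=levels)
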