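import numpy as np
import pandas as pd
import pytest

from sliderselect import (
    ExpressionMatrix,
    make_fig1_fixture,
    normalize_contributions,
)


@pytest.fixture(scope="session")
def fig1_matrix():
    return make_fig1_fixture()


@pytest.fixture(scope="session")
def fig1_contrib(fig1_matrix):
    return normalize_contributions(fig1_matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_contrib_table(rng, n_features, n_facets, zero_frac=0.1):
    """Random non-negative matrix with some all-zero rows, plus its
    normalized percentages/defined map in plain-dict form for oracles."""
    raw = rng.gamma(1.0, 50.0, size=(n_features, n_facets))
    zero_rows = rng.random(n_features) < zero_frac
    raw[zero_rows] = 0.0
    features = [f"g{i}" for i in range(n_features)]
    facets = [f"t{j}" for j in range(n_facets)]
    matrix = ExpressionMatrix(pd.DataFrame(raw, index=features, columns=facets))
    contrib = normalize_contributions(matrix)
    pct = {
        f: {t: contrib.percentages.at[f, t] for t in facets} for f in features
    }
    defined = {f: bool(contrib.defined_mask[f]) for f in features}
    return contrib, pct, defined


def random_intervals(rng, facets, n_constraints):
    """Random slider intervals on a subset of facets (may include [0,0])."""
    chosen = rng.choice(len(facets), size=min(n_constraints, len(facets)),
                        replace=False)
    intervals = {}
    for j in chosen:
        lo, hi = np.sort(np.round(rng.uniform(0, 100, size=2), 1))
        if rng.random() < 0.15:
            lo = hi = 0.0  # exclusion slider
        intervals[facets[j]] = (float(lo), float(hi))
    return intervals
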