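import numpy as np
import pandas as pd
import pytest

from polyprof import FRACTIONS, FractionCountMatrix


def make_fcm(counts, replicates=None, ribo_ng=10.0, total_ug=5.0, phase="custom"):
    """Build a FractionCountMatrix from a genes x (7 * n_reps) array.

    ``counts`` may be a 2-D array whose columns cycle fraction-major
    (A..G for rep 1, then rep 2, ...) or a DataFrame already carrying the
    (fraction, replicate) MultiIndex.
    """
    if isinstance(counts, pd.DataFrame) and isinstance(counts.columns, pd.MultiIndex):
        cols = counts.columns
        frame = counts
    else:
        arr = np.atleast_2d(np.asarray(counts, dtype=float))
        n_reps = arr.shape[1] // len(FRACTIONS)
        replicates = replicates or list(range(1, n_reps + 1))
        cols = pd.MultiIndex.from_product([replicates, list(FRACTIONS)]).swaplevel()
        cols = pd.MultiIndex.from_tuples([(f, k) for k in replicates for f in FRACTIONS],
                                         names=["fraction", "replicate"])
        frame = pd.DataFrame(arr, columns=cols,
                             index=[f"g{i}" for i in range(arr.shape[0])])
    ribo = pd.Series(np.broadcast_to(ribo_ng, len(cols)).astype(float), index=cols)
    total = pd.Series(np.broadcast_to(total_ug, len(cols)).astype(float), index=cols)
    return FractionCountMatrix(frame, ribo, total, phase=phase)


@pytest.fixture(scope="session")
def study_dataset():
    """Gradient dataset at the package's default study conditions."""
    from polyprof import simulate_counts

    return simulate_counts(seed=20_260_925)
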