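import numpy as np
import pytest

from dnbtip.expression_io import ExpressionSeries


def make_series(values, n_times, n_reps, gene_ids=None):
    """Build an ExpressionSeries from a genes x (n_times*n_reps) array."""
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    labels, time_of, rep_of = [], {}, {}
    for t in range(1, n_times + 1):
        for r in range(1, n_reps + 1):
            lab = f"M{t}_R{r}"
            labels.append(lab)
            time_of[lab] = t
            rep_of[lab] = r
    return ExpressionSeries(gene_ids, labels, time_of, rep_of, values)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def small_random_series():
    """20 genes x 3 time points x 4 replicates of plain Gaussian noise."""
    rng = np.random.default_rng(42)
    return make_series(rng.normal(size=(20, 12)), n_times=3, n_reps=4)
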