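import numpy as np
import pytest

from jacbic.io_formats import ExpressionMatrix


def make_expr(values, scale="log_rsem", gene_prefix="g", sample_prefix="s"):
    """ExpressionMatrix from a 2-D array with generated ids."""
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, scale)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
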