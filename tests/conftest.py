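import numpy as np
import pandas as pd

from amlsig.preprocess import ExpressionMatrix


def make_matrix(values, genes=None, samples=None, state="raw_counts"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), state
    )
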