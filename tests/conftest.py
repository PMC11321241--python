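import numpy as np
import pandas as pd
import pytest

import stemwalk as sw


@pytest.fixture
def small_expr() -> sw.ExpressionMatrix:
    """3 genes x 4 samples, one gene per co-expression biotype."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [4.0, 3.0, 2.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return sw.ExpressionMatrix(
        values=values, biotype={"g1": "PCG", "g2": "lncRNA", "g3": "miRNA"}
    )


@pytest.fixture
def random_expr() -> sw.ExpressionMatrix:
    """20 genes x 30 samples of mixed biotypes with generic random values."""
    rng = np.random.default_rng(7)
    biotypes = (["PCG"] * 8) + (["TF"] * 2) + (["lncRNA"] * 5) + (["miRNA"] * 5)
    genes = [f"g{i:02d}" for i in range(20)]
    values = pd.DataFrame(
        rng.standard_normal((20, 30)),
        index=genes,
        columns=[f"s{j:02d}" for j in range(30)],
    )
    return sw.ExpressionMatrix(values=values, biotype=dict(zip(genes, biotypes)))


@pytest.fixture(scope="session")
def planted_dataset() -> sw.SyntheticDataset:
    """Default study-condition dataset: 30 seed PCGs, 20 planted ncRNAs,
    400 background genes, 200 samples, rho = 0.9."""
    return sw.generate(sw.SyntheticSpec(rng_seed=11))
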