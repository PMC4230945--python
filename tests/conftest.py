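import numpy as np
import pandas as pd
import pytest

import refstab as r


@pytest.fixture
def design() -> r.SampleDesign:
    """The study layout: 3 organs x 5 stages, one sample per cell."""
    rows = [
        (f"{o}_{s}", o, s, 1)
        for o in ("root", "stem", "leaf")
        for s in ("LP", "FS", "GFS", "RFS", "RGS")
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "organ", "stage", "replicate"])
    return r.SampleDesign(df.set_index("sample_id"))


@pytest.fixture
def hand_quantities() -> pd.DataFrame:
    """3-gene quantity matrix with known pairwise variations (0, 1, 1)."""
    return pd.DataFrame(
        [[1.0, 2.0, 4.0], [2.0, 4.0, 8.0], [1.0, 1.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture(scope="session")
def panel_ct() -> r.CtTable:
    """Simulated 20-gene x 15-sample x 3-replicate Ct table (study-like)."""
    return r.simulate_ct(r.default_truth(11))


def random_quantities(rng, n_genes, n_samples) -> pd.DataFrame:
    """Random positive quantity matrix rescaled to max 1 per gene."""
    ct = rng.uniform(18, 30, size=(n_genes, n_samples))
    q = 2.0 ** (ct.min(axis=1, keepdims=True) - ct)
    return pd.DataFrame(
        q,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
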