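import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from milkgut import MarkerPanel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel() -> MarkerPanel:
    return MarkerPanel.default()


@pytest.fixture
def small_counts() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    X = rng.integers(0, 50, size=(12, 6))
    X[:, 0] += 10  # no all-zero rows
    return pd.DataFrame(
        X, index=[f"S{i:02d}" for i in range(12)], columns=[f"g{j}" for j in range(6)]
    )


def presence_vector(panel: MarkerPanel, n_hmo: int, ara: bool, n_lnt: int = 0) -> pd.Series:
    """Marker presence vector with the first ``n_hmo`` cluster genes, both or
    neither ara gene, and the first ``n_lnt`` transporter genes set."""
    bits = {g: 0 for g in panel.all_genes}
    for g in panel.hmo_cluster[:n_hmo]:
        bits[g] = 1
    if ara:
        for g in panel.ara_genes:
            bits[g] = 1
    for g in panel.lnt_genes[:n_lnt]:
        bits[g] = 1
    return pd.Series(bits, name="sample")
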