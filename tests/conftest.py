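from importlib import resources

import numpy as np
import pandas as pd
import pytest

from reprokit.io import read_roles, read_sif
from reprokit.network import InteractionNetwork


@pytest.fixture()
def fig4_network() -> InteractionNetwork:
    """The packaged curated network with the named regulatory paths."""
    data = resources.files("reprokit") / "data"
    return InteractionNetwork.from_edges(
        read_sif(data / "fig4_network.sif"), read_roles(data / "fig4_roles.tsv")
    )


@pytest.fixture()
def toy_matrix():
    """Tiny two-group expression matrix for detection/DE unit tests."""
    from reprokit.expression import ExpressionMatrix

    probes = [f"p{i}" for i in range(4)]
    samples = ["donor-a", "donor-b", "t24-a", "t24-b"]
    groups = pd.Series(["donor", "donor", "t24", "t24"], index=samples)
    intens = pd.DataFrame(
        np.array([
            [5.0, 5.2, 6.1, 6.9],
            [8.0, 8.1, 8.0, 8.1],
            [7.0, 7.1, 7.2, 7.0],
            [6.0, 6.2, 6.1, 6.3],
        ]),
        index=probes, columns=samples,
    )
    det = pd.DataFrame(0.001, index=probes, columns=samples)
    return ExpressionMatrix(intens, det, groups)
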