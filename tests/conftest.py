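import numpy as np
import pandas as pd
import pytest

from spatialfly import GenePanel, SpotTable
from spatialfly.synthetic_data import paper_like_body_scene


@pytest.fixture()
def panel3() -> GenePanel:
    return GenePanel(("geneA", "geneB", "geneC"))


@pytest.fixture()
def tiny_spots(panel3) -> SpotTable:
    df = pd.DataFrame(
        {
            "gene": ["geneA", "geneB", "geneC"],
            "x": [1.0, 2.0, 3.0],
            "y": [4.0, 5.0, 6.0],
            "sample": ["s1", "s1", "s1"],
        }
    )
    return SpotTable(df, panel3)


def make_spots(genes, xs, ys, panel=None, sample="s1") -> SpotTable:
    genes = list(genes)
    panel = panel or GenePanel(tuple(dict.fromkeys(genes)))
    df = pd.DataFrame(
        {"gene": genes, "x": np.asarray(xs, float), "y": np.asarray(ys, float),
         "sample": sample}
    )
    return SpotTable(df, panel)


@pytest.fixture(scope="session")
def body_scene():
    """Standard synthetic body section, default seed; shared across tests."""
    return paper_like_body_scene(seed=0)
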