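import numpy as np
import pandas as pd
import pytest

from lhcoding import synthetic
from lhcoding.anatomy import Box


@pytest.fixture(scope="session")
def small_panel():
    """12-odor balanced panel plus blank."""
    return synthetic.gen_odor_panel(12, seed=101)


@pytest.fixture(scope="session")
def small_dataset(small_panel):
    """PN-like and LHON-like types, 3 cells each, 4 trials."""
    templates = [
        synthetic.pn_template(cell_type="PNa"),
        synthetic.lhon_template(cell_type="LHONa"),
    ]
    return synthetic.gen_spike_dataset(templates, 3, small_panel, seed=202)


@pytest.fixture(scope="session")
def region_layout():
    return {
        "LH": Box("LH", (0.0, 0.0, 0.0), (40.0, 40.0, 40.0)),
        "SLP": Box("SLP", (60.0, 0.0, 0.0), (100.0, 40.0, 40.0)),
        "AVLP": Box("AVLP", (0.0, 60.0, 0.0), (40.0, 100.0, 40.0)),
    }


@pytest.fixture(scope="session")
def skeleton_set(region_layout):
    """3 planted types, 3 jittered copies each."""
    return synthetic.gen_skeleton_set(3, 3, region_layout, seed=303, jitter=0.3)


def chain_skeleton(coords, labels=None):
    """A simple path skeleton through the given 3-D coordinates."""
    from lhcoding.datasets import LabeledSkeleton

    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    labels = labels if labels is not None else [3] * n
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(1, n + 1),
            "label": labels,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "radius": 0.5,
            "parent_id": [-1] + list(range(1, n)),
        }
    )
    return LabeledSkeleton(nodes, skeleton_id="chain")
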