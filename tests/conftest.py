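import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def foci_frame(rows):
    """Build a foci table from (cell_id, bivalent_id, channel, position) rows."""
    return pd.DataFrame(rows, columns=["cell_id", "bivalent_id", "channel", "position_frac"])


@pytest.fixture
def make_foci():
    return foci_frame
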