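import numpy as np
import pytest

from panelnet import SymptomPanel, make_ground_truth, simulate_panel
from panelnet.types import DEFAULT_NODE_LABELS


def panel_from_items(items_pre, items_post=None):
    """Minimal complete panel around raw item matrices (no outcome)."""
    items_pre = np.asarray(items_pre)
    n, p = items_pre.shape
    labels = DEFAULT_NODE_LABELS if p == 20 else tuple(f"V{i+1}" for i in range(p))
    return SymptomPanel(
        subject_id=np.arange(n),
        items_pre=items_pre,
        items_post=items_pre if items_post is None else np.asarray(items_post),
        age=np.full(n, 12.0), sex=np.zeros(n, int), race=np.zeros(n, int),
        maltreatment=np.zeros(n, int),
        outcome_pre=np.full(n, np.nan), outcome_post=np.full(n, np.nan),
        node_labels=labels,
    )


@pytest.fixture(scope="session")
def default_truth():
    return make_ground_truth(seed=7)


@pytest.fixture(scope="session")
def default_panel(default_truth):
    return simulate_panel(default_truth, n=652, seed=7)


@pytest.fixture(scope="session")
def small_panel(default_truth):
    return simulate_panel(default_truth, n=200, seed=11)
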