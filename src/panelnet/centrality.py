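"""Signed expected-influence centrality for undirected and directed networks.

One-step expected influence (EI) sums a node's edge weights preserving
sign; when every edge is positive it coincides with strength. For a
cross-lagged network the diagonal (autoregressive) cells are excluded:
out-EI of node i sums its outgoing effects b[i, j] (j != i), in-EI of node
j sums its incoming effects b[i, j] (i != j). Nodes with z > cutoff
(population-sd z-scores across nodes) are flagged central.
"""

from __future__ import annotations

import numpy as np

from .types import CentralityTable, DirectedNetwork, WeightedNetwork, zscore


def expected_influence(net: WeightedNetwork, z_cutoff: float = 1.0) -> CentralityTable:
    """One-step signed EI for a symmetric partial-correlation network."""
    ei = net.weights.sum(axis=1)
    z = zscore(ei)
    return CentralityTable(
        node_labels=net.node_labels,
        ei_raw=ei, ei_z=z, is_central=z > z_cutoff,
        meta={"z_sd": "population", "z_cutoff": z_cutoff},
    )


def directed_expected_influence(net: DirectedNetwork,
                                z_cutoff: float = 1.0) -> CentralityTable:
    """In- and out-EI for a cross-lagged network, autoregressive cells excluded."""
    b = net.b
    off = b - np.diag(np.diag(b))
    out_ei = off.sum(axis=1)
    in_ei = off.sum(axis=0)
    out_z = zscore(out_ei)
    in_z = zscore(in_ei)
    return CentralityTable(
        node_labels=net.node_labels,
        in_ei_raw=in_ei, in_ei_z=in_z, in_is_central=in_z > z_cutoff,
        out_ei_raw=out_ei, out_ei_z=out_z, out_is_central=out_z > z_cutoff,
        meta={"z_sd": "population", "z_cutoff": z_cutoff},
    )
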