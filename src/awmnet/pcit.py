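"""PCIT: partial-correlation and information-theory network inference.

For every trio of AWM rows (x, y, z) the three first-order partial
correlations are computed,

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

and a data-driven local tolerance is set to the mean of the three
partial-to-direct ratios,

    eps = ( |r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz| ) / 3.

The association x-y is flagged as explainable by z — and its edge removed —
when both |r_xy| <= eps * |r_xz| and |r_xy| <= eps * |r_yz|.  Surviving
pairs form an undirected network whose edge weights are the direct
correlations r_xy.  Trios in which any direct correlation has |r| = 1
(partial correlation undefined) or is exactly 0 (ratio undefined) are
skipped.

With six trait columns per row, sample correlations are noisy, so networks
are usually trimmed afterwards to |r| >= 0.98 (:func:`trim_network`).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from ._compat import njit

log = logging.getLogger(__name__)


def row_correlations(awm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every pair of AWM rows."""
    x = awm_matrix.to_numpy(float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = awm_matrix.index[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"row {bad!r} is constant; correlation undefined")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=awm_matrix.index, columns=awm_matrix.index)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z."""
    den = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if den <= 0.0:
        raise ValueError("partial correlation undefined: |r| = 1 in the conditioning pair")
    return (r_xy - r_xz * r_yz) / np.sqrt(den)


@njit(cache=True)
def _pcit_keep(r):
    n = r.shape[0]
    keep = np.ones((n, n), np.uint8)
    for x in range(n - 1):
        for y in range(x + 1, n):
            rxy = r[x, y]
            for z in range(n):
                if z == x or z == y:
                    continue
                rxz = r[x, z]
                ryz = r[y, z]
                if rxy == 0.0 or rxz == 0.0 or ryz == 0.0:
                    continue
                d1 = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
                d2 = (1.0 - rxy * rxy) * (1.0 - ryz * ryz)
                d3 = (1.0 - rxy * rxy) * (1.0 - rxz * rxz)
                if d1 <= 0.0 or d2 <= 0.0 or d3 <= 0.0:
                    continue
                p_xy = (rxy - rxz * ryz) / np.sqrt(d1)
                p_xz = (rxz - rxy * ryz) / np.sqrt(d2)
                p_yz = (ryz - rxy * rxz) / np.sqrt(d3)
                eps = (abs(p_xy / rxy) + abs(p_xz / rxz) + abs(p_yz / ryz)) / 3.0
                if abs(rxy) <= eps * abs(rxz) and abs(rxy) <= eps * abs(ryz):
                    keep[x, y] = 0
                    keep[y, x] = 0
                    break
    return keep


def pcit(correlations: pd.DataFrame) -> nx.Graph:
    """Run PCIT on a correlation matrix; returns the inferred network.

    Nodes are all matrix rows; an edge x-y with weight r_xy survives unless
    some third row explains the association under the local tolerance.
    Zero correlations never become edges.  With fewer than 3 nodes no trio
    exists and all nonzero correlations are retained (with a warning).
    """
    r = correlations.to_numpy(float)
    if not np.allclose(r, r.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    nodes = list(correlations.index)
    n = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if n < 3:
        log.warning("fewer than 3 nodes: no trios, all nonzero correlations retained")
        keep = np.ones((n, n), np.uint8)
    else:
        keep = _pcit_keep(np.ascontiguousarray(r))
    for i in range(n - 1):
        for j in range(i + 1, n):
            if keep[i, j] and r[i, j] != 0.0:
                g.add_edge(nodes[i], nodes[j], weight=float(r[i, j]))
    return g


def trim_network(network: nx.Graph, threshold: float = 0.98, signed: bool = False) -> nx.Graph:
    """Keep edges with |weight| >= threshold (or weight >= threshold when
    ``signed``); node set is preserved."""
    out = nx.Graph()
    out.add_nodes_from(network.nodes)
    for u, v, d in network.edges(data=True):
        wt = d["weight"]
        val = wt if signed else abs(wt)
        if val >= threshold:
            out.add_edge(u, v, **d)
    return out


def connected_nodes(network: nx.Graph) -> set:
    """Nodes with at least one retained connection."""
    return {n for n, d in network.degree if d > 0}


def write_edgelist(network: nx.Graph, path) -> None:
    rows = [
        {"node_a": u, "node_b": v, "weight": d["weight"]}
        for u, v, d in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)
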