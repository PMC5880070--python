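"""Across-breed network statistics.

Covers the intersection of breed-specific gene networks with its exact
significance test, pairwise shared sub-networks, scale-free (power-law)
degree-distribution testing, and the QTL-anchored hub report.

The intersection test models each breed's network gene set as an
independent uniform draw without replacement from a common gene universe.
The size of the intersection of the first two sets is hypergeometric, and
because each further set is independent of the earlier ones, the
intersection size after adding a set of size m is again hypergeometric
given the current intersection size.  Chaining these kernels gives the
exact distribution of the multi-set intersection; the tail is accumulated
in log space so p-values far below 1e-300 remain representable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp, zeta
from scipy.stats import hypergeom

from .pcit import connected_nodes

log = logging.getLogger(__name__)


@dataclass
class IntersectionResult:
    shared_nodes: set
    set_sizes: dict
    universe_n: int
    observed_k: int
    p_value: float | None = None


def intersect_networks(networks: dict, universe_n: int | None = None) -> IntersectionResult:
    """Genes shared by every breed network (nodes with at least one retained
    connection).  The p-value is filled in when ``universe_n`` is given."""
    if len(networks) < 2:
        raise ValueError("need at least two networks to intersect")
    node_sets = {b: connected_nodes(g) for b, g in networks.items()}
    shared = set.intersection(*node_sets.values())
    res = IntersectionResult(
        shared_nodes=shared,
        set_sizes={b: len(s) for b, s in node_sets.items()},
        universe_n=universe_n or 0,
        observed_k=len(shared),
    )
    if universe_n:
        res.p_value = exact_intersection_pvalue(
            list(res.set_sizes.values()), universe_n, res.observed_k
        )
    return res


def intersection_log_pmf(set_sizes, universe_n: int) -> np.ndarray:
    """Exact log-probabilities of the multi-set intersection size.

    Entry k is log P(|A_1 ∩ ... ∩ A_s| = k) for independent uniform draws
    without replacement of the given sizes from a universe of ``universe_n``.
    """
    sizes = [int(m) for m in set_sizes]
    if any(m > universe_n for m in sizes):
        raise ValueError("set size exceeds the universe")
    if not sizes:
        raise ValueError("need at least one set size")
    # the intersection of the first set alone is the set itself
    cap = sizes[0]
    logp = np.full(cap + 1, -np.inf)
    logp[cap] = 0.0
    for m in sizes[1:]:
        new_cap = min(cap, m)
        j = np.arange(cap + 1)
        k = np.arange(new_cap + 1)
        # kernel[j, k] = log P(Hypergeom(N, j, m) = k)
        kernel = hypergeom.logpmf(k[None, :], universe_n, j[:, None], m)
        logp = logsumexp(logp[:, None] + kernel, axis=0)
        cap = new_cap
    return logp


def exact_intersection_pvalue(set_sizes, universe_n: int, observed_k: int) -> float:
    """P(intersection >= observed_k); exact, computed in log space.

    For two sets this is the hypergeometric survival function; an
    infeasibly large ``observed_k`` returns 0 with a warning.
    """
    if observed_k > min(set_sizes):
        log.warning(
            "observed intersection %d exceeds the smallest set (%d); p = 0",
            observed_k, min(set_sizes),
        )
        return 0.0
    if observed_k <= 0:
        return 1.0
    logp = intersection_log_pmf(set_sizes, universe_n)
    return float(min(1.0, np.exp(logsumexp(logp[observed_k:]))))


def shared_edges(networks: dict, breeds=None) -> set:
    """Unordered node pairs present in every network of ``breeds``
    (presence-based: weights and signs are ignored)."""
    breeds = list(breeds or networks)
    if len(breeds) < 2:
        raise ValueError("need at least two networks to compare edges")
    edge_sets = [
        {frozenset((u, v)) for u, v in networks[b].edges} for b in breeds
    ]
    return set.intersection(*edge_sets)


# ---------------------------------------------------------------------------
# power-law degree-distribution test

def _fit_alpha(x: np.ndarray, xmin: int) -> float:
    tail = x[x >= xmin]
    return 1.0 + tail.size / np.log(tail / (xmin - 0.5)).sum()


def _ks_distance(x: np.ndarray, xmin: int, alpha: float) -> float:
    tail = np.sort(x[x >= xmin])
    n = tail.size
    vals = np.unique(tail)
    # discrete power-law CDF via the Hurwitz zeta function
    z0 = zeta(alpha, xmin)
    cdf = 1.0 - zeta(alpha, vals + 1) / z0
    ecdf_hi = np.searchsorted(tail, vals, side="right") / n
    ecdf_lo = np.searchsorted(tail, vals, side="left") / n
    return float(np.max(np.maximum(np.abs(ecdf_hi - cdf), np.abs(ecdf_lo - cdf))))


def _fit_powerlaw(x: np.ndarray):
    candidates = np.unique(x)
    if candidates.size > 1:
        candidates = candidates[:-1]   # need >= 2 distinct tail values
    best = None
    for xmin in candidates:
        tail_n = int((x >= xmin).sum())
        if tail_n < 2:
            continue
        alpha = _fit_alpha(x, int(xmin))
        if not np.isfinite(alpha) or alpha <= 1.0:
            continue
        d = _ks_distance(x, int(xmin), alpha)
        if best is None or d < best[2]:
            best = (int(xmin), alpha, d)
    if best is None:
        raise ValueError("degree sequence is degenerate; power-law fit undefined")
    return best


def _sample_powerlaw(rng, n, xmin, alpha):
    u = rng.random(n)
    return np.floor((xmin - 0.5) * (1.0 - u) ** (-1.0 / (alpha - 1.0)) + 0.5).astype(int)


def powerlaw_ks_test(degrees, n_boot: int = 100, seed: int = 0):
    """Fit a discrete power law to a degree sequence and bootstrap a
    goodness-of-fit p-value (Clauset-Shalizi-Newman procedure).

    The tail start x_min is chosen by KS minimization, the exponent by
    maximum likelihood, and the p-value is the fraction of semi-parametric
    bootstrap replicates whose best-fit KS distance exceeds the observed
    one.  Returns ``(alpha, ks, p)``.
    """
    x = np.asarray([d for d in degrees if d >= 1], int)
    if x.size < 10:
        raise ValueError("need at least 10 nodes with degree >= 1")
    if np.unique(x).size == 1:
        raise ValueError("all degrees equal; power-law fit undefined")
    xmin, alpha, ks = _fit_powerlaw(x)

    rng = np.random.default_rng(seed)
    below = x[x < xmin]
    n_tail = int((x >= xmin).sum())
    exceed = 0
    for _ in range(n_boot):
        tail_draws = rng.binomial(x.size, n_tail / x.size)
        synth = np.concatenate(
            [
                _sample_powerlaw(rng, tail_draws, xmin, alpha),
                rng.choice(below, size=x.size - tail_draws, replace=True)
                if below.size
                else _sample_powerlaw(rng, x.size - tail_draws, xmin, alpha),
            ]
        )
        try:
            _, _, d = _fit_powerlaw(synth)
        except ValueError:
            continue
        if d >= ks:
            exceed += 1
    return float(alpha), float(ks), exceed / n_boot


def hub_report(
    network: nx.Graph, gene_qtl: pd.DataFrame, top_fraction: float = 0.05
) -> pd.DataFrame:
    """Most-connected genes (top ``top_fraction`` of nodes by degree) that
    lie within a QTL; returns ``gene, degree, qtl`` sorted by degree."""
    deg = dict(network.degree)
    if not deg:
        return pd.DataFrame(columns=["gene", "degree", "qtl"])
    n_top = max(1, int(np.ceil(top_fraction * len(deg))))
    cutoff = sorted(deg.values(), reverse=True)[n_top - 1]
    top = {g for g, d in deg.items() if d >= cutoff}
    if top_fraction >= 1.0:
        top = set(deg)
    qtl_map = gene_qtl.groupby("gene")["qtl"].agg(lambda s: ",".join(sorted(s)))
    rows = [
        {"gene": g, "degree": deg[g], "qtl": qtl_map[g]}
        for g in top
        if g in qtl_map.index
    ]
    return (
        pd.DataFrame(rows, columns=["gene", "degree", "qtl"])
        .sort_values(["degree", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
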