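"""Genomic and pedigree relationship matrices for network-enriched GBLUP.

Six genomic kernels are used in the prediction models:

- BASE: VanRaden method-1 G on the whole marker panel,
  ``G = MM' / (2 sum p_j (1 - p_j))`` with M = code - 2p;
- TOP25 / BOT75: method-1 G on markers ranking in the per-trait top PV_g
  quartile for at least three of the six traits, and on the complement;
- NET / FREE: method-1 G on the AWM source markers and on the complement;
- CONN: ``G = Z D Z'`` with Z centered-and-scaled genotypes over the NET
  markers and D the gene-gene correlation structure derived from the AWM
  network (unit diagonal, network edge weights off-diagonal), rescaled to
  the BASE matrix with VanRaden's allele-frequency-free normalization
  (affine match of mean diagonal and mean off-diagonal).

The pedigree numerator relationship matrix A (tabular method) drives the
k-means family clustering used for cross-validation folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

log = logging.getLogger(__name__)

GRM_LABELS = ("BASE", "TOP25", "BOT75", "NET", "CONN", "FREE")


@dataclass
class GRM:
    matrix: pd.DataFrame
    label: str
    markers: list

    @property
    def bulls(self):
        return self.matrix.index

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(float)


def _centered(genotypes: GenotypeMatrix, markers=None):
    g = genotypes if markers is None else genotypes.subset_markers(markers)
    codes = g.codes.to_numpy(float)
    codes = np.where(np.isnan(codes), np.nanmean(codes, axis=0), codes)
    p = codes.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic marker available for the relationship matrix")
    if (~poly).sum():
        log.warning("excluding %d monomorphic marker(s) from G", int((~poly).sum()))
    return codes[:, poly] - 2 * p[poly], p[poly], list(np.asarray(g.markers)[poly])


def vanraden_g(genotypes: GenotypeMatrix, markers=None, label: str = "BASE") -> GRM:
    """VanRaden method-1 genomic relationship matrix.

    Allele frequencies are computed from the analysed bulls (base-population
    frequencies are not observable); monomorphic markers are excluded.
    """
    M, p, used = _centered(genotypes, markers)
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = M @ M.T / denom
    idx = genotypes.bulls
    return GRM(pd.DataFrame(G, index=idx, columns=idx), label, used)


def partition_top25(pvg_by_trait: pd.DataFrame, min_traits: int = 3, percentile: float = 75.0):
    """TOP25 = markers in the per-trait top PV_g quartile for at least
    ``min_traits`` traits; BOT75 = the complement of the panel."""
    from .gwas import retain_top_fraction

    counts = pd.Series(0, index=pvg_by_trait.index)
    for t in pvg_by_trait.columns:
        counts[retain_top_fraction(pvg_by_trait[t], percentile)] += 1
    top = list(pvg_by_trait.index[counts >= min_traits])
    bot = list(pvg_by_trait.index[counts < min_traits])
    return top, bot


def partition_network(awm, panel) -> tuple:
    """NET = AWM source markers; FREE = panel complement."""
    if len(awm.rows) == 0:
        raise ValueError("AWM is empty; no network marker partition possible")
    net_set = set(awm.markers)
    panel = list(panel)
    net = [m for m in panel if m in net_set]
    free = [m for m in panel if m not in net_set]
    return net, free


def network_d_matrix(awm, network, markers) -> pd.DataFrame:
    """Gene-gene correlation structure D for the CONN kernel, ordered like
    ``markers``: unit diagonal, trimmed-network edge weights off-diagonal."""
    marker_to_row = {m: r for r, m in awm.source_marker.items()}
    rows = [marker_to_row[m] for m in markers]
    d = np.eye(len(rows))
    pos = {r: i for i, r in enumerate(rows)}
    for u, v, dat in network.edges(data=True):
        if u in pos and v in pos:
            d[pos[u], pos[v]] = d[pos[v], pos[u]] = dat["weight"]
    return pd.DataFrame(d, index=markers, columns=markers)


def _nearest_psd(d: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(d)
    if vals.min() >= -1e-10:
        return d
    clipped = (vecs * np.maximum(vals, 0.0)) @ vecs.T
    dist = float(np.linalg.norm(d - clipped))
    np.fill_diagonal(clipped, 1.0)
    log.info("D was indefinite; nearest-PSD projection applied (|D - D+|_F = %.3g)", dist)
    return clipped


def freq_free_rescale(raw: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Affine rescaling matching mean diagonal and mean off-diagonal to the
    reference matrix (VanRaden's allele-frequency-free normalization)."""
    n = raw.shape[0]
    off = ~np.eye(n, dtype=bool)
    rd, ro = raw.diagonal().mean(), raw[off].mean()
    td, to = reference.diagonal().mean(), reference[off].mean()
    if np.isclose(rd, ro):
        raise ValueError("raw matrix has no diagonal/off-diagonal contrast to rescale")
    b = (td - to) / (rd - ro)
    a = to - b * ro
    return a + b * raw


def conn_g(
    genotypes: GenotypeMatrix,
    net_markers,
    d: pd.DataFrame,
    reference: GRM,
) -> GRM:
    """Network-correlation kernel ``G = Z D Z'`` scaled against a reference.

    Z holds centered genotypes scaled per marker by ``sqrt(2 p (1-p))``
    (VanRaden's centered-and-scaled coding); an indefinite D is replaced by
    its nearest PSD projection with the diagonal restored to 1.
    """
    M, p, used = _centered(genotypes, net_markers)
    if list(d.index) != list(used):
        d = d.loc[used, used]
    if d.shape[0] != M.shape[1]:
        raise ValueError("D dimension does not match the network marker set")
    Z = M / np.sqrt(2.0 * p * (1.0 - p))
    D = _nearest_psd(d.to_numpy(float))
    raw = Z @ D @ Z.T / Z.shape[1]
    G = freq_free_rescale(raw, reference.values())
    idx = genotypes.bulls
    return GRM(pd.DataFrame(G, index=idx, columns=idx), "CONN", used)


def a_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    Requires parents to precede offspring; unknown parents follow founder
    rules.  Inbreeding is accommodated through the diagonal recursion."""
    animals = pedigree["animal"].tolist()
    idx = {a: i for i, a in enumerate(animals)}
    sire = pedigree["sire"].tolist()
    dam = pedigree["dam"].tolist()
    n = len(animals)
    A = np.zeros((n, n))
    for i in range(n):
        s = idx.get(sire[i]) if pd.notna(sire[i]) else None
        d = idx.get(dam[i]) if pd.notna(dam[i]) else None
        if (pd.notna(sire[i]) and s is None) or (pd.notna(dam[i]) and d is None):
            raise ValueError(
                f"parent of {animals[i]} not listed before it; pedigree must be sorted"
            )
        if (s is not None and s >= i) or (d is not None and d >= i):
            raise ValueError(f"pedigree cycle or ordering violation at {animals[i]}")
        for j in range(i):
            a = 0.0
            if s is not None:
                a += 0.5 * A[j, s]
            if d is not None:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        f = 0.5 * A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + f
    return pd.DataFrame(A, index=animals, columns=animals)


def build_all_grms(
    genotypes: GenotypeMatrix,
    pvg_by_trait: pd.DataFrame,
    awm,
    network,
) -> dict:
    """Construct the six labelled kernels on a common bull ordering."""
    panel = list(genotypes.markers)
    top, bot = partition_top25(pvg_by_trait)
    net, free = partition_network(awm, panel)
    grms = {"BASE": vanraden_g(genotypes, label="BASE")}
    for label, markers in (("TOP25", top), ("BOT75", bot), ("NET", net), ("FREE", free)):
        if markers:
            grms[label] = vanraden_g(genotypes, markers, label=label)
        else:
            log.warning("marker set %s is empty; kernel skipped", label)
    d = network_d_matrix(awm, network, net)
    grms["CONN"] = conn_g(genotypes, net, d, grms["BASE"])
    return grms
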