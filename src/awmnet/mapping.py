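"""SNP-to-gene mapping and gene/QTL interval overlap.

Coordinates are 1-based and inclusive on both ends throughout the package.
A SNP maps to every gene whose interval, extended by ``max_dist`` (default
2,500 bp) on each side, contains the SNP position; when several genes
qualify all are retained (a strict nearest-only mode is available).  A gene
is assigned to a QTL when its interval is wholly contained in the QTL
interval ("located within"); a partial-overlap mode is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def map_snp_to_genes(
    marker_map: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: int = 2500,
    nearest_only: bool = False,
) -> pd.DataFrame:
    """Map markers to genes within ``max_dist`` bp of the gene boundary.

    Returns a frame ``marker, gene, distance`` (distance 0 inside the gene);
    markers with no gene in range are absent.  Markers on chromosomes
    missing from the annotation are logged and left unmapped.
    """
    out = []
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}
    n_offchrom = 0
    for row in marker_map.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            n_offchrom += 1
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        dist = np.where(
            row.bp < start, start - row.bp, np.where(row.bp > end, row.bp - end, 0)
        )
        hit = np.flatnonzero(dist <= max_dist)
        if hit.size == 0:
            continue
        if nearest_only:
            hit = hit[[np.argmin(dist[hit])]]
        for h in hit:
            out.append((row.marker, sub["name"].iat[h], int(dist[h])))
    if n_offchrom:
        log.warning("%d marker(s) on chromosomes absent from the annotation", n_offchrom)
    return pd.DataFrame(out, columns=["marker", "gene", "distance"])


def genes_in_qtl(
    genes: pd.DataFrame, qtl: pd.DataFrame, containment: bool = True
) -> pd.DataFrame:
    """Assign genes to QTL intervals; returns a frame ``gene, qtl``.

    By default the gene interval must be wholly contained in the QTL
    interval; with ``containment=False`` any overlap qualifies.  All
    qualifying QTL are reported per gene.
    """
    out = []
    if qtl.empty:
        return pd.DataFrame(columns=["gene", "qtl"])
    by_chrom = {c: q for c, q in qtl.groupby("chrom")}
    for g in genes.itertuples(index=False):
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        for q in sub.itertuples(index=False):
            if containment:
                ok = q.start <= g.start and g.end <= q.end
            else:
                ok = g.start <= q.end and q.start <= g.end
            if ok:
                out.append((g.name, q.name))
    return pd.DataFrame(out, columns=["gene", "qtl"])
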