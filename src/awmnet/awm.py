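"""Association weight matrix (AWM) construction.

The AWM summarizes six single-trait GWAS into one genes x traits matrix of
standardized effect sizes.  Rows are genes (or unmapped SNPs admitted under
criterion *a*), columns are traits, and each cell is the z-score of the
posterior-mean SNP effect within its column.  Row-wise co-association
across traits is what the downstream PCIT network works on.

SNP selection criteria (a marker qualifies if it meets at least one):
  a) significant for all traits;
  b) significant for all functional traits (DCD, MCD, GL);
  c) significant for all type traits (STAT, STR, RW).

One-SNP-one-gene: when several selected SNPs map to a gene, the one with
the largest PV_g averaged across traits represents it; exact ties break by
genomic order.  Unmapped SNPs are kept as their own rows only under
criterion a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import FUNCTIONAL_TRAITS, TYPE_TRAITS


@dataclass
class TraitGroups:
    functional: tuple = FUNCTIONAL_TRAITS
    type: tuple = TYPE_TRAITS

    def __post_init__(self):
        if set(self.functional) & set(self.type):
            raise ValueError("functional and type trait groups must be disjoint")

    @property
    def all(self) -> tuple:
        return tuple(self.functional) + tuple(self.type)


@dataclass
class AWM:
    """Standardized gene x trait effect matrix with row provenance."""

    matrix: pd.DataFrame            # rows x traits, column-standardized
    source_marker: pd.Series        # row id -> marker id
    mean_pvg: pd.Series             # row id -> mean PV_g across traits
    criteria: pd.Series = field(default=None)  # marker -> label string e.g. "ab"

    @property
    def rows(self) -> pd.Index:
        return self.matrix.index

    @property
    def markers(self) -> list:
        return self.source_marker.tolist()


def select_relevant_snp(
    significant: dict, groups: TraitGroups | None = None
) -> pd.Series:
    """Markers meeting at least one of criteria a/b/c, labeled with every
    criterion met.  ``significant`` maps trait -> iterable of marker ids."""
    groups = groups or TraitGroups()
    sets = {t: set(v) for t, v in significant.items()}
    inter_all = set.intersection(*(sets[t] for t in groups.all))
    inter_fun = set.intersection(*(sets[t] for t in groups.functional))
    inter_typ = set.intersection(*(sets[t] for t in groups.type))
    labels = {}
    for m in inter_all | inter_fun | inter_typ:
        lab = ""
        lab += "a" if m in inter_all else ""
        lab += "b" if m in inter_fun else ""
        lab += "c" if m in inter_typ else ""
        labels[m] = lab
    return pd.Series(labels, dtype=object, name="criteria").sort_index()


def resolve_one_snp_per_gene(
    criteria: pd.Series,
    snp_gene_map: pd.DataFrame,
    pvg_by_trait: pd.DataFrame,
    marker_map: pd.DataFrame,
) -> pd.DataFrame:
    """Assign one selected marker per gene (largest mean PV_g across traits);
    unmapped markers stay as own rows when they meet criterion a.

    Returns a frame indexed by row id with columns ``marker, mean_pvg``.
    """
    selected = criteria.index
    mean_pvg = pvg_by_trait.loc[selected].mean(axis=1)
    order = (
        marker_map.set_index("marker")
        .loc[selected, ["chrom", "bp"]]
        .assign(chrom=lambda d: d["chrom"].astype(str))
    )

    mapped = snp_gene_map[snp_gene_map["marker"].isin(selected)]
    rows = {}
    for gene, grp in mapped.groupby("gene"):
        cands = grp["marker"].unique()
        # largest mean PV_g wins; exact ties break by (chrom, bp)
        best = sorted(
            cands,
            key=lambda m: (-mean_pvg[m], order.loc[m, "chrom"], order.loc[m, "bp"]),
        )[0]
        rows[gene] = best
    mapped_markers = set(mapped["marker"])
    for m in selected:
        if m not in mapped_markers and "a" in criteria[m]:
            rows[m] = m

    out = pd.DataFrame(
        {"marker": pd.Series(rows), "mean_pvg": pd.Series({r: mean_pvg[m] for r, m in rows.items()})}
    )
    out.index.name = "row"
    return out.sort_index()


def build_awm(row_assignment: pd.DataFrame, abar_by_trait: pd.DataFrame) -> AWM:
    """Assemble the AWM and z-score each trait column over its rows
    (population standard deviation)."""
    if len(row_assignment) < 3:
        raise ValueError("AWM needs at least 3 rows for row-wise correlations")
    eff = abar_by_trait.loc[row_assignment["marker"]].to_numpy(float)
    mean = eff.mean(axis=0)
    sd = eff.std(axis=0)   # population (n-denominator) SD
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = abar_by_trait.columns[zero[0]]
        raise ValueError(f"AWM column for trait {bad!r} has zero variance")
    z = (eff - mean) / sd
    matrix = pd.DataFrame(z, index=row_assignment.index, columns=abar_by_trait.columns)
    return AWM(
        matrix=matrix,
        source_marker=row_assignment["marker"],
        mean_pvg=row_assignment["mean_pvg"],
    )


def awm_from_gwas(
    summaries: dict,
    snp_gene_map: pd.DataFrame,
    marker_map: pd.DataFrame,
    groups: TraitGroups | None = None,
    percentile: float = 75.0,
) -> AWM:
    """End-to-end AWM construction from per-trait posterior summaries."""
    from .gwas import retain_top_fraction

    groups = groups or TraitGroups()
    significant = {t: retain_top_fraction(s.pvg, percentile) for t, s in summaries.items()}
    criteria = select_relevant_snp(significant, groups)
    if criteria.empty:
        raise ValueError("no marker meets any of the selection criteria a/b/c")
    traits = list(groups.all)
    pvg = pd.DataFrame({t: summaries[t].pvg for t in traits})
    abar = pd.DataFrame({t: summaries[t].abar for t in traits})
    assignment = resolve_one_snp_per_gene(criteria, snp_gene_map, pvg, marker_map)
    awm = build_awm(assignment, abar)
    awm.criteria = criteria
    return awm
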