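"""Synthetic multi-breed bull populations for the network-prediction pipeline.

The generator emulates the data structure of a national dairy-cattle
evaluation: paternal half-sib families of progeny-tested bulls, biallelic
SNP genotypes obtained by Mendelian gene-drop through the pedigree, six
genetically correlated traits with sparse marker effects (a fraction
``1 - pi_qtl`` of markers carries an effect), and PTAs (predicted
transmitting abilities, half the breeding value) whose squared correlation
with the true transmitting ability equals a per-bull reliability.

Dams are not progeny-tested and are treated as unobserved Hardy-Weinberg
founders: each bull's maternal allele is drawn from the founder allele
frequency unless an explicit genotyped dam appears in the pedigree.  The
maternal grandsire (MGS) is recorded for parent-average fallbacks but does
not contribute gametes, since the dam herself is not tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAITS = ("DCD", "MCD", "GL", "STAT", "STR", "RW")
FUNCTIONAL_TRAITS = ("DCD", "MCD", "GL")
TYPE_TRAITS = ("STAT", "STR", "RW")

_STAGE_PED, _STAGE_GENO, _STAGE_ANNOT, _STAGE_TRAIT = 11, 13, 17, 19


def default_genetic_correlations(n_traits: int = 6) -> np.ndarray:
    """Moderate positive genetic correlations (0.3 within the calving block
    DCD/MCD/GL, 0.5 within the type block STAT/STR/RW, 0.2 across blocks)."""
    c = np.full((n_traits, n_traits), 0.2)
    half = n_traits // 2
    c[:half, :half] = 0.3
    c[half:, half:] = 0.5
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SimConfig:
    """Parameters of one simulated population.

    ``n_sires`` / ``progeny_per_sire`` may be scalars (shared by all breeds)
    or per-breed sequences of length ``n_breeds``.
    """

    n_breeds: int = 1
    n_sires: int | tuple = 25
    progeny_per_sire: int | tuple = 40
    n_markers: int = 2000
    n_genes: int = 400
    genome: tuple = ((1, 100_000_000), (2, 100_000_000))
    maf_range: tuple = (0.05, 0.5)
    pi_qtl: float = 0.9
    n_traits: int = 6
    genetic_correlation_matrix: np.ndarray | None = None
    heritabilities: tuple = (0.1, 0.1, 0.5, 0.4, 0.4, 0.4)
    reliability_range: tuple = (0.5, 0.9)
    rel_pa_range: tuple = (0.1, 0.35)
    missing_rate: float = 0.0
    fraction_near_gene: float = 0.6
    qtl_fraction: float = 0.2
    ld_block_size: int | None = None
    n_birth_years: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.genetic_correlation_matrix is None:
            self.genetic_correlation_matrix = default_genetic_correlations(self.n_traits)
        self.genetic_correlation_matrix = np.asarray(self.genetic_correlation_matrix, float)
        self.validate()

    def validate(self):
        c = self.genetic_correlation_matrix
        if c.shape != (self.n_traits, self.n_traits):
            raise ValueError("genetic_correlation_matrix shape does not match n_traits")
        if not np.allclose(c, c.T):
            raise ValueError("genetic_correlation_matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("genetic_correlation_matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("genetic_correlation_matrix is not positive definite")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.pi_qtl <= 1:
            raise ValueError("pi_qtl must lie in [0, 1]")
        if len(self.heritabilities) != self.n_traits:
            raise ValueError("need one heritability per trait")
        if any(not 0 < h < 1 for h in self.heritabilities):
            raise ValueError("heritabilities must lie in (0, 1)")
        lo, hi = self.reliability_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("reliability_range must satisfy 0 < low <= high <= 1")
        for name in ("n_breeds", "n_markers", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for v in (*np.atleast_1d(self.n_sires), *np.atleast_1d(self.progeny_per_sire)):
            if v <= 0:
                raise ValueError("sire/progeny counts must be positive")

    def per_breed(self, name: str, breed: int) -> int:
        v = getattr(self, name)
        return int(np.atleast_1d(v)[breed % len(np.atleast_1d(v))])

    def traits(self) -> tuple:
        return TRAITS[: self.n_traits]


@dataclass
class GenotypeMatrix:
    """Bulls x markers minor-allele counts with positions and frequencies."""

    codes: pd.DataFrame              # bulls x markers, {0,1,2, NaN}
    marker_map: pd.DataFrame         # chrom, marker, bp (1-based)
    allele_freq: pd.Series           # per marker, realized minor-allele freq

    @property
    def bulls(self):
        return self.codes.index

    @property
    def markers(self):
        return self.codes.columns

    def subset_bulls(self, bulls) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes.loc[bulls], self.marker_map, self.allele_freq)

    def subset_markers(self, markers) -> "GenotypeMatrix":
        keep = [m for m in self.markers if m in set(markers)]
        mm = self.marker_map[self.marker_map["marker"].isin(keep)].reset_index(drop=True)
        return GenotypeMatrix(self.codes[keep], mm, self.allele_freq.loc[keep])


@dataclass
class TrueValues:
    """Simulation ground truth: breeding values and marker effects."""

    tbv: pd.DataFrame          # animals x traits
    effects: pd.DataFrame      # markers x traits (on the scaled TBV scale)
    qtl_mask: pd.Series        # per marker, True where effect row is nonzero


@dataclass
class BreedData:
    name: str
    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix
    genes: pd.DataFrame
    qtl: pd.DataFrame
    evaluations: pd.DataFrame
    truth: TrueValues
    config: SimConfig = field(repr=False, default=None)


def _rng(config: SimConfig, stage: int, breed: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage, breed])


# ---------------------------------------------------------------------------
# pedigree

def simulate_pedigree(config: SimConfig, breed: int = 0) -> pd.DataFrame:
    """One generation of paternal half-sib families.

    Returns a frame with columns ``animal, sire, dam, birth_year, mgs``;
    founder sires come first, dams are unknown (``NA``) and each bull's MGS
    is a sire sampled at random.
    """
    rng = _rng(config, _STAGE_PED, breed)
    n_sires = config.per_breed("n_sires", breed)
    n_prog = config.per_breed("progeny_per_sire", breed)
    tag = f"B{breed}"
    sires = [f"{tag}S{i:04d}" for i in range(n_sires)]
    rows = [(s, pd.NA, pd.NA, 0, pd.NA) for s in sires]
    k = 0
    for s in sires:
        for _ in range(n_prog):
            mgs = sires[rng.integers(n_sires)]
            year = 1 + int(rng.integers(config.n_birth_years))
            rows.append((f"{tag}P{k:05d}", s, pd.NA, year, mgs))
            k += 1
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year", "mgs"])


# ---------------------------------------------------------------------------
# genotypes

def _founder_haplotypes(rng, n_hap, maf, ld_block_size):
    m = maf.size
    if ld_block_size is None:
        return (rng.random((n_hap, m)) < maf).astype(np.int8)
    # block-LD mode: founder haplotypes are copies of a small ancestral pool
    # within windows, creating within-block LD
    n_anc = 20
    anc = (rng.random((n_anc, m)) < maf).astype(np.int8)
    out = np.empty((n_hap, m), np.int8)
    for start in range(0, m, ld_block_size):
        stop = min(start + ld_block_size, m)
        pick = rng.integers(n_anc, size=n_hap)
        out[:, start:stop] = anc[pick, start:stop]
    return out


def simulate_genotypes(
    pedigree: pd.DataFrame, config: SimConfig, breed: int = 0
) -> GenotypeMatrix:
    """Mendelian gene-drop of biallelic markers through the pedigree.

    Founders are in Hardy-Weinberg proportions at founder MAFs drawn in
    ``maf_range``.  Every non-founder receives one gamete from each parent;
    a missing parent contributes a population gamete at the founder MAF.
    """
    rng = _rng(config, _STAGE_GENO, breed)
    m = config.n_markers
    maf = rng.uniform(*config.maf_range, size=m)

    lengths = dict(config.genome)
    chroms = list(lengths)
    per_chrom = np.array_split(np.arange(m), len(chroms))
    recs = []
    for c, idx in zip(chroms, per_chrom):
        if idx.size == 0:
            continue
        pos = np.sort(rng.choice(lengths[c] - 1, size=idx.size, replace=False)) + 1
        for i, p in zip(idx, pos):
            recs.append((str(c), f"M{i:06d}", int(p)))
    marker_map = pd.DataFrame(recs, columns=["chrom", "marker", "bp"])
    markers = marker_map["marker"].tolist()

    animals = pedigree["animal"].tolist()
    index = {a: i for i, a in enumerate(animals)}
    hap = np.zeros((len(animals), 2, m), np.int8)
    is_founder = pedigree["sire"].isna() & pedigree["dam"].isna()
    founders = np.flatnonzero(is_founder.to_numpy())
    fh = _founder_haplotypes(rng, 2 * founders.size, maf, config.ld_block_size)
    hap[founders] = fh.reshape(founders.size, 2, m)

    for row in pedigree.itertuples(index=False):
        i = index[row.animal]
        if pd.isna(row.sire) and pd.isna(row.dam):
            continue
        for slot, parent in enumerate((row.sire, row.dam)):
            if pd.isna(parent):
                hap[i, slot] = rng.random(m) < maf
            else:
                ph = hap[index[parent]]
                hap[i, slot] = ph[(rng.random(m) < 0.5).astype(np.int8), np.arange(m)]

    codes = hap.sum(axis=1).astype(float)
    if config.missing_rate > 0:
        codes[rng.random(codes.shape) < config.missing_rate] = np.nan

    codes_df = pd.DataFrame(codes, index=pd.Index(animals, name="bull"), columns=markers)
    freq = codes_df.mean(axis=0, skipna=True) / 2.0
    return GenotypeMatrix(codes_df, marker_map, freq.rename("allele_freq"))


# ---------------------------------------------------------------------------
# annotation

def simulate_annotation(config: SimConfig, breed: int = 0, marker_map=None):
    """Gene and QTL interval tables consistent with the marker map.

    Genes are placed so that approximately ``fraction_near_gene`` of markers
    lie within 2,500 bp of a gene (exact at fractions 0 and 1); QTL intervals
    cover ``qtl_fraction`` of each chromosome.
    """
    rng = _rng(config, _STAGE_ANNOT, breed)
    if marker_map is None:
        marker_map = simulate_genotypes(
            simulate_pedigree(config, breed).head(1), config, breed
        ).marker_map
    lengths = dict((str(c), l) for c, l in config.genome)

    m = len(marker_map)
    k = int(round(config.fraction_near_gene * m))
    covered = np.zeros(m, bool)
    covered[rng.choice(m, size=k, replace=False)] = True

    genes = []
    gid = 0
    for chrom, sub in marker_map.groupby("chrom", sort=False):
        pos = sub["bp"].to_numpy()
        cov = covered[sub.index.to_numpy()]
        length = lengths[chrom]
        # maximal runs of genomically consecutive covered markers -> one gene
        i = 0
        while i < pos.size:
            if not cov[i]:
                i += 1
                continue
            j = i
            while j + 1 < pos.size and cov[j + 1]:
                j += 1
            # extend edges but never to within 2,500 bp of an uncovered marker
            left_gap = pos[i] - pos[i - 1] if i > 0 else pos[i]
            right_gap = pos[j + 1] - pos[j] if j + 1 < pos.size else length - pos[j]
            w_left = int(np.clip(left_gap - 2501, 1, 500))
            w_right = int(np.clip(right_gap - 2501, 1, 500))
            genes.append((chrom, max(1, pos[i] - w_left), min(length, pos[j] + w_right),
                          f"G{gid:05d}"))
            gid += 1
            i = j + 1

    # top up with marker-free genes until n_genes is reached
    span = 1000
    tries = 0
    all_pos = {c: sub["bp"].to_numpy() for c, sub in marker_map.groupby("chrom")}
    while gid < config.n_genes:
        tries += 1
        if tries > 50 * config.n_genes:
            raise ValueError(
                f"cannot place {config.n_genes} genes on the configured genome "
                "without violating the near-marker fraction"
            )
        chrom = str(config.genome[rng.integers(len(config.genome))][0])
        start = 1 + int(rng.integers(max(1, lengths[chrom] - span)))
        pos = all_pos.get(chrom, np.array([], int))
        if pos.size and np.min(np.abs(pos - (start + span // 2))) < span // 2 + 2600:
            continue
        genes.append((chrom, start, start + span, f"G{gid:05d}"))
        gid += 1

    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "name"])
    genes_df = genes_df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    qtl = []
    for qi, (chrom, length) in enumerate(config.genome):
        qlen = int(config.qtl_fraction * length)
        if qlen < 1:
            continue
        start = 1 + int(rng.integers(length - qlen))
        qtl.append((str(chrom), start, start + qlen - 1, f"QTL{qi:03d}"))
    qtl_df = pd.DataFrame(qtl, columns=["chrom", "start", "end", "name"])
    return genes_df, qtl_df


# ---------------------------------------------------------------------------
# traits

def simulate_traits(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    config: SimConfig,
    breed: int = 0,
):
    """Sparse correlated marker effects, TBVs, and PTA evaluation records.

    Marker effects are zero with probability ``pi_qtl`` and otherwise
    multivariate normal across traits with the configured genetic
    correlations; per trait, effects are rescaled so the TBV variance equals
    the configured heritability (phenotypic variance 1).  PTA = TBV/2 plus
    noise sized so that corr(PTA, TBV/2)^2 equals the bull's reliability.
    """
    rng = _rng(config, _STAGE_TRAIT, breed)
    t = config.n_traits
    traits = config.traits()
    corr = config.genetic_correlation_matrix
    codes = genotypes.codes.to_numpy(float)
    p = genotypes.allele_freq.to_numpy(float)
    m = p.size

    centered = np.where(np.isnan(codes), 0.0, codes - 2 * p)

    mask = rng.random(m) >= config.pi_qtl
    chol = np.linalg.cholesky(corr)
    effects = np.zeros((m, t))
    effects[mask] = rng.standard_normal((mask.sum(), t)) @ chol.T

    # moment matching: with a finite QTL count the realized genetic
    # covariance is noisy, so it is rescaled to the target exactly
    # (variances to h^2, correlations to the configured matrix)
    tbv = centered @ effects
    cov = np.cov(tbv, rowvar=False, ddof=0)
    h = np.sqrt(np.asarray(config.heritabilities, float))
    target = corr * np.outer(h, h)
    try:
        t_map = np.linalg.inv(np.linalg.cholesky(cov)).T @ np.linalg.cholesky(target).T
        tbv = tbv @ t_map
        effects = effects @ t_map
    except np.linalg.LinAlgError:
        # too few QTL for a full-rank genetic covariance: variances only
        for j in range(t):
            v = tbv[:, j].var()
            if v > 0:
                s = np.sqrt(config.heritabilities[j] / v)
                tbv[:, j] *= s
                effects[:, j] *= s

    animals = genotypes.bulls
    tbv_df = pd.DataFrame(tbv, index=animals, columns=traits)

    rel = rng.uniform(*config.reliability_range, size=(len(animals), t))
    tta = tbv / 2.0                                   # true transmitting ability
    var_tta = np.maximum(tbv.var(axis=0) / 4.0, 0.0)
    noise_sd = np.sqrt(var_tta * (1.0 - rel) / rel)
    pta = tta + rng.standard_normal(rel.shape) * noise_sd
    pta_df = pd.DataFrame(pta, index=animals, columns=traits)
    rel_df = pd.DataFrame(rel, index=animals, columns=traits)

    ped = pedigree.set_index("animal")
    progeny = [a for a in animals if a in ped.index and pd.notna(ped.loc[a, "sire"])]
    cohort_mean = {
        (yr, tr): pta_df.loc[grp.index, tr].mean()
        for yr, grp in ped.loc[progeny].groupby("birth_year")
        for tr in traits
    }

    recs = []
    for a in progeny:
        sire, mgs, year = ped.loc[a, "sire"], ped.loc[a].get("mgs", pd.NA), ped.loc[a, "birth_year"]
        for tr in traits:
            recs.append(
                dict(
                    bull=a,
                    trait=tr,
                    pta=pta_df.loc[a, tr],
                    rel=rel_df.loc[a, tr],
                    sire_pta=pta_df.loc[sire, tr] if pd.notna(sire) else np.nan,
                    mgs_pta=pta_df.loc[mgs, tr] if pd.notna(mgs) else np.nan,
                    ayb_pta=cohort_mean[(year, tr)],
                    rel_pa=rng.uniform(*config.rel_pa_range),
                )
            )
    evaluations = pd.DataFrame(recs)

    truth = TrueValues(
        tbv=tbv_df,
        effects=pd.DataFrame(effects, index=genotypes.markers, columns=traits),
        qtl_mask=pd.Series(mask, index=genotypes.markers, name="qtl_mask"),
    )
    return truth, evaluations


# ---------------------------------------------------------------------------

def simulate_breed(config: SimConfig, breed: int = 0, name: str | None = None) -> BreedData:
    """Run the full generator for one breed."""
    pedigree = simulate_pedigree(config, breed)
    genotypes = simulate_genotypes(pedigree, config, breed)
    genes, qtl = simulate_annotation(config, breed, marker_map=genotypes.marker_map)
    truth, evaluations = simulate_traits(genotypes, pedigree, config, breed)
    return BreedData(
        name=name or f"breed{breed}",
        pedigree=pedigree,
        genotypes=genotypes,
        genes=genes,
        qtl=qtl,
        evaluations=evaluations,
        truth=truth,
        config=config,
    )


def simulate_all(config: SimConfig, names=None) -> dict:
    names = names or [f"breed{b}" for b in range(config.n_breeds)]
    return {nm: simulate_breed(config, b, nm) for b, nm in enumerate(names)}
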