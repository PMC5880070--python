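"""Bayesian GBLUP with one or two genomic kernels under pedigree-family CV.

Model: ``y = 1 mu + sum_k g_k + e`` with ``g_k ~ N(0, G_k sigma_k^2)``,
``e ~ N(0, R sigma_e^2)``, ``R_ii = 1/w_i``.  Each kernel is
eigendecomposed once per fit, ``G_k = U_k L_k U_k'``, and the genetic
vector reparameterized as ``g_k = U_k sqrt(L_k) a_k`` with iid normal
``a_k``; the sampler then reduces to single-site Gibbs over the ``a_k``
coordinates, which keeps every update O(n) and handles singular kernels
without repair.  Variance components get scaled-inverse-chi-square priors
(df 5) with scales set from an even split of half the phenotypic variance
across the genetic kernels.

The seven prediction models pair kernels as in the model/GRM grid:
1 BASE; 2 TOP25; 3 TOP25+BOT75; 4 NET; 5 NET+FREE; 6 CONN; 7 CONN+FREE.

Cross-validation masks one pedigree family (k-means on the rows of the
numerator relationship matrix) at a time; the marker association, AWM,
network and marker partitions are all rebuilt from the training bulls
only, so no validation pseudo-phenotype can leak into model construction.
Accuracy is the Pearson correlation between predicted and masked dPTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._compat import njit
from .awm import TraitGroups, awm_from_gwas
from .gwas import BayesBConfig, gwas_all_traits
from .grm import GRM, build_all_grms
from .pcit import pcit, row_correlations, trim_network

log = logging.getLogger(__name__)

MODEL_SPECS = {
    1: ("BASE",),
    2: ("TOP25",),
    3: ("TOP25", "BOT75"),
    4: ("NET",),
    5: ("NET", "FREE"),
    6: ("CONN",),
    7: ("CONN", "FREE"),
}


@dataclass
class GBLUPConfig:
    chain_length: int = 20_000
    burn_in: int = 5_000
    df0: float = 5.0
    use_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")


@dataclass
class GBLUPFit:
    mu: float
    gvalues: pd.DataFrame            # bulls x kernels, posterior-mean genetic values
    variances: dict                  # kernel label -> posterior-mean variance
    sigma_e: float

    @property
    def predictions(self) -> pd.Series:
        return self.gvalues.sum(axis=1) + self.mu

    def variance_fractions(self) -> dict:
        tot = sum(self.variances.values()) + self.sigma_e
        return {k: v / tot for k, v in self.variances.items()}


def kmeans_families(A: pd.DataFrame, k: int = 4, seed: int = 0) -> pd.Series:
    """Cluster animals into k families by k-means on the rows of the
    pedigree relationship matrix (each animal is its relationship profile)."""
    if k > len(A):
        raise ValueError("more folds than animals")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(A.to_numpy(float))
    folds = pd.Series(labels, index=A.index, name="fold")
    log.info("family sizes: %s", folds.value_counts().sort_index().to_dict())
    return folds


@njit(cache=True)
def _gblup_chain(B1, B2, y, w, obs, chain, burn, df0, S1, S2, Se, fixed,
                 sig1_0, sig2_0, sige_0, seed):
    np.random.seed(seed)
    n = y.shape[0]
    r1 = B1.shape[1]
    r2 = B2.shape[1]
    n_obs = 0
    sw = 0.0
    for i in range(n):
        if obs[i] == 1:
            n_obs += 1
            sw += w[i]

    bwb1 = np.zeros(r1)
    for j in range(r1):
        acc = 0.0
        for i in range(n):
            if obs[i] == 1:
                acc += w[i] * B1[i, j] * B1[i, j]
        bwb1[j] = acc
    bwb2 = np.zeros(r2)
    for j in range(r2):
        acc = 0.0
        for i in range(n):
            if obs[i] == 1:
                acc += w[i] * B2[i, j] * B2[i, j]
        bwb2[j] = acc

    a1 = np.zeros(r1)
    a2 = np.zeros(r2)
    mu = 0.0
    ssy = 0.0
    for i in range(n):
        if obs[i] == 1:
            mu += w[i] * y[i]
    mu /= sw
    sig1, sig2, sige = sig1_0, sig2_0, sige_0

    e = np.zeros(n)
    for i in range(n):
        if obs[i] == 1:
            e[i] = y[i] - mu

    g1_mean = np.zeros(n)
    g2_mean = np.zeros(n)
    mu_sum = 0.0
    v1_sum = 0.0
    v2_sum = 0.0
    ve_sum = 0.0
    kept = chain - burn

    for it in range(chain):
        # intercept
        acc = 0.0
        for i in range(n):
            if obs[i] == 1:
                acc += w[i] * (e[i] + mu)
        mu_new = acc / sw + np.random.standard_normal() * np.sqrt(sige / sw)
        for i in range(n):
            if obs[i] == 1:
                e[i] += mu - mu_new
        mu = mu_new

        for j in range(r1):
            aj = a1[j]
            rhs = 0.0
            for i in range(n):
                if obs[i] == 1:
                    rhs += w[i] * B1[i, j] * (e[i] + B1[i, j] * aj)
            prec = bwb1[j] / sige + 1.0 / sig1
            mean = (rhs / sige) / prec
            newa = mean + np.random.standard_normal() / np.sqrt(prec)
            diff = newa - aj
            for i in range(n):
                if obs[i] == 1:
                    e[i] -= B1[i, j] * diff
            a1[j] = newa

        for j in range(r2):
            aj = a2[j]
            rhs = 0.0
            for i in range(n):
                if obs[i] == 1:
                    rhs += w[i] * B2[i, j] * (e[i] + B2[i, j] * aj)
            prec = bwb2[j] / sige + 1.0 / sig2
            mean = (rhs / sige) / prec
            newa = mean + np.random.standard_normal() / np.sqrt(prec)
            diff = newa - aj
            for i in range(n):
                if obs[i] == 1:
                    e[i] -= B2[i, j] * diff
            a2[j] = newa

        if fixed == 0:
            ss1 = 0.0
            for j in range(r1):
                ss1 += a1[j] * a1[j]
            sig1 = (df0 * S1 + ss1) / np.random.chisquare(df0 + r1)
            if r2 > 0:
                ss2 = 0.0
                for j in range(r2):
                    ss2 += a2[j] * a2[j]
                sig2 = (df0 * S2 + ss2) / np.random.chisquare(df0 + r2)
            sse = 0.0
            for i in range(n):
                if obs[i] == 1:
                    sse += w[i] * e[i] * e[i]
            sige = (df0 * Se + sse) / np.random.chisquare(df0 + n_obs)

        if it >= burn:
            mu_sum += mu
            v1_sum += sig1
            v2_sum += sig2
            ve_sum += sige
            for i in range(n):
                acc1 = 0.0
                for j in range(r1):
                    acc1 += B1[i, j] * a1[j]
                g1_mean[i] += acc1
                if r2 > 0:
                    acc2 = 0.0
                    for j in range(r2):
                        acc2 += B2[i, j] * a2[j]
                    g2_mean[i] += acc2

    return (g1_mean / kept, g2_mean / kept, mu_sum / kept,
            v1_sum / kept, v2_sum / kept, ve_sum / kept)


def _eigen_basis(G: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(G)
    keep = vals > tol * max(vals.max(), 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


def fit_gblup(
    y: pd.Series,
    w: pd.Series,
    kernels: list[GRM],
    config: GBLUPConfig | None = None,
    fixed_variances: dict | None = None,
) -> GBLUPFit:
    """Fit the weighted GBLUP model by Gibbs sampling.

    ``y`` may contain NaN for masked (validation) bulls; their kernel rows
    stay in the model so posterior genetic values — and hence predictions
    ``mu + sum_k g_k`` — are produced for them.  ``fixed_variances`` maps
    kernel labels and ``"residual"`` to known variances (no variance
    updates), which is how the sampler is checked against a direct
    mixed-model solve.
    """
    config = config or GBLUPConfig()
    if not 1 <= len(kernels) <= 2:
        raise ValueError("one or two kernels supported")
    bulls = list(kernels[0].bulls)
    for k in kernels[1:]:
        if list(k.bulls) != bulls:
            raise ValueError("kernels must share the same bull ordering")
    yv = y.reindex(bulls).to_numpy(float)
    obs = np.isfinite(yv).astype(np.int8)
    if obs.sum() < 3:
        raise ValueError("need at least 3 observed records")
    wv = w.reindex(bulls).to_numpy(float) if config.use_weights else np.ones(len(bulls))
    wv = np.where(obs == 1, wv, 1.0)
    if np.any(wv <= 0):
        raise ValueError("weights must be strictly positive")
    yv = np.where(obs == 1, yv, 0.0)

    B = [np.ascontiguousarray(_eigen_basis(k.values())) for k in kernels]
    if len(B) == 1:
        B.append(np.zeros((len(bulls), 0)))

    vy = float(np.var(yv[obs == 1]))
    nk = len(kernels)
    # prior scales: half the phenotypic variance split across kernels
    S_g = [0.5 * vy / nk] * nk + [0.0]
    S_e = 0.5 * vy
    fixed = 0
    sig0 = [S_g[0], S_g[1] if nk == 2 else 0.0, S_e]
    if fixed_variances is not None:
        fixed = 1
        sig0 = [
            fixed_variances[kernels[0].label],
            fixed_variances[kernels[1].label] if nk == 2 else 0.0,
            fixed_variances["residual"],
        ]

    g1, g2, mu, v1, v2, ve = _gblup_chain(
        B[0], B[1], yv, wv, obs,
        config.chain_length, config.burn_in, config.df0,
        S_g[0], S_g[1], S_e, fixed,
        max(sig0[0], 1e-12), max(sig0[1], 1e-12), max(sig0[2], 1e-12),
        int(config.seed) % (2**31 - 1),
    )
    gvalues = pd.DataFrame({kernels[0].label: g1}, index=bulls)
    variances = {kernels[0].label: v1}
    if nk == 2:
        gvalues[kernels[1].label] = g2
        variances[kernels[1].label] = v2
    return GBLUPFit(mu=mu, gvalues=gvalues, variances=variances, sigma_e=ve)


@dataclass
class CVResult:
    per_fold: pd.DataFrame     # trait, model, fold, accuracy, variance fractions
    summary: pd.DataFrame = field(default=None)

    def summarize(self) -> pd.DataFrame:
        g = self.per_fold.groupby(["trait", "model"])["accuracy"]
        self.summary = g.agg(accuracy="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s))).reset_index()
        return self.summary


def _train_networks(deregressed, genotypes, snp_gene_map, marker_map,
                    gwas_config, groups, trim_threshold):
    """GWAS + AWM + trimmed network on (training) records only."""
    summaries = gwas_all_traits(deregressed, genotypes, gwas_config)
    awm = awm_from_gwas(summaries, snp_gene_map, marker_map, groups)
    network = trim_network(pcit(row_correlations(awm.matrix)), trim_threshold)
    pvg = pd.DataFrame({t: s.pvg for t, s in summaries.items()})
    return summaries, awm, network, pvg


def run_cross_validation(
    deregressed: pd.DataFrame,
    genotypes,
    folds: pd.Series,
    snp_gene_map: pd.DataFrame,
    models=(1, 2, 3, 4, 5, 6, 7),
    traits=None,
    gwas_config: BayesBConfig | None = None,
    gblup_config: GBLUPConfig | None = None,
    groups: TraitGroups | None = None,
    trim_threshold: float = 0.98,
) -> CVResult:
    """Pedigree-family cross-validation of the seven prediction models.

    Per fold, the whole marker-association chain (GWAS, AWM, network and
    marker partitions) is rebuilt on training bulls only; kernels span all
    bulls (genotypes carry no phenotype information), the validation dPTAs
    are masked during fitting, and accuracy is their Pearson correlation
    with the predictions.  Folds with fewer than 3 validation records are
    skipped with a warning.
    """
    gwas_config = gwas_config or BayesBConfig()
    gblup_config = gblup_config or GBLUPConfig()
    groups = groups or TraitGroups()
    traits = list(traits or sorted(deregressed["trait"].unique()))
    bulls = list(genotypes.bulls)
    folds = folds.reindex(bulls)

    needed = {lbl for m in models for lbl in MODEL_SPECS[int(m)]}

    rows = []
    for f in sorted(folds.unique()):
        val = [b for b in bulls if folds[b] == f]
        train = [b for b in bulls if folds[b] != f]
        if len(val) < 3:
            log.warning("fold %s has %d validation bulls; skipped", f, len(val))
            continue
        train_recs = deregressed[deregressed["bull"].isin(train)]
        if needed == {"BASE"}:
            # no model uses training-derived marker sets
            from .grm import vanraden_g

            grms = {"BASE": vanraden_g(genotypes, label="BASE")}
        else:
            train_geno = genotypes.subset_bulls(train)
            cfg = BayesBConfig(**{**gwas_config.__dict__,
                                  "seed": gwas_config.seed + 101 * (int(f) + 1)})
            _, awm_f, net_f, pvg_f = _train_networks(
                train_recs, train_geno, snp_gene_map, genotypes.marker_map,
                cfg, groups, trim_threshold,
            )
            grms = build_all_grms(genotypes, pvg_f, awm_f, net_f)

        for trait in traits:
            sub = deregressed[deregressed["trait"] == trait].set_index("bull")
            y = sub["dpta"].reindex(bulls)
            w = sub["w"].reindex(bulls).fillna(1.0)
            y_masked = y.copy()
            y_masked[val] = np.nan
            for model in models:
                labels = MODEL_SPECS[int(model)]
                if any(lbl not in grms for lbl in labels):
                    log.warning("model %s skipped in fold %s: kernel missing", model, f)
                    continue
                kern = [grms[lbl] for lbl in labels]
                gcfg = GBLUPConfig(**{
                    **gblup_config.__dict__,
                    "seed": gblup_config.seed + 13 * (int(f) + 1) + int(model),
                })
                fit = fit_gblup(y_masked, w, kern, gcfg)
                pred = fit.predictions[val]
                truth = y[val]
                ok = truth.notna()
                if ok.sum() < 3 or pred[ok].std() == 0 or truth[ok].std() == 0:
                    log.warning("fold %s trait %s model %s: correlation undefined; skipped",
                                f, trait, model)
                    continue
                acc = float(np.corrcoef(pred[ok], truth[ok])[0, 1])
                row = {"trait": trait, "model": int(model), "fold": f, "accuracy": acc,
                       "sigma_e": fit.sigma_e}
                for lbl, frac in fit.variance_fractions().items():
                    row[f"frac_{lbl}"] = frac
                rows.append(row)
    result = CVResult(per_fold=pd.DataFrame(rows))
    result.summarize()
    return result
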