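"""GBLUP sampler against a direct GLS solve, k-means families, and the
cross-validation contract including the leakage guarantee."""

import numpy as np
import pandas as pd
import pytest

from awmnet.gblup import (
    GBLUPConfig,
    MODEL_SPECS,
    fit_gblup,
    kmeans_families,
    run_cross_validation,
)
from awmnet.grm import GRM, a_matrix, vanraden_g
from awmnet.gwas import BayesBConfig, gwas_all_traits

from conftest import random_genotypes


class TestKMeansFamilies:
    def test_block_diagonal_families_recovered(self):
        blocks = []
        ids = []
        for fam in range(4):
            ids += [f"f{fam}_{i}" for i in range(6)]
        A = np.eye(24)
        for fam in range(4):
            s = slice(6 * fam, 6 * fam + 6)
            A[s, s] = 0.5
            A[range(6 * fam, 6 * fam + 6), range(6 * fam, 6 * fam + 6)] = 1.0
        Adf = pd.DataFrame(A, index=ids, columns=ids)
        folds = kmeans_families(Adf, k=4, seed=0)
        for fam in range(4):
            labels = folds[[f"f{fam}_{i}" for i in range(6)]]
            assert labels.nunique() == 1

    def test_single_fold(self):
        A = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        assert kmeans_families(A, k=1, seed=1).nunique() == 1

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        m = rng.random((20, 20))
        A = pd.DataFrame(m @ m.T)
        a = kmeans_families(A, k=4, seed=5)
        b = kmeans_families(A, k=4, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_more_folds_than_animals_errors(self):
        A = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="folds"):
            kmeans_families(A, k=4)


@pytest.fixture(scope="module")
def gblup_instance():
    rng = np.random.default_rng(5)
    g = random_genotypes(rng, 50, 400)
    G = vanraden_g(g)
    n = 50
    sg, se = 0.4, 0.6
    Gm = G.values()
    L = np.linalg.cholesky(Gm + 1e-8 * np.eye(n))
    gtrue = L @ rng.standard_normal(n) * np.sqrt(sg)
    w = rng.uniform(0.5, 2.0, n)
    y = 1.0 + gtrue + rng.standard_normal(n) * np.sqrt(se / w)
    return G, pd.Series(y, index=G.bulls), pd.Series(w, index=G.bulls), sg, se


class TestFitGBLUP:
    def test_matches_direct_mme_solve(self, gblup_instance):
        """With variances fixed, posterior-mean genetic values must agree
        with the closed-form GLS-BLUP solution."""
        G, y, w, sg, se = gblup_instance
        fit = fit_gblup(
            y, w, [G], GBLUPConfig(chain_length=8000, burn_in=2000, seed=2),
            fixed_variances={"BASE": sg, "residual": se},
        )
        n = len(y)
        V = sg * G.values() + np.diag(se / w.to_numpy())
        Vi = np.linalg.inv(V)
        one = np.ones(n)
        beta = (one @ Vi @ y.to_numpy()) / (one @ Vi @ one)
        ghat = sg * G.values() @ Vi @ (y.to_numpy() - beta)
        rmse = np.sqrt(np.mean((fit.gvalues["BASE"].to_numpy() - ghat) ** 2))
        assert rmse < 0.01

    def test_null_signal_shrinks_to_weighted_mean(self, gblup_instance):
        G, y, w, _, _ = gblup_instance
        rng = np.random.default_rng(0)
        ynull = pd.Series(5.0 + rng.standard_normal(len(y)) * 0.01, index=y.index)
        fit = fit_gblup(
            ynull, w, [G], GBLUPConfig(chain_length=3000, burn_in=600, seed=3),
            fixed_variances={"BASE": 1e-8, "residual": 1.0},
        )
        wmean = float(np.sum(w * ynull) / np.sum(w))
        assert np.allclose(fit.predictions, wmean, atol=0.05)

    def test_masked_bulls_get_predictions(self, gblup_instance):
        G, y, w, sg, se = gblup_instance
        ym = y.copy()
        ym.iloc[:10] = np.nan
        fit = fit_gblup(ym, w, [G], GBLUPConfig(chain_length=2000, burn_in=400, seed=4))
        assert np.isfinite(fit.predictions.iloc[:10]).all()
        # masked relatives of strong records should still deviate from mu
        assert fit.gvalues["BASE"].iloc[:10].abs().sum() > 0

    def test_two_identical_kernels_preserve_total_variance(self, gblup_instance):
        G, y, w, _, _ = gblup_instance
        G2 = GRM(G.matrix.copy(), "NET", G.markers)
        cfg = GBLUPConfig(chain_length=6000, burn_in=1500, seed=5)
        one = fit_gblup(y, w, [G], cfg)
        two = fit_gblup(y, w, [G, G2], cfg)
        tot1 = one.variances["BASE"]
        tot2 = two.variances["BASE"] + two.variances["NET"]
        assert tot2 == pytest.approx(tot1, rel=0.35)
        pred_corr = np.corrcoef(one.predictions, two.predictions)[0, 1]
        assert pred_corr > 0.98

    def test_deterministic(self, gblup_instance):
        G, y, w, _, _ = gblup_instance
        cfg = GBLUPConfig(chain_length=500, burn_in=100, seed=6)
        a = fit_gblup(y, w, [G], cfg)
        b = fit_gblup(y, w, [G], cfg)
        pd.testing.assert_frame_equal(a.gvalues, b.gvalues)

    def test_validation(self, gblup_instance):
        G, y, w, _, _ = gblup_instance
        with pytest.raises(ValueError, match="kernels"):
            fit_gblup(y, w, [G, G, G])
        with pytest.raises(ValueError, match="burn_in"):
            GBLUPConfig(chain_length=10, burn_in=10)


@pytest.fixture(scope="module")
def cv_inputs(demo_breed_module):
    return demo_breed_module


@pytest.fixture(scope="module")
def demo_breed_module():
    from awmnet.deregress import deregress, filter_records
    from awmnet.gwas import qc_markers
    from awmnet.simulate import SimConfig, simulate_breed

    cfg = SimConfig(n_sires=10, progeny_per_sire=16, n_markers=400, n_genes=80,
                    pi_qtl=0.9, fraction_near_gene=0.7, seed=17)
    breed = simulate_breed(cfg)
    dreg = filter_records(deregress(breed.evaluations), min_rel=0.2)
    geno = qc_markers(breed.genotypes)
    geno = geno.subset_bulls([b for b in geno.bulls if b in set(dreg["bull"])])
    from awmnet.mapping import map_snp_to_genes

    sgm = map_snp_to_genes(geno.marker_map, breed.genes)
    A = a_matrix(breed.pedigree)
    bulls = list(geno.bulls)
    folds = kmeans_families(A.loc[bulls, bulls], k=3, seed=1)
    return breed, dreg, geno, sgm, folds


class TestCrossValidation:
    def test_models_run_and_accuracies_bounded(self, demo_breed_module):
        _, dreg, geno, sgm, folds = demo_breed_module
        res = run_cross_validation(
            dreg, geno, folds, sgm,
            models=(1, 4, 5),
            traits=["GL"],
            gwas_config=BayesBConfig(chain_length=800, burn_in=200, seed=3),
            gblup_config=GBLUPConfig(chain_length=800, burn_in=200, seed=3),
        )
        assert not res.per_fold.empty
        assert res.per_fold["accuracy"].between(-1, 1).all()
        assert set(res.per_fold["model"]) == {1, 4, 5}
        fracs = res.per_fold.filter(like="frac_")
        assert (fracs.fillna(0) >= 0).all().all()

    def test_leakage_canary_training_gwas_bit_identical(self, demo_breed_module):
        """Planting an extreme pseudo-phenotype on a validation bull must
        not change the training-set GWAS output in any bit."""
        _, dreg, geno, _, folds = demo_breed_module
        f0 = sorted(folds.unique())[0]
        val = folds.index[folds == f0]
        train = [b for b in geno.bulls if b not in set(val)]
        cfg = BayesBConfig(chain_length=600, burn_in=150, seed=9)

        poisoned = dreg.copy()
        mask = poisoned["bull"] == val[0]
        poisoned.loc[mask, "dpta"] = 1e6

        tg = geno.subset_bulls(train)
        clean = gwas_all_traits(dreg[dreg["bull"].isin(train)], tg, cfg, traits=["DCD"])
        dirty = gwas_all_traits(poisoned[poisoned["bull"].isin(train)], tg, cfg,
                                traits=["DCD"])
        pd.testing.assert_frame_equal(clean["DCD"].table, dirty["DCD"].table)
        assert clean["DCD"].mu == dirty["DCD"].mu


def test_model_specs_match_table_layout():
    assert MODEL_SPECS[3] == ("TOP25", "BOT75")
    assert MODEL_SPECS[7] == ("CONN", "FREE")
    assert all(1 <= len(v) <= 2 for v in MODEL_SPECS.values())
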