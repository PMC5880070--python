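"""Bayes-B sampler behaviour, marker QC, PV_g arithmetic and retention."""

import numpy as np
import pandas as pd
import pytest

from awmnet.gwas import (
    BayesBConfig,
    compute_pvg,
    qc_markers,
    retain_top_fraction,
    run_bayesb,
)
from awmnet.simulate import GenotypeMatrix

from conftest import random_genotypes


def geno_from_codes(codes: np.ndarray) -> GenotypeMatrix:
    m = codes.shape[1]
    df = pd.DataFrame(codes.astype(float), columns=[f"M{j}" for j in range(m)],
                      index=[f"b{i}" for i in range(codes.shape[0])])
    mm = pd.DataFrame({"chrom": "1", "marker": df.columns, "bp": np.arange(m) * 1000 + 1})
    return GenotypeMatrix(df, mm, df.mean(skipna=True) / 2)


class TestQC:
    def test_maf_boundary_strict(self):
        n = 1000
        codes = np.zeros((n, 2))
        codes[:98, 0] = 1.0   # MAF 0.049 -> removed
        codes[:100, 1] = 1.0  # MAF 0.050 -> kept
        g = geno_from_codes(codes)
        kept = qc_markers(g, min_maf=0.05, min_call=0.0)
        assert list(kept.markers) == ["M1"]

    def test_call_rate_boundary(self):
        codes = np.ones((100, 2))
        codes[:50, 0] = 0.0
        codes[:11, 1] = np.nan   # call rate 0.89 -> removed
        g = geno_from_codes(codes)
        kept = qc_markers(g, min_maf=0.0, min_call=0.90)
        assert list(kept.markers) == ["M0"]

    def test_identity_when_clean(self):
        rng = np.random.default_rng(1)
        g = random_genotypes(rng, 50, 20, maf_low=0.4, maf_high=0.5)
        kept = qc_markers(g)
        assert list(kept.markers) == list(g.markers)
        assert np.allclose(kept.codes, g.codes)

    def test_missing_imputed_to_marker_mean(self):
        codes = np.array([[0.0, 2.0], [2.0, 0.0], [np.nan, 1.0], [1.0, 1.0]])
        g = geno_from_codes(codes)
        kept = qc_markers(g, min_maf=0.0, min_call=0.5)
        assert kept.codes.iloc[2, 0] == pytest.approx(1.0)

    def test_all_removed_errors(self):
        g = geno_from_codes(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="every marker"):
            qc_markers(g)


class TestPVg:
    def test_single_nonzero_effect(self):
        assert np.allclose(compute_pvg([2.0, 0, 0], [0.5, 0.5, 0.5]), [1, 0, 0])

    def test_symmetry_of_equal_effects(self):
        assert np.allclose(compute_pvg([1.0, -1.0], [0.3, 0.3]), [0.5, 0.5])

    def test_hand_arithmetic(self):
        # weights 2*0.5*0.5 = 0.5 and 2*0.1*0.9 = 0.18
        got = compute_pvg([1.0, 1.0], [0.5, 0.1])
        assert got == pytest.approx([0.5 / 0.68, 0.18 / 0.68], abs=1e-4)
        assert got == pytest.approx([0.7353, 0.2647], abs=1e-4)

    def test_fixed_alleles_contribute_zero(self):
        got = compute_pvg([1.0, 1.0], [0.0, 0.4])
        assert got[0] == 0.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_pvg([0.0, 0.0], [0.5, 0.5])


class TestRetention:
    def test_quarter_of_eight(self):
        pvg = pd.Series(np.arange(8) / 8.0, index=[f"M{i}" for i in range(8)])
        assert len(retain_top_fraction(pvg)) == 2

    def test_all_equal_keeps_all(self):
        pvg = pd.Series(0.1, index=[f"M{i}" for i in range(12)])
        assert len(retain_top_fraction(pvg)) == 12

    def test_ties_at_threshold_inclusive(self):
        pvg = pd.Series([1, 2, 3, 3, 3, 4, 5, 6], index=list("abcdefgh"), dtype=float)
        kept = retain_top_fraction(pvg)  # threshold = sorted[6] = 5
        assert set(kept) == {"g", "h"}
        pvg2 = pd.Series([1, 1, 1, 1, 1, 1, 5, 5], index=list("abcdefgh"), dtype=float)
        assert set(retain_top_fraction(pvg2)) == {"g", "h"}


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(2)
    n, m = 150, 300
    g = random_genotypes(rng, n, m)
    Zc = g.codes.to_numpy() - 2 * g.allele_freq.to_numpy()
    eff = np.zeros(m)
    qtl = rng.choice(m, 10, replace=False)
    eff[qtl] = rng.standard_normal(10)
    gv = Zc @ eff
    eff *= np.sqrt(0.5 / gv.var())
    y = Zc @ eff + rng.standard_normal(n) * np.sqrt(0.5)
    return g, y, eff


class TestSampler:
    def test_determinism(self, signal_data):
        g, y, _ = signal_data
        cfg = BayesBConfig(chain_length=800, burn_in=200, seed=4)
        a = run_bayesb(y, np.ones(len(y)), g, cfg)
        b = run_bayesb(y, np.ones(len(y)), g, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.mu == b.mu and a.sigma_e == b.sigma_e

    def test_recovers_effects(self, signal_data):
        g, y, eff = signal_data
        cfg = BayesBConfig(chain_length=3000, burn_in=600, seed=4)
        s = run_bayesb(y, np.ones(len(y)), g, cfg)
        assert np.corrcoef(s.abar, eff)[0, 1] > 0.5

    def test_null_y_gives_no_concentrated_pvg(self):
        rng = np.random.default_rng(6)
        g = random_genotypes(rng, 80, 100)
        y = np.zeros(80)
        s = run_bayesb(y, np.ones(80), g,
                       BayesBConfig(chain_length=2000, burn_in=400, seed=6))
        assert s.pvg.max() < 0.5
        # effects scatter symmetrically about zero
        mc_se = np.abs(s.abar).mean() / np.sqrt(len(s.abar))
        assert abs(s.abar.mean()) < 3 * max(mc_se, 1e-6)

    def test_pi_zero_includes_every_marker(self):
        rng = np.random.default_rng(7)
        g = random_genotypes(rng, 40, 25)
        y = rng.standard_normal(40)
        s = run_bayesb(y, np.ones(40), g,
                       BayesBConfig(pi=0.0, chain_length=400, burn_in=100, seed=1))
        assert (s.table["inclusion_freq"] == 1.0).all()

    def test_posterior_mu_matches_weighted_mean_on_null(self):
        rng = np.random.default_rng(8)
        g = random_genotypes(rng, 120, 30)
        w = rng.uniform(0.5, 3.0, 120)
        y = 2.0 + rng.standard_normal(120) / np.sqrt(w)
        s = run_bayesb(y, w, g, BayesBConfig(chain_length=3000, burn_in=600, seed=2))
        wmean = np.sum(w * y) / np.sum(w)
        assert s.mu == pytest.approx(wmean, abs=3 * np.sqrt(s.sigma_e / w.sum()))

    def test_chain_length_robustness(self, signal_data):
        """Summaries from two chain lengths agree, mirroring the preliminary
        analysis with a longer chain."""
        g, y, _ = signal_data
        s1 = run_bayesb(y, np.ones(len(y)), g,
                        BayesBConfig(chain_length=5000, burn_in=1000, seed=4))
        s2 = run_bayesb(y, np.ones(len(y)), g,
                        BayesBConfig(chain_length=4000, burn_in=500, seed=10))
        assert np.corrcoef(s1.abar, s2.abar)[0, 1] > 0.99

    def test_input_validation(self, signal_data):
        g, y, _ = signal_data
        bad = y.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            run_bayesb(bad, np.ones(len(y)), g)
        with pytest.raises(ValueError, match="positive"):
            run_bayesb(y, np.zeros(len(y)), g)
        with pytest.raises(ValueError, match="burn_in"):
            BayesBConfig(chain_length=100, burn_in=100)
        with pytest.raises(ValueError, match="pi"):
            BayesBConfig(pi=1.0)

    def test_prior_scale_algebra(self):
        cfg = BayesBConfig()
        assert cfg.scale_marker == pytest.approx(5 * 2 / 4)   # sigma^2 (nu-2)/nu
        assert cfg.scale_resid == pytest.approx(3 * 8 / 10)
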