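"""Relationship matrices: VanRaden method 1, marker partitions, the CONN
kernel, and the pedigree A-matrix."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from awmnet.awm import AWM
from awmnet.grm import (
    a_matrix,
    conn_g,
    freq_free_rescale,
    network_d_matrix,
    partition_network,
    partition_top25,
    vanraden_g,
)
from awmnet.simulate import GenotypeMatrix

from conftest import random_genotypes


def geno(codes, markers=None):
    codes = np.asarray(codes, float)
    markers = markers or [f"M{j}" for j in range(codes.shape[1])]
    df = pd.DataFrame(codes, columns=markers,
                      index=[f"b{i}" for i in range(codes.shape[0])])
    mm = pd.DataFrame({"chrom": "1", "marker": markers,
                       "bp": np.arange(len(markers)) * 1000 + 1})
    return GenotypeMatrix(df, mm, df.mean() / 2)


class TestVanRaden:
    def test_two_bull_hand_example(self):
        # codes 0 and 2 at one marker, p = 0.5: M = (-1, +1), denom = 0.5
        g = vanraden_g(geno([[0.0], [2.0]]))
        assert np.allclose(g.matrix, [[2, -2], [-2, 2]])

    def test_identical_rows_identical_relationships(self):
        rng = np.random.default_rng(0)
        codes = rng.binomial(2, 0.4, (5, 100)).astype(float)
        codes[1] = codes[0]
        g = vanraden_g(geno(codes))
        assert np.allclose(g.matrix.iloc[0], g.matrix.iloc[1])
        assert g.matrix.iloc[0, 0] == pytest.approx(g.matrix.iloc[1, 1])

    def test_hwe_mean_diagonal_near_one(self):
        rng = np.random.default_rng(1)
        g = vanraden_g(random_genotypes(rng, 200, 5000))
        assert g.matrix.to_numpy().diagonal().mean() == pytest.approx(1.0, abs=0.02)

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(2)
        g = vanraden_g(random_genotypes(rng, 40, 200))
        m = g.matrix.to_numpy()
        assert np.allclose(m, m.T, atol=1e-10)
        assert np.linalg.eigvalsh(m).min() > -1e-8

    def test_monomorphic_markers_excluded(self):
        codes = np.array([[0.0, 1], [0, 2], [0, 0]])
        g = vanraden_g(geno(codes))
        assert g.markers == ["M1"]

    def test_no_polymorphic_markers_errors(self):
        with pytest.raises(ValueError, match="polymorphic"):
            vanraden_g(geno(np.zeros((3, 2))))


class TestPartitions:
    def make_pvg(self, m=40, seed=0):
        rng = np.random.default_rng(seed)
        markers = [f"M{j}" for j in range(m)]
        return pd.DataFrame(
            rng.random((m, 6)), index=markers,
            columns=["DCD", "MCD", "GL", "STAT", "STR", "RW"],
        )

    def test_top25_threshold_counts(self):
        pvg = self.make_pvg()
        top, bot = partition_top25(pvg, min_traits=3)
        # recompute membership counts independently
        counts = sum(
            (pvg[t].rank(ascending=False) <= 10).astype(int) for t in pvg.columns
        )
        assert set(top) == set(counts[counts >= 3].index)

    def test_exact_partition(self):
        pvg = self.make_pvg(seed=3)
        top, bot = partition_top25(pvg)
        assert set(top) | set(bot) == set(pvg.index)
        assert set(top) & set(bot) == set()

    def test_network_partition(self):
        awm = AWM(
            matrix=pd.DataFrame(np.eye(3), index=["g1", "g2", "m9"]),
            source_marker=pd.Series({"g1": "M1", "g2": "M5", "m9": "M9"}),
            mean_pvg=pd.Series({"g1": 0.1, "g2": 0.2, "m9": 0.3}),
        )
        panel = [f"M{j}" for j in range(12)]
        net, free = partition_network(awm, panel)
        assert set(net) == {"M1", "M5", "M9"}
        assert set(net) & set(free) == set()
        assert set(net) | set(free) == set(panel)


class TestConn:
    def setup_data(self, n=30, m=12, seed=4):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, n, m)
        base = vanraden_g(g, label="BASE")
        net = list(g.markers[:6])
        return g, base, net

    def test_identity_d_reproduces_net_numerator(self):
        g, base, net = self.setup_data()
        d = pd.DataFrame(np.eye(6), index=net, columns=net)
        got = conn_g(g, net, d, base)
        # independent route: centered-and-scaled ZZ'/m then the same rescale
        sub = g.codes[net].to_numpy()
        p = sub.mean(axis=0) / 2
        Z = (sub - 2 * p) / np.sqrt(2 * p * (1 - p))
        raw = Z @ Z.T / len(net)
        want = freq_free_rescale(raw, base.values())
        assert np.allclose(got.values(), want, atol=1e-10)

    def test_scaling_contract(self):
        g, base, net = self.setup_data(seed=5)
        d = pd.DataFrame(np.eye(6), index=net, columns=net)
        got = conn_g(g, net, d, base).values()
        ref = base.values()
        assert got.diagonal().mean() == pytest.approx(ref.diagonal().mean(), abs=1e-8)
        off = ~np.eye(len(ref), dtype=bool)
        assert got[off].mean() == pytest.approx(ref[off].mean(), abs=1e-8)

    def test_single_offdiagonal_pair_changes_only_cross_term(self):
        g, base, net = self.setup_data(seed=6)
        d0 = np.eye(6)
        d1 = d0.copy()
        d1[0, 1] = d1[1, 0] = 1.0
        sub = g.codes[net].to_numpy()
        p = sub.mean(axis=0) / 2
        Z = (sub - 2 * p) / np.sqrt(2 * p * (1 - p))
        raw0 = Z @ d0 @ Z.T / 6
        raw1 = Z @ d1 @ Z.T / 6
        cross = (np.outer(Z[:, 0], Z[:, 1]) + np.outer(Z[:, 1], Z[:, 0])) / 6
        assert np.allclose(raw1 - raw0, cross, atol=1e-12)

    def test_indefinite_d_projected_to_psd(self):
        g, base, net = self.setup_data(seed=7)
        d = np.eye(6)
        # an inconsistent correlation pattern that is not PSD
        d[0, 1] = d[1, 0] = 0.99
        d[0, 2] = d[2, 0] = 0.99
        d[1, 2] = d[2, 1] = -0.99
        got = conn_g(g, net, pd.DataFrame(d, index=net, columns=net), base)
        assert np.isfinite(got.values()).all()

    def test_dimension_mismatch_errors(self):
        g, base, net = self.setup_data()
        d = pd.DataFrame(np.eye(3), index=net[:3], columns=net[:3])
        with pytest.raises((ValueError, KeyError)):
            conn_g(g, net, d, base)

    def test_d_matrix_from_network(self):
        awm = AWM(
            matrix=pd.DataFrame(np.eye(3), index=["g1", "g2", "g3"]),
            source_marker=pd.Series({"g1": "M1", "g2": "M2", "g3": "M3"}),
            mean_pvg=pd.Series({"g1": 0.1, "g2": 0.2, "g3": 0.3}),
        )
        net = nx.Graph()
        net.add_edge("g1", "g3", weight=-0.99)
        d = network_d_matrix(awm, net, ["M1", "M2", "M3"])
        want = np.eye(3)
        want[0, 2] = want[2, 0] = -0.99
        assert np.allclose(d, want)


class TestAMatrix:
    def ped(self, rows):
        return pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year"])

    def test_closed_forms(self):
        ped = self.ped([
            ("s", pd.NA, pd.NA, 0),
            ("d", pd.NA, pd.NA, 0),
            ("d2", pd.NA, pd.NA, 0),
            ("full1", "s", "d", 1),
            ("full2", "s", "d", 1),
            ("half", "s", "d2", 1),
        ])
        A = a_matrix(ped)
        assert A.loc["s", "full1"] == pytest.approx(0.5)      # parent-offspring
        assert A.loc["full1", "full2"] == pytest.approx(0.5)  # full sibs
        assert A.loc["full1", "half"] == pytest.approx(0.25)  # half sibs
        assert A.loc["s", "s"] == 1.0                          # founder diagonal
        assert A.loc["s", "d"] == 0.0

    def test_inbred_offspring_diagonal(self):
        ped = self.ped([
            ("s", pd.NA, pd.NA, 0),
            ("d", pd.NA, pd.NA, 0),
            ("o", "s", "d", 1),
            ("inbred", "s", "o", 2),   # sire mated to his daughter
        ])
        A = a_matrix(ped)
        assert A.loc["inbred", "inbred"] == pytest.approx(1.25)

    def test_unsorted_pedigree_rejected(self):
        ped = self.ped([("o", "s", pd.NA, 1), ("s", pd.NA, pd.NA, 0)])
        with pytest.raises(ValueError, match="sorted|ordering"):
            a_matrix(ped)

    def test_symmetric_psd(self, demo_breed):
        A = a_matrix(demo_breed.pedigree)
        m = A.to_numpy()
        assert np.allclose(m, m.T)
        assert np.linalg.eigvalsh(m).min() > -1e-8
        assert (m.diagonal() >= 1.0 - 1e-12).all()
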