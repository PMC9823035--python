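"""AWM variant selection, matrix assembly and PCIT network inference."""

import numpy as np
import pandas as pd
import pytest

import pecknet as pn
from pecknet import awm as awm_mod
from pecknet import simulate as sim
from pecknet.awm import (
    GeneNetwork,
    awm_correlation,
    build_awm,
    export_network,
    pcit,
    read_network,
    select_awm_variants,
)

TINY = 1e-12


def scan(ids, p, beta=None, se=None):
    m = len(ids)
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "id": ids,
            "maf": 0.3,
            "n": 100,
            "beta": beta if beta is not None else np.ones(m),
            "se": se if se is not None else np.ones(m),
            "p": p,
        }
    )


def pcit_oracle(c):
    """Exhaustive O(n^3) trio enumeration, written independently of the
    vectorized implementation."""
    c = np.asarray(c, float)
    n = c.shape[0]
    sig = np.ones((n, n), dtype=bool)
    for x in range(n):
        for y in range(n):
            if x != y and abs(c[x, y]) < TINY:
                sig[x, y] = False
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z == x or z == y:
                    continue
                rxy, rxz, ryz = c[x, y], c[x, z], c[y, z]
                pxy = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
                pxz = (rxz - rxy * ryz) / np.sqrt((1 - rxy**2) * (1 - ryz**2))
                pyz = (ryz - rxy * rxz) / np.sqrt((1 - rxy**2) * (1 - rxz**2))
                eps = (
                    abs(pxy) / max(abs(rxy), TINY)
                    + abs(pxz) / max(abs(rxz), TINY)
                    + abs(pyz) / max(abs(ryz), TINY)
                ) / 3.0
                if abs(rxy) < eps * abs(rxz) and abs(rxy) < eps * abs(ryz):
                    sig[x, y] = sig[y, x] = False
    return sig


def random_corr(rng, n):
    data = rng.normal(size=(n + 10, n)) @ rng.normal(size=(n, n))
    return np.corrcoef(data, rowvar=False)


def sig_matrix(net: GeneNetwork):
    n = len(net.nodes)
    idx = {v: i for i, v in enumerate(net.nodes)}
    sig = np.ones((n, n), dtype=bool)
    for _, e in net.edges.iterrows():
        a, b = idx[e["node_a"]], idx[e["node_b"]]
        sig[a, b] = sig[b, a] = bool(e["significant"])
    return sig


class TestSelect:
    def test_main_branch(self):
        main = scan(["v1", "v2"], [5e-5, 0.5])
        assert select_awm_variants(main, {}) == ["v1"]

    def test_egwas_branch_boundary_at_ten(self):
        main = scan(["v1"], [0.5])
        ten = {f"g{i}": scan(["v1"], [5e-5]) for i in range(10)}
        nine = {f"g{i}": scan(["v1"], [5e-5]) for i in range(9)}
        assert select_awm_variants(main, ten) == ["v1"]
        assert select_awm_variants(main, nine) == []

    def test_selection_ordered_by_position(self):
        main = scan(["v1", "v2", "v3"], [5e-5, 1e-6, 0.9])
        assert select_awm_variants(main, {}) == ["v1", "v2"]

    def test_printed_selection_fraction(self):
        """57 qualifying variants out of 35,571 is 0.16%."""
        m = 35_571
        ids = [f"v{i}" for i in range(m)]
        p = np.full(m, 0.5)
        p[:57] = 5e-5
        selected = select_awm_variants(scan(ids, p), {})
        assert len(selected) == 57
        assert round(100 * len(selected) / m, 2) == 0.16


class TestBuild:
    def test_z_is_beta_over_se(self):
        main = scan(["v1"], [1e-5], beta=[0.5], se=[0.25])
        awm = build_awm(["v1"], main, {"g1": scan(["v1"], [0.5], beta=[1.0], se=[0.5])})
        assert awm.z.loc["v1", "FPD_BC"] == pytest.approx(2.0)
        assert awm.z.loc["v1", "g1"] == pytest.approx(2.0)

    def test_missing_scan_entry_fills_zero(self):
        main = scan(["v1", "v2"], [1e-5, 1e-5])
        egwas = {"g1": scan(["v1"], [0.5])}  # v2 absent from the gene scan
        awm = build_awm(["v1", "v2"], main, egwas)
        assert awm.z.loc["v2", "g1"] == 0.0

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            build_awm([], scan(["v1"], [0.5]), {})

    def test_hub_targets_correlate_in_awm(self):
        """AWM columns of hub-regulated genes co-vary across selected
        variants more than unrelated gene pairs."""
        cfg = pn.SimConfig(
            seed=21, n_samples=300, n_expr_samples=300, n_genes=30,
            tf_hub=(0, tuple(range(1, 13)), 0.9),
            eqtl_hotspots=((13, 14, 15), (16, 17, 18)),
            qtl_spec=((10, 0.05),), h2_polygenic=0.1,
            n_chromosomes=3, n_variants_per_chrom=60, n_chip_per_chrom=40,
        )
        gt, truth, pheno, expr = sim.simulate_cohort(cfg)
        main = pn.mlma_loco(gt, pheno, covariates=("hatch", "line"))
        egwas = awm_mod.run_egwas(gt, expr, covariates=("hatch",), pheno=pheno)
        selected = select_awm_variants(main, egwas, min_egwas_hits=3)
        assert selected
        awm = build_awm(selected, main, egwas)
        corr = awm_correlation(awm)
        targets = [f"EG{g:03d}" for g in (1, 2, 3, 4, 5)]
        others = [f"EG{g:03d}" for g in (20, 22, 24, 26, 28)]
        t_corr = np.mean(
            [abs(corr.loc[a, b]) for i, a in enumerate(targets) for b in targets[i + 1:]]
        )
        o_corr = np.mean(
            [abs(corr.loc[a, b]) for i, a in enumerate(others) for b in others[i + 1:]]
        )
        assert t_corr > o_corr


class TestRunEgwas:
    def test_constant_expression_gene_skipped(self):
        cfg = pn.SimConfig(
            seed=31, n_samples=80, n_expr_samples=80, n_genes=4,
            tf_hub=(0, (1,), 0.5), qtl_spec=(),
            n_chromosomes=2, n_variants_per_chrom=20, n_chip_per_chrom=20,
        )
        gt, truth, pheno, expr = sim.simulate_cohort(cfg)
        expr = expr.copy()
        expr["EG002"] = 1.0  # zero variance
        res = awm_mod.run_egwas(gt, expr, covariates=("hatch",), pheno=pheno)
        assert "EG002" not in res
        assert set(res) == {"EG000", "EG001", "EG003"}
        panels = {tuple(r["id"]) for r in res.values()}
        assert len(panels) == 1  # all scans share the variant panel


class TestPcit:
    def test_two_traits_always_significant(self):
        net = pcit(np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert len(net.edges) == 1
        assert bool(net.edges["significant"].iloc[0])

    def test_strong_chain_keeps_indirect_edge(self):
        """r_xy = r_yz = 0.8, r_xz = 0.64: the trio tolerance is
        eps = (0.781 + 0 + 0.781)/3 = 0.521 and 0.64 > 0.521*0.8, so the
        indirect edge survives (hand computation of the trio rule)."""
        c = np.array([[1.0, 0.8, 0.64], [0.8, 1.0, 0.8], [0.64, 0.8, 1.0]])
        net = pcit(c)
        assert sig_matrix(net).all()

    def test_weak_chain_prunes_indirect_edge(self):
        """r_xy = r_yz = 0.5, r_xz = 0.25: eps = 0.596 and
        0.25 < 0.596*0.5 on both sides, so (x, z) is pruned while the two
        direct edges survive."""
        c = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        net = pcit(c)
        edges = net.edges.set_index(["node_a", "node_b"])["significant"]
        assert not edges.loc[("T0", "T2")]
        assert edges.loc[("T0", "T1")] and edges.loc[("T1", "T2")]

    @pytest.mark.parametrize("n", [3, 5, 10, 20, 40])
    def test_matches_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            c = random_corr(rng, n)
            net = pcit(c)
            assert np.array_equal(sig_matrix(net), pcit_oracle(c))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        c = random_corr(rng, 12)
        labels = [f"G{i}" for i in range(12)]
        perm = rng.permutation(12)
        net_a = pcit(pd.DataFrame(c, index=labels, columns=labels))
        cp = c[np.ix_(perm, perm)]
        lp = [labels[i] for i in perm]
        net_b = pcit(pd.DataFrame(cp, index=lp, columns=lp))
        def edge_set(net):
            return {
                tuple(sorted((e["node_a"], e["node_b"])))
                for _, e in net.edges.iterrows()
                if e["significant"]
            }
        assert edge_set(net_a) == edge_set(net_b)

    def test_pruning_never_adds_edges(self):
        rng = np.random.default_rng(9)
        c = random_corr(rng, 15)
        net = pcit(c)
        n_pairs = 15 * 14 // 2
        assert len(net.edges) == n_pairs
        assert int(net.edges["significant"].sum()) <= n_pairs

    def test_near_zero_direct_correlation_pruned(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 1e-14
        c[2, 3] = c[3, 2] = 0.5
        net = pcit(c)
        edges = net.edges.set_index(["node_a", "node_b"])["significant"]
        assert not edges.loc[("T0", "T1")]

    def test_perfect_proxy_is_pruned(self):
        # T0 and T1 perfectly correlated; their edges to T2 go through a
        # perfect proxy and are flagged non-significant
        c = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        net = pcit(c)
        edges = net.edges.set_index(["node_a", "node_b"])["significant"]
        assert edges.loc[("T0", "T1")]  # the duplicate pair itself survives
        assert not edges.loc[("T0", "T2")]
        assert not edges.loc[("T1", "T2")]

    def test_asymmetric_input_rejected(self):
        c = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError):
            pcit(c)


class TestExport:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        net = pcit(random_corr(rng, 8))
        path = tmp_path / "net.tsv"
        export_network(net, path)
        back = read_network(path)
        want = net.edges.loc[net.edges["significant"]]
        assert len(back) == len(want)
        got = {(r["node_a"], r["node_b"]) for _, r in back.iterrows()}
        assert got == {(r["node_a"], r["node_b"]) for _, r in want.iterrows()}

    def test_empty_network_header_only(self, tmp_path):
        net = GeneNetwork(
            nodes=[], edges=pd.DataFrame(columns=["node_a", "node_b", "weight", "significant"])
        )
        path = tmp_path / "empty.tsv"
        export_network(net, path)
        assert path.read_text() == "node_a\tinteraction\tnode_b\tweight\n"

    def test_three_edge_network(self, tmp_path):
        net = pcit(np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1.0]]))
        path = tmp_path / "three.tsv"
        export_network(net, path, significant_only=False)
        assert len(path.read_text().strip().splitlines()) == 4
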