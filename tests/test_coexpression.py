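"""Seed-anchored co-expression networks: profiles, pruning, unions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcnsurv.coexpression import (
    build_gcn,
    network_gene_union,
    read_edge_list,
    spearman_profile,
    write_edge_list,
)
from gcnsurv.datamodel_io import ExpressionMatrix, SeedGeneSet


def matrix_with(rows: dict[str, np.ndarray]) -> ExpressionMatrix:
    genes = list(rows)
    vals = np.vstack([rows[g] for g in genes])
    return ExpressionMatrix(genes, [f"S{j}" for j in range(vals.shape[1])], vals)


def gcn_oracle(rho: pd.DataFrame, thr: float):
    """Exhaustive nomination oracle, written as literal enumeration."""
    seeds = list(rho.index)
    genes = list(rho.columns)
    seed_set = set(seeds)
    cand = {}
    for s in seeds:
        for g in genes:
            if s == g:
                continue
            r = rho.loc[s, g]
            if np.isnan(r) or abs(r) < thr:
                continue
            key = (min(s, g), max(s, g)) if g in seed_set else (s, g)
            if key not in cand or abs(r) > abs(cand[key]):
                cand[key] = float(r)
    nominated = set()
    nodes = set()
    for a, b in cand:
        nodes.add(a)
        nodes.add(b)
    for node in nodes:
        inc = [(abs(r), other, key)
               for key, r in cand.items()
               for other in key if node in key and other != node]
        inc.sort(key=lambda e: (-e[0], e[1]))
        for _, _, key in inc[:2]:
            nominated.add(key)
    return nominated


class TestSpearmanProfile:
    def test_monotone_transform_gives_one(self, rng):
        s = rng.normal(size=12)
        m = matrix_with({"seed": s, "g": np.exp(s)})
        rho = spearman_profile(m, SeedGeneSet(["seed"]))
        assert rho.loc["seed", "g"] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        s = rng.normal(size=12)
        m = matrix_with({"seed": s, "g": -s})
        rho = spearman_profile(m, SeedGeneSet(["seed"]))
        assert rho.loc["seed", "g"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        m = matrix_with({f"g{i}": rng.normal(size=10) for i in range(6)})
        # inject ties to exercise midranks
        m.values[2, :4] = m.values[2, 4]
        rho = spearman_profile(m, SeedGeneSet(["g0", "g2"]))
        for s in ("g0", "g2"):
            for g in m.gene_ids:
                if s == g:
                    assert np.isnan(rho.loc[s, g])
                    continue
                ra = stats.rankdata(m.values[m.gene_ids.index(s)])
                rb = stats.rankdata(m.values[m.gene_ids.index(g)])
                expect = np.corrcoef(ra, rb)[0, 1]
                assert rho.loc[s, g] == pytest.approx(expect, abs=1e-12)

    def test_missing_seed_listed(self, rng):
        m = matrix_with({"a": rng.normal(size=5)})
        with pytest.raises(KeyError, match="zz"):
            spearman_profile(m, SeedGeneSet(["a", "zz"]))

    def test_mask_too_small(self, rng):
        m = matrix_with({"a": rng.normal(size=5), "b": rng.normal(size=5)})
        with pytest.raises(ValueError, match="3"):
            spearman_profile(m, SeedGeneSet(["a"]), np.array([1, 1, 0, 0, 0], bool))


class TestBuildGcn:
    def test_no_candidates_gives_isolated_seeds(self, rng):
        seeds = [f"s{i}" for i in range(34)]
        rho = pd.DataFrame(
            rng.uniform(-0.5, 0.5, size=(34, 50)),
            index=seeds,
            columns=seeds + [f"g{i}" for i in range(16)],
        )
        net = build_gcn(rho, 0.99, "all")
        assert len(net.edges) == 0
        assert net.nodes == frozenset(seeds)

    def test_top_two_nomination_and_union_rule(self):
        # the seed nominates only its two strongest edges (0.85, 0.83); g3's
        # edge survives anyway because g3 nominates its single candidate
        rho = pd.DataFrame([[0.85, 0.83, 0.80]], index=["s"], columns=["g1", "g2", "g3"])
        net = build_gcn(rho, 0.79, "all")
        assert net.nomination_counts()["s"] == 2
        assert net.edge_pairs == {("s", "g1"), ("s", "g2"), ("s", "g3")}
        # at a threshold cutting g3 out, only the seed's nominations remain
        net_hi = build_gcn(rho, 0.82, "all")
        assert net_hi.edge_pairs == {("s", "g1"), ("s", "g2")}

    def test_matches_exhaustive_oracle(self, rng):
        for rep in range(25):
            seeds = [f"s{i}" for i in range(5)]
            genes = seeds + [f"g{i}" for i in range(35)]
            vals = rng.uniform(-1, 1, size=(5, 40))
            rho = pd.DataFrame(vals, index=seeds, columns=genes)
            for s in seeds:
                rho.loc[s, s] = np.nan
            # symmetrize seed-seed entries as a real profile would be
            for i, a in enumerate(seeds):
                for b in seeds[i + 1:]:
                    rho.loc[b, a] = rho.loc[a, b]
            thr = float(rng.uniform(0.3, 0.95))
            net = build_gcn(rho, thr, "all")
            assert net.edge_pairs == gcn_oracle(rho, thr), f"rep {rep}, thr {thr}"

    def test_threshold_nestedness(self, rng):
        seeds = [f"s{i}" for i in range(5)]
        genes = seeds + [f"g{i}" for i in range(35)]
        vals = rng.uniform(-1, 1, size=(5, 40))
        rho = pd.DataFrame(vals, index=seeds, columns=genes)
        for s in seeds:
            rho.loc[s, s] = np.nan
        lo = build_gcn(rho, 0.5, "all")
        hi = build_gcn(rho, 0.7, "all")
        assert hi.edge_pairs <= lo.edge_pairs
        assert hi.nodes <= lo.nodes

    def test_nomination_cap(self, rng):
        rho = pd.DataFrame(
            rng.uniform(-1, 1, size=(4, 30)),
            index=[f"s{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(4)] + [f"g{i}" for i in range(26)],
        )
        net = build_gcn(rho, 0.4, "all")
        assert all(c <= 2 for c in net.nomination_counts().values())

    def test_sample_permutation_invariance(self, rng):
        m = matrix_with({f"g{i}": rng.normal(size=20) for i in range(8)})
        seeds = SeedGeneSet(["g0", "g1"])
        perm = rng.permutation(20)
        m2 = ExpressionMatrix(list(m.gene_ids), [m.sample_ids[j] for j in perm], m.values[:, perm])
        n1 = build_gcn(spearman_profile(m, seeds), 0.3, "all")
        n2 = build_gcn(spearman_profile(m2, seeds), 0.3, "all")
        assert n1.edge_pairs == n2.edge_pairs

    def test_recurrence_strata_disjoint(self, rng):
        m = matrix_with({f"g{i}": rng.normal(size=30) for i in range(6)})
        event = rng.random(30) < 0.4
        seeds = SeedGeneSet(["g0"])
        rec = spearman_profile(m, seeds, event)
        non = spearman_profile(m, seeds, ~event)
        assert not np.allclose(rec.loc["g0", "g1"], non.loc["g0", "g1"])


class TestUnionAndIO:
    def test_union_of_isolated_seeds(self, rng):
        seeds = [f"s{i}" for i in range(34)]
        rho = pd.DataFrame(np.zeros((34, 34)), index=seeds, columns=seeds)
        net = build_gcn(rho, 0.9, "all")
        assert network_gene_union([net]) == sorted(seeds)

    def test_disjoint_and_overlap_union(self, rng):
        vals = rng.uniform(-1, 1, (2, 9))
        cols = [f"x{i}" for i in range(9)]
        rho1 = pd.DataFrame(np.array([[0.9, 0.85, 0.1]]), index=["a"], columns=["p", "q", "r"])
        rho2 = pd.DataFrame(np.array([[0.95, 0.9, 0.2, 0.3]]), index=["b"], columns=["u", "v", "w", "z"])
        n1 = build_gcn(rho1, 0.8, "all")
        n2 = build_gcn(rho2, 0.8, "all")
        assert len(network_gene_union([n1, n2])) == 3 + 3  # a,p,q + b,u,v
        rho3 = pd.DataFrame(np.array([[0.9, 0.85]]), index=["a"], columns=["p", "v"])
        n3 = build_gcn(rho3, 0.8, "all")
        union = network_gene_union([n1, n2, n3])
        assert union == sorted(set(n1.nodes) | set(n2.nodes) | set(n3.nodes))

    def test_graphml_roundtrip(self, rng, tmp_path):
        from gcnsurv.coexpression import read_graphml, write_graphml

        seeds = [f"s{i}" for i in range(3)]
        rho = pd.DataFrame(
            rng.uniform(-1, 1, (3, 12)),
            index=seeds,
            columns=seeds + [f"g{i}" for i in range(9)],
        )
        for s in seeds:
            rho.loc[s, s] = np.nan
        net = build_gcn(rho, 0.4, "no_recurrence")
        p = tmp_path / "net.graphml"
        write_graphml(net, p)
        back = read_graphml(p)
        assert back.edge_pairs == net.edge_pairs
        assert back.nodes == net.nodes
        assert back.stratum == net.stratum

    def test_edge_list_roundtrip(self, rng, tmp_path):
        seeds = [f"s{i}" for i in range(3)]
        rho = pd.DataFrame(
            rng.uniform(-1, 1, (3, 10)),
            index=seeds,
            columns=seeds + [f"g{i}" for i in range(7)],
        )
        for s in seeds:
            rho.loc[s, s] = np.nan
        net = build_gcn(rho, 0.5, "recurrence")
        p = tmp_path / "net.tsv"
        write_edge_list(net, p)
        back = read_edge_list(p)
        assert back.edge_pairs == net.edge_pairs
        assert back.nodes == net.nodes
        assert back.stratum == "recurrence"
        assert back.threshold_r == net.threshold_r
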