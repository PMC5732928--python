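import itertools
import math

import networkx as nx
import numpy as np
import pytest

import riverkin as rk
from riverkin import mtdna as mt
from riverkin.data_model import HaplotypeAlignment


class TestSummary:
    def test_hd_hand_value(self):
        # haplotype counts (2, 2, 1): Hd = (5/4)(1 - 0.36) = 0.8
        aln = HaplotypeAlignment({"a": "AAAA", "b": "AAAA", "c": "AATT",
                                  "d": "AATT", "e": "TTTT"})
        s = mt.mtdna_summary(aln)
        assert s.h == 3
        assert s.Hd == pytest.approx(0.8, abs=1e-12)

    def test_identical_sequences(self):
        aln = HaplotypeAlignment({k: "ACGT" for k in "abc"})
        s = mt.mtdna_summary(aln)
        assert (s.Hd, s.pi, s.S) == (0.0, 0.0, 0)

    def test_pi_hand_value(self):
        # ACGT/ACGA/ACTA: diffs (1, 2, 1), 4 sites -> pi = (4/3)/4
        aln = HaplotypeAlignment({"a": "ACGT", "b": "ACGA", "c": "ACTA"})
        s = mt.mtdna_summary(aln)
        assert s.S == 2
        assert s.pi == pytest.approx((4 / 3) / 4, abs=1e-12)

    def test_single_sequence_na(self):
        s = mt.mtdna_summary(HaplotypeAlignment({"a": "ACGT"}))
        assert s.n == 1 and math.isnan(s.Hd) and math.isnan(s.pi)

    def test_quadratic_form_oracles(self):
        """Hd and pi match independent quadratic-form evaluations to
        1e-12 on random alignments."""
        for seed in range(25):
            aln = rk.sim_mtdna(12, 60, theta=3.0, seed=seed + 40)
            s = mt.mtdna_summary(aln)
            n = aln.n_sequences
            counts = aln.haplotype_frequencies()
            hd = (n / (n - 1)) * (1 - np.sum((counts / n) ** 2))
            assert s.Hd == pytest.approx(hd, abs=1e-12)
            seqs = [aln.sequences[i] for i in aln.sequences]
            usable = aln.usable_sites
            diffs = [sum(a[s_] != b[s_] for s_ in usable)
                     for a, b in itertools.combinations(seqs, 2)]
            pi = np.mean(diffs) / len(usable)
            assert s.pi == pytest.approx(pi, abs=1e-12)


class TestFuFs:
    def test_many_haplotypes_small_theta_strongly_negative(self):
        # n=4 all distinct, one mutation apart each from a backbone
        aln = HaplotypeAlignment({"a": "AAAAAAAA", "b": "TAAAAAAA",
                                  "c": "ATAAAAAA", "d": "AATAAAAA"})
        fs = mt.fu_fs(aln)
        sp = mt.ewens_k_tail(4, 4, mt._pairwise_stats(aln)[0])
        assert fs == pytest.approx(math.log(sp / (1 - sp)), abs=1e-12)
        assert fs < -1.0

    def test_stirling_tail_against_direct_enumeration(self):
        """Ewens K-tail for n=4 from Stirling numbers matches the direct
        Ewens sampling formula: P(K=k) = |s(n,k)| theta^k / theta^(n)."""
        theta = 0.7
        n = 4
        s_unsigned = {1: 6, 2: 11, 3: 6, 4: 1}
        rising = theta * (theta + 1) * (theta + 2) * (theta + 3)
        pk = {k: s_unsigned[k] * theta**k / rising for k in range(1, 5)}
        assert sum(pk.values()) == pytest.approx(1.0, abs=1e-12)
        for k_obs in range(1, 5):
            tail = sum(pk[k] for k in range(k_obs, 5))
            assert mt.ewens_k_tail(n, k_obs, theta) == \
                pytest.approx(tail, abs=1e-12)

    def test_single_haplotype_na(self):
        aln = HaplotypeAlignment({k: "ACGT" for k in "abcd"})
        assert math.isnan(mt.fu_fs(aln))

    def test_neutral_mean_near_zero(self):
        vals = []
        for s in range(150):
            aln = rk.sim_mtdna(20, 500, theta=5.0, seed=s)
            v = mt.fu_fs(aln)
            if not math.isnan(v):
                vals.append(v)
        se = np.std(vals) / math.sqrt(len(vals))
        assert abs(np.mean(vals)) < max(4 * se, 0.5)


class TestR2:
    def test_hand_value(self):
        # AAA/AAT/ATT: minor-state singletons at both sites -> U = (1,0,1)
        aln = HaplotypeAlignment({"a": "AAA", "b": "AAT", "c": "ATT"})
        k = 4 / 3
        expected = math.sqrt((2 * (1 - k / 2) ** 2 + (k / 2) ** 2) / 3) / 2
        assert mt.r2_statistic(aln) == pytest.approx(expected, abs=1e-12)
        assert mt.r2_statistic(aln) == pytest.approx(0.2357022603955158)

    def test_no_segregating_sites_na(self):
        aln = HaplotypeAlignment({k: "ACGT" for k in "ab"})
        assert math.isnan(mt.r2_statistic(aln))


class TestNeutralityPvalues:
    def test_median_statistic_gives_half(self):
        rng = np.random.default_rng(0)
        sims = [mt._simulate_fixed_s(20, 12, rng) for _ in range(301)]
        r2s = sorted(mt._r2_from(20, 12, k, U) for _, k, U in sims)
        med = r2s[150]
        ps = mt.neutrality_pvalues(float("nan"), med, 20, 12,
                                   n_sims=400, seed=5)
        assert abs(ps["p_r2"] - 0.5) < 0.1

    def test_growth_detected_by_r2(self):
        """A star-like genealogy (every mutation a singleton) yields a
        small R2 with a small coalescent p-value."""
        seqs = {"ref": "A" * 12}
        for i in range(11):
            s = list("A" * 12)
            s[i] = "T"
            seqs[f"s{i}"] = "".join(s)
        aln = HaplotypeAlignment(seqs)
        r2 = mt.r2_statistic(aln)
        ps = mt.neutrality_pvalues(float("nan"), r2, aln.n_sequences,
                                   aln.n_segregating_sites,
                                   n_sims=500, seed=6)
        assert ps["p_r2"] < 0.05

    def test_seeded_reproducibility(self):
        a = mt.neutrality_pvalues(-1.0, 0.1, 15, 8, n_sims=300, seed=7)
        b = mt.neutrality_pvalues(-1.0, 0.1, 15, 8, n_sims=300, seed=7)
        assert a == b


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        aln = HaplotypeAlignment({"a": "AAAA", "b": "TTTA"})
        G = mt.median_joining_network(aln)
        assert G.number_of_nodes() == 2
        assert G.number_of_edges() == 1
        (_, _, data), = G.edges(data=True)
        assert data["weight"] == 3

    def test_median_vector_added_when_cheaper(self):
        # 000 / 110 / 101 in binary coding: star through 100 costs 3 < 4
        aln = HaplotypeAlignment({"a": "AAA", "b": "TTA", "c": "TAT"})
        G = mt.median_joining_network(aln)
        medians = [n for n, d in G.nodes(data=True) if not d["observed"]]
        assert len(medians) == 1
        assert G.nodes[medians[0]]["states"] == "TAA"
        total = sum(d["weight"] for _, _, d in G.edges(data=True))
        # exhaustive Steiner check over {A,T}^3 candidate interior points
        best = 4  # MST cost without a Steiner point
        for cand in itertools.product("AT", repeat=3):
            cost = sum(sum(x != y for x, y in zip(cand, h))
                       for h in ("AAA", "TTA", "TAT"))
            best = min(best, cost)
        assert total == best == 3

    def test_connectivity_and_mst_cost_bound(self):
        """The network always spans all observed haplotypes and costs no
        more than their MST."""
        for seed in range(8):
            aln = rk.sim_mtdna(15, 100, theta=4.0, seed=seed + 10)
            if aln.n_haplotypes < 2:
                continue
            G = mt.median_joining_network(aln)
            observed = {f"H{h}" for h in set(aln.haplotype_index.values())}
            assert observed <= set(G.nodes)
            assert nx.is_connected(G)
            # MST over observed haplotypes only
            haps = {}
            for ind, h in aln.haplotype_index.items():
                haps.setdefault(h, aln.sequences[ind])
            K = nx.Graph()
            usable = aln.usable_sites
            for h1, h2 in itertools.combinations(haps, 2):
                d = sum(haps[h1][s] != haps[h2][s] for s in usable)
                K.add_edge(h1, h2, weight=d)
            mst_cost = sum(d["weight"] for _, _, d in
                           nx.minimum_spanning_tree(K).edges(data=True))
            # a spanning tree through the network (with its Steiner
            # medians) costs no more than the observed-haplotype MST
            net_tree_cost = sum(d["weight"] for _, _, d in
                                nx.minimum_spanning_tree(G).edges(data=True))
            assert net_tree_cost <= mst_cost + 1e-9
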