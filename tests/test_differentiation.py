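import itertools

import numpy as np
import pytest

import riverkin as rk
from riverkin import differentiation as dif
from riverkin.data_model import HaplotypeAlignment, SampleMetadata


def dest_oracle(freq_vectors, sizes):
    """Independent direct evaluation of the corrected Jost's D formula from
    per-population frequency vectors and sample sizes."""
    k = len(freq_vectors)
    P = np.asarray(freq_vectors, dtype=float)
    ns = np.asarray(sizes, dtype=float)
    n_harm = k / np.sum(1.0 / ns)
    hs = (2 * n_harm / (2 * n_harm - 1)) * (1 - np.mean(np.sum(P**2, axis=1)))
    pbar = P.mean(axis=0)
    ht = 1 - np.sum(pbar**2) + hs / (2 * n_harm * k)
    return ((ht - hs) / (1 - hs)) * (k / (k - 1))


def make_two_pop(genosA, genosB):
    n = len(genosA) + len(genosB)
    ids = [f"i{k}" for k in range(n)]
    calls = np.array([[g] for g in genosA + genosB])
    m = rk.GenotypeMatrix(ids, ["L"], calls)
    site = {i: ("P1" if k < len(genosA) else "P2")
            for k, i in enumerate(ids)}
    return m, SampleMetadata(site)


class TestJostD:
    def test_identical_samples_at_known_negative_bias(self):
        g = [[1, 2]] * 5 + [[1, 1]] * 3 + [[2, 2]] * 2
        m, md = make_two_pop(g, g)
        _, d = rk.jost_dest(m, md)
        # the sample-size-corrected estimator sits just below 0 on
        # identical samples; the exact value follows from the formulas
        nh, k = 10.0, 2
        p1 = 11 / 20
        hs_plug = 1 - (p1**2 + (1 - p1) ** 2)
        hs = (2 * nh / (2 * nh - 1)) * hs_plug
        ht = hs_plug + hs / (2 * nh * k)
        oracle = ((ht - hs) / (1 - hs)) * (k / (k - 1))
        assert oracle < 0
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_fixed_demes_approach_one(self):
        m, md = make_two_pop([[1, 1]] * 40, [[2, 2]] * 40)
        _, d = rk.jost_dest(m, md)
        assert d > 0.97

    def test_matches_formula_oracle(self):
        """2 demes, 1 locus, frequencies (0.7, 0.3) vs (0.3, 0.7), n=10."""
        a = [[1, 1]] * 4 + [[1, 2]] * 6        # 14 x allele1, 6 x allele2
        b = [[2, 2]] * 4 + [[1, 2]] * 6
        m, md = make_two_pop(a, b)
        per, d = rk.jost_dest(m, md)
        oracle = dest_oracle([[0.7, 0.3], [0.3, 0.7]], [10, 10])
        assert d == pytest.approx(oracle, abs=1e-12)
        assert per["L"] == pytest.approx(oracle, abs=1e-12)

    def test_label_order_invariance(self, three_deme_data):
        genos, md = three_deme_data
        pops = md.populations()
        _, d1 = rk.jost_dest(genos, md, pops)
        _, d2 = rk.jost_dest(genos, md, pops[::-1])
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_significance_floor_on_diverged_demes(self, three_deme_data):
        genos, md = three_deme_data
        p = rk.dest_significance(genos, md, md.populations()[:2],
                                 n_bootstrap=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_bootstrap_minimum_enforced(self, three_deme_data):
        genos, md = three_deme_data
        with pytest.raises(ValueError):
            rk.dest_significance(genos, md, n_bootstrap=50)

    def test_panmictic_not_significant(self):
        genos, md = rk.sim_structured_pops(2, 20, 0.0, 2.0, rk.IAM, seed=21)
        p = rk.dest_significance(genos, md, n_bootstrap=199, seed=3)
        assert p > 0.05


class TestAmovaPhiST:
    def test_fixed_haplotypes_phi_one(self):
        aln = HaplotypeAlignment({"a": "AAAA", "b": "AAAA",
                                  "c": "TTTA", "d": "TTTA"})
        md = SampleMetadata({"a": "P1", "b": "P1", "c": "P2", "d": "P2"})
        phi, _ = rk.amova_phist(aln, md, n_perm=100, seed=1)
        assert phi == pytest.approx(1.0, abs=1e-12)

    def test_components_match_ssd_oracle(self):
        """2 pops x 3 sequences: brute-force sums of squared deviations."""
        seqs = {"a": "AAAAA", "b": "AATAA", "c": "AATTA",
                "d": "TTTTT", "e": "TTTTA", "f": "ATTTT"}
        md = SampleMetadata({k: ("P1" if k in "abc" else "P2") for k in seqs})
        aln = HaplotypeAlignment(seqs)
        phi, _ = rk.amova_phist(aln, md, n_perm=100, seed=1)

        ids = list(seqs)
        d = {(i, j): sum(x != y for x, y in zip(seqs[i], seqs[j]))
             for i, j in itertools.product(ids, ids)}
        n, k = 6, 2
        ssd_t = sum(d[i, j] for i, j in itertools.combinations(ids, 2)) / n
        ssd_w = 0.0
        for group in ("abc", "def"):
            ssd_w += sum(d[i, j] for i, j
                         in itertools.combinations(group, 2)) / 3
        sigma_b = ssd_w / (n - k)
        n_eff = (n - (9 + 9) / n) / (k - 1)
        sigma_a = ((ssd_t - ssd_w) / (k - 1) - sigma_b) / n_eff
        assert phi == pytest.approx(sigma_a / (sigma_a + sigma_b), abs=1e-12)

    def test_panmictic_phi_near_zero_can_be_negative(self):
        rng = np.random.default_rng(5)
        phis = []
        for s in range(30):
            aln = rk.sim_mtdna(16, 300, theta=4.0, seed=s + 300)
            ids = list(aln.sequences)
            labels = rng.permutation(["P1"] * 8 + ["P2"] * 8)
            md = SampleMetadata(dict(zip(ids, labels)))
            phi, _ = rk.amova_phist(aln, md, n_perm=10, seed=s)
            phis.append(phi)
        assert abs(np.mean(phis)) < 0.1
        assert min(phis) < 0  # negative values are reported, not clamped

    def test_singleton_population_participates(self):
        seqs = {"a": "AAAA", "b": "AATA", "c": "TTTT"}
        md = SampleMetadata({"a": "P1", "b": "P1", "c": "P2"})
        phi, p = rk.amova_phist(aln := HaplotypeAlignment(seqs), md,
                                n_perm=50, seed=1)
        assert np.isfinite(phi)

    def test_all_identical_sequences_na(self):
        seqs = {k: "AAAA" for k in "abcd"}
        md = SampleMetadata({"a": "P1", "b": "P1", "c": "P2", "d": "P2"})
        phi, p = rk.amova_phist(HaplotypeAlignment(seqs), md, n_perm=10)
        assert np.isnan(phi)

    def test_monotone_in_divergence_time(self):
        """Median phi_ST increases with drift time on two-deme mtDNA-like
        data built by sampling haplotypes within vs between simulations."""
        meds = []
        for div, reps in ((0.0, 12), (0.8, 12)):
            phis = []
            for s in range(reps):
                genos, md = rk.sim_structured_pops(2, 10, div, 3.0, rk.IAM,
                                                   seed=s + 700, n_loci=1)
                # haploid analogue: use first allele as a 1-site haplotype
                seqs = {}
                alleles = sorted({int(a) for a in
                                  genos.calls[:, 0, 0].tolist()})
                base = "ACGT" * ((len(alleles) + 3) // 4)
                for i, ind in enumerate(genos.individuals):
                    a = int(genos.calls[i, 0, 0])
                    seqs[ind] = base[alleles.index(a)] * 4
                try:
                    phi, _ = rk.amova_phist(HaplotypeAlignment(seqs), md,
                                            n_perm=10, seed=s)
                except ValueError:
                    continue
                if np.isfinite(phi):
                    phis.append(phi)
            meds.append(np.median(phis))
        assert meds[0] < meds[1]
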