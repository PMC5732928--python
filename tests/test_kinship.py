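import itertools
import math

import numpy as np
import pytest

import riverkin as rk
from riverkin import kinship
from riverkin.kinship import (MOMENT_ESTIMATORS, classify_relationship,
                              relatedness_dyadml, relatedness_moment)


def single_locus(gx, gy):
    return np.array([gx]), np.array([gy])


class TestMomentEstimators:
    def test_qg_identical_heterozygotes_is_one(self):
        # three alleles so the QG denominator does not vanish
        freqs = [{1: 0.3, 2: 0.3, 3: 0.4}]
        gx, gy = single_locus([1, 2], [1, 2])
        assert relatedness_moment(gx, gy, freqs, "QG") == \
            pytest.approx(1.0, abs=1e-12)

    def test_qg_vanishing_denominator_is_na(self):
        # identical heterozygotes at a biallelic 50/50 locus: num = den = 0
        freqs = [{1: 0.5, 2: 0.5}]
        gx, gy = single_locus([1, 2], [1, 2])
        assert math.isnan(relatedness_moment(gx, gy, freqs, "QG"))

    @pytest.mark.parametrize("estimator", MOMENT_ESTIMATORS)
    def test_unrelated_mean_near_zero(self, estimator, uniform_freqs):
        pp = rk.sim_pedigree_pairs(uniform_freqs, "U", 1500, seed=5)
        vals = np.array([relatedness_moment(pp.x[i], pp.y[i], uniform_freqs,
                                            estimator)
                         for i in range(pp.n_pairs)])
        vals = vals[~np.isnan(vals)]
        se = vals.std(ddof=1) / math.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se + 0.01

    @pytest.mark.parametrize("category,r", [("HS", 0.25), ("FS", 0.5)])
    def test_category_means(self, category, r, uniform_freqs):
        pp = rk.sim_pedigree_pairs(uniform_freqs, category, 1500, seed=6)
        for est in MOMENT_ESTIMATORS:
            vals = np.array([relatedness_moment(pp.x[i], pp.y[i],
                                                uniform_freqs, est)
                             for i in range(pp.n_pairs)])
            vals = vals[~np.isnan(vals)]
            se = vals.std(ddof=1) / math.sqrt(vals.size)
            assert abs(vals.mean() - r) < 3 * se + 0.01, est

    def test_pair_order_exchangeable(self, uniform_freqs):
        pp = rk.sim_pedigree_pairs(uniform_freqs, "HS", 30, seed=7)
        for est in MOMENT_ESTIMATORS:
            for i in range(10):
                a = relatedness_moment(pp.x[i], pp.y[i], uniform_freqs, est)
                b = relatedness_moment(pp.y[i], pp.x[i], uniform_freqs, est)
                assert a == pytest.approx(b, abs=1e-10)

    def test_moment_estimates_exit_unit_interval(self, uniform_freqs):
        pp = rk.sim_pedigree_pairs(uniform_freqs, "U", 300, seed=8)
        vals = [relatedness_moment(pp.x[i], pp.y[i], uniform_freqs, "QG")
                for i in range(pp.n_pairs)]
        assert min(vals) < 0  # unbounded moment estimator


class TestDyadML:
    def test_no_shared_alleles_gives_zero(self):
        freqs = [{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}]
        gx, gy = single_locus([1, 2], [3, 4])
        r, coeffs = relatedness_dyadml(gx, gy, freqs)
        assert r == pytest.approx(0.0, abs=1e-6)
        assert coeffs["k0"] == pytest.approx(1.0, abs=1e-6)

    def test_po_pairs_fit_k1_near_one(self, uniform_freqs):
        pp = rk.sim_pedigree_pairs(uniform_freqs, "PO", 300, seed=9)
        k1s, rs = [], []
        for i in range(pp.n_pairs):
            r, c = relatedness_dyadml(pp.x[i], pp.y[i], uniform_freqs)
            k1s.append(c["k1"])
            rs.append(r)
        assert np.mean(k1s) > 0.9
        assert abs(np.mean(rs) - 0.5) < 0.02

    def test_bounded_in_unit_interval(self, uniform_freqs):
        pp = rk.sim_pedigree_pairs(uniform_freqs, "U", 200, seed=10)
        for i in range(pp.n_pairs):
            r, _ = relatedness_dyadml(pp.x[i], pp.y[i], uniform_freqs)
            assert 0.0 <= r <= 1.0

    def test_agrees_with_simplex_grid_oracle(self, uniform_freqs):
        """EM maximum matches a brute-force grid search over the
        (k0, k1, k2) simplex to 1e-3 in r."""
        pp = rk.sim_pedigree_pairs(uniform_freqs, "FS", 25, seed=11)
        step = 0.02
        grid = [(k2, k1) for k2 in np.arange(0, 1 + 1e-9, step)
                for k1 in np.arange(0, 1 - k2 + 1e-9, step)]
        prep = kinship._prep(uniform_freqs)
        for i in range(12):
            r_em, _ = relatedness_dyadml(pp.x[i], pp.y[i], uniform_freqs)
            C = []
            for l, pl in enumerate(prep):
                x = tuple(int(v) for v in pp.x[i][l])
                y = tuple(int(v) for v in pp.y[i][l])
                C.append([kinship._mode_pair_prob(x, y, pl.p, m)
                          for m in (2, 1, 0)])
            C = np.array(C)
            best_ll, best_r = -np.inf, None
            for k2, k1 in grid:
                w = np.array([k2, k1, 1 - k2 - k1])
                mix = C @ w
                if np.any(mix <= 0):
                    continue
                ll = np.sum(np.log(mix))
                if ll > best_ll:
                    best_ll, best_r = ll, k1 / 2 + k2
            assert abs(r_em - best_r) < step  # grid resolution bound

    def test_jacquard_reduces_to_noninbred_on_outbred_pairs(self,
                                                            uniform_freqs):
        pp = rk.sim_pedigree_pairs(uniform_freqs, "FS", 40, seed=12)
        diffs = []
        for i in range(20):
            r1, _ = relatedness_dyadml(pp.x[i], pp.y[i], uniform_freqs,
                                       allow_inbreeding=False)
            r9, _ = relatedness_dyadml(pp.x[i], pp.y[i], uniform_freqs,
                                       allow_inbreeding=True)
            diffs.append(abs(r1 - r9))
        assert np.mean(diffs) < 0.05


class TestClassification:
    def test_mendelian_exclusion_of_po(self):
        freqs = [{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}]
        gx, gy = single_locus([1, 2], [3, 4])
        cat, logl = classify_relationship(gx, gy, freqs)
        assert logl["PO"] == -math.inf
        assert cat == "U"

    def test_single_locus_hand_likelihoods(self):
        """(ab, ab) at a locus with four equifrequent alleles: per-mode
        pair probabilities computed by hand."""
        p = 0.25
        freqs = [{1: p, 2: p, 3: p, 4: p}]
        gx, gy = single_locus([1, 2], [1, 2])
        _, logl = classify_relationship(gx, gy, freqs)
        hwe = 2 * p * p
        by_mode = {2: hwe,                       # identical forced
                   1: hwe * (0.5 * p + 0.5 * p),  # share one, draw other
                   0: hwe * hwe}
        for lab in ("U", "HS", "FS", "PO"):
            k0, k1, k2 = rk.CATEGORIES[lab].k
            lik = k2 * by_mode[2] + k1 * by_mode[1] + k0 * by_mode[0]
            assert logl[lab] == pytest.approx(math.log(lik), abs=1e-12)

    def test_fullsib_pairs_mostly_fs_or_po(self, uniform_freqs):
        pp = rk.sim_pedigree_pairs(uniform_freqs, "FS", 300, seed=13)
        cats = [classify_relationship(pp.x[i], pp.y[i], uniform_freqs)[0]
                for i in range(pp.n_pairs)]
        frac = np.mean([c in ("FS", "PO") for c in cats])
        assert frac >= 0.8

    def test_tie_breaks_to_less_related(self):
        # a monomorphic-information locus makes all categories equal
        freqs = [{1: 0.5, 2: 0.5}]
        gx, gy = single_locus([1, 1], [2, 2])
        cat, logl = classify_relationship(gx, gy, freqs)
        assert cat == "U"  # PO excluded; among the rest U is least related


class TestEvaluateEstimators:
    def test_report_shape_and_ordering(self, uniform_freqs):
        df = kinship.evaluate_estimators(uniform_freqs, n_pairs=400, seed=14)
        assert set(df["category"]) == {"U", "HS", "FS"}
        for est in kinship.ALL_ESTIMATORS:
            sub = df[df["estimator"] == est].set_index("category")["mean"]
            assert sub["U"] < sub["HS"] < sub["FS"]

    def test_likelihood_estimator_least_variable(self, uniform_freqs):
        df = kinship.evaluate_estimators(uniform_freqs, n_pairs=400, seed=14,
                                         estimators=("Ritland", "DyadML"))
        sub = df[df["category"] == "U"].set_index("estimator")["variance"]
        assert sub["DyadML"] <= sub["Ritland"]
        assert df.attrs["recommended"] == "DyadML"

    def test_seeded_determinism(self, uniform_freqs):
        a = kinship.evaluate_estimators(uniform_freqs, n_pairs=100, seed=15,
                                        estimators=("QG",))
        b = kinship.evaluate_estimators(uniform_freqs, n_pairs=100, seed=15,
                                        estimators=("QG",))
        assert a.equals(b)


class TestPairwiseTable:
    def test_table_symmetric_and_complete(self):
        genos = rk.sim_population_equilibrium(8, 10, 3.0, rk.IAM, seed=16)
        table = kinship.pairwise_relatedness(genos, ("QG", "DyadML"))
        assert len(table.pairs) == 28
        m = table.matrix("QG", genos.individuals)
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
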