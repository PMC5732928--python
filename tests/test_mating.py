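import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riverkin as rk
from riverkin import mating
from riverkin.data_model import SampleMetadata
from riverkin.kinship import RelatednessTable


def metadata_with(f, m, u):
    site, sex = {}, {}
    for i in range(f):
        site[f"F{i}"] = "X"
        sex[f"F{i}"] = "F"
    for i in range(m):
        site[f"M{i}"] = "X"
        sex[f"M{i}"] = "M"
    for i in range(u):
        site[f"U{i}"] = "X"
        sex[f"U{i}"] = "U"
    return SampleMetadata(site, sex)


def fake_table(pairs_df, r_a, r_b):
    rows = []
    for _, row in pairs_df.iterrows():
        rows.append({"id1": row["id1"], "id2": row["id2"],
                     "DyadML": r_a, "QG": r_b})
    return RelatednessTable(pd.DataFrame(rows), ("DyadML", "QG"))


class TestEnumeration:
    def test_study_scale_counts(self):
        md = metadata_with(44, 21, 5)
        pairs = mating.enumerate_pairings(md)
        assert len(pairs) == 44 * 21 + 5 * 69 == 1269
        assert (pairs["context"] == "FxM").sum() == 924

    def test_single_cross(self):
        pairs = mating.enumerate_pairings(metadata_with(1, 1, 0))
        assert len(pairs) == 1

    def test_unknown_only_double_counts(self):
        pairs = mating.enumerate_pairings(metadata_with(0, 0, 3))
        assert len(pairs) == 6          # 3 unique pairs listed twice
        assert pairs["duplicate"].sum() == 3
        unique = mating.enumerate_pairings(metadata_with(0, 0, 3),
                                           unique_pairs=True)
        assert len(unique) == 3

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 6))
    def test_count_identity(self, f, m, u):
        """F*M + U*(N-1) for arbitrary sex assignments."""
        if f + m + u < 2:
            return
        md = metadata_with(f, m, u)
        n = f + m + u
        assert len(mating.enumerate_pairings(md)) == f * m + u * (n - 1)


class TestClassification:
    @pytest.mark.parametrize("r,expected", [
        (0.1, "advisable"), (0.2499, "advisable"),
        (0.25, "marginal"), (0.4, "marginal"), (0.5, "marginal"),
        (0.5001, "inadvisable"), (0.9, "inadvisable"),
    ])
    def test_threshold_boundaries(self, r, expected):
        assert mating.classify_r(r) == expected

    def test_consensus_takes_more_severe(self):
        md = metadata_with(1, 1, 0)
        pairs = mating.enumerate_pairings(md)
        plan = mating.classify_pairings(pairs, fake_table(pairs, 0.1, 0.3))
        assert plan.pairs["consensus"].iloc[0] == "marginal"
        plan2 = mating.classify_pairings(pairs, fake_table(pairs, 0.1, 0.1))
        assert plan2.pairs["consensus"].iloc[0] == "advisable"

    def test_missing_estimates_warn_and_exclude(self):
        md = metadata_with(2, 1, 0)
        pairs = mating.enumerate_pairings(md)
        table = fake_table(pairs.iloc[:1], 0.1, 0.1)
        with pytest.warns(UserWarning, match="lack a relatedness"):
            plan = mating.classify_pairings(pairs, table)
        assert (plan.pairs["consensus"] == "unevaluated").sum() == 1
        assert plan.summary()["count"].sum() == 1

    def test_category_monotone_in_r(self):
        order = {"advisable": 0, "marginal": 1, "inadvisable": 2}
        cats = [order[mating.classify_r(r)]
                for r in np.linspace(0, 1, 101)]
        assert cats == sorted(cats)


class TestReport:
    def test_printed_percentages_reproduce(self):
        """Counts (1108, 140, 21) of 1269 give 87.3 / 11.0 / 1.7."""
        md = metadata_with(44, 21, 5)
        pairs = mating.enumerate_pairings(md)
        rs = np.concatenate([np.full(1108, 0.1), np.full(140, 0.3),
                             np.full(21, 0.6)])
        # assign one value per unordered pair so duplicated U-U listings
        # classify consistently
        lut = {}
        for (_, row), r in zip(pairs.iterrows(), rs):
            lut.setdefault(frozenset((row["id1"], row["id2"])), r)
        rows = [{"id1": row["id1"], "id2": row["id2"],
                 "DyadML": lut[frozenset((row["id1"], row["id2"]))],
                 "QG": lut[frozenset((row["id1"], row["id2"]))]}
                for _, row in pairs.iterrows()]
        table = RelatednessTable(pd.DataFrame(rows), ("DyadML", "QG"))
        plan = mating.classify_pairings(pairs, table)
        summary, matrix = mating.mating_report(plan)
        by = summary.set_index("category")
        # duplicated U-U rows shift a handful of counts; the percentage
        # arithmetic count/total*100 at one decimal is what must hold
        for cat in ("advisable", "marginal", "inadvisable"):
            c = by.loc[cat, "count"]
            assert by.loc[cat, "percent"] == round(100 * c / 1269, 1)

    def test_exact_percent_arithmetic(self):
        assert round(100 * 1108 / 1269, 1) == 87.3
        assert round(100 * 140 / 1269, 1) == 11.0
        assert round(100 * 21 / 1269, 1) == 1.7

    def test_single_advisable_pair(self):
        md = metadata_with(1, 1, 0)
        pairs = mating.enumerate_pairings(md)
        plan = mating.classify_pairings(pairs, fake_table(pairs, 0.05, 0.05))
        s = plan.summary().set_index("category")["percent"]
        assert s["advisable"] == 100.0
        assert s["marginal"] == 0.0

    def test_percentages_recompute_from_matrix(self):
        md = metadata_with(3, 2, 1)
        pairs = mating.enumerate_pairings(md)
        rng = np.random.default_rng(1)
        lut = {}
        for _, row in pairs.iterrows():
            lut.setdefault(frozenset((row["id1"], row["id2"])),
                           float(rng.uniform(0, 0.8)))
        rows = [{"id1": r["id1"], "id2": r["id2"],
                 "DyadML": lut[frozenset((r["id1"], r["id2"]))],
                 "QG": lut[frozenset((r["id1"], r["id2"]))]}
                for _, r in pairs.iterrows()]
        table = RelatednessTable(pd.DataFrame(rows), ("DyadML", "QG"))
        plan = mating.classify_pairings(pairs, table)
        summary, matrix = mating.mating_report(plan)
        # cross-foot: recount plan rows from the matrix cells they map to
        for _, row in plan.pairs.iterrows():
            assert matrix.loc[row["id1"], row["id2"]] == row["consensus"]


class TestPedigreeBroodstock:
    def test_true_close_kin_rarely_advisable(self, uniform_freqs):
        """FS and PO pairs with 20 informative loci almost never land in
        the advisable class under the DyadML/QG consensus."""
        from riverkin.kinship import relatedness_dyadml, relatedness_moment
        bad = total = 0
        for cat in ("FS", "PO"):
            pp = rk.sim_pedigree_pairs(uniform_freqs, cat, 120, seed=17)
            for i in range(pp.n_pairs):
                r_a, _ = relatedness_dyadml(pp.x[i], pp.y[i], uniform_freqs)
                r_b = relatedness_moment(pp.x[i], pp.y[i], uniform_freqs,
                                         "QG")
                ca, cb = mating.classify_r(r_a), mating.classify_r(r_b)
                sev = max(ca, cb, key=lambda c: mating._SEVERITY[c])
                total += 1
                bad += sev == "advisable"
        assert bad / total <= 0.05
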