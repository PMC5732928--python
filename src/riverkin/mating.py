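"""Captive-breeding mating advisor.

Enumerates candidate broodstock pairings (every female x male cross, plus
every pairing involving an unknown-sex individual), classifies each by
pairwise relatedness against the theoretical category thresholds — below
0.25 advisable, 0.25 to 0.5 inclusive marginal (half-sib-level kinship),
above 0.5 inadvisable (full-sib / parent-offspring level) — and reports a
two-estimator consensus in which the more severe category wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SampleMetadata
from .kinship import RelatednessTable

ADVISABLE, MARGINAL, INADVISABLE = "advisable", "marginal", "inadvisable"
_SEVERITY = {ADVISABLE: 0, MARGINAL: 1, INADVISABLE: 2}


def classify_r(r: float) -> str:
    """Threshold classification of a relatedness value (closed interval
    [0.25, 0.5] is marginal)."""
    if np.isnan(r):
        return "unevaluated"
    if r < 0.25:
        return ADVISABLE
    if r <= 0.5:
        return MARGINAL
    return INADVISABLE


def enumerate_pairings(metadata: SampleMetadata,
                       unique_pairs: bool = False) -> pd.DataFrame:
    """Candidate pairings: all F x M crosses plus, for each unknown-sex
    individual, a pairing with every other individual.

    The default enumeration lists each U-U pair twice (once per U
    endpoint), reproducing the F*M + U*(N-1) arithmetic of broodstock
    screening; such rows carry ``duplicate=True`` on their second
    occurrence.  ``unique_pairs=True`` drops the duplicates.
    """
    inds = metadata.individuals
    if len(inds) < 2:
        raise ValueError("need at least 2 individuals")
    females = [i for i in inds if metadata.sex[i] == "F"]
    males = [i for i in inds if metadata.sex[i] == "M"]
    unknown = [i for i in inds if metadata.sex[i] == "U"]
    rows = []
    seen: set[frozenset] = set()
    for f in females:
        for m in males:
            rows.append({"id1": f, "id2": m, "context": "FxM",
                         "duplicate": False})
            seen.add(frozenset((f, m)))
    for u in unknown:
        for other in inds:
            if other == u:
                continue
            key = frozenset((u, other))
            dup = key in seen
            rows.append({"id1": u, "id2": other, "context": "U-involved",
                         "duplicate": dup})
            seen.add(key)
    df = pd.DataFrame(rows)
    if unique_pairs and len(df):
        df = df[~df["duplicate"]].reset_index(drop=True)
    return df


@dataclass
class MatingPlan:
    pairs: pd.DataFrame      # id1, id2, context, r_a, r_b, cat_a, cat_b, consensus
    method_a: str
    method_b: str
    note: str = ("consensus rule: the more severe of the two categories "
                 "(advisable < marginal < inadvisable)")

    def summary(self) -> pd.DataFrame:
        evaluated = self.pairs[self.pairs["consensus"] != "unevaluated"]
        total = len(evaluated)
        rows = []
        for cat in (ADVISABLE, MARGINAL, INADVISABLE):
            n = int((evaluated["consensus"] == cat).sum())
            pct = round(100.0 * n / total, 1) if total else float("nan")
            rows.append({"category": cat, "count": n, "percent": pct})
        return pd.DataFrame(rows)


def classify_pairings(pairs: pd.DataFrame, relatedness: RelatednessTable,
                      method_a: str = "DyadML",
                      method_b: str = "QG") -> MatingPlan:
    """Classify every enumerated pairing under two estimators and take the
    severity-max consensus.  Pairs without an estimate under either method
    are reported ``unevaluated`` and excluded from percentages."""
    lut_a = relatedness.lookup(method_a)
    lut_b = relatedness.lookup(method_b)
    out = pairs.copy()
    r_a, r_b, cat_a, cat_b, consensus = [], [], [], [], []
    n_missing = 0
    for _, row in pairs.iterrows():
        key = frozenset((row["id1"], row["id2"]))
        ra = lut_a.get(key, float("nan"))
        rb = lut_b.get(key, float("nan"))
        ca, cb = classify_r(ra), classify_r(rb)
        if "unevaluated" in (ca, cb):
            cons = "unevaluated"
            n_missing += 1
        else:
            cons = max(ca, cb, key=lambda c: _SEVERITY[c])
        r_a.append(ra)
        r_b.append(rb)
        cat_a.append(ca)
        cat_b.append(cb)
        consensus.append(cons)
    out["r_a"], out["r_b"] = r_a, r_b
    out["cat_a"], out["cat_b"], out["consensus"] = cat_a, cat_b, consensus
    if n_missing:
        warnings.warn(f"{n_missing} pairings lack a relatedness estimate "
                      "and are excluded from percentages")
    return MatingPlan(out, method_a, method_b)


def mating_report(plan: MatingPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category summary plus a broodstock x broodstock consensus
    category matrix."""
    summary = plan.summary()
    inds = sorted(set(plan.pairs["id1"]) | set(plan.pairs["id2"]))
    matrix = pd.DataFrame("", index=inds, columns=inds, dtype=object)
    for _, row in plan.pairs.iterrows():
        matrix.loc[row["id1"], row["id2"]] = row["consensus"]
        matrix.loc[row["id2"], row["id1"]] = row["consensus"]
    return summary, matrix
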