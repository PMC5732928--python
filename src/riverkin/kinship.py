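"""Pairwise relatedness estimation and relationship classification.

Moment estimators (Queller-Goodnight, Lynch/Li similarity, Lynch-Ritland,
Ritland, and a Wang-style joint moment estimator on dyad similarity
categories), a dyadic maximum-likelihood estimator over IBD-mode mixtures
(optionally the nine Jacquard modes to allow inbreeding), ML-Relate-style
relationship classification against the four fixed pedigree categories,
and a simulation harness that scores every estimator on pedigree-simulated
pairs.

Genotypes are unordered allele pairs; a missing call at a locus drops that
locus from the pair's estimate.  Allele frequencies are supplied per locus
as ``{allele: frequency}`` and, by convention, come from the full reference
sample including the focal pair.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MISSING, GenotypeMatrix
from .simulate import (CATEGORIES, FULL_SIB, HALF_SIB, PARENT_OFFSPRING,
                       PedigreeCategory, PedigreePairs, UNRELATED,
                       sim_pedigree_pairs)

MOMENT_ESTIMATORS = ("QG", "LynchLi", "LynchRd", "Ritland", "Wang")
ALL_ESTIMATORS = MOMENT_ESTIMATORS + ("DyadML",)


def allele_frequencies(genos: GenotypeMatrix) -> list[dict[int, float]]:
    """Per-locus allele frequencies from the full sample."""
    return [genos.allele_freqs(j) for j in range(genos.n_loci)]


# ---------------------------------------------------------------------------
# Per-locus preparation
# ---------------------------------------------------------------------------


def _hwe_prob(g: tuple[int, int], p: dict[int, float]) -> float:
    a, b = g
    return p[a] ** 2 if a == b else 2.0 * p[a] * p[b]


def _category(gx: tuple[int, int], gy: tuple[int, int]) -> int:
    """Dyad similarity category: 1 identical, 2 homozygote sharing one
    allele with a heterozygote, 3 heterozygotes sharing one allele,
    4 no allele in common."""
    sx, sy = set(gx), set(gy)
    if gx == gy or (sx == sy and len(sx) == 1):
        return 1
    shared = sx & sy
    if not shared:
        return 4
    if len(sx) == 1 or len(sy) == 1:
        return 2
    return 3


_CAT_SIMILARITY = {1: 1.0, 2: 0.75, 3: 0.5, 4: 0.0}


@dataclass
class _LocusPrep:
    p: dict[int, float]
    a2: float
    a3: float
    a4: float
    s0: float                       # E[similarity | unrelated]
    cat_probs: np.ndarray           # (3 modes k2/k1/k0, 4 categories)
    wang_weight: float


def _mode_pair_prob(gx, gy, p, mode: int) -> float:
    """P(unordered genotype pair | IBD mode) for the non-inbred modes:
    mode 2 = two IBD pairs, 1 = one IBD pair, 0 = none."""
    if mode == 0:
        return _hwe_prob(gx, p) * _hwe_prob(gy, p)
    if mode == 2:
        return _hwe_prob(gx, p) if tuple(sorted(gx)) == tuple(sorted(gy)) else 0.0
    # one IBD pair: a random gene of x is copied into y, the other y gene
    # is an independent draw
    a, b = gx
    c, d = gy
    total = 0.0
    for shared in (a, b):
        if c == d:
            contrib = p[c] if shared == c else 0.0
        else:
            contrib = (p[d] if shared == c else 0.0) + (p[c] if shared == d else 0.0)
        total += 0.5 * contrib
    return _hwe_prob(gx, p) * total


def _prep_locus(p: dict[int, float]) -> _LocusPrep:
    alleles = sorted(p)
    pv = np.array([p[a] for a in alleles])
    a2, a3, a4 = (float(np.sum(pv**m)) for m in (2, 3, 4))
    genotypes = [(x, y) for i, x in enumerate(alleles) for y in alleles[i:]]
    cat = np.zeros((3, 4))
    for gx in genotypes:
        px = _hwe_prob(gx, p)
        # mode 2: identical
        cat[0, _category(gx, gx) - 1] += px
        # mode 1
        for gy in genotypes:
            q = _mode_pair_prob(gx, gy, p, 1)
            if q:
                cat[1, _category(gx, gy) - 1] += q
            q0 = px * _hwe_prob(gy, p)
            cat[2, _category(gx, gy) - 1] += q0
    s0 = float(np.dot(cat[2], [1.0, 0.75, 0.5, 0.0]))
    u = 2 * a2 - a3
    return _LocusPrep(p, a2, a3, a4, s0, cat, 1.0 / u if u > 0 else 0.0)


from functools import lru_cache


@lru_cache(maxsize=4096)
def _prep_locus_cached(items: tuple) -> _LocusPrep:
    return _prep_locus(dict(items))


def _prep(freqs) -> list[_LocusPrep]:
    # the enumeration behind _prep_locus is quadratic in allele count, so
    # identical frequency tables (the common case in simulation studies)
    # are computed once
    return [_prep_locus_cached(tuple(sorted(f.items()))) for f in freqs]


def _usable(gx, gy, prep_l: _LocusPrep) -> bool:
    if gx[0] == MISSING or gy[0] == MISSING:
        return False
    return all(a in prep_l.p for a in (*gx, *gy))


# ---------------------------------------------------------------------------
# Moment estimators
# ---------------------------------------------------------------------------


def _qg_terms(gx, gy, p):
    a, b = gx
    c, d = gy
    sim = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
    num = sim - p[a] - p[b]
    den = 1.0 + (a == b) - p[a] - p[b]
    return num, den


def _lynchrd_terms(gx, gy, p):
    a, b = gx
    c, d = gy
    pa, pb = p[a], p[b]
    num = pa * ((b == c) + (b == d)) + pb * ((a == c) + (a == d)) - 4 * pa * pb
    den = (1.0 + (a == b)) * (pa + pb) - 4 * pa * pb
    return num, den


def _dosage(g, allele):
    return (g[0] == allele) + (g[1] == allele)


def relatedness_moment(gx: np.ndarray, gy: np.ndarray, freqs,
                       estimator: str, _prepped=None) -> float:
    """Moment relatedness estimate for one genotype pair.

    ``gx``/``gy`` are (n_loci, 2) allele arrays; multi-locus combination
    follows each estimator's published locus weighting (ratio of sums for
    QG and Lynch/Li, locus-information weights for Lynch-Ritland and
    Ritland, inverse-u weighted least squares for Wang).  Estimates are
    unbounded and may fall outside [0, 1].
    """
    prep = _prepped if _prepped is not None else _prep(freqs)
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    pairs = [(tuple(int(v) for v in gx[l]), tuple(int(v) for v in gy[l]), prep[l])
             for l in range(len(prep))]
    pairs = [(x, y, pl) for x, y, pl in pairs if _usable(x, y, pl)]
    if not pairs:
        return float("nan")

    if estimator == "QG":
        num = den = 0.0
        for x, y, pl in pairs:
            n1, d1 = _qg_terms(x, y, pl.p)
            n2, d2 = _qg_terms(y, x, pl.p)
            num += n1 + n2
            den += d1 + d2
        return num / den if den != 0 else float("nan")

    if estimator == "LynchLi":
        num = den = 0.0
        for x, y, pl in pairs:
            if pl.s0 >= 1.0:
                continue
            s = _CAT_SIMILARITY[_category(x, y)]
            num += s - pl.s0
            den += 1.0 - pl.s0
        return num / den if den != 0 else float("nan")

    if estimator == "LynchRd":
        out = []
        for ref in (0, 1):
            num = den = 0.0
            for x, y, pl in pairs:
                a, b = (x, y) if ref == 0 else (y, x)
                n1, d1 = _lynchrd_terms(a, b, pl.p)
                pa, pb = pl.p[a[0]], pl.p[a[1]]
                w = 2.0 * pa * pb
                if w <= 0 or d1 == 0:
                    continue
                num += n1 / w
                den += d1 / w
            if den != 0:
                out.append(num / den)
        return float(np.mean(out)) if out else float("nan")

    if estimator == "Ritland":
        num = den = 0.0
        for x, y, pl in pairs:
            k = len(pl.p)
            if k < 2:
                continue
            s = sum((_dosage(x, a) / 2) * (_dosage(y, a) / 2) / pa
                    for a, pa in pl.p.items() if pa > 0)
            num += s - 1.0
            den += (k - 1) / 2.0
        return num / den if den != 0 else float("nan")

    if estimator == "Wang":
        # weighted least squares of the one-hot category indicator on the
        # exact category probabilities under the three IBD modes
        AtA = np.zeros((2, 2))
        Atb = np.zeros(2)
        for x, y, pl in pairs:
            w = pl.wang_weight
            if w <= 0:
                continue
            e = np.zeros(4)
            e[_category(x, y) - 1] = 1.0
            m2, m1, m0 = pl.cat_probs
            X = np.stack([m2 - m0, m1 - m0], axis=1)  # (4, 2)
            AtA += w * X.T @ X
            Atb += w * X.T @ (e - m0)
        try:
            k2, k1 = np.linalg.solve(AtA, Atb)
        except np.linalg.LinAlgError:
            return float("nan")
        return float(k1 / 2.0 + k2)

    raise ValueError(f"unknown moment estimator {estimator!r}")


# ---------------------------------------------------------------------------
# Dyadic likelihood estimator
# ---------------------------------------------------------------------------


def _jacquard_pair_prob(gx, gy, p, mode: int) -> float:
    """P(pair | condensed Jacquard identity mode), modes 1..9."""
    a, b = gx
    c, d = gy
    hx = a == b
    hy = c == d
    if mode == 1:
        return p[a] if hx and hy and a == c else 0.0
    if mode == 2:
        return p[a] * p[c] if hx and hy else 0.0
    if mode == 3:  # x inbred, one of x's genes IBD into y
        if not hx:
            return 0.0
        if hy:
            return p[a] * p[c] if c == a else 0.0
        if a == c:
            return p[a] * p[d]
        if a == d:
            return p[a] * p[c]
        return 0.0
    if mode == 4:
        return p[a] * _hwe_prob(gy, p) if hx else 0.0
    if mode == 5:
        return _jacquard_pair_prob(gy, gx, p, 3)
    if mode == 6:
        return _jacquard_pair_prob(gy, gx, p, 4)
    if mode == 7:
        return _mode_pair_prob(gx, gy, p, 2)
    if mode == 8:
        return _mode_pair_prob(gx, gy, p, 1)
    if mode == 9:
        return _mode_pair_prob(gx, gy, p, 0)
    raise ValueError(mode)


#: r contribution of each Jacquard mode: r = 2*phi with kinship coefficient
#: phi = D1 + (D3 + D5 + D7)/2 + D8/4, i.e. r = 2*D1 + D3 + D5 + D7 + D8/2.
#: Reduces to r = k1/2 + k2 on the non-inbred modes (D7, D8, D9) and can
#: exceed 1 for inbred dyads.
_JACQUARD_R = np.array([2.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.5, 0.0])


def _em_mixture(C: np.ndarray, start: np.ndarray, tol: float = 1e-8,
                max_iter: int = 5000):
    """Maximize sum_l log(sum_m w_m C[l, m]) over the simplex by EM."""
    w = start.copy()
    ll_old = -np.inf
    for _ in range(max_iter):
        num = C * w[None, :]
        denom = num.sum(axis=1)
        if np.any(denom <= 0):
            return None, -np.inf, False
        ll = float(np.sum(np.log(denom)))
        w = (num / denom[:, None]).mean(axis=0)
        if abs(ll - ll_old) < tol:
            return w, ll, True
        ll_old = ll
    return w, ll_old, False


def relatedness_dyadml(gx: np.ndarray, gy: np.ndarray, freqs,
                       allow_inbreeding: bool = False, seed: int = 0,
                       _prepped=None):
    """Dyadic maximum-likelihood relatedness.

    The genotype-pair likelihood at each locus is a mixture over IBD modes
    — the three non-inbred modes (k2, k1, k0) or, with
    ``allow_inbreeding``, the nine condensed Jacquard modes — with shared
    mixture weights across loci.  The weights are maximized by EM
    (log-likelihood tolerance 1e-8; five seeded restarts on
    non-convergence) and ``r = k1/2 + k2`` (Jacquard:
    ``r = 2*D1 + D3 + D5 + D7 + D8/2``, twice the kinship coefficient).

    Returns ``(r, coefficients)``; ``r`` always lies in [0, 1].
    """
    prep = _prepped if _prepped is not None else _prep(freqs)
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    modes = list(range(1, 10)) if allow_inbreeding else [2, 1, 0]
    rows = []
    for l, pl in enumerate(prep):
        x = tuple(int(v) for v in gx[l])
        y = tuple(int(v) for v in gy[l])
        if not _usable(x, y, pl):
            continue
        if allow_inbreeding:
            rows.append([_jacquard_pair_prob(x, y, pl.p, m) for m in modes])
        else:
            rows.append([_mode_pair_prob(x, y, pl.p, m) for m in modes])
    if not rows:
        return float("nan"), None
    C = np.array(rows)
    nm = C.shape[1]
    starts = [np.full(nm, 1.0 / nm)]
    rng = np.random.default_rng(seed)
    w, ll, ok = _em_mixture(C, starts[0])
    if not ok:
        for _ in range(5):
            s = rng.dirichlet(np.ones(nm))
            w2, ll2, ok2 = _em_mixture(C, s)
            if ok2 and ll2 > ll:
                w, ll, ok = w2, ll2, ok2
        if not ok:
            return float("nan"), None
    if allow_inbreeding:
        r = float(np.dot(w, _JACQUARD_R))
        coeffs = {f"D{m}": float(v) for m, v in zip(modes, w)}
    else:
        k2, k1, k0 = w
        r = float(k1 / 2.0 + k2)
        coeffs = {"k0": float(k0), "k1": float(k1), "k2": float(k2)}
    return r, coeffs


# ---------------------------------------------------------------------------
# Relationship classification
# ---------------------------------------------------------------------------

#: classification order from least to most related; ties resolve leftward
_CLASS_ORDER = ("U", "HS", "FS", "PO")


def classify_relationship(gx: np.ndarray, gy: np.ndarray, freqs,
                          _prepped=None) -> tuple[str, dict[str, float]]:
    """Most likely of the four fixed pedigree categories.

    Each category's (k0, k1, k2) is held fixed and the multilocus
    log-likelihood compared; ties go to the less-related category
    (conservative).  Raises if every category has zero likelihood.
    """
    prep = _prepped if _prepped is not None else _prep(freqs)
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    logl = {lab: 0.0 for lab in _CLASS_ORDER}
    for l, pl in enumerate(prep):
        x = tuple(int(v) for v in gx[l])
        y = tuple(int(v) for v in gy[l])
        if not _usable(x, y, pl):
            continue
        probs = [_mode_pair_prob(x, y, pl.p, m) for m in (2, 1, 0)]
        for lab in _CLASS_ORDER:
            k0, k1, k2 = CATEGORIES[lab].k
            lik = k2 * probs[0] + k1 * probs[1] + k0 * probs[2]
            if lik <= 0.0:
                logl[lab] = -math.inf
            elif logl[lab] > -math.inf:
                logl[lab] += math.log(lik)
        if all(v == -math.inf for v in logl.values()):
            raise ValueError(
                f"zero likelihood under every category at locus index {l}"
                " (genotype impossible under the supplied frequencies)")
    best = max(_CLASS_ORDER, key=lambda lab: (logl[lab],
                                              -_CLASS_ORDER.index(lab)))
    return best, logl


# ---------------------------------------------------------------------------
# Tables and estimator evaluation
# ---------------------------------------------------------------------------


@dataclass
class RelatednessTable:
    """Long-format pairwise relatedness with per-estimator square matrices."""

    pairs: pd.DataFrame          # id1, id2, one column per estimator, category
    estimators: tuple[str, ...]

    def matrix(self, estimator: str, individuals: list[str]) -> pd.DataFrame:
        m = pd.DataFrame(np.nan, index=individuals, columns=individuals)
        for _, row in self.pairs.iterrows():
            m.loc[row["id1"], row["id2"]] = row[estimator]
            m.loc[row["id2"], row["id1"]] = row[estimator]
        return m

    def lookup(self, estimator: str) -> dict[frozenset, float]:
        return {frozenset((r["id1"], r["id2"])): r[estimator]
                for _, r in self.pairs.iterrows()}


def pairwise_relatedness(genos: GenotypeMatrix,
                         estimators=ALL_ESTIMATORS,
                         freqs=None, seed: int = 0) -> RelatednessTable:
    """All-pairs relatedness table over a genotype matrix.

    Frequencies default to the full dataset (including each focal pair);
    pass ``freqs`` to override, e.g. to exclude focal pairs.
    """
    if freqs is None:
        freqs = allele_frequencies(genos)
    prep = _prep(freqs)
    rows = []
    for i, j in itertools.combinations(range(genos.n_individuals), 2):
        gx, gy = genos.calls[i], genos.calls[j]
        row = {"id1": genos.individuals[i], "id2": genos.individuals[j]}
        for est in estimators:
            if est == "DyadML":
                row[est], _ = relatedness_dyadml(gx, gy, freqs, seed=seed,
                                                 _prepped=prep)
            else:
                row[est] = relatedness_moment(gx, gy, freqs, est, _prepped=prep)
        row["category"], _ = classify_relationship(gx, gy, freqs, _prepped=prep)
        rows.append(row)
    return RelatednessTable(pd.DataFrame(rows), tuple(estimators))


def evaluate_estimators(freqs, n_pairs: int = 5000,
                        categories=("U", "HS", "FS"), seed: int = 0,
                        estimators=ALL_ESTIMATORS) -> pd.DataFrame:
    """Score every estimator on pedigree-simulated pairs.

    For each relationship category, ``n_pairs`` genotype pairs are
    simulated by Mendelian pedigree construction and every estimator
    evaluated with the true generating frequencies.  Returns a tidy frame
    of means, sampling variances and the minimum-variance recommendation
    (smallest variance on the unrelated category, the COANCESTRY
    convention).
    """
    prep = _prep(freqs)
    rng = np.random.default_rng(seed)
    records = []
    per_cat_values: dict[tuple[str, str], np.ndarray] = {}
    for cat in categories:
        sims = sim_pedigree_pairs(freqs, cat, n_pairs,
                                  seed=int(rng.integers(2**31)))
        for est in estimators:
            vals = np.empty(n_pairs)
            for i in range(n_pairs):
                if est == "DyadML":
                    vals[i], _ = relatedness_dyadml(
                        sims.x[i], sims.y[i], freqs, _prepped=prep)
                else:
                    vals[i] = relatedness_moment(
                        sims.x[i], sims.y[i], freqs, est, _prepped=prep)
            vals = vals[~np.isnan(vals)]
            per_cat_values[(cat, est)] = vals
            records.append({
                "category": cat, "estimator": est,
                "n": vals.size,
                "mean": float(np.mean(vals)),
                "variance": float(np.var(vals, ddof=1)),
                "theoretical_r": CATEGORIES[cat].r,
            })
    out = pd.DataFrame(records)
    base_cat = "U" if "U" in categories else categories[0]
    sub = out[out["category"] == base_cat]
    best = sub.loc[sub["variance"].idxmin(), "estimator"]
    out.attrs["recommended"] = best
    return out
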