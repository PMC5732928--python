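"""Within-population nuclear diversity statistics and locus-level tests.

Per-locus summaries (A, rarefied allelic richness, Ho, Nei's unbiased He,
F_IS), an exact Hardy-Weinberg test estimated by Markov chain Monte Carlo
over genotype tables with fixed allele counts, a G-statistic permutation
test of two-locus linkage disequilibrium, and private-allele counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import MISSING, GenotypeMatrix, SampleMetadata


@dataclass
class LocusSummary:
    locus: str
    n: int            # genotyped individuals
    A: int            # alleles observed
    Ar: float         # allelic richness rarefied to g genes
    Ho: float
    He: float
    Fis: float        # NaN when He == 0


@dataclass
class HweResult:
    p: float
    se: float
    flag: str = ""    # "untestable" when the locus cannot reject


def _locus_calls(genos: GenotypeMatrix, locus: str | int) -> np.ndarray:
    j = locus if isinstance(locus, int) else genos.locus_index(locus)
    calls = genos.calls[:, j, :]
    return calls[calls[:, 0] != MISSING]


def allelic_richness(counts: Sequence[int], g: int) -> float:
    """Rarefied allele count: E[number of alleles in g genes drawn without
    replacement], computed as sum_i [1 - C(N - N_i, g) / C(N, g)]."""
    counts = np.asarray(counts, dtype=int)
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds sample of {N} genes")
    if g < 1:
        raise ValueError("g must be >= 1")
    logC_N_g = math.lgamma(N + 1) - math.lgamma(g + 1) - math.lgamma(N - g + 1)
    total = 0.0
    for Ni in counts:
        if N - Ni < g:
            total += 1.0
        else:
            logC = (math.lgamma(N - Ni + 1) - math.lgamma(g + 1)
                    - math.lgamma(N - Ni - g + 1))
            total += 1.0 - math.exp(logC - logC_N_g)
    return total


def locus_summary(genos: GenotypeMatrix, locus: str | int,
                  rarefaction_g: int | None = None) -> LocusSummary:
    """Summary statistics for one locus in one population sample.

    He is Nei's unbiased gene diversity ``(2n/(2n-1)) (1 - sum p_i^2)``,
    F_IS the per-locus ``1 - Ho/He`` (NaN at monomorphic loci), and Ar the
    rarefaction of the allele count to ``rarefaction_g`` genes (defaults to
    the full sample, where Ar equals A exactly).
    """
    name = locus if isinstance(locus, str) else genos.loci[locus]
    calls = _locus_calls(genos, locus)
    n = calls.shape[0]
    if n == 0:
        raise ValueError(f"locus {name!r}: no non-missing calls")
    alleles, counts = np.unique(calls.ravel(), return_counts=True)
    N = 2 * n
    p = counts / N
    g = N if rarefaction_g is None else rarefaction_g
    Ar = allelic_richness(counts, g)
    He = (N / (N - 1)) * (1.0 - float(np.sum(p**2))) if N > 1 else 0.0
    Ho = float(np.mean(calls[:, 0] != calls[:, 1]))
    Fis = 1.0 - Ho / He if He > 0 else float("nan")
    return LocusSummary(name, n, len(alleles), Ar, Ho, He, Fis)


def multilocus_fis(summaries: Sequence[LocusSummary]) -> float:
    """Multi-locus F_IS as the ratio of sums, sum(He - Ho) / sum(He)."""
    he = sum(s.He for s in summaries)
    if he == 0:
        return float("nan")
    return sum(s.He - s.Ho for s in summaries) / he


# ---------------------------------------------------------------------------
# Exact HWE test (MCMC over genotype tables)
# ---------------------------------------------------------------------------


def _table_logprob(counts: dict[tuple[int, int], int]) -> float:
    """Log of Levene's conditional table probability up to a constant:
    h*ln(2) - sum ln(n_ij!), h = number of heterozygotes."""
    lp = 0.0
    for (a, b), n in counts.items():
        if a != b:
            lp += n * math.log(2.0)
        lp -= math.lgamma(n + 1)
    return lp


def hwe_exact_mcmc(genos: GenotypeMatrix, locus: str | int,
                   dememorization: int = 1000, batches: int = 100,
                   iters_per_batch: int = 10000, seed: int = 0) -> HweResult:
    """Exact Hardy-Weinberg test, probability-test dialect.

    The chain swaps the contents of two random allele slots each step.
    Over ordered slot assignments the walk is uniform, and a genotype table
    T corresponds to ``n!/prod(n_ij!) * 2^h`` assignments, so the induced
    table distribution is exactly Levene's conditional distribution — no
    accept/reject step is needed.  The p-value is the chain fraction of
    tables whose conditional probability is <= the observed table's, and
    the Monte-Carlo standard error comes from batch means.
    """
    calls = _locus_calls(genos, locus)
    n = calls.shape[0]
    alleles = np.unique(calls.ravel())
    if len(alleles) < 2 or n < 3:
        return HweResult(1.0, 0.0, "untestable")
    rng = np.random.default_rng(seed)
    state = calls.copy()
    counts: dict[tuple[int, int], int] = {}
    for a, b in state:
        key = (int(a), int(b))
        counts[key] = counts.get(key, 0) + 1
    logp = _table_logprob(counts)
    logp_obs = logp
    tol = 1e-9

    def geno_key(a, b):
        return (int(a), int(b)) if a <= b else (int(b), int(a))

    def cell_delta(key, dn):
        """Full log-prob change (2^h and factorial terms) from adding dn
        to table cell `key`."""
        old = counts.get(key, 0)
        new = old + dn
        d = math.lgamma(old + 1) - math.lgamma(new + 1)
        if key[0] != key[1]:
            d += dn * math.log(2.0)
        counts[key] = new
        if new == 0:
            del counts[key]
        return d

    total_iters = dememorization + batches * iters_per_batch
    u_idx = rng.integers(0, n, size=total_iters)
    v_idx = rng.integers(0, n - 1, size=total_iters)
    pos = rng.integers(0, 2, size=(total_iters, 2))

    batch_hits = np.zeros(batches)
    for step in range(total_iters):
        u = u_idx[step]
        v = v_idx[step]
        if v >= u:
            v += 1
        pu, pv = pos[step]
        au, av = state[u, pu], state[v, pv]
        if au != av:
            old_u = geno_key(state[u, 0], state[u, 1])
            old_v = geno_key(state[v, 0], state[v, 1])
            new_u = geno_key(av, state[u, 1 - pu])
            new_v = geno_key(au, state[v, 1 - pv])
            logp += cell_delta(old_u, -1)
            logp += cell_delta(old_v, -1)
            logp += cell_delta(new_u, +1)
            logp += cell_delta(new_v, +1)
            state[u, pu], state[v, pv] = av, au
        if step >= dememorization:
            b = (step - dememorization) // iters_per_batch
            batch_hits[b] += logp <= logp_obs + tol
    batch_means = batch_hits / iters_per_batch
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return HweResult(p, se)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def _g_statistic(ga: np.ndarray, gb: np.ndarray) -> float:
    """G statistic of the two-locus genotype contingency table."""
    cats_a, ia = np.unique(ga, return_inverse=True, axis=0)
    cats_b, ib = np.unique(gb, return_inverse=True, axis=0)
    obs = np.zeros((len(cats_a), len(cats_b)))
    np.add.at(obs, (ia, ib), 1.0)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))


def ld_permutation_test(genos: GenotypeMatrix, locus_a: str | int,
                        locus_b: str | int, n_perm: int = 1000,
                        seed: int = 0) -> float:
    """Permutation test of genotypic association between two loci.

    The G statistic of the genotype x genotype contingency table is compared
    to its distribution under ``n_perm`` random permutations of one locus'
    genotypes among individuals; p uses the add-one rule with ties counted
    as >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ja = locus_a if isinstance(locus_a, int) else genos.locus_index(locus_a)
    jb = locus_b if isinstance(locus_b, int) else genos.locus_index(locus_b)
    ga_all, gb_all = genos.calls[:, ja, :], genos.calls[:, jb, :]
    keep = (ga_all[:, 0] != MISSING) & (gb_all[:, 0] != MISSING)
    ga, gb = ga_all[keep], gb_all[keep]
    if len(np.unique(ga, axis=0)) < 2 or len(np.unique(gb, axis=0)) < 2:
        return 1.0
    obs = _g_statistic(ga, gb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _g_statistic(ga, gb[rng.permutation(len(gb))]) >= obs - 1e-12
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------


def private_alleles(genos: GenotypeMatrix,
                    metadata: SampleMetadata) -> dict[str, int]:
    """Number of alleles observed in exactly one population, summed over
    loci, keyed by population."""
    pops = metadata.populations()
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    idx_of = {ind: i for i, ind in enumerate(genos.individuals)}
    members = {p: [idx_of[i] for i in metadata.members(p) if i in idx_of]
               for p in pops}
    result = {p: 0 for p in pops}
    for j in range(genos.n_loci):
        seen: dict[str, set[int]] = {}
        for p in pops:
            calls = genos.calls[members[p], j, :]
            calls = calls[calls[:, 0] != MISSING]
            seen[p] = set(np.unique(calls.ravel()).tolist()) if calls.size else set()
        for p in pops:
            others = set().union(*(seen[q] for q in pops if q != p))
            result[p] += len(seen[p] - others)
    return result
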