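"""Between-population differentiation.

Jost's D_EST on microsatellite allele frequencies (nearly unbiased
sample-size-corrected heterozygosity estimators, bootstrap significance
under pooled frequencies) and AMOVA phi_ST on haplotype alignments
(pairwise difference distances, permutation significance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (MISSING, GenotypeMatrix, HaplotypeAlignment,
                         SampleMetadata, holm_bonferroni)


@dataclass
class PairwiseMatrix:
    """Symmetric pairwise statistic matrix with p-values and adjusted
    (Holm-Bonferroni) reject decisions."""

    labels: list[str]
    values: pd.DataFrame
    pvalues: pd.DataFrame | None = None
    rejected: pd.DataFrame | None = None

    def adjust(self, alpha: float = 0.05) -> None:
        if self.pvalues is None:
            raise ValueError("no p-values to adjust")
        pairs = list(itertools.combinations(self.labels, 2))
        ps = [self.pvalues.loc[a, b] for a, b in pairs]
        dec = holm_bonferroni(ps, alpha)
        rej = pd.DataFrame(np.nan, index=self.labels, columns=self.labels,
                           dtype=object)
        for (a, b), d in zip(pairs, dec):
            rej.loc[a, b] = rej.loc[b, a] = bool(d)
        self.rejected = rej


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------


def _pop_freq_table(genos: GenotypeMatrix, metadata: SampleMetadata,
                    populations: list[str], locus: int):
    """Per-population allele frequencies and sample sizes at one locus."""
    idx_of = {ind: i for i, ind in enumerate(genos.individuals)}
    freqs, sizes = [], []
    for p in populations:
        rows = [idx_of[i] for i in metadata.members(p) if i in idx_of]
        calls = genos.calls[rows, locus, :]
        calls = calls[calls[:, 0] != MISSING]
        sizes.append(calls.shape[0])
        freqs.append(calls.ravel())
    return freqs, sizes


def _dest_locus(allele_lists: list[np.ndarray], sizes: list[int]) -> float:
    """Jost's D at one locus from per-population gene samples.

    Uses the nearly unbiased estimators: ``Hs = (2n~/(2n~-1)) (1 - mean_j
    sum_i p_ij^2)`` with ``n~`` the harmonic mean sample size, ``Ht = 1 -
    sum_i pbar_i^2 + Hs/(2 n~ k)``, and ``D = ((Ht-Hs)/(1-Hs)) * k/(k-1)``.
    """
    keep = [(a, n) for a, n in zip(allele_lists, sizes) if n > 0]
    k = len(keep)
    if k < 2:
        return float("nan")
    alleles = np.unique(np.concatenate([a for a, _ in keep]))
    P = np.zeros((k, alleles.size))
    for j, (a, _) in enumerate(keep):
        idx = np.searchsorted(alleles, a)
        np.add.at(P[j], idx, 1.0)
        P[j] /= a.size
    ns = np.array([n for _, n in keep], dtype=float)
    n_harm = k / np.sum(1.0 / ns)
    mean_sum_p2 = float(np.mean(np.sum(P**2, axis=1)))
    hs = (2 * n_harm / (2 * n_harm - 1)) * (1.0 - mean_sum_p2)
    pbar = P.mean(axis=0)
    ht = 1.0 - float(np.sum(pbar**2)) + hs / (2 * n_harm * k)
    if hs >= 1.0:
        return float("nan")
    return ((ht - hs) / (1.0 - hs)) * (k / (k - 1))


def jost_dest(genos: GenotypeMatrix, metadata: SampleMetadata,
              populations: list[str] | None = None,
              combine: str = "mean") -> tuple[dict[str, float], float]:
    """Per-locus and overall Jost's D across the given populations.

    The overall value combines loci by the arithmetic mean by default
    (``combine="harmonic"`` uses the harmonic mean of positive per-locus
    values instead).  Loci undefined in every population are skipped.
    """
    if populations is None:
        populations = metadata.populations()
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    per_locus: dict[str, float] = {}
    for j, name in enumerate(genos.loci):
        alleles, sizes = _pop_freq_table(genos, metadata, populations, j)
        d = _dest_locus(alleles, sizes)
        if not np.isnan(d):
            per_locus[name] = d
    if not per_locus:
        return per_locus, float("nan")
    vals = np.array(list(per_locus.values()))
    if combine == "mean":
        overall = float(np.mean(vals))
    elif combine == "harmonic":
        pos = vals[vals > 0]
        overall = float(len(pos) / np.sum(1.0 / pos)) if pos.size else 0.0
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    return per_locus, overall


def dest_significance(genos: GenotypeMatrix, metadata: SampleMetadata,
                      populations: list[str] | None = None,
                      n_bootstrap: int = 1000, seed: int = 0) -> float:
    """Bootstrap p-value for the overall D.

    The null resamples every population's genotypes from the pooled allele
    frequencies (random union of gametes), recomputes overall D each time,
    and applies the add-one rule.
    """
    if n_bootstrap < 99:
        raise ValueError("n_bootstrap must be >= 99")
    if populations is None:
        populations = metadata.populations()
    _, obs = jost_dest(genos, metadata, populations)
    if np.isnan(obs):
        return float("nan")
    rng = np.random.default_rng(seed)
    # pooled allele pools and per-pop gene sample sizes, per locus
    pooled, sizes_per_locus = [], []
    for j in range(genos.n_loci):
        alleles, sizes = _pop_freq_table(genos, metadata, populations, j)
        pooled.append(np.concatenate([a for a in alleles if a.size]))
        sizes_per_locus.append(sizes)
    hits = 0
    for _ in range(n_bootstrap):
        d_loci = []
        for j in range(genos.n_loci):
            pool = pooled[j]
            if pool.size == 0:
                continue
            samples = [rng.choice(pool, size=2 * n) if n else np.array([], dtype=int)
                       for n in sizes_per_locus[j]]
            d = _dest_locus(samples, sizes_per_locus[j])
            if not np.isnan(d):
                d_loci.append(d)
        if d_loci and np.mean(d_loci) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_bootstrap)


def pairwise_dest(genos: GenotypeMatrix, metadata: SampleMetadata,
                  n_bootstrap: int = 1000, seed: int = 0,
                  alpha: float = 0.05) -> PairwiseMatrix:
    pops = metadata.populations()
    vals = pd.DataFrame(np.nan, index=pops, columns=pops)
    ps = pd.DataFrame(np.nan, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(pops, 2):
        _, d = jost_dest(genos, metadata, [a, b])
        p = dest_significance(genos, metadata, [a, b], n_bootstrap,
                              seed=int(rng.integers(2**31)))
        vals.loc[a, b] = vals.loc[b, a] = d
        ps.loc[a, b] = ps.loc[b, a] = p
    out = PairwiseMatrix(pops, vals, ps)
    out.adjust(alpha)
    return out


# ---------------------------------------------------------------------------
# AMOVA phi_ST
# ---------------------------------------------------------------------------


def pairwise_difference_matrix(alignment: HaplotypeAlignment) -> np.ndarray:
    """Counts of nucleotide differences over usable (complete-deletion)
    sites, for all sequence pairs."""
    mat = alignment.site_matrix()
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1:] = np.sum(mat[i] != mat[i + 1:], axis=1)
    return d + d.T


def _phi_st(d: np.ndarray, groups: np.ndarray) -> float:
    """Two-level AMOVA phi_ST from a squared-distance matrix.

    Pairwise nucleotide-difference counts play the role of squared molecular
    distances; SSD(total) and SSD(within) give variance components sigma2_a
    (among) and sigma2_b (within), phi_ST = sigma2_a / (sigma2_a + sigma2_b).
    Negative values are reported as computed.
    """
    n = d.shape[0]
    labels = np.unique(groups)
    k = labels.size
    ssd_total = d[np.triu_indices(n, 1)].sum() / n
    ssd_within = 0.0
    sizes = []
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sizes.append(idx.size)
        if idx.size > 1:
            sub = d[np.ix_(idx, idx)]
            ssd_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    sizes = np.array(sizes, dtype=float)
    df_a = k - 1
    df_b = n - k
    if df_b <= 0:
        return float("nan")
    sigma_b = ssd_within / df_b
    n_eff = (n - np.sum(sizes**2) / n) / df_a
    sigma_a = ((ssd_total - ssd_within) / df_a - sigma_b) / n_eff
    denom = sigma_a + sigma_b
    if denom == 0:
        return float("nan")
    return float(sigma_a / denom)


def amova_phist(alignment: HaplotypeAlignment, metadata: SampleMetadata,
                populations: list[str] | None = None, n_perm: int = 10000,
                seed: int = 0) -> tuple[float, float]:
    """Global AMOVA phi_ST with permutation p-value.

    Significance permutes individuals among populations (sizes kept fixed),
    with the add-one rule; ``n_perm`` defaults to 10,000.
    """
    if populations is None:
        populations = metadata.populations()
    ids = [i for i in alignment.sequences if metadata.site.get(i) in populations]
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences across the populations")
    sub = alignment.subset(ids)
    d = pairwise_difference_matrix(sub)
    groups = np.array([metadata.site[i] for i in ids])
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 populations with sequences")
    obs = _phi_st(d, groups)
    if np.isnan(obs):
        return obs, float("nan")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = _phi_st(d, groups[rng.permutation(len(groups))])
        hits += perm >= obs - 1e-12
    return obs, (1 + hits) / (1 + n_perm)


def pairwise_phist(alignment: HaplotypeAlignment, metadata: SampleMetadata,
                   n_perm: int = 10000, seed: int = 0,
                   alpha: float = 0.05) -> PairwiseMatrix:
    pops = [p for p in metadata.populations()
            if any(metadata.site.get(i) == p for i in alignment.sequences)]
    vals = pd.DataFrame(np.nan, index=pops, columns=pops)
    ps = pd.DataFrame(np.nan, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(pops, 2):
        try:
            phi, p = amova_phist(alignment, metadata, [a, b], n_perm,
                                 seed=int(rng.integers(2**31)))
        except ValueError:
            phi, p = float("nan"), float("nan")
        vals.loc[a, b] = vals.loc[b, a] = phi
        ps.loc[a, b] = ps.loc[b, a] = p
    out = PairwiseMatrix(pops, vals, ps)
    if ps.notna().to_numpy().any():
        pairs = [(a, b) for a, b in itertools.combinations(pops, 2)
                 if not np.isnan(ps.loc[a, b])]
        dec = holm_bonferroni([ps.loc[a, b] for a, b in pairs], alpha)
        rej = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=object)
        for (a, b), dcs in zip(pairs, dec):
            rej.loc[a, b] = rej.loc[b, a] = bool(dcs)
        out.rejected = rej
    return out
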