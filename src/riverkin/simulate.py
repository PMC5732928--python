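"""Synthetic genotype and sequence generators.

Everything downstream of the raw study data is exercised against data drawn
from these generators: neutral-coalescent microsatellite populations under
the infinite-alleles (IAM), stepwise (SMM) and two-phase (TPM) mutation
models, recently bottlenecked populations, isolated demes diverging by pure
drift, coalescent mtDNA control-region alignments with a transition bias,
and genotype pairs built from explicit pedigrees (unrelated, half-sib,
full-sib, parent-offspring) with hidden identity-by-descent labels.

Time is measured in units of ``2N`` generations, so a branch of length ``t``
accumulates mutations at rate ``theta/2`` per unit with ``theta = 4*N*mu``.
All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import GenotypeMatrix, HaplotypeAlignment, SampleMetadata

# Root allele for stepwise ladders; keeps 3-digit GenePop encodable.
SMM_ROOT = 100

TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class MutationModel:
    """Microsatellite mutation model.

    ``TPM`` realizes each mutation as a single ±1 step with probability
    ``p_single`` (default 0.70) and otherwise as a brand-new allele
    (IAM-type jump); this per-mutation mixture is the ``tpm_variant``
    "mixture" dialect — a geometric multi-step variant is not implemented.
    """

    kind: str = "IAM"
    p_single: float = 0.70
    tpm_variant: str = "mixture"

    def __post_init__(self) -> None:
        if self.kind not in {"IAM", "SMM", "TPM"}:
            raise ValueError(f"unknown mutation model {self.kind!r}")
        if not 0.0 <= self.p_single <= 1.0:
            raise ValueError("p_single must lie in [0, 1]")


IAM = MutationModel("IAM")
SMM = MutationModel("SMM")
TPM = MutationModel("TPM")


@dataclass(frozen=True)
class PedigreeCategory:
    """Relationship category with its Cotterman k-coefficients."""

    label: str
    k: tuple[float, float, float]  # (k0, k1, k2)

    @property
    def r(self) -> float:
        return self.k[1] / 2 + self.k[2]


UNRELATED = PedigreeCategory("U", (1.0, 0.0, 0.0))
HALF_SIB = PedigreeCategory("HS", (0.5, 0.5, 0.0))
FULL_SIB = PedigreeCategory("FS", (0.25, 0.5, 0.25))
PARENT_OFFSPRING = PedigreeCategory("PO", (0.0, 1.0, 0.0))
CATEGORIES = {c.label: c for c in (UNRELATED, HALF_SIB, FULL_SIB, PARENT_OFFSPRING)}


# ---------------------------------------------------------------------------
# Coalescent genealogy
# ---------------------------------------------------------------------------


def _genealogy(n: int, rng: np.random.Generator):
    """Kingman coalescent for ``n`` genes.

    Returns ``(parent, blen, order)``: parent index per node (-1 at the
    root), branch length to the parent, and node indices sorted root-first
    (so children always follow their parent).  Tips are nodes ``0..n-1``.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        for x in sorted((i, j), reverse=True):
            active.pop(x)
        active.append(nxt)
        nxt += 1
    blen = np.zeros(n_nodes)
    has_parent = parent >= 0
    blen[has_parent] = time[parent[has_parent]] - time[has_parent]
    order = np.argsort(time)[::-1]  # root first
    return parent, blen, order


def _sim_locus(n_genes: int, theta: float, model: MutationModel,
               rng: np.random.Generator) -> np.ndarray:
    """Allele states of ``n_genes`` sampled genes at one neutral locus.

    Mutations on a branch are realized in aggregate: under SMM the net
    displacement of m steps is ``2*Binomial(m, 1/2) - m``; under IAM only
    the most recent mutation matters; under TPM the branch state is a
    fresh allele plus the net displacement of the single-step mutations
    that follow the last jump (trailing-run length is truncated
    geometric).  This is distributionally identical to realizing each
    mutation one at a time.
    """
    if n_genes == 1:
        return np.array([SMM_ROOT])
    parent, blen, order = _genealogy(n_genes, rng)
    n_mut = rng.poisson(theta / 2 * blen)
    state = np.empty(parent.size, dtype=np.int64)
    state[order[0]] = SMM_ROOT
    next_new = SMM_ROOT  # running max for IAM-type novel alleles

    def net_step(m: int) -> int:
        return int(2 * rng.binomial(m, 0.5) - m) if m else 0

    for node in order[1:]:
        s = int(state[parent[node]])
        m = int(n_mut[node])
        if m:
            if model.kind == "SMM":
                s += net_step(m)
            elif model.kind == "IAM":
                next_new += 10
                s = next_new
            else:  # TPM: scan the i.i.d. mutation sequence from the end
                p = model.p_single
                t = 0
                while t < m and rng.random() < p:
                    t += 1
                if t == m:          # every mutation was a single step
                    s += net_step(m)
                else:               # jump at position m-t, then t steps
                    next_new += 10
                    s = next_new + net_step(t)
            if s < 1:
                s = 1  # allele codes stay positive; reflecting floor
        state[node] = s
    return state[:n_genes]


def ewens_expected_alleles(theta: float, n_genes: int) -> float:
    """Ewens sampling formula expectation E[K] = sum theta/(theta+i)."""
    i = np.arange(n_genes)
    return float(np.sum(theta / (theta + i)))


def watterson_theta_for_s(target_s: float, n: int) -> float:
    """theta such that Watterson's E[S] = theta * sum_{i=1}^{n-1} 1/i hits target."""
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(target_s / a1)


# ---------------------------------------------------------------------------
# Population generators
# ---------------------------------------------------------------------------


def _genes_to_matrix(genes: np.ndarray, n_individuals: int, n_loci: int,
                     prefix: str = "ind") -> GenotypeMatrix:
    calls = genes.reshape(n_loci, n_individuals, 2).transpose(1, 0, 2)
    ids = [f"{prefix}{i + 1}" for i in range(n_individuals)]
    loci = [f"locus{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(ids, loci, calls)


def sim_population_equilibrium(n_individuals: int, n_loci: int, theta: float,
                               model: MutationModel = IAM, seed: int = 0,
                               prefix: str = "ind") -> GenotypeMatrix:
    """Mutation-drift-equilibrium population: independent neutral coalescents
    per locus, mutations realized under ``model``."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed)
    n_genes = 2 * n_individuals
    genes = np.stack([_sim_locus(n_genes, theta, model, rng)
                      for _ in range(n_loci)])
    return _genes_to_matrix(genes, n_individuals, n_loci, prefix)


def _forward_wf(pool: np.ndarray, size: int, generations: int,
                rng: np.random.Generator) -> np.ndarray:
    """Forward Wright-Fisher drift of a (n_loci, N, 2) diploid gene pool
    to ``size`` diploids for ``generations`` generations (no mutation)."""
    n_loci = pool.shape[0]
    for _ in range(generations):
        n_parents = pool.shape[1]
        parents = rng.integers(0, n_parents, size=(n_loci, size, 2))
        which = rng.integers(0, 2, size=(n_loci, size, 2))
        li = np.arange(n_loci)[:, None, None]
        pool = pool[li, parents, which]
    return pool


def sim_bottleneck(n_individuals: int, n_loci: int, theta: float,
                   model: MutationModel = IAM, crash_factor: float = 0.1,
                   generations_since: int = 5, seed: int = 0,
                   n_base: int = 200, prefix: str = "ind") -> GenotypeMatrix:
    """Recently bottlenecked population.

    An equilibrium population of ``n_base`` diploids is simulated by
    coalescent, crashed to ``round(n_base * crash_factor)`` diploids, drifted
    forward (Wright-Fisher, mutation-free — the crash phase spans few
    generations) for ``generations_since`` generations, and ``n_individuals``
    are sampled from the final generation.
    """
    if not 0 < crash_factor <= 1:
        raise ValueError("crash_factor must lie in (0, 1]")
    if generations_since < 1:
        raise ValueError("generations_since must be >= 1")
    n_crash = int(round(n_base * crash_factor))
    if n_crash < 2:
        raise ValueError(f"reduced size {n_crash} < 2; raise crash_factor or n_base")
    rng = np.random.default_rng(seed)
    genes = np.stack([_sim_locus(2 * n_base, theta, model, rng)
                      for _ in range(n_loci)])
    pool = genes.reshape(n_loci, n_base, 2)
    if crash_factor < 1:
        pool = _forward_wf(pool, n_crash, generations_since, rng)
    take = rng.choice(pool.shape[1], size=n_individuals,
                      replace=pool.shape[1] < n_individuals)
    sample = pool[:, take, :]
    return _genes_to_matrix(sample.reshape(n_loci, -1), n_individuals, n_loci, prefix)


def sim_structured_pops(n_pops: int, n_per_pop: int, divergence: float,
                        theta: float, model: MutationModel = IAM,
                        seed: int = 0, n_loci: int = 20, deme_size: int = 50
                        ) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Isolated demes diverging from a common ancestral pool by pure drift.

    An ancestral equilibrium sample of ``2 * deme_size * n_pops`` genes per
    locus is partitioned into ``n_pops`` founding pools; each pool then
    drifts independently (Wright-Fisher, mutation-free) for
    ``round(divergence * 2 * deme_size)`` generations — ``divergence`` is
    drift time in units of ``2N`` with ``N = deme_size`` diploids — before
    ``n_per_pop`` individuals are sampled from each deme.
    """
    if n_pops < 2:
        raise ValueError("need at least 2 demes")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if n_per_pop > deme_size:
        raise ValueError("n_per_pop cannot exceed deme_size")
    rng = np.random.default_rng(seed)
    t_gens = int(round(divergence * 2 * deme_size))
    n_anc = 2 * deme_size * n_pops
    anc = np.stack([_sim_locus(n_anc, theta, model, rng)
                    for _ in range(n_loci)])  # (n_loci, n_anc)
    perm = rng.permutation(n_anc)
    anc = anc[:, perm]
    pools = anc.reshape(n_loci, n_pops, deme_size, 2)
    blocks, ids, site = [], [], {}
    for d in range(n_pops):
        pool = pools[:, d]
        if t_gens > 0:
            pool = _forward_wf(pool, deme_size, t_gens, rng)
        take = rng.choice(deme_size, size=n_per_pop, replace=False)
        blocks.append(pool[:, take, :])
        for i in range(n_per_pop):
            ind = f"deme{d + 1}_ind{i + 1}"
            ids.append(ind)
            site[ind] = f"deme{d + 1}"
    genes = np.concatenate(blocks, axis=1)  # (n_loci, n_total, 2)
    calls = genes.transpose(1, 0, 2)
    loci = [f"locus{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(ids, loci, calls), SampleMetadata(site)


def sim_mtdna(n_sequences: int, length: int = 791, theta: float | None = None,
              ts_bias: float = 34 / 7, seed: int = 0,
              base_freqs: Sequence[float] = (0.3414, 0.1966, 0.2098, 0.2523),
              prefix: str = "seq") -> HaplotypeAlignment:
    """Coalescent mtDNA alignment with finite-sites mutation and ts bias.

    Defaults emulate a ~791 bp control-region fragment: ``theta`` defaults to
    the Watterson value giving E[S] ~= 38 at n = 70, each mutation is a
    transition with probability ``ts_bias / (ts_bias + 1)`` (default 34:7),
    and the root composition follows the empirical A/C/G/T fractions.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if ts_bias < 0:
        raise ValueError("ts_bias must be >= 0")
    if theta is None:
        theta = watterson_theta_for_s(38.0, max(n_sequences, 2))
    rng = np.random.default_rng(seed)
    p = np.asarray(base_freqs, dtype=float)
    p = p / p.sum()
    root = rng.choice(4, size=length, p=p)
    seqs_idx = np.tile(root, (n_sequences, 1))
    if n_sequences > 1 and theta > 0:
        parent, blen, order = _genealogy(n_sequences, rng)
        n_mut = rng.poisson(theta / 2 * blen)
        ts_p = ts_bias / (ts_bias + 1.0) if ts_bias > 0 else 0.0
        node_seq = {order[0]: root.copy()}
        # map base index: A0 C1 G2 T3; transitions A<->G (0,2), C<->T (1,3)
        ts_map = np.array([2, 3, 0, 1])
        tv_map = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
        for node in order[1:]:
            s = node_seq[parent[node]].copy()
            for _ in range(n_mut[node]):
                site = rng.integers(length)
                b = s[site]
                if rng.random() < ts_p:
                    s[site] = ts_map[b]
                else:
                    s[site] = tv_map[b][rng.integers(2)]
            node_seq[node] = s
            if node < n_sequences:
                seqs_idx[node] = s
    seqs = {f"{prefix}{i + 1}": "".join(BASES[seqs_idx[i]])
            for i in range(n_sequences)}
    return HaplotypeAlignment(seqs)


# ---------------------------------------------------------------------------
# Pedigree pairs with IBD bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class PedigreePairs:
    """Simulated genotype pairs from an explicit pedigree.

    ``x``/``y`` are allele arrays of shape (n_pairs, n_loci, 2); ``x_ibd``/
    ``y_ibd`` carry hidden founder-gene labels of the same shape, so realized
    identity-by-descent states are observable: at a locus, the number of
    label matches between the pair's genes defines the realized k-state.
    """

    category: PedigreeCategory
    x: np.ndarray
    y: np.ndarray
    x_ibd: np.ndarray
    y_ibd: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.x.shape[0]

    @property
    def n_loci(self) -> int:
        return self.x.shape[1]

    def realized_k(self) -> np.ndarray:
        """Per pair x locus: number of IBD allele pairs (0, 1 or 2)."""
        a, b = self.x_ibd[..., 0], self.x_ibd[..., 1]
        c, d = self.y_ibd[..., 0], self.y_ibd[..., 1]
        # maximum matching between {a,b} and {c,d} on labels
        m_ac, m_ad = a == c, a == d
        m_bc, m_bd = b == c, b == d
        two = (m_ac & m_bd) | (m_ad & m_bc)
        one = m_ac | m_ad | m_bc | m_bd
        return np.where(two, 2, np.where(one, 1, 0))


def _freq_arrays(freqs: Sequence[dict[int, float]]):
    alleles, probs = [], []
    for i, f in enumerate(freqs):
        a = np.array(sorted(f))
        p = np.array([f[k] for k in a], dtype=float)
        if a.size == 0 or np.any(p < 0):
            raise ValueError(f"locus {i}: invalid frequency table")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"locus {i}: frequencies sum to {p.sum():.6f}, not 1")
        alleles.append(a)
        probs.append(p / p.sum())
    return alleles, probs


def sim_pedigree_pairs(freqs: Sequence[dict[int, float]],
                       category: PedigreeCategory | str,
                       n_pairs: int, seed: int = 0) -> PedigreePairs:
    """Generate genotype pairs by explicit parental construction.

    Founders are drawn gene-by-gene from ``freqs`` (one allele-frequency
    table per locus) and offspring are produced by Mendelian segregation:
    full sibs share both parents, half sibs one, parent-offspring pairs are
    a founder and its child, unrelated pairs are independent draws.  Founder
    genes carry unique labels so realized IBD states are observable.
    """
    if isinstance(category, str):
        category = CATEGORIES[category.upper()]
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    alleles, probs = _freq_arrays(freqs)
    n_loci = len(alleles)
    if all(a.size == 1 for a in alleles):
        import warnings
        warnings.warn("all loci monomorphic: pairs are uninformative")
    rng = np.random.default_rng(seed)

    def founders(k):
        """k founders: (alleles, labels) arrays of shape (k, n_loci, 2)."""
        g = np.empty((k, n_loci, 2), dtype=np.int64)
        for j in range(n_loci):
            idx = rng.choice(alleles[j].size, size=(k, 2), p=probs[j])
            g[:, j, :] = alleles[j][idx]
        lab = np.arange(k * n_loci * 2).reshape(k, n_loci, 2)
        return g, lab

    def child(pa, pa_lab, ma, ma_lab):
        """Mendelian offspring of two (n_pairs, n_loci, 2) parents."""
        pick_p = rng.integers(0, 2, size=pa.shape[:2])
        pick_m = rng.integers(0, 2, size=ma.shape[:2])
        ii = np.arange(pa.shape[0])[:, None]
        jj = np.arange(pa.shape[1])[None, :]
        g = np.stack([pa[ii, jj, pick_p], ma[ii, jj, pick_m]], axis=2)
        lab = np.stack([pa_lab[ii, jj, pick_p], ma_lab[ii, jj, pick_m]], axis=2)
        return g, lab

    def batch_founders(k):
        """k independent founders per pair: shape (k, n_pairs, n_loci, 2)."""
        g, lab = founders(k * n_pairs)
        return (g.reshape(k, n_pairs, n_loci, 2),
                lab.reshape(k, n_pairs, n_loci, 2))

    lab = category.label
    if lab == "U":
        g, labels = batch_founders(2)
        x, xl, y, yl = g[0], labels[0], g[1], labels[1]
    elif lab == "PO":
        g, labels = batch_founders(2)
        x, xl = g[0], labels[0]
        y, yl = child(g[0], labels[0], g[1], labels[1])
    elif lab == "FS":
        g, labels = batch_founders(2)
        x, xl = child(g[0], labels[0], g[1], labels[1])
        y, yl = child(g[0], labels[0], g[1], labels[1])
    elif lab == "HS":
        g, labels = batch_founders(3)
        x, xl = child(g[0], labels[0], g[1], labels[1])
        y, yl = child(g[0], labels[0], g[2], labels[2])
    else:  # pragma: no cover
        raise ValueError(f"unknown category {lab!r}")
    return PedigreePairs(category, x, y, xl, yl)
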