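"""Mitochondrial sequence statistics, neutrality tests and networks.

Haplotype and nucleotide diversity with their standard errors, Fu's Fs from
the Ewens sampling distribution, the Ramos-Onsins & Rozas R2 statistic,
coalescent significance for both (fixed-S conditioning), and Bandelt-style
median-joining haplotype networks.

All computations use the alignment's usable sites (complete deletion of
columns carrying a gap or N in any sequence).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np

from .data_model import HaplotypeAlignment
from .simulate import _genealogy


def _log_int(x: int) -> float:
    """Natural log of a (possibly huge) positive integer."""
    if x <= 0:
        raise ValueError("log of non-positive integer")
    b = x.bit_length() - 53
    if b <= 0:
        return math.log(x)
    return math.log(x >> b) + b * math.log(2.0)


@lru_cache(maxsize=32)
def _log_stirling_first(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n (unsigned Stirling, first kind)."""
    row = [1]  # |s(0, 0)| = 1
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            prev = row[k] if k < len(row) else 0
            new[k] = (m - 1) * prev + row[k - 1]
        row = new
    return tuple(-math.inf if v == 0 else _log_int(v) for v in row)


def ewens_k_tail(n: int, k_obs: int, theta: float) -> float:
    """Pr(K >= k_obs) for the number of alleles in an Ewens sample of n
    genes at scaled mutation rate theta."""
    if theta <= 0:
        return 0.0 if k_obs > 1 else 1.0
    logs = _log_stirling_first(n)
    log_theta = math.log(theta)
    log_rising = sum(math.log(theta + i) for i in range(n))
    terms = [logs[k] + k * log_theta - log_rising for k in range(1, n + 1)]
    m = max(terms)
    total = sum(math.exp(t - m) for t in terms)
    tail = sum(math.exp(t - m) for t in terms[k_obs - 1:])
    return tail / total


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class MtdnaSummary:
    n: int
    usable_sites: int
    S: int
    h: int
    Hd: float
    Hd_sd: float
    pi: float                 # per site
    pi_sd: float
    base_composition: dict[str, float]
    transitions: int
    transversions: int
    mean_pairwise_diff: float


def _pairwise_stats(alignment: HaplotypeAlignment) -> tuple[float, np.ndarray]:
    """(mean pairwise differences, per-sequence singleton counts U_i)."""
    mat = alignment.site_matrix()
    n = mat.shape[0]
    k_sum = 0.0
    U = np.zeros(n)
    for col in mat.T:
        states, counts = np.unique(col, return_counts=True)
        # pairwise differences contributed by this site
        k_sum += (n * (n - 1) - np.sum(counts * (counts - 1))) / 2
        for st, c in zip(states, counts):
            if c == 1:
                U[np.flatnonzero(col == st)[0]] += 1
    k_mean = k_sum / (n * (n - 1) / 2) if n > 1 else 0.0
    return k_mean, U


def mtdna_summary(alignment: HaplotypeAlignment) -> MtdnaSummary:
    """Haplotype and nucleotide diversity with standard Nei-style SDs.

    ``Hd = (n/(n-1)) (1 - sum f_i^2)`` with its sampling variance; ``pi`` is
    the mean pairwise difference per usable site with the standard total
    (stochastic + sampling) variance.  A single sequence yields NaNs.
    """
    n = alignment.n_sequences
    mat = alignment.site_matrix()
    L = alignment.usable_sites.size
    comp_counts = {b: 0 for b in "ACGT"}
    for s in alignment.sequences.values():
        for b in "ACGT":
            comp_counts[b] += s.count(b)
    total = sum(comp_counts.values())
    comp = {b: c / total if total else float("nan") for b, c in comp_counts.items()}
    ts, tv = alignment.mutation_counts()
    if n < 2:
        nan = float("nan")
        return MtdnaSummary(n, L, 0, alignment.n_haplotypes, nan, nan, nan,
                            nan, comp, ts, tv, nan)
    f = alignment.haplotype_frequencies() / n
    sum2, sum3 = float(np.sum(f**2)), float(np.sum(f**3))
    hd = (n / (n - 1)) * (1.0 - sum2)
    var_hd = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    k_mean, _ = _pairwise_stats(alignment)
    pi = k_mean / L if L else 0.0
    # total variance of pi per site (coalescent stochastic + sampling)
    var_pi = ((n + 1) / (3.0 * (n - 1))) * (pi / L if L else 0.0) \
        + (2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))) * pi**2
    return MtdnaSummary(n, L, alignment.n_segregating_sites,
                        alignment.n_haplotypes, hd, math.sqrt(max(var_hd, 0.0)),
                        pi, math.sqrt(max(var_pi, 0.0)), comp, ts, tv, k_mean)


# ---------------------------------------------------------------------------
# Neutrality statistics
# ---------------------------------------------------------------------------


def fu_fs(alignment: HaplotypeAlignment) -> float:
    """Fu's Fs.

    With theta estimated by the mean number of pairwise differences, S' is
    the Ewens probability of observing at least the sampled number of
    haplotypes; Fs = ln(S'/(1-S')).  A haplotype excess (many haplotypes
    for the observed theta) drives Fs negative.
    """
    n = alignment.n_sequences
    k_obs = alignment.n_haplotypes
    if n < 2 or alignment.n_segregating_sites < 1 or k_obs == 1:
        return float("nan")
    theta, _ = _pairwise_stats(alignment)
    return _fs_from(n, k_obs, theta)


def _fs_from(n: int, k_obs: int, theta: float) -> float:
    sp = ewens_k_tail(n, k_obs, theta)
    if sp <= 0.0 or sp >= 1.0:
        return float("nan")
    return math.log(sp / (1.0 - sp))


def r2_statistic(alignment: HaplotypeAlignment) -> float:
    """Ramos-Onsins & Rozas R2.

    ``R2 = sqrt(mean_i (U_i - k/2)^2) / S`` where U_i counts the singleton
    mutations carried by sequence i (minor-state count 1, outgroup-free)
    and k is the mean pairwise difference.  Small under star-like
    genealogies (recent growth).
    """
    S = alignment.n_segregating_sites
    if S < 1:
        return float("nan")
    n = alignment.n_sequences
    k_mean, U = _pairwise_stats(alignment)
    return float(math.sqrt(np.mean((U - k_mean / 2.0) ** 2)) / S)


def _r2_from(n: int, S: int, k_mean: float, U: np.ndarray) -> float:
    return float(math.sqrt(np.mean((U - k_mean / 2.0) ** 2)) / S)


def _simulate_fixed_s(n: int, S: int, rng: np.random.Generator):
    """One constant-size coalescent replicate with exactly S mutations
    placed multinomially on branches (infinite sites).

    Returns (haplotype count, mean pairwise differences, singleton counts).
    """
    parent, blen, order = _genealogy(n, rng)
    probs = blen / blen.sum()
    muts = rng.multinomial(S, probs)
    # tip sets per node, children processed before parents
    n_nodes = parent.size
    below = np.zeros((n_nodes, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for node in order[::-1][:-1]:  # tips/internal upward, skip root
        below[parent[node]] |= below[node]
    # site patterns
    cols = []
    for node in range(n_nodes):
        for _ in range(muts[node]):
            cols.append(below[node])
    M = np.array(cols, dtype=bool).T if cols else np.zeros((n, 0), dtype=bool)
    c = M.sum(axis=0)
    k_mean = float(np.sum(2 * c * (n - c)) / (n * (n - 1)))
    # haplotypes: unique rows
    if M.shape[1]:
        packed = np.packbits(M, axis=1)
        k_hap = np.unique(packed, axis=0).shape[0]
    else:
        k_hap = 1
    U = np.zeros(n)
    for j in range(M.shape[1]):
        col = M[:, j]
        cc = int(col.sum())
        if cc == 1:
            U[np.argmax(col)] += 1
        elif cc == n - 1:
            U[np.argmin(col)] += 1
    return k_hap, k_mean, U


def neutrality_pvalues(fs_obs: float, r2_obs: float, n: int, S: int,
                       n_sims: int = 10000, seed: int = 0
                       ) -> dict[str, float]:
    """Coalescent p-values for Fs and R2 under fixed-S conditioning.

    Constant-size coalescent samples of ``n`` sequences with exactly ``S``
    segregating sites; ``p = Pr(sim <= obs)`` for both statistics (both are
    small/negative under demographic expansion).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    fs_hits = r2_hits = fs_n = r2_n = 0
    for _ in range(n_sims):
        k_hap, k_mean, U = _simulate_fixed_s(n, S, rng)
        if not math.isnan(fs_obs):
            sim_fs = _fs_from(n, k_hap, k_mean)
            if not math.isnan(sim_fs):
                fs_n += 1
                fs_hits += sim_fs <= fs_obs
        if not math.isnan(r2_obs):
            sim_r2 = _r2_from(n, S, k_mean, U)
            r2_n += 1
            r2_hits += sim_r2 <= r2_obs
    return {
        "p_fs": fs_hits / fs_n if fs_n else float("nan"),
        "p_r2": r2_hits / r2_n if r2_n else float("nan"),
    }


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------


def _hamming(a: tuple, b: tuple) -> int:
    return sum(x != y for x, y in zip(a, b))


def _spanning_network(nodes: list[tuple], epsilon: int = 0) -> set[tuple[int, int]]:
    """epsilon-relaxed minimum spanning network (union of all MSTs at
    epsilon = 0) by grouped-level Kruskal; returns index edges."""
    n = len(nodes)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = _hamming(nodes[i], nodes[j])
    comp = list(range(n))

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    edges: set[tuple[int, int]] = set()
    levels = sorted(set(dist.values()))
    for d in levels:
        # components as frozen at this level (epsilon widens the window)
        candidates = [e for e, w in dist.items() if d <= w <= d + epsilon]
        joinable = [(i, j) for i, j in candidates if find(i) != find(j)]
        for i, j in joinable:
            edges.add((i, j))
        for i, j in joinable:
            ri, rj = find(i), find(j)
            if ri != rj:
                comp[ri] = rj
        if len({find(i) for i in range(n)}) == 1 and epsilon == 0:
            break
    return edges


def median_joining_network(alignment: HaplotypeAlignment,
                           epsilon: int = 0) -> nx.Graph:
    """Median-joining haplotype network (Bandelt et al. construction).

    Iterates: build the epsilon-relaxed minimum spanning network over the
    current node set; for every connected triplet, form the per-site
    majority (median) vector and add it when novel and strictly cheaper to
    connect the triplet through than the triplet's own spanning tree;
    repeat until no new medians appear.  Obsolete medians (unsampled,
    degree <= 2, not on any shortest connection between their neighbors)
    are pruned.  Node weights are haplotype frequencies; edge labels list
    the mutated alignment positions.

    Sites with more than two observed states are handled by the same
    majority rule (hub state on three-way ties); the graph attribute
    ``multistate_sites`` flags them.
    """
    if alignment.n_haplotypes < 1:
        raise ValueError("empty alignment")
    mat = alignment.site_matrix()
    ids = list(alignment.sequences)
    hap_rows: dict[tuple, int] = {}
    freqs: dict[tuple, int] = {}
    for row, ind in zip(mat, ids):
        t = tuple(row)
        hap_rows.setdefault(t, alignment.haplotype_index[ind])
        freqs[t] = freqs.get(t, 0) + 1
    observed = list(hap_rows)
    multistate = [int(s) for s, col in zip(alignment.polymorphic_sites, mat.T)
                  if np.unique(col).size > 2]

    nodes: list[tuple] = list(observed)
    known = set(nodes)
    while True:
        edges = _spanning_network(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        new_medians = []
        for hub, nbrs in adj.items():
            for a, b in itertools.combinations(sorted(nbrs), 2):
                trip = (nodes[hub], nodes[a], nodes[b])
                med = []
                for states in zip(*trip):
                    vals, cnts = np.unique(states, return_counts=True)
                    med.append(states[0] if cnts.max() == 1
                               else vals[np.argmax(cnts)])
                med = tuple(med)
                if med in known:
                    continue
                star = sum(_hamming(med, t) for t in trip)
                pair = sorted(_hamming(x, y) for x, y
                              in itertools.combinations(trip, 2))
                if star < pair[0] + pair[1]:
                    new_medians.append(med)
                    known.add(med)
        if not new_medians:
            break
        nodes.extend(new_medians)

    # prune obsolete medians, rebuilding the network until stable
    while True:
        edges = _spanning_network(nodes, epsilon)
        deg: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in edges:
            deg[i].add(j)
            deg[j].add(i)
        drop = None
        for i, t in enumerate(nodes):
            if t in freqs:
                continue
            nbrs = sorted(deg[i])
            if len(nbrs) <= 1:
                drop = i
                break
            if len(nbrs) == 2:
                u, v = nodes[nbrs[0]], nodes[nbrs[1]]
                if _hamming(u, t) + _hamming(t, v) > _hamming(u, v):
                    drop = i
                    break
        if drop is None:
            break
        nodes.pop(drop)

    G = nx.Graph(multistate_sites=multistate, epsilon=epsilon)
    names = []
    n_median = 0
    for t in nodes:
        if t in freqs:
            name = f"H{hap_rows[t]}"
            G.add_node(name, frequency=freqs[t], observed=True,
                       states="".join(t))
        else:
            n_median += 1
            name = f"mv{n_median}"
            G.add_node(name, frequency=0, observed=False, states="".join(t))
        names.append(name)
    for i, j in _spanning_network(nodes, epsilon):
        sites = [int(alignment.polymorphic_sites[s])
                 for s in range(len(nodes[i])) if nodes[i][s] != nodes[j][s]]
        G.add_edge(names[i], names[j], weight=len(sites), sites=sites)
    return G


def write_network_graphml(G: "nx.Graph", path) -> None:
    """Write a haplotype network to GraphML; list-valued attributes
    (``sites``, ``multistate_sites``) become comma-joined strings because
    GraphML supports only scalar data values."""
    H = G.copy()

    def _flatten(d):
        for key, val in d.items():
            if isinstance(val, (list, tuple)):
                d[key] = ",".join(str(v) for v in val)

    _flatten(H.graph)
    for _, d in H.nodes(data=True):
        _flatten(d)
    for _, _, d in H.edges(data=True):
        _flatten(d)
    nx.write_graphml(H, path)
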