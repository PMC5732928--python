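"""Individual-based structure inference.

DAPC (PCA reduction followed by linear discriminant analysis on a priori
site labels, retained-PC count chosen by the alpha score) and neighbor
joining on inter-individual Euclidean allele-frequency distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data_model import MISSING, GenotypeMatrix


def individual_allele_table(genos: GenotypeMatrix) -> pd.DataFrame:
    """Individuals x (locus, allele) allele-dosage fractions.

    Each genotype contributes 0.5 per allele copy, so the columns of one
    locus sum to 1 per individual.  Missing genotypes are imputed with the
    column mean over typed individuals (the standard centring-neutral choice
    for PCA input).
    """
    columns: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    for j, locus in enumerate(genos.loci):
        calls = genos.calls[:, j, :]
        typed = calls[:, 0] != MISSING
        alleles = np.unique(calls[typed].ravel())
        block = np.zeros((genos.n_individuals, alleles.size))
        for c, a in enumerate(alleles):
            block[:, c] = np.sum(calls == a, axis=1) / 2.0
        if typed.any() and not typed.all():
            block[~typed] = block[typed].mean(axis=0)
        blocks.append(block)
        columns.extend((locus, int(a)) for a in alleles)
    table = pd.DataFrame(np.hstack(blocks), index=genos.individuals,
                         columns=pd.MultiIndex.from_tuples(columns,
                                                           names=["locus", "allele"]))
    return table


@dataclass
class DapcResult:
    n_pcs: int
    coords: pd.DataFrame       # individuals x discriminant axes
    membership: pd.DataFrame   # individuals x groups, rows sum to 1
    alpha_scores: dict[int, float]

    def assignments(self) -> pd.Series:
        return self.membership.idxmax(axis=1)


def _fit_dapc(X: np.ndarray, groups: np.ndarray, n_pcs: int):
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(X)
    uniq = np.unique(groups)
    n_da = min(len(uniq) - 1, n_pcs)
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    ld = lda.fit_transform(scores, groups)
    centroids = np.stack([ld[groups == g].mean(axis=0) for g in uniq])
    d2 = ((ld[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    # membership from squared distances to centroids, softmax-normalized
    w = np.exp(-0.5 * (d2 - d2.min(axis=1, keepdims=True)))
    member = w / w.sum(axis=1, keepdims=True)
    return ld, member, uniq


def _reassignment_rate(member: np.ndarray, groups: np.ndarray,
                       uniq: np.ndarray) -> float:
    assigned = uniq[np.argmax(member, axis=1)]
    return float(np.mean(assigned == groups))


def dapc(table: pd.DataFrame, groups, n_pcs: int | str = "auto",
         seed: int = 0, n_randomizations: int = 10,
         max_pcs: int = 20) -> DapcResult:
    """Discriminant analysis of principal components on a priori groups.

    ``n_pcs="auto"`` scans 1..min(max_pcs, rank) and keeps the count
    maximizing the alpha score: observed proportion of correct reassignment
    minus its mean under ``n_randomizations`` random permutations of the
    group labels.
    """
    groups = np.asarray([str(g) for g in groups])
    uniq, cnt = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(cnt < 2):
        warnings.warn(f"groups of a single individual: "
                      f"{uniq[cnt < 2].tolist()}")
    X = table.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    rank = int(np.linalg.matrix_rank(X))
    rank = min(rank, X.shape[0] - 1, X.shape[1])
    rng = np.random.default_rng(seed)

    def alpha(npc: int) -> float:
        _, member, u = _fit_dapc(X, groups, npc)
        obs = _reassignment_rate(member, groups, u)
        rand = []
        for _ in range(n_randomizations):
            g = groups[rng.permutation(len(groups))]
            _, m, u2 = _fit_dapc(X, g, npc)
            rand.append(_reassignment_rate(m, g, u2))
        return obs - float(np.mean(rand))

    alpha_scores: dict[int, float] = {}
    if n_pcs == "auto":
        for npc in range(1, min(max_pcs, rank) + 1):
            alpha_scores[npc] = alpha(npc)
        best = max(alpha_scores, key=lambda k: (alpha_scores[k], -k))
    else:
        best = int(n_pcs)
        if best > rank:
            warnings.warn(f"n_pcs={best} exceeds rank {rank}; clipped")
            best = rank
        alpha_scores[best] = alpha(best)
    ld, member, u = _fit_dapc(X, groups, best)
    coords = pd.DataFrame(ld, index=table.index,
                          columns=[f"LD{i + 1}" for i in range(ld.shape[1])])
    membership = pd.DataFrame(member, index=table.index, columns=u)
    return DapcResult(best, coords, membership, alpha_scores)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def euclidean_distances(table: pd.DataFrame) -> pd.DataFrame:
    X = table.to_numpy(dtype=float)
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    return pd.DataFrame(np.sqrt(d2), index=table.index, columns=table.index)


def nj_tree(distances: pd.DataFrame | np.ndarray,
            labels: list[str] | None = None) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Deterministic: Q-matrix ties are broken by the smallest (i, j) index
    pair in current node order.  Negative branch lengths are clamped to
    zero with the length transferred to the sibling edge.
    """
    if isinstance(distances, pd.DataFrame):
        labels = [str(x) for x in distances.index]
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        if labels is None:
            labels = [f"t{i + 1}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n == 1:
        return f"{labels[0]};"
    if n == 2:
        return f"({labels[0]}:{d[0, 1] / 2:.10g},{labels[1]}:{d[0, 1] / 2:.10g});"

    nodes = [f"{lab}" for lab in labels]  # subtree newick fragments
    D = d.copy()
    active = list(range(n))

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if best is None or Q[i, j] < Q[best] - 1e-12:
                    best = (i, j)
        i, j = best
        dij = sub[i, j]
        li = dij / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        ai, aj = active[i], active[j]
        new = f"({nodes[ai]}:{li:.10g},{nodes[aj]}:{lj:.10g})"
        # distances from the new node to the remaining ones
        newrow = np.zeros(D.shape[0] + 1)
        for t, at in enumerate(active):
            if t in (i, j):
                continue
            newrow[at] = (sub[i, t] + sub[j, t] - dij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(new)
        active = [a for t, a in enumerate(active) if t not in (i, j)]
        active.append(D.shape[0] - 1)

    # final three nodes: star resolution with closed-form branch lengths
    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return (f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},"
            f"{nodes[c]}:{lc:.10g});")
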