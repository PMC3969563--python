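"""Individual-level structure: distance matrices, NJ trees, PCA, clustering.

The species/cluster detection surface is deliberately simple: average
pairwise allelic distance for neighbor joining, correlation-based PCA of the
dosage matrix, and k-means on the leading components with a silhouette-based
suggestion for the number of clusters.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
import skbio

from radpop.genotypes import GenotypeMatrix
from radpop.stats import _check_complete


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.d = d


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    explained_fraction: np.ndarray
    loadings: np.ndarray          # components x SNPs
    site_index: np.ndarray        # columns of the matrix actually used


def pairwise_distance_matrix(m: GenotypeMatrix) -> DistanceMatrix:
    """Average pairwise allele difference per site between individuals.

    For diploids i, j the per-site distance is the mean over the four
    allele pairings, ``p_i (1 - p_j) + p_j (1 - p_i)`` with ``p = dosage/2``,
    summed over sites and divided by ``L``.  This equals D_XY computed
    between singleton "populations".
    """
    _check_complete(m.G)
    P = m.G / 2.0
    D = P @ (1.0 - P).T + (1.0 - P) @ P.T
    D /= m.L
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(labels=list(m.samples["sample_id"]), d=D)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> skbio.TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted skbio TreeNode.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sister branch of the join, preserving the path length between the
    two joined taxa.  Requires at least three taxa.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    d = dm.d.copy()
    nodes = [skbio.TreeNode(name=str(lab)) for lab in dm.labels]
    active = list(range(n))

    while len(active) > 2:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = d[a, b]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (k - 2))
        lj = dij - li
        # clamp negatives, moving the deficit onto the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = skbio.TreeNode()
        nodes[a].length = float(max(li, 0.0))
        nodes[b].length = float(max(lj, 0.0))
        parent.extend([nodes[a], nodes[b]])

        dnew = 0.5 * (d[a, :] + d[b, :] - dij)
        d = np.vstack([d, dnew])
        d = np.hstack([d, np.append(dnew, 0.0)[:, None]])
        nodes.append(parent)
        new_index = d.shape[0] - 1
        active = [x for x in active if x not in (a, b)] + [new_index]

    a, b = active
    # final edge: attach the remaining node as sibling with the leftover length
    root = nodes[b] if len(nodes[b].children) else nodes[a]
    other = nodes[a] if root is nodes[b] else nodes[b]
    other.length = float(max(d[a, b], 0.0))
    root.append(other)
    return root


def tree_to_newick(tree: skbio.TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# PCA and cluster assignment


def pca_genotypes(
    m: GenotypeMatrix,
    n_components: int = 2,
    standardize: bool = True,
    site_index: np.ndarray | None = None,
) -> PcaResult:
    """PCA of the samples x dosage matrix.

    ``standardize=True`` scales each SNP to unit variance (correlation PCA).
    Zero-variance SNPs are dropped.  Component signs are fixed by making the
    largest-magnitude loading of each component positive, so results are
    reproducible across linear-algebra backends.
    """
    _check_complete(m.G)
    cols = np.arange(m.n_sites) if site_index is None else np.asarray(site_index)
    X = m.G[:, cols].astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 SNPs")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} zero-variance SNPs", stacklevel=2)
    X = X[:, keep]
    cols = cols[keep]
    X = X - X.mean(axis=0)
    if standardize:
        X = X / X.std(axis=0)
    k = min(n_components, min(X.shape) - 1) if min(X.shape) > 1 else 1
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for c in range(loadings.shape[0]):
        sign = np.sign(loadings[c, np.argmax(np.abs(loadings[c]))])
        if sign < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    score_df = pd.DataFrame(
        scores,
        index=m.samples["sample_id"].to_numpy(),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PcaResult(
        scores=score_df,
        explained_fraction=pca.explained_variance_ratio_,
        loadings=loadings,
        site_index=cols,
    )


def assign_clusters(scores: PcaResult | np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels on leading PCs (50 restarts, best inertia)."""
    X = scores.scores.to_numpy() if isinstance(scores, PcaResult) else np.asarray(scores)
    if k > X.shape[0]:
        raise ValueError("more clusters than samples")
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    return km.fit_predict(X)


def suggest_k(scores: PcaResult | np.ndarray, k_max: int = 5, seed: int = 0) -> int:
    """Silhouette-best number of clusters among k = 2..k_max."""
    X = scores.scores.to_numpy() if isinstance(scores, PcaResult) else np.asarray(scores)
    best_k, best_s = 2, -np.inf
    for k in range(2, min(k_max, X.shape[0] - 1) + 1):
        labels = assign_clusters(X, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_chisq(genotype_counts: tuple[int, int, int]) -> tuple[float, float]:
    """Chi-square test of Hardy-Weinberg proportions for one biallelic locus.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa).  One degree of freedom.
    Returns (chi2, p); a fixed locus returns (nan, nan) with a warning.
    """
    n_aa_, n_ab, n_bb = (int(x) for x in genotype_counts)
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_aa_ + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        import warnings

        warnings.warn("fixed locus: HWE test undefined", stacklevel=2)
        return float("nan"), float("nan")
    q = 1 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_aa_, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(chi2_dist.sf(chi2, df=1))
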