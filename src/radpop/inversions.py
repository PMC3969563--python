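"""Detection and karyotyping of segregating inversions from LD islands.

A polymorphic inversion suppresses recombination between orientations, so
its tags travel as two deep haplotype classes: pairwise r-squared between
tags inside the region is elevated far above the chromosome-arm background,
individuals separate into three PCA clusters (two homokaryotypes and the
heterokaryotype between them), and the heterokaryotype cluster has the
highest SNP heterozygosity.  The scan statistic used here (median inter-tag
r-squared against an arm-background quantile, over runs of consecutive tags)
is a reproducible replacement for reading LD triangle plots by eye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from radpop.genotypes import GenotypeMatrix, TagLocation, population_mask
from radpop.stats import (
    _check_complete,
    dxy_site_totals,
    individual_heterozygosity,
    sliding_window,
    wc_fst_per_locus,
)
from radpop.clustering import assign_clusters, hwe_chisq, pca_genotypes


@dataclass
class LdMatrix:
    chrom: str | None
    positions: np.ndarray
    r2: np.ndarray
    site_index: np.ndarray     # columns of the source matrix


@dataclass
class LdBlock:
    chrom: str
    start: int
    end: int
    mean_r2_inside: float
    background_r2: float
    n_tags: int
    tag_indices: list[int]     # columns of the LdMatrix inside the block

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# EM haplotype-frequency r^2


def em_haplotype_freqs(
    g1: np.ndarray, g2: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, list[float]]:
    """Two-locus haplotype frequencies from unphased diploid dosages.

    Only the double heterozygote is phase-ambiguous; the EM iterates its
    phase weight to the maximum-likelihood haplotype frequencies
    ``(p11, p10, p01, p00)`` over (alt, alt) .. (ref, ref).  Returns the
    frequencies and the log-likelihood trace (non-decreasing).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    n = len(g1)
    C = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            C[a, b] = np.sum((g1 == a) & (g2 == b))
    w = 0.5
    trace: list[float] = []
    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        n11 = 2 * C[2, 2] + C[2, 1] + C[1, 2] + w * C[1, 1]
        n10 = 2 * C[2, 0] + C[2, 1] + C[1, 0] + (1 - w) * C[1, 1]
        n01 = 2 * C[0, 2] + C[1, 2] + C[0, 1] + (1 - w) * C[1, 1]
        n00 = 2 * C[0, 0] + C[0, 1] + C[1, 0] + w * C[1, 1]
        new = np.array([n11, n10, n01, n00]) / (2 * n)
        trace.append(_dip_loglik(C, new))
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
        denom = freqs[0] * freqs[3] + freqs[1] * freqs[2]
        w = freqs[0] * freqs[3] / denom if denom > 0 else 0.5
    return freqs, trace


def _dip_loglik(C: np.ndarray, f: np.ndarray) -> float:
    p11, p10, p01, p00 = f
    # genotype-pair probabilities under random union of haplotypes
    hap = {(1, 1): p11, (1, 0): p10, (0, 1): p01, (0, 0): p00}
    ll = 0.0
    for a in range(3):
        for b in range(3):
            if C[a, b] == 0:
                continue
            prob = 0.0
            for h1, q1 in hap.items():
                for h2, q2 in hap.items():
                    if h1[0] + h2[0] == a and h1[1] + h2[1] == b:
                        prob += q1 * q2
            ll += C[a, b] * np.log(max(prob, 1e-300))
    return ll


def _em_r2_all_pairs(G: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Vectorised EM r^2 for every SNP pair of a complete dosage matrix."""
    n, s = G.shape
    I = [(G == a).astype(float) for a in range(3)]
    C = {(a, b): I[a].T @ I[b] for a in range(3) for b in range(3)}
    W = np.full((s, s), 0.5)
    base11 = 2 * C[2, 2] + C[2, 1] + C[1, 2]
    base10 = 2 * C[2, 0] + C[2, 1] + C[1, 0]
    base01 = 2 * C[0, 2] + C[1, 2] + C[0, 1]
    base00 = 2 * C[0, 0] + C[0, 1] + C[1, 0]
    dh = C[1, 1]
    two_n = 2.0 * n
    prev = None
    for _ in range(max_iter):
        p11 = (base11 + W * dh) / two_n
        p10 = (base10 + (1 - W) * dh) / two_n
        p01 = (base01 + (1 - W) * dh) / two_n
        p00 = (base00 + W * dh) / two_n
        if prev is not None and np.max(np.abs(p11 - prev)) < tol:
            break
        prev = p11
        denom = p11 * p00 + p10 * p01
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(denom > 0, p11 * p00 / np.where(denom > 0, denom, 1.0), 0.5)
    pA = (p11 + p10)    # alt freq at locus 1 (rows)
    pB = (p11 + p01)    # alt freq at locus 2 (cols)
    D = p11 - pA * pB
    var = pA * (1 - pA) * pB * (1 - pB)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(var > 0, D * D / np.where(var > 0, var, 1.0), np.nan)
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_r2_matrix(
    m: GenotypeMatrix,
    pop: str | None = None,
    region: tuple | str | None = None,
    site_index: np.ndarray | None = None,
    min_maf: float = 0.05,
) -> LdMatrix:
    """Pairwise EM-based r^2 between all polymorphic SNPs of a region.

    Haplotype frequencies for each unphased pair are estimated by the
    two-locus EM (double-heterozygote phase resolved iteratively); r^2 is
    ``D^2 / (pA pa pB pb)``.  Monomorphic SNPs are dropped, and SNPs with
    minor-allele frequency below ``min_maf`` are excluded (a pair of rare
    variants carried by the same individual yields a spurious r^2 of 1, the
    usual reason LD scans apply a MAF floor).
    """
    sub = m if pop is None else m.subset_population(pop)
    _check_complete(sub.G)
    cols = np.arange(sub.n_sites) if site_index is None else np.asarray(site_index)
    chroms = sub.sites["chrom"].to_numpy()
    pos = sub.sites["pos"].to_numpy()
    chrom_label = None
    if region is not None:
        if isinstance(region, str):
            mask = chroms == region
            chrom_label = region
        else:
            c, s, e = region
            mask = (chroms == c) & (pos >= s) & (pos <= e)
            chrom_label = c
        cols = cols[mask[cols]]
    poly = sub.polymorphic_mask() & sub.is_variant
    cols = cols[poly[cols]]
    if min_maf > 0 and len(cols):
        freqs = sub.allele_freqs()[cols]
        maf = np.minimum(freqs, 1 - freqs)
        cols = cols[maf >= min_maf]
    if len(cols) < 2:
        raise ValueError("need at least two polymorphic SNPs for LD")
    r2 = _em_r2_all_pairs(sub.G[:, cols])
    return LdMatrix(chrom=chrom_label, positions=pos[cols], r2=r2, site_index=cols)


def genotype_r2_matrix(m: GenotypeMatrix, pop: str | None = None,
                       site_index: np.ndarray | None = None) -> LdMatrix:
    """Composite (dosage-correlation) r^2 -- a cross-check for the EM r^2."""
    sub = m if pop is None else m.subset_population(pop)
    _check_complete(sub.G)
    cols = np.arange(sub.n_sites) if site_index is None else np.asarray(site_index)
    poly = sub.polymorphic_mask() & sub.is_variant
    cols = cols[poly[cols]]
    X = sub.G[:, cols].astype(float)
    r = np.corrcoef(X, rowvar=False)
    return LdMatrix(chrom=None, positions=sub.sites["pos"].to_numpy()[cols],
                    r2=r * r, site_index=cols)


# ---------------------------------------------------------------------------
# block scan


def _tag_pair_scores(ld: LdMatrix, tags: list[TagLocation] | None) -> tuple[np.ndarray, list]:
    """Collapse an SNP-level r^2 matrix to a tag-level score matrix.

    The score for a pair of tags is the *maximum* r^2 over their SNP cross
    pairs: inversion tags travel as deep haplotype classes, so each carries
    some orientation-informative SNPs in near-perfect LD with those of other
    inversion tags, while gene flux leaves other SNPs uninformative -- a
    median over SNP pairs would dilute the signal.  If ``tags`` is None,
    every SNP is treated as its own tag.
    """
    if tags is None:
        spans = [(int(p), int(p)) for p in ld.positions]
        groups = [[i] for i in range(len(ld.positions))]
        return ld.r2, list(zip(spans, groups))
    arm_tags = [t for t in tags if ld.chrom is None or t.chrom == ld.chrom]
    groups = []
    for t in arm_tags:
        cols = np.flatnonzero((ld.positions >= t.start) & (ld.positions <= t.end))
        if len(cols):
            groups.append(((t.start, t.end), cols.tolist()))
    k = len(groups)
    score = np.full((k, k), np.nan)
    for i in range(k):
        ci = groups[i][1]
        for j in range(i, k):
            cj = groups[j][1]
            sub = ld.r2[np.ix_(ci, cj)]
            if i == j:
                score[i, j] = 1.0
            else:
                val = np.nanmax(sub) if np.isfinite(sub).any() else np.nan
                score[i, j] = score[j, i] = val
    return score, groups


def ld_block_scan(
    ld: LdMatrix,
    tags: list[TagLocation] | None = None,
    min_tags: int = 5,
    r2_threshold_quantile: float = 0.95,
    neighborhood: int | None = None,
) -> list[LdBlock]:
    """Find runs of consecutive tags in elevated LD.

    The SNP-level r^2 matrix is first collapsed to tag-pair scores (max
    cross-SNP r^2; see :func:`_tag_pair_scores`).  Each tag's local score is
    the median of its scores with the ``neighborhood`` nearest tags on
    either side (default ``min_tags``); a tag is flagged when this exceeds
    the ``r2_threshold_quantile`` quantile of all tag-pair scores on the
    arm, and runs of at least ``min_tags`` flagged tags are reported as
    blocks with their outermost tag spans.  With ``tags=None`` the columns
    of ``ld`` (e.g. one SNP per tag) are the scan units.
    """
    pair, groups = _tag_pair_scores(ld, tags)
    s = pair.shape[0]
    if s < min_tags:
        return []
    nb = neighborhood or min_tags
    off_diag = pair[np.triu_indices(s, k=1)]
    off_diag = off_diag[np.isfinite(off_diag)]
    if len(off_diag) == 0:
        return []
    threshold = float(np.quantile(off_diag, r2_threshold_quantile))

    scores = np.empty(s)
    for i in range(s):
        lo, hi = max(0, i - nb), min(s, i + nb + 1)
        window = np.concatenate([pair[i, lo:i], pair[i, i + 1:hi]])
        window = window[np.isfinite(window)]
        scores[i] = np.median(window) if len(window) else -np.inf
    flagged = scores > threshold

    blocks: list[LdBlock] = []
    i = 0
    while i < s:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < s and flagged[j + 1]:
            j += 1
        if j - i + 1 >= min_tags:
            idx = list(range(i, j + 1))
            inside = pair[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
            outside_mask = np.ones(s, dtype=bool)
            outside_mask[idx] = False
            rest = np.flatnonzero(outside_mask)
            outside = (
                pair[np.ix_(rest, rest)][np.triu_indices(len(rest), k=1)]
                if len(rest) > 1 else np.array([0.0])
            )
            blocks.append(LdBlock(
                chrom=ld.chrom or (tags[0].chrom if tags else ""),
                start=groups[idx[0]][0][0], end=groups[idx[-1]][0][1],
                mean_r2_inside=float(np.nanmean(inside)),
                background_r2=float(np.nanmedian(outside)),
                n_tags=len(idx), tag_indices=idx,
            ))
        i = j + 1
    return blocks


# ---------------------------------------------------------------------------
# karyotype calling


KARYOTYPE_LABELS = ("homokaryotype_1", "heterokaryotype", "homokaryotype_2")


def karyotype_call(
    m: GenotypeMatrix,
    block: LdBlock | tuple,
    seed: int = 0,
    pop: str | None = None,
    min_silhouette: float = 0.5,
) -> pd.DataFrame:
    """Assign inversion karyotypes from within-block PCA clusters.

    PCA of the SNPs inside the block separates orientation classes along
    PC1.  k-means with k in {2, 3} is chosen by silhouette; with three
    clusters the PC1-middle cluster must also have the highest mean
    heterozygosity to be called the heterokaryotype (otherwise every call is
    flagged ``uncalled``).  With two clusters (one homokaryotype absent from
    the sample) the higher-heterozygosity cluster is the heterokaryotype.
    Returns a data frame with sample_id, karyotype, cluster, PC1, mean_het.
    """
    sub = m if pop is None else m.subset_population(pop)
    chrom, start, end = (
        (block.chrom, block.start, block.end) if isinstance(block, LdBlock) else block
    )
    chroms = sub.sites["chrom"].to_numpy()
    pos = sub.sites["pos"].to_numpy()
    inside = np.flatnonzero(
        (chroms == chrom) & (pos >= start) & (pos <= end)
        & sub.polymorphic_mask() & sub.is_variant
    )
    if len(inside) < 3:
        raise ValueError("need at least 3 SNPs inside the block")
    het = individual_heterozygosity(sub, site_index=inside)

    out = pd.DataFrame({
        "sample_id": sub.samples["sample_id"].to_numpy(),
        "karyotype": "uncalled",
        "cluster": -1,
        "PC1": np.nan,
        "mean_het": het.to_numpy(),
    })
    unique_rows = np.unique(sub.G[:, inside], axis=0)
    if len(unique_rows) < 2:
        warnings.warn("no genotype variation inside block; all samples uncalled",
                      stacklevel=2)
        return out

    pca = pca_genotypes(sub, n_components=2, standardize=True, site_index=inside)
    X = pca.scores.to_numpy()
    out["PC1"] = X[:, 0]

    from sklearn.metrics import silhouette_score

    best_k, best_s, best_labels = None, -np.inf, None
    for k in (2, 3):
        if k > len(unique_rows) or k >= len(X):
            continue
        labels = assign_clusters(X, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s, best_labels = k, s, labels
    if best_k is None or best_s < min_silhouette:
        warnings.warn(
            f"no well-separated clusters inside block (silhouette {best_s:.2f}); "
            "all samples uncalled", stacklevel=2,
        )
        return out

    labels = best_labels
    out["cluster"] = labels
    cl_pc1 = np.array([X[labels == c, 0].mean() for c in range(best_k)])
    cl_het = np.array([het.to_numpy()[labels == c].mean() for c in range(best_k)])
    # anchor homokaryotype numbering to mean alt dosage inside the block,
    # which is invariant to SNP order and PC sign
    cl_dosage = np.array([
        sub.G[labels == c][:, inside].mean() for c in range(best_k)
    ])
    order = np.argsort(cl_pc1)           # left-to-right on PC1
    if best_k == 3:
        middle = order[1]
        if np.argmax(cl_het) != middle:
            warnings.warn(
                "PC1-middle cluster is not the most heterozygous; karyotypes "
                "uncalled", stacklevel=2,
            )
            return out
        homs = [order[0], order[2]]
        homs.sort(key=lambda c: cl_dosage[c])
        name_of = {homs[0]: "homokaryotype_1", middle: "heterokaryotype",
                   homs[1]: "homokaryotype_2"}
    else:
        het_cluster = int(np.argmax(cl_het))
        name_of = {het_cluster: "heterokaryotype",
                   1 - het_cluster: "homokaryotype_1"}
    out["karyotype"] = [name_of[c] for c in labels]
    return out


def karyotype_stratified_stats(
    m: GenotypeMatrix,
    calls: pd.DataFrame,
    block: LdBlock | tuple,
    outgroup: str | None = None,
    fst_window_snps: int = 25,
    dxy_window_sites: int = 1000,
    dxy_step_sites: int = 100,
) -> dict:
    """Statistics stratified by inversion karyotype across the arm.

    Produces (i) a sliding-window F_ST profile between the two homokaryotype
    classes, with means inside and outside the block, (ii) windowed D_XY of
    each homokaryotype against an outgroup population, (iii) the count of
    polymorphisms shared by the homokaryotypes inside the block, (iv) a
    Hardy-Weinberg chi-square on karyotype counts and (v) a karyotype-by-
    location homogeneity chi-square.  Statistics whose cluster sizes are
    insufficient are skipped with a warning.
    """
    chrom, start, end = (
        (block.chrom, block.start, block.end) if isinstance(block, LdBlock) else block
    )
    ids = m.samples["sample_id"].to_numpy()
    karyo = (
        calls.set_index("sample_id")["karyotype"]
        .reindex(ids, fill_value="uncalled")   # samples outside the called set
        .to_numpy()
    )
    hom1 = karyo == "homokaryotype_1"
    hom2 = karyo == "homokaryotype_2"
    het_n = int((karyo == "heterokaryotype").sum())
    report: dict = {
        "karyotype_counts": {
            "homokaryotype_1": int(hom1.sum()),
            "heterokaryotype": het_n,
            "homokaryotype_2": int(hom2.sum()),
        },
        "block": (chrom, start, end),
    }

    arm = np.flatnonzero(m.sites["chrom"].to_numpy() == chrom)
    pos = m.sites["pos"].to_numpy()[arm]
    in_block = (pos >= start) & (pos <= end)

    # (iv) HWE on karyotype counts
    counts = (int(hom1.sum()), het_n, int(hom2.sum()))
    if counts[0] + counts[2] > 0 and min(counts[0] + counts[1], counts[2] + counts[1]) > 0:
        chi2, p = hwe_chisq(counts)
        report["hwe"] = {"chi2": chi2, "p": p}

    # (v) karyotype frequency homogeneity across locations
    loc = m.samples["location"].to_numpy()
    called = karyo != "uncalled"
    table = pd.crosstab(karyo[called], loc[called])
    if table.shape[0] > 1 and table.shape[1] > 1:
        chi2, p, dof, _ = chi2_contingency(table)
        report["location_homogeneity"] = {"chi2": float(chi2), "p": float(p), "df": int(dof)}

    if hom1.sum() >= 2 and hom2.sum() >= 2:
        both = hom1 | hom2
        codes = np.where(hom1[both], 0, 1)
        Garm = m.G[np.ix_(both, arm)]
        seg = ((Garm.sum(axis=0) > 0) & (Garm.sum(axis=0) < 2 * both.sum()))
        theta = wc_fst_per_locus(Garm[:, seg], codes)
        wpos = pos[seg]
        profile = sliding_window(wpos, theta, size=fst_window_snps, step=1,
                                 mode="snp", stat="mean")
        report["fst_profile"] = profile
        inside_mask = (wpos >= start) & (wpos <= end)
        finite = np.isfinite(theta)
        report["fst_mean_inside"] = float(np.nanmean(theta[inside_mask & finite])) if (inside_mask & finite).any() else float("nan")
        report["fst_mean_outside"] = float(np.nanmean(theta[~inside_mask & finite])) if (~inside_mask & finite).any() else float("nan")

        # (iii) shared polymorphisms between homokaryotypes inside the block
        blk_cols = arm[in_block]
        Gb1 = m.G[np.ix_(hom1, blk_cols)]
        Gb2 = m.G[np.ix_(hom2, blk_cols)]
        c1, c2 = Gb1.sum(axis=0), Gb2.sum(axis=0)
        seg1 = (c1 > 0) & (c1 < 2 * hom1.sum())
        seg2 = (c2 > 0) & (c2 < 2 * hom2.sum())
        report["shared_polymorphisms_in_block"] = int((seg1 & seg2).sum())
    else:
        warnings.warn("fewer than 2 diploids in a homokaryotype class; "
                      "F_ST and sharing statistics skipped", stacklevel=2)

    if outgroup is not None and hom1.sum() >= 1 and hom2.sum() >= 1:
        og = population_mask(m, outgroup)
        for name, mask in (("homokaryotype_1", hom1), ("homokaryotype_2", hom2)):
            d = dxy_site_totals(m.G[np.ix_(mask, arm)], m.G[np.ix_(og, arm)])
            win = sliding_window(pos, d, size=dxy_window_sites,
                                 step=dxy_step_sites, mode="snp", stat="mean")
            report[f"dxy_{name}_vs_{outgroup}"] = win
    return report
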