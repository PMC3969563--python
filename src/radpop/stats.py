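"""Diversity, divergence, differentiation and site-classification statistics.

Conventions
-----------
* All per-site quantities divide by ``L``, the number of analysed sites
  including invariant ones, so values are comparable across data sets with
  different SNP densities.
* pi uses the unbiased ``m/(m-1)`` sample-size correction (``m`` = number of
  sampled chromosomes); diploid genotypes contribute allele counts with no
  Hardy-Weinberg assumption.
* Weir & Cockerham (1984) variance components are combined across loci as a
  ratio of sums; negative per-locus components are retained untruncated.
* Permutation p-values use the ``(k + 1) / (N + 1)`` correction so that an
  empirical p of exactly zero is never reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radpop.genotypes import GenotypeMatrix, MISSING, TagLocation, population_mask
from radpop.genotypes import draw_one_snp_per_tag

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# constants for scalar conversions


@dataclass(frozen=True)
class Constants:
    """Mutation-rate and generation-time constants used for scaling.

    Defaults follow the fruit-fly-derived nuclear rate of 1.1e-8 per year
    with 10 generations per year, i.e. 1.1e-9 per generation.
    """

    mu_per_year: float = 1.1e-8
    generations_per_year: float = 10.0

    @property
    def mu_per_gen(self) -> float:
        return self.mu_per_year / self.generations_per_year


def ne_from_theta(theta_per_site: float, c: Constants = Constants()) -> float:
    """Effective population size from theta = 4 Ne mu (mu per generation)."""
    return theta_per_site / (4.0 * c.mu_per_gen)


def nm_from_fst(fst_value: float) -> float:
    """Island-model effective migrant number Nm = (1 - Fst) / (4 Fst)."""
    if not 0.0 < fst_value < 1.0:
        raise ValueError("Nm is defined only for Fst in (0, 1)")
    return (1.0 - fst_value) / (4.0 * fst_value)


def divergence_time_years(da_per_site: float, c: Constants = Constants()) -> float:
    """Split time in years from net divergence, T = D_A / (2 mu_per_year)."""
    return da_per_site / (2.0 * c.mu_per_year)


# ---------------------------------------------------------------------------
# Tajima (1989) machinery


def tajima_constants(m: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for ``m`` sampled chromosomes."""
    if m < 2:
        raise ValueError("need at least two chromosomes")
    i = np.arange(1, m)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def watterson_theta(S: int, n_chrom: int, L: float) -> float:
    """Watterson's theta per site, S / (a1 L)."""
    if L <= 0:
        raise ValueError("L must be positive")
    return S / (tajima_constants(n_chrom)["a1"] * L)


def tajimas_d(pi_total: float, S: int, n_chrom: int) -> float:
    """Tajima's D from the total (not per-site) pairwise diversity and S.

    Returns NaN (with a warning) when there are no segregating sites.
    """
    if S == 0:
        warnings.warn("Tajima's D undefined with S = 0", stacklevel=2)
        return float("nan")
    k = tajima_constants(n_chrom)
    num = pi_total - S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return num / np.sqrt(var)


# ---------------------------------------------------------------------------
# within-population diversity


@dataclass
class DiversityResult:
    pop: str
    n_chrom: int
    L: int
    S: int
    pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float
    pi_sd: float | None = None
    constants: dict[str, float] = field(default_factory=dict)


def _check_complete(G: np.ndarray) -> None:
    if (G == MISSING).any():
        raise ValueError("statistic requires a complete (no-missing) matrix; "
                         "run filter_sites first")


def _pi_site_totals(G: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity contributions for one population."""
    m = 2 * G.shape[0]
    ca = G.sum(axis=0)
    return 2.0 * ca * (m - ca) / (m * (m - 1))


def diversity_stats(
    m: GenotypeMatrix,
    pop: str,
    tags: list[TagLocation] | None = None,
) -> DiversityResult:
    """pi, Watterson's theta and Tajima's D for one population.

    If ``tags`` is given, the standard deviation of pi is estimated by a
    delete-one-tag jackknife (tags are the natural independent unit of RAD
    data); otherwise ``pi_sd`` is None.
    """
    sub = m.subset_population(pop)
    _check_complete(sub.G)
    if sub.L <= 0:
        raise ValueError("empty matrix")
    n_chrom = 2 * sub.n_samples
    pi_sites = _pi_site_totals(sub.G)
    pi_total = float(pi_sites.sum())
    S = sub.S
    theta = watterson_theta(S, n_chrom, sub.L) if S else 0.0
    if S:
        D = tajimas_d(pi_total, S, n_chrom)
    else:
        D = float("nan")
        warnings.warn(f"population {pop!r} is monomorphic; Tajima's D undefined",
                      stacklevel=2)

    pi_sd = None
    if tags is not None and len(tags) > 1:
        pi_sd = _jackknife_pi_sd(pi_sites, tags, sub.L)

    return DiversityResult(
        pop=pop, n_chrom=n_chrom, L=sub.L, S=S,
        pi_per_site=pi_total / sub.L,
        theta_w_per_site=theta, tajimas_d=D, pi_sd=pi_sd,
        constants=tajima_constants(n_chrom),
    )


def _jackknife_pi_sd(pi_sites: np.ndarray, tags: list[TagLocation], L: int) -> float:
    T = len(tags)
    pi_total = pi_sites.sum()
    mean_tag_L = L / T  # tag L includes un-enumerated invariant positions
    est = np.empty(T)
    for t, tag in enumerate(tags):
        drop = pi_sites[tag.site_indices].sum()
        est[t] = (pi_total - drop) / (L - mean_tag_L)
    return float(np.sqrt((T - 1) / T * np.sum((est - est.mean()) ** 2)))


def individual_heterozygosity(
    m: GenotypeMatrix, site_index: np.ndarray | None = None
) -> pd.Series:
    """Per-sample fraction of heterozygous calls over a SNP subset."""
    G = m.G if site_index is None else m.G[:, np.asarray(site_index)]
    if G.shape[1] == 0:
        raise ValueError("empty site subset")
    called = G != MISSING
    het = (G == 1) & called
    frac = het.sum(axis=1) / np.maximum(called.sum(axis=1), 1)
    return pd.Series(frac, index=m.samples["sample_id"].to_numpy(), name="heterozygosity")


# ---------------------------------------------------------------------------
# between-population divergence


@dataclass
class DivergenceResult:
    pops: tuple[str, str]
    L: int
    dxy_per_site: float
    da_per_site: float
    pi_within: tuple[float, float]
    t_years: float | None = None


def dxy_site_totals(G1: np.ndarray, G2: np.ndarray) -> np.ndarray:
    """Per-site mean inter-population allele difference (unphased dosages)."""
    p1 = G1.sum(axis=0) / (2 * G1.shape[0])
    p2 = G2.sum(axis=0) / (2 * G2.shape[0])
    return p1 * (1 - p2) + p2 * (1 - p1)


def divergence_stats(
    m: GenotypeMatrix, pop1: str, pop2: str, c: Constants | None = Constants()
) -> DivergenceResult:
    """Absolute (D_XY) and net (D_A) divergence between two populations.

    D_A subtracts the mean within-population diversity; the optional
    constants convert D_A into a split time in years via D_A = 2 mu T.
    """
    mask1 = population_mask(m, pop1)
    mask2 = population_mask(m, pop2)
    if (mask1 & mask2).any():
        raise ValueError(f"populations {pop1!r} and {pop2!r} share samples")
    G1, G2 = m.G[mask1], m.G[mask2]
    _check_complete(G1)
    _check_complete(G2)
    L = m.L
    dxy = float(dxy_site_totals(G1, G2).sum()) / L
    pi1 = float(_pi_site_totals(G1).sum()) / L
    pi2 = float(_pi_site_totals(G2).sum()) / L
    da = dxy - (pi1 + pi2) / 2.0
    t_years = divergence_time_years(da, c) if c is not None else None
    return DivergenceResult(
        pops=(pop1, pop2), L=L, dxy_per_site=dxy, da_per_site=da,
        pi_within=(pi1, pi2), t_years=t_years,
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST


def wc_fst_components(
    G: np.ndarray, pop_codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) from diploid dosages.

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals.  Loci monomorphic in the pooled
    sample yield (0, 0, 0) and should be excluded from ratio-of-sums
    estimates by the caller.
    """
    _check_complete(G)
    pops = np.unique(pop_codes)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = np.array([(pop_codes == p).sum() for p in pops], dtype=float)
    if (n_i < 2).any():
        raise ValueError("every population needs at least two diploids")
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)

    p_il = np.stack([G[pop_codes == p].sum(axis=0) / (2 * n) for p, n in zip(pops, n_i)])
    h_il = np.stack([(G[pop_codes == p] == 1).mean(axis=0) for p in pops])

    w = n_i[:, None] / (r * nbar)
    pbar = (w * p_il).sum(axis=0)
    s2 = (n_i[:, None] * (p_il - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (w * h_il).sum(axis=0)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    cc = hbar / 2.0
    mono = (pbar == 0) | (pbar == 1)
    a[mono] = b[mono] = cc[mono] = 0.0
    return a, b, cc


def wc_fst_multilocus(G: np.ndarray, pop_codes: np.ndarray) -> float:
    """Ratio-of-sums multilocus WC84 theta-hat."""
    a, b, c = wc_fst_components(G, pop_codes)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def wc_fst_per_locus(G: np.ndarray, pop_codes: np.ndarray) -> np.ndarray:
    """Per-locus theta-hat (NaN at loci monomorphic in the pooled sample)."""
    a, b, c = wc_fst_components(G, pop_codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(a + b + c != 0, a / (a + b + c), np.nan)


@dataclass
class FstResult:
    pops: tuple[str, ...]
    per_locus: pd.DataFrame
    multilocus: float
    permutation_p: float | None
    n_permutations: int
    subset_estimates: list[float]
    reported: float


def fst(
    m: GenotypeMatrix,
    pops: list[str],
    tags: list[TagLocation] | None = None,
    n_perm: int = 8000,
    n_subsets: int = 5,
    seed: int = 0,
) -> FstResult:
    """Weir-Cockerham F_ST between populations with a permutation test.

    When ``tags`` is supplied, ``n_subsets`` independent one-SNP-per-tag
    subsets are drawn (seeds ``seed .. seed + n_subsets - 1``) and the median
    multilocus estimate across subsets is reported, which removes the
    within-tag linkage bias of RAD data.  Significance is assessed by
    permuting population labels among individuals on the subset that attains
    the median.  With ``tags=None`` a single estimate uses all SNPs.
    """
    masks = [population_mask(m, p) for p in pops]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                raise ValueError(f"populations {pops[i]!r}/{pops[j]!r} overlap")
    union = np.zeros(m.n_samples, dtype=bool)
    codes = np.full(m.n_samples, -1)
    for k, mask in enumerate(masks):
        union |= mask
        codes[mask] = k
    sub = m.take_samples(union)
    codes = codes[union]

    if tags is not None:
        subsets = [
            draw_one_snp_per_tag(sub, tags, seed=seed + k).G
            for k in range(n_subsets)
        ]
    else:
        poly = sub.polymorphic_mask() & sub.is_variant
        subsets = [sub.G[:, poly]]

    estimates = [wc_fst_multilocus(G, codes) for G in subsets]
    order = int(np.argsort(estimates)[len(estimates) // 2])
    reported = float(estimates[order])
    G_med = subsets[order]

    a, b, c = wc_fst_components(G_med, codes)
    per_locus = pd.DataFrame({"a": a, "b": b, "c": c})
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus["theta"] = np.where(a + b + c != 0, a / (a + b + c), np.nan)

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed + 7919)
        obs = estimates[order]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(codes))
            if wc_fst_multilocus(G_med, codes[perm]) >= obs:
                hits += 1
        p = (hits + 1) / (n_perm + 1)

    return FstResult(
        pops=tuple(pops), per_locus=per_locus,
        multilocus=float(estimates[order]), permutation_p=p,
        n_permutations=n_perm, subset_estimates=[float(e) for e in estimates],
        reported=reported,
    )


# ---------------------------------------------------------------------------
# inbreeding coefficient


def fis_test(
    m: GenotypeMatrix, pop: str, n_perm: int = 8000, seed: int = 0
) -> tuple[float, float]:
    """Multilocus F_IS = 1 - H_obs / H_exp with an allele-permutation test.

    H_exp carries the unbiased ``m/(m-1)`` correction.  The null distribution
    re-pairs alleles at random among individuals within the population,
    independently at every locus; the returned p is one-sided for a
    heterozygote *deficit* (F_IS greater than or equal to observed).
    """
    sub = m.subset_population(pop)
    _check_complete(sub.G)
    if sub.n_samples < 2:
        raise ValueError("need at least two diploids")
    poly = sub.polymorphic_mask() & sub.is_variant
    if not poly.any():
        warnings.warn("no polymorphic loci; F_IS undefined", stacklevel=2)
        return float("nan"), float("nan")
    G = sub.G[:, poly]
    n = G.shape[0]
    mm = 2 * n
    p_hat = G.sum(axis=0) / mm
    h_exp = 2 * p_hat * (1 - p_hat) * mm / (mm - 1)
    h_obs = (G == 1).mean(axis=0)
    fis = 1.0 - h_obs.sum() / h_exp.sum()

    # alleles as a (2n, loci) array; permutations re-pair rows per locus
    alleles = np.zeros((mm, G.shape[1]), dtype=np.int8)
    alleles[0::2] = (G >= 1).astype(np.int8)
    alleles[1::2] = (G == 2).astype(np.int8)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        shuffled = rng.permuted(alleles, axis=0)
        h_perm = (shuffled[0::2] != shuffled[1::2]).mean(axis=0)
        if 1.0 - h_perm.sum() / h_exp.sum() >= fis:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(fis), float(p)


# ---------------------------------------------------------------------------
# site classification


SITE_LABELS = ("monomorphic", "private_to_p1", "private_to_p2", "shared", "fixed_difference")


@dataclass
class SiteClassification:
    pops: tuple[str, str]
    labels: np.ndarray  # per-site string labels
    counts: dict[str, int]


def classify_sites(m: GenotypeMatrix, pop1: str, pop2: str) -> SiteClassification:
    """Label every site as shared/private/fixed between two populations."""
    G1 = m.G[population_mask(m, pop1)]
    G2 = m.G[population_mask(m, pop2)]
    _check_complete(G1)
    _check_complete(G2)
    c1, c2 = G1.sum(axis=0), G2.sum(axis=0)
    m1, m2 = 2 * G1.shape[0], 2 * G2.shape[0]
    seg1 = (c1 > 0) & (c1 < m1)
    seg2 = (c2 > 0) & (c2 < m2)
    fix1, fix2 = c1 == m1, c2 == m2

    labels = np.full(m.n_sites, "monomorphic", dtype=object)
    labels[seg1 & ~seg2] = "private_to_p1"
    labels[~seg1 & seg2] = "private_to_p2"
    labels[seg1 & seg2] = "shared"
    labels[~seg1 & ~seg2 & (fix1 != fix2)] = "fixed_difference"
    counts = {lab: int((labels == lab).sum()) for lab in SITE_LABELS}
    counts["monomorphic"] += m.extra_monomorphic
    return SiteClassification(pops=(pop1, pop2), labels=labels, counts=counts)


def classify_sites_venn(m: GenotypeMatrix, pops: list[str]) -> dict[str, int]:
    """Three-population Venn of polymorphism sharing plus pairwise fixed
    differences, in the style of a shared/private polymorphism diagram."""
    if len(pops) != 3:
        raise ValueError("venn classification needs exactly three populations")
    seg = []
    for p in pops:
        G = m.G[population_mask(m, p)]
        _check_complete(G)
        c = G.sum(axis=0)
        seg.append((c > 0) & (c < 2 * G.shape[0]))
    s1, s2, s3 = seg
    out = {
        f"private_{pops[0]}": int((s1 & ~s2 & ~s3).sum()),
        f"private_{pops[1]}": int((~s1 & s2 & ~s3).sum()),
        f"private_{pops[2]}": int((~s1 & ~s2 & s3).sum()),
        f"shared_{pops[0]}_{pops[1]}": int((s1 & s2 & ~s3).sum()),
        f"shared_{pops[0]}_{pops[2]}": int((s1 & ~s2 & s3).sum()),
        f"shared_{pops[1]}_{pops[2]}": int((~s1 & s2 & s3).sum()),
        f"shared_all": int((s1 & s2 & s3).sum()),
    }
    for i in range(3):
        for j in range(i + 1, 3):
            cls = classify_sites(m, pops[i], pops[j])
            out[f"fixed_{pops[i]}_{pops[j]}"] = cls.counts["fixed_difference"]
    return out


# ---------------------------------------------------------------------------
# sliding windows


def sliding_window(
    positions: np.ndarray,
    values: np.ndarray,
    size: int,
    step: int,
    mode: str = "bp",
    stat: str = "mean",
) -> pd.DataFrame:
    """Windowed summary of a positioned series.

    ``mode="bp"`` slides half-open ``[start, start + size)`` windows along the
    coordinate axis (windows with no datum are omitted); ``mode="snp"`` slides
    a fixed count of consecutive data points (only full windows are emitted).
    Returns columns ``start, end, n, value`` with half-open coordinates.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape:
        raise ValueError("positions and values must align")
    order = np.argsort(positions, kind="stable")
    positions, values = positions[order], values[order]
    rows = []
    if mode == "bp":
        if len(positions) == 0:
            return pd.DataFrame(columns=["start", "end", "n", "value"])
        lo, hi = int(positions.min()), int(positions.max())
        csum = np.concatenate([[0.0], np.cumsum(values)])
        for start in range(lo, hi + 1, step):
            i = np.searchsorted(positions, start, side="left")
            j = np.searchsorted(positions, start + size, side="left")
            if j > i:
                total = csum[j] - csum[i]
                rows.append((start, start + size, j - i,
                             total / (j - i) if stat == "mean" else total))
    elif mode == "snp":
        for i in range(0, len(positions) - size + 1, step):
            chunk = values[i:i + size]
            rows.append((
                int(positions[i]), int(positions[i + size - 1]) + 1, size,
                chunk.mean() if stat == "mean" else chunk.sum(),
            ))
    else:
        raise ValueError("mode must be 'bp' or 'snp'")
    return pd.DataFrame(rows, columns=["start", "end", "n", "value"])
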