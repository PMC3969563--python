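"""Folded site-frequency-spectrum demographic inference.

Single-population size histories are fitted to the folded SFS by maximum
multinomial likelihood: the expected spectrum under a history ``N(t)`` is
computed exactly (up to quadrature tolerance) from the coalescent, the
observed minor-allele-count histogram is treated as a multinomial draw from
the expected proportions, and nested models are compared by likelihood-ratio
test with nonparametric bootstrap confidence intervals.

Expected spectra
----------------
With ``n`` sampled chromosomes, the number-of-lineages process backward in
time is a pure death chain with rate ``k(k-1)/2 / nu(t)`` (time in units of
``2 N_ancestral`` generations, sizes relative to the ancestral size).  The
expected time spent with ``j`` ancestral lineages, ``E[T_j]``, is obtained
from the eigendecomposition of the standard death chain: within an epoch of
relative size ``nu(t)`` the state distribution is a mixture of terms
``exp(-c_m Lambda(t))`` where ``Lambda`` is the accumulated coalescent
intensity, so sojourn integrals reduce to closed forms (constant epochs) or
one-dimensional quadratures (exponential epochs).  The expected unfolded
spectrum then follows from the classical combinatorial identity

    E[xi_i]  proportional to  sum_j  j E[T_j] C(n-i-1, j-2) / C(n-1, j-1)

and is folded onto minor-allele counts, the ``i = n/2`` class counted once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist, qmc

from radpop.genotypes import GenotypeMatrix, TagLocation, draw_one_snp_per_tag

MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "standard_neutral": (),
    "two_epoch": ("nu", "T"),
    "exp_growth": ("nu", "T"),
    "bottle_growth": ("nuB", "nuF", "T"),
}

# bounds in natural units; optimization happens in log space
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu": (1e-2, 100.0),
    "nuB": (1e-2, 1000.0),
    "nuF": (1e-2, 100.0),
    "T": (1e-3, 8.0),
}

# nested model pairs for likelihood-ratio tests (simple -> complex)
NESTED: dict[tuple[str, str], int] = {
    ("standard_neutral", "two_epoch"): 2,
    ("standard_neutral", "exp_growth"): 2,
    ("standard_neutral", "bottle_growth"): 3,
    ("two_epoch", "bottle_growth"): 1,
    ("exp_growth", "bottle_growth"): 1,
}


@dataclass(frozen=True)
class DemographicModel:
    """A named single-population size history in coalescent units.

    Sizes are relative to the ancestral population; times are in units of
    ``2 N_ancestral`` generations, measured backward from the present.

    * ``standard_neutral`` -- constant size.
    * ``two_epoch(nu, T)`` -- instantaneous change to ``nu`` at time ``T``.
    * ``exp_growth(nu, T)`` -- exponential change reaching ``nu`` at present,
      starting from the ancestral size at time ``T``.
    * ``bottle_growth(nuB, nuF, T)`` -- instantaneous change to ``nuB`` at
      ``T``, then exponential change reaching ``nuF`` at present.
    """

    name: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_PARAMS:
            raise ValueError(f"unknown model {self.name!r}")
        expected = MODEL_PARAMS[self.name]
        if tuple(self.params) != expected:
            missing = set(expected) - set(self.params)
            extra = set(self.params) - set(expected)
            raise ValueError(f"model {self.name}: missing {missing or '{}'}, extra {extra or '{}'}")
        for k, v in self.params.items():
            if k == "T":
                if v < 0:
                    raise ValueError("T must be >= 0")
            elif v <= 0:
                raise ValueError(f"{k} must be > 0")

    # convenience constructors ------------------------------------------------

    @classmethod
    def standard_neutral(cls) -> "DemographicModel":
        return cls("standard_neutral")

    @classmethod
    def two_epoch(cls, nu: float, T: float) -> "DemographicModel":
        return cls("two_epoch", {"nu": nu, "T": T})

    @classmethod
    def exp_growth(cls, nu: float, T: float) -> "DemographicModel":
        return cls("exp_growth", {"nu": nu, "T": T})

    @classmethod
    def bottle_growth(cls, nuB: float, nuF: float, T: float) -> "DemographicModel":
        return cls("bottle_growth", {"nuB": nuB, "nuF": nuF, "T": T})

    @classmethod
    def from_vector(cls, name: str, vector: np.ndarray) -> "DemographicModel":
        return cls(name, dict(zip(MODEL_PARAMS[name], (float(v) for v in vector))))

    @property
    def k(self) -> int:
        return len(self.params)

    def epochs(self) -> list[tuple[float, float, float]]:
        """Epochs recent-to-past as (duration, nu_recent, nu_old); the
        ancestral constant-size-1 epoch is implicit."""
        p = self.params
        if self.name == "standard_neutral" or p.get("T", 0.0) == 0.0:
            return []
        if self.name == "two_epoch":
            return [(p["T"], p["nu"], p["nu"])]
        if self.name == "exp_growth":
            return [(p["T"], p["nu"], 1.0)]
        return [(p["T"], p["nuF"], p["nuB"])]

    # size and intensity functions (used by the simulator) --------------------

    def size_at(self, t: float) -> float:
        """Relative size nu(t) at time t back from the present."""
        t0 = 0.0
        for T_e, nu_r, nu_o in self.epochs():
            if t < t0 + T_e:
                u = (t - t0) / T_e
                return nu_r * (nu_o / nu_r) ** u
            t0 += T_e
        return 1.0

    def rescaled_time(self, t: float) -> float:
        """Coalescent intensity Lambda(t) = int_0^t ds / nu(s)."""
        lam, t0 = 0.0, 0.0
        for T_e, nu_r, nu_o in self.epochs():
            dt = min(max(t - t0, 0.0), T_e)
            if dt > 0:
                lam += _epoch_lambda(dt, T_e, nu_r, nu_o)
            t0 += T_e
        return lam + max(t - t0, 0.0)

    def real_time(self, lam: float) -> float:
        """Inverse of :meth:`rescaled_time`."""
        t0 = 0.0
        for T_e, nu_r, nu_o in self.epochs():
            dl = _epoch_lambda(T_e, T_e, nu_r, nu_o)
            if lam <= dl:
                return t0 + _epoch_lambda_inv(lam, T_e, nu_r, nu_o)
            lam -= dl
            t0 += T_e
        return t0 + lam


def _epoch_lambda(t: float, T_e: float, nu_r: float, nu_o: float) -> float:
    if nu_r == nu_o:
        return t / nu_r
    lg = np.log(nu_o / nu_r)
    return T_e / (nu_r * lg) * (1.0 - (nu_o / nu_r) ** (-t / T_e))


def _epoch_lambda_inv(lam: float, T_e: float, nu_r: float, nu_o: float) -> float:
    if nu_r == nu_o:
        return lam * nu_r
    lg = np.log(nu_o / nu_r)
    arg = 1.0 - lam * nu_r * lg / T_e
    return -T_e / lg * np.log(arg)


# ---------------------------------------------------------------------------
# folded SFS container


@dataclass
class FoldedSFS:
    """Counts of segregating sites by minor-allele count 1..floor(n/2)."""

    n_chrom: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n_chrom // 2:
            raise ValueError(
                f"need {self.n_chrom // 2} frequency classes for n = {self.n_chrom}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative class counts")

    @property
    def S(self) -> int:
        return int(round(self.counts.sum()))

    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def resample(self, rng: np.random.Generator) -> "FoldedSFS":
        """Nonparametric bootstrap: resample the S SNPs with replacement."""
        new = rng.multinomial(self.S, self.proportions())
        return FoldedSFS(self.n_chrom, new.astype(float))


def folded_afs(
    m: GenotypeMatrix,
    pop: str,
    one_per_tag: bool = False,
    tags: list[TagLocation] | None = None,
    seed: int = 0,
    exclude: list | None = None,
) -> FoldedSFS:
    """Folded spectrum of minor-allele counts for one population.

    ``exclude`` is a list of regions to drop before tallying -- either bare
    chromosome names or ``(chrom, start, end)`` with 1-based inclusive ends
    (used to remove the X chromosome and polymorphic inversions, whose
    genealogies violate the single-population model).  With ``one_per_tag``
    the spectrum is built from one random SNP per tag location.
    """
    sub = m.subset_population(pop)
    if exclude:
        keep = np.ones(sub.n_sites, dtype=bool)
        chroms = sub.sites["chrom"].to_numpy()
        pos = sub.sites["pos"].to_numpy()
        for region in exclude:
            if isinstance(region, str):
                keep &= chroms != region
            else:
                c, s, e = region
                keep &= ~((chroms == c) & (pos >= s) & (pos <= e))
        sub = sub.take_sites(keep)
        if tags is not None:
            tags = _remap_tags(tags, np.flatnonzero(keep))
    if one_per_tag:
        if tags is None:
            raise ValueError("one_per_tag requires tag locations")
        sub = draw_one_snp_per_tag(sub, tags, seed=seed)
    n = 2 * sub.n_samples
    ac = sub.alt_counts()
    mac = np.minimum(ac, n - ac)
    mac = mac[(mac > 0)]
    counts = np.bincount(mac, minlength=n // 2 + 1)[1: n // 2 + 1]
    return FoldedSFS(n_chrom=n, counts=counts.astype(float))


def _remap_tags(tags: list[TagLocation], kept: np.ndarray) -> list[TagLocation]:
    lookup = {int(old): new for new, old in enumerate(kept)}
    out = []
    for t in tags:
        idx = [lookup[j] for j in t.site_indices if j in lookup]
        if idx:
            out.append(TagLocation(t.tag_id, t.chrom, t.start, t.end, idx))
    return out


# ---------------------------------------------------------------------------
# expected spectra


@lru_cache(maxsize=32)
def _death_chain_eigen(n: int):
    """Eigendecomposition of the standard coalescent death chain on k=2..n.

    Returns (c, V) where ``c[j]`` is ``k(k-1)/2`` for ``k = j + 2`` and the
    columns of upper-triangular ``V`` are the right eigenvectors for
    eigenvalues ``-c``.  Accuracy for the sample sizes used here (n <= ~40)
    is verified against a matrix exponential in the test suite.
    """
    ks = np.arange(2, n + 1)
    c = ks * (ks - 1) / 2.0
    dim = n - 1
    V = np.zeros((dim, dim))
    for M in range(dim):
        V[M, M] = 1.0
        for k in range(M - 1, -1, -1):
            # row k of (A + c_M I) v = 0 with A upper-bidiagonal:
            # (c_M - c_k) v_k + c_{k+1} v_{k+1} = 0
            V[k, M] = c[k + 1] * V[k + 1, M] / (c[k] - c[M])
    return c, V


@lru_cache(maxsize=32)
def _sfs_weights(n: int) -> np.ndarray:
    """W[i, j]: probability that a branch present while ``j+2`` lineages
    exist subtends ``i+1`` of the n samples (Polanski-Kimmel weights)."""
    i = np.arange(1, n)            # derived-allele counts
    j = np.arange(2, n + 1)        # number of ancestral lineages
    lnum = gammaln(n - i[:, None]) - gammaln(j[None, :] - 1) - gammaln(n - i[:, None] - j[None, :] + 2)
    lden = gammaln(n) - gammaln(j[None, :]) - gammaln(n - j[None, :] + 1)
    with np.errstate(invalid="ignore"):
        W = np.exp(lnum - lden)
    # zero where the binomial is undefined (i too large for j lineages)
    W[n - i[:, None] - j[None, :] + 2 <= 0] = 0.0
    return W


_EXP_QUAD_PANELS = np.concatenate([[0.0], np.geomspace(1e-7, 1.0, 29)])
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(8)


def _epoch_sojourn_exp(q, c, V, T_e, nu_r, nu_o):
    """Sojourn integrals over an exponential-size epoch by panel quadrature."""
    edges = _EXP_QUAD_PANELS * T_e
    t_nodes = []
    w_nodes = []
    for a, b in zip(edges[:-1], edges[1:]):
        half = (b - a) / 2.0
        t_nodes.append(half * (_GL_NODES + 1.0) + a)
        w_nodes.append(half * _GL_WEIGHTS)
    t_nodes = np.concatenate(t_nodes)
    w_nodes = np.concatenate(w_nodes)
    lam = np.array([_epoch_lambda(t, T_e, nu_r, nu_o) for t in t_nodes])
    # P_j(t) = sum_m V[j, m] q_m exp(-c_m lam(t))
    E = np.exp(-np.outer(c, lam)) * q[:, None]     # (m, nodes)
    return V @ (E @ w_nodes)


def expected_sojourn_times(model: DemographicModel, n_chrom: int) -> np.ndarray:
    """E[T_j], expected real time spent with j = 2..n ancestral lineages."""
    if n_chrom < 2:
        raise ValueError("need n_chrom >= 2")
    c, V = _death_chain_eigen(n_chrom)
    dim = n_chrom - 1
    p = np.zeros(dim)
    p[-1] = 1.0                     # all mass at k = n
    total = np.zeros(dim)
    for T_e, nu_r, nu_o in model.epochs():
        # expand the epoch-start distribution in the eigenbasis; scaled time
        # runs 0 .. dlam locally within the epoch
        q = solve_triangular(V, p, lower=False)
        dlam = _epoch_lambda(T_e, T_e, nu_r, nu_o)
        if nu_r == nu_o:
            integrals = (1.0 - np.exp(-c * dlam)) * nu_r / c
            total += V @ (q * integrals)
        else:
            total += _epoch_sojourn_exp(q, c, V, T_e, nu_r, nu_o)
        p = V @ (q * np.exp(-c * dlam))
        p = np.clip(p, 0.0, None)
    # ancestral constant-size epoch: E[extra time with j lineages] = P(K >= j)/c_j
    survivor = np.cumsum(p[::-1])[::-1]
    total += survivor / c
    return total


def expected_folded_sfs(model: DemographicModel, n_chrom: int) -> np.ndarray:
    """Expected folded SFS proportions over minor-allele classes 1..n//2."""
    if n_chrom < 4:
        raise ValueError("need n_chrom >= 4")
    T_j = expected_sojourn_times(model, n_chrom)
    j = np.arange(2, n_chrom + 1)
    xi = _sfs_weights(n_chrom) @ (j * T_j)          # unfolded, i = 1..n-1
    half = n_chrom // 2
    eta = xi[:half].copy()
    for i in range(1, half + 1):
        if n_chrom - i != i:
            eta[i - 1] += xi[n_chrom - i - 1]
    total = eta.sum()
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError(f"expected SFS failed to integrate for {model}")
    return eta / total


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    model: DemographicModel
    loglik: float
    expected: np.ndarray
    at_bounds: bool = False
    n_starts: int = 1
    ci95: dict[str, tuple[float, float]] | None = None

    @property
    def params(self) -> dict[str, float]:
        return self.model.params


def multinomial_loglik(sfs: FoldedSFS, proportions: np.ndarray) -> float:
    """Multinomial log likelihood of the observed folded SFS (including the
    multinomial coefficient, so values are comparable across models)."""
    counts = sfs.counts
    const = gammaln(counts.sum() + 1) - gammaln(counts + 1).sum()
    with np.errstate(divide="ignore"):
        lp = np.where(counts > 0, counts * np.log(proportions), 0.0)
    return float(const + lp.sum())


def fit_demographic_model(
    sfs: FoldedSFS,
    model_name: str,
    starts: int = 20,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    x0: dict[str, float] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one size-history model to a folded SFS.

    Optimization is Nelder-Mead over log-transformed parameters with
    ``starts`` Latin-hypercube restarts inside the bounds (an explicit ``x0``
    adds one start at that point, useful for warm-started bootstrap refits).
    A fit whose optimum sits within 1% of a bound is flagged ``at_bounds``.
    """
    if sfs.S == 0:
        raise ValueError("cannot fit an empty spectrum")
    names = MODEL_PARAMS[model_name]
    if not names:
        props = expected_folded_sfs(DemographicModel.standard_neutral(), sfs.n_chrom)
        return FitResult(DemographicModel.standard_neutral(),
                         multinomial_loglik(sfs, props), props)

    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.log(np.array([bnds[p][0] for p in names]))
    hi = np.log(np.array([bnds[p][1] for p in names]))

    counts = sfs.counts
    const = gammaln(counts.sum() + 1) - gammaln(counts + 1).sum()

    def negloglik(logx: np.ndarray) -> float:
        # reflect-free penalty outside the box keeps Nelder-Mead inside
        penalty = np.sum(np.maximum(logx - hi, 0.0) ** 2 + np.maximum(lo - logx, 0.0) ** 2)
        z = np.clip(logx, lo, hi)
        model = DemographicModel.from_vector(model_name, np.exp(z))
        props = expected_folded_sfs(model, sfs.n_chrom)
        with np.errstate(divide="ignore"):
            lp = np.where(counts > 0, counts * np.log(props), 0.0)
        return -(const + lp.sum()) + 1e4 * penalty

    rng = np.random.default_rng(seed)
    points: list[np.ndarray] = []
    if starts > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=rng)
        points = [lo + (hi - lo) * row for row in sampler.random(starts)]
    if x0 is not None:
        points.insert(0, np.log(np.array([x0[p] for p in names])))
    if not points:
        raise ValueError("need starts > 0 or an explicit x0")

    best = None
    for p0 in points:
        res = minimize(
            negloglik, p0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    z = np.clip(best.x, lo, hi)
    model = DemographicModel.from_vector(model_name, np.exp(z))
    at_bounds = bool(np.any(z - lo < 0.01) or np.any(hi - z < 0.01))
    props = expected_folded_sfs(model, sfs.n_chrom)
    return FitResult(model, multinomial_loglik(sfs, props), props,
                     at_bounds=at_bounds, n_starts=len(points))


def compare_models_lrt(fits: list[FitResult]) -> "pd.DataFrame":
    """Rank fits by log likelihood; add likelihood-ratio tests for nested pairs.

    Non-nested pairs are reported by raw log likelihood only.  The LRT
    statistic is 2 * (loglik_complex - loglik_simple) against chi-square with
    df equal to the difference in parameter count.
    """
    import pandas as pd

    by_name = {f.model.name: f for f in fits}
    rows = []
    for f in sorted(fits, key=lambda f: -f.loglik):
        row = {
            "model": f.model.name,
            "k": f.model.k,
            "loglik": f.loglik,
            **{f"param_{k}": v for k, v in f.model.params.items()},
        }
        tests = []
        for (simple, complex_), df in NESTED.items():
            if complex_ == f.model.name and simple in by_name:
                stat = max(2.0 * (f.loglik - by_name[simple].loglik), 0.0)
                tests.append((simple, stat, df, float(chi2_dist.sf(stat, df))))
        if tests:
            simple, stat, df, p = min(tests, key=lambda t: t[2])
            row.update({"lrt_vs": simple, "lrt_stat": stat, "lrt_df": df, "lrt_p": p})
        rows.append(row)
    return pd.DataFrame(rows)


def best_model_by_lrt(fits: list[FitResult], alpha: float = 0.05) -> FitResult:
    """Parsimony-aware model choice: climb the nested-model ladder, accepting
    a more complex model only when the likelihood-ratio test rejects the
    simpler one at ``alpha``; non-nested alternatives with the same parameter
    count are compared by raw log likelihood."""
    by_k: dict[int, list[FitResult]] = {}
    for f in fits:
        by_k.setdefault(f.model.k, []).append(f)
    current = min(fits, key=lambda f: (f.model.k, -f.loglik))
    for k in sorted(by_k):
        if k <= current.model.k:
            continue
        candidates = sorted(by_k[k], key=lambda f: -f.loglik)
        for cand in candidates:
            df = NESTED.get((current.model.name, cand.model.name))
            if df is None:
                continue
            stat = max(2.0 * (cand.loglik - current.loglik), 0.0)
            if chi2_dist.sf(stat, df) < alpha:
                current = cand
                break
    return current


def bootstrap_ci(
    sfs: FoldedSFS,
    model_name: str,
    n_boot: int = 200,
    seed: int = 0,
    fit: FitResult | None = None,
    starts: int = 1,
) -> dict[str, tuple[float, float]]:
    """Percentile 95% intervals from nonparametric SNP bootstrap.

    SNPs are resampled with replacement (a multinomial redraw of the SFS),
    each replicate refitted warm-started at the point MLE plus ``starts``
    random restarts.  Replicates that fail to converge are dropped and
    counted in a warning.
    """
    if fit is None:
        fit = fit_demographic_model(sfs, model_name, seed=seed)
    names = MODEL_PARAMS[model_name]
    if not names:
        return {}
    rng = np.random.default_rng(seed)
    draws: list[list[float]] = []
    failures = 0
    for _ in range(n_boot):
        rep = sfs.resample(rng)
        try:
            refit = fit_demographic_model(
                rep, model_name, starts=starts,
                seed=int(rng.integers(2**31 - 1)), x0=fit.model.params,
            )
        except Exception:
            failures += 1
            continue
        draws.append([refit.model.params[p] for p in names])
    if failures:
        warnings.warn(f"{failures} bootstrap replicates failed to converge", stacklevel=2)
    arr = np.asarray(draws)
    return {
        p: (float(np.percentile(arr[:, i], 2.5)), float(np.percentile(arr[:, i], 97.5)))
        for i, p in enumerate(names)
    }
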