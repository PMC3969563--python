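"""Diversity, divergence, F-statistics and site classification."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from radpop.genotypes import group_tag_locations
from radpop.simulate import SimulationConfig, simulate_population, simulate_species_complex
from radpop.stats import (
    Constants,
    classify_sites,
    divergence_stats,
    diversity_stats,
    dxy_site_totals,
    fis_test,
    fst,
    individual_heterozygosity,
    ne_from_theta,
    nm_from_fst,
    divergence_time_years,
    sliding_window,
    tajimas_d,
    tajima_constants,
    watterson_theta,
    wc_fst_components,
    wc_fst_multilocus,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# published-table worked examples (inputs are the printed n, L, S, pi)

TABLE2 = [
    # (n_chrom, L, S, pi_x1e3, theta_x1e3, D)
    ("merus_kilifi", 24, 253_043, 4_135, 4.13, 4.38, -0.2255),
    ("gambiae_kilifi", 26, 172_655, 4_852, 8.07, 7.36, 0.3840),
    ("gambiae_all", 48, 172_655, 6_387, 8.42, 8.34, 0.0377),
    ("arabiensis_all", 72, 129_315, 5_137, 6.84, 8.20, -0.5846),
]


@pytest.mark.parametrize("name,n,L,S,pi3,theta3,D", TABLE2)
def test_watterson_theta_matches_published(name, n, L, S, pi3, theta3, D):
    assert watterson_theta(S, n, L) * 1e3 == pytest.approx(theta3, abs=0.005)


@pytest.mark.parametrize("name,n,L,S,pi3,theta3,D", TABLE2)
def test_tajimas_d_matches_published(name, n, L, S, pi3, theta3, D):
    # pi is printed to 3 s.f., so D is reproducible to ~1e-2
    d = tajimas_d(pi3 * 1e-3 * L, S, n)
    assert d == pytest.approx(D, abs=0.01)


# ---------------------------------------------------------------------------
# pi / theta / D mechanics


def brute_force_pi(G):
    """All-pairs chromosome comparison; the oracle for per-site pi."""
    alleles = np.concatenate([(G >= 1).astype(int)[:, None, :],
                              (G == 2).astype(int)[:, None, :]], axis=1)
    chroms = alleles.reshape(-1, G.shape[1])
    total = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(chroms.shape[0]), 2):
        total += (chroms[i] != chroms[j]).sum()
        npairs += 1
    return total / npairs


def test_pi_against_all_pairs_enumeration():
    rng = np.random.default_rng(5)
    G = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
    m = make_matrix(G)
    r = diversity_stats(m, "sp")
    assert r.pi_per_site * m.L == pytest.approx(brute_force_pi(G), rel=1e-12)


def test_pi_two_two_split():
    # 4 chromosomes as 2 pseudo-diploids, one site with a 2/2 allele split
    m = make_matrix(np.array([[2], [0]], dtype=np.int8))
    r = diversity_stats(m, "sp")
    assert r.pi_per_site == pytest.approx(4 / 6)


def test_monomorphic_matrix():
    m = make_matrix(np.zeros((4, 3), dtype=np.int8))
    with pytest.warns(UserWarning):
        r = diversity_stats(m, "sp")
    assert r.pi_per_site == 0
    assert r.theta_w_per_site == 0
    assert np.isnan(r.tajimas_d)


def test_tajimas_d_zero_when_pi_equals_theta():
    k = tajima_constants(10)
    S = 25
    assert tajimas_d(S / k["a1"], S, 10) == pytest.approx(0.0, abs=1e-12)


def test_unknown_population_is_fatal():
    m = make_matrix(np.ones((4, 3), dtype=np.int8))
    with pytest.raises(KeyError):
        diversity_stats(m, "nope")


# ---------------------------------------------------------------------------
# divergence


def test_dxy_fixed_difference():
    m = make_matrix(np.array([[2], [2], [0], [0]], dtype=np.int8),
                    species=["p1", "p1", "p2", "p2"])
    r = divergence_stats(m, "p1", "p2")
    assert r.dxy_per_site == pytest.approx(1.0)
    assert r.da_per_site == pytest.approx(1.0)


def test_dxy_identical_monomorphic():
    m = make_matrix(np.zeros((4, 5), dtype=np.int8),
                    species=["p1", "p1", "p2", "p2"])
    r = divergence_stats(m, "p1", "p2")
    assert r.dxy_per_site == 0.0


def test_dxy_against_enumeration():
    # p1 = 0.5, p2 = 0.25 at one site -> 0.5*0.75 + 0.25*0.5 = 0.5
    G1 = np.array([[1], [1]], dtype=np.int8)           # p = 0.5
    G2 = np.array([[1], [0]], dtype=np.int8)           # p = 0.25
    d = dxy_site_totals(G1, G2)
    assert d[0] == pytest.approx(0.5)
    # brute force over all inter-population chromosome pairs
    a1 = np.array([1, 0, 1, 0])
    a2 = np.array([1, 0, 0, 0])
    brute = np.mean([x != y for x in a1 for y in a2])
    assert d[0] == pytest.approx(brute)


def test_dxy_self_equals_uncorrected_pi():
    rng = np.random.default_rng(8)
    G = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
    p = G.sum(axis=0) / (2 * G.shape[0])
    np.testing.assert_allclose(dxy_site_totals(G, G), 2 * p * (1 - p))


def test_overlapping_pops_fatal():
    # "a" addresses a species, "y" a location; sample 1 belongs to both
    m = make_matrix(np.ones((4, 3), dtype=np.int8),
                    species=["a", "a", "b", "b"],
                    location=["x", "y", "y", "y"])
    with pytest.raises(ValueError, match="share samples"):
        divergence_stats(m, "a", "y")


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def hand_wc84(G, codes):
    """Independent scalar WC84 implementation (the formula written out)."""
    pops = np.unique(codes)
    r = len(pops)
    n_i = np.array([(codes == p).sum() for p in pops], float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    out = []
    for l in range(G.shape[1]):
        p_i = np.array([G[codes == p, l].sum() / (2 * n) for p, n in zip(pops, n_i)])
        h_i = np.array([(G[codes == p, l] == 1).mean() for p in pops])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out.append((a, b, c))
    return np.array(out).T


def test_wc84_components_match_hand_formula(two_pop_matrix):
    codes = np.array([0] * 10 + [1] * 10)
    a, b, c = wc_fst_components(two_pop_matrix.G, codes)
    ha, hb, hc = hand_wc84(two_pop_matrix.G, codes)
    np.testing.assert_allclose(a, ha)
    np.testing.assert_allclose(b, hb)
    np.testing.assert_allclose(c, hc)


def test_fst_fixed_difference_is_one():
    G = np.array([[2]] * 5 + [[0]] * 5, dtype=np.int8)
    assert wc_fst_multilocus(G, np.array([0] * 5 + [1] * 5)) == pytest.approx(1.0)


def test_fst_identical_pops_near_zero():
    # two pops drawn from the same allele frequencies: expectation ~ 0,
    # possibly slightly negative
    rng = np.random.default_rng(3)
    freqs = rng.uniform(0.1, 0.9, size=600)
    G = (rng.random((24, 600, 2)) < freqs[None, :, None]).sum(axis=2).astype(np.int8)
    theta = wc_fst_multilocus(G, np.array([0] * 12 + [1] * 12))
    assert abs(theta) < 0.03


def hudson_fst(G, codes):
    """Hudson (1992) estimator: 1 - Hw/Hb, ratio of sums over loci."""
    G1, G2 = G[codes == 0], G[codes == 1]
    n1, n2 = 2 * G1.shape[0], 2 * G2.shape[0]
    p1, p2 = G1.sum(0) / n1, G2.sum(0) / n2
    # mean within-pop heterozygosity (unbiased) and between-pop diversity
    hw = p1 * (1 - p1) * n1 / (n1 - 1) + p2 * (1 - p2) * n2 / (n2 - 1)
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    keep = hb > 0
    return 1 - hw[keep].sum() / hb[keep].sum()


def test_wc_agrees_with_hudson_on_balanced_design():
    cfg = SimulationConfig(seed=17, n_per_pop=12, n_tags=200,
                           n_locations=(2, 1, 1), migration=12.0)
    m, _ = simulate_species_complex(cfg)
    sub = m.subset_population("A")
    codes = (sub.samples["location"] == "loc2_A").to_numpy().astype(int)
    poly = sub.polymorphic_mask() & sub.is_variant
    G = sub.G[:, poly]
    assert abs(wc_fst_multilocus(G, codes) - hudson_fst(G, codes)) < 0.02


def test_fst_decreases_with_migration():
    values = []
    for mig in (4.0, 12.0, 48.0):
        reps = []
        for rep in range(3):
            cfg = SimulationConfig(seed=100 + rep, n_per_pop=8, n_tags=120,
                                   n_locations=(2, 1, 1), migration=mig)
            m, _ = simulate_species_complex(cfg)
            r = fst(m, ["loc1_A", "loc2_A"], n_perm=0)
            reps.append(r.reported)
        values.append(np.mean(reps))
    assert values[0] > values[1] > values[2]


def test_fst_median_of_subsets(two_pop_matrix):
    tags = group_tag_locations(two_pop_matrix)
    r = fst(two_pop_matrix, ["p1", "p2"], tags=tags, n_perm=99, n_subsets=5, seed=0)
    assert len(r.subset_estimates) == 5
    assert r.reported == float(np.median(r.subset_estimates))
    assert 0 < r.permutation_p <= 1


def test_small_pop_is_fatal():
    m = make_matrix(np.ones((3, 4), dtype=np.int8), species=["p1", "p2", "p2"])
    with pytest.raises(ValueError):
        fst(m, ["p1", "p2"], n_perm=0)


def test_permutation_p_uniform_under_null():
    """Permutation p-values over null splits pass a KS uniformity check."""
    rng = np.random.default_rng(77)
    pvals = []
    for _ in range(200):
        freqs = rng.uniform(0.1, 0.9, size=60)
        G = (rng.random((16, 60, 2)) < freqs[None, :, None]).sum(axis=2).astype(np.int8)
        m = make_matrix(G, species=["p1"] * 8 + ["p2"] * 8)
        r = fst(m, ["p1", "p2"], n_perm=99, seed=int(rng.integers(2**31)))
        pvals.append(r.permutation_p)
    assert kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# F_IS


def test_fis_negative_for_all_heterozygotes():
    m = make_matrix(np.ones((6, 20), dtype=np.int8))
    f, p = fis_test(m, "sp", n_perm=99, seed=0)
    assert f < 0


def test_fis_near_zero_at_hwe():
    col = np.array([2, 1, 1, 0] * 3, dtype=np.int8)   # exact HWE at p=0.5? p=0.5, Hobs=0.5
    m = make_matrix(np.tile(col[:, None], (1, 50)))
    f, p = fis_test(m, "sp", n_perm=199, seed=1)
    assert abs(f) < 0.05
    assert p > 0.1


def test_fis_recovers_inbreeding_truth():
    """Genotypes drawn with inbreeding F=0.2 recover F_IS within +-0.05."""
    rng = np.random.default_rng(12)
    F = 0.2
    n, s = 40, 500
    p = rng.uniform(0.2, 0.8, size=s)
    probs = np.stack([
        (1 - p) ** 2 + F * p * (1 - p),
        2 * p * (1 - p) * (1 - F),
        p**2 + F * p * (1 - p),
    ])
    G = np.array([[rng.choice(3, p=probs[:, l]) for l in range(s)]
                  for _ in range(n)], dtype=np.int8)
    m = make_matrix(G)
    f, pval = fis_test(m, "sp", n_perm=99, seed=2)
    assert f == pytest.approx(F, abs=0.05)
    assert pval < 0.05


def test_fis_undefined_without_polymorphism():
    m = make_matrix(np.zeros((4, 5), dtype=np.int8))
    with pytest.warns(UserWarning):
        f, p = fis_test(m, "sp", n_perm=10)
    assert np.isnan(f)


# ---------------------------------------------------------------------------
# site classification


def test_classification_labels():
    G = np.array([
        # private_p1, fixed, shared, monomorphic
        [1, 2, 1, 0],
        [0, 2, 0, 0],
        [0, 0, 1, 0],
        [0, 0, 0, 0],
    ], dtype=np.int8)
    m = make_matrix(G, species=["p1", "p1", "p2", "p2"])
    cls = classify_sites(m, "p1", "p2")
    assert list(cls.labels) == [
        "private_to_p1", "fixed_difference", "shared", "monomorphic"]
    assert cls.counts["shared"] == 1


# ---------------------------------------------------------------------------
# sliding windows


def test_constant_series_windows():
    w = sliding_window(np.arange(1, 101), np.full(100, 3.0), size=10, step=5,
                       mode="bp", stat="mean")
    assert (w["value"] == 3.0).all()


def test_snp_window_count():
    w = sliding_window(np.arange(30) * 7 + 1, np.arange(30.0), size=25, step=1,
                       mode="snp")
    assert len(w) == 6


def test_bp_window_matches_direct_computation():
    pos = np.array([1, 2, 5, 11, 12, 13, 20, 25, 26, 30])
    val = np.arange(10.0)
    w = sliding_window(pos, val, size=10, step=10, mode="bp", stat="sum")
    assert w.loc[0, "value"] == val[pos < 11].sum()
    # windows are half-open: pos 11 falls in the second window
    assert w.loc[1, "value"] == val[(pos >= 11) & (pos < 21)].sum()


def test_bad_window_size():
    with pytest.raises(ValueError):
        sliding_window(np.arange(5), np.arange(5.0), size=0, step=1)


# ---------------------------------------------------------------------------
# scalar conversions


def test_ne_conversion_one_million():
    assert ne_from_theta(0.0044, Constants()) == pytest.approx(1.0e6)


def test_nm_values():
    assert nm_from_fst(0.2) == pytest.approx(1.0)
    assert nm_from_fst(0.041) == pytest.approx(5.848, abs=1e-3)
    with pytest.raises(ValueError):
        nm_from_fst(0.0)


def test_divergence_time_scaling():
    # D_A = 2 mu T  ->  T = D_A / (2 mu)
    assert divergence_time_years(2.2e-3) == pytest.approx(1e5)


# ---------------------------------------------------------------------------
# individual heterozygosity


def test_individual_heterozygosity_values():
    G = np.zeros((2, 10), dtype=np.int8)
    G[1, :3] = 1
    m = make_matrix(G)
    het = individual_heterozygosity(m)
    assert het.iloc[0] == 0.0
    assert het.iloc[1] == pytest.approx(0.3)
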