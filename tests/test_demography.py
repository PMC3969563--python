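"""Folded SFS construction, expected spectra, model fitting and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm, solve_triangular

from radpop.demography import (
    DemographicModel,
    FoldedSFS,
    best_model_by_lrt,
    bootstrap_ci,
    compare_models_lrt,
    expected_folded_sfs,
    expected_sojourn_times,
    fit_demographic_model,
    folded_afs,
    multinomial_loglik,
    _death_chain_eigen,
)
from radpop.genotypes import group_tag_locations
from radpop.simulate import SimulationConfig, simulate_population

from conftest import make_matrix


# ---------------------------------------------------------------------------
# folded SFS construction


def test_folded_tally_simple():
    # n = 4 chromosomes; alt count 3 folds to minor count 1, alt count 2
    # sits in the n/2 class (counted once)
    m = make_matrix(np.array([[2, 1], [1, 1]], dtype=np.int8))
    sfs = folded_afs(m, "sp")
    assert sfs.n_chrom == 4
    assert sfs.counts.tolist() == [1.0, 1.0]


def test_folded_conservation():
    rng = np.random.default_rng(1)
    G = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
    m = make_matrix(G)
    sfs = folded_afs(m, "sp")
    assert sfs.S == m.S


def test_folded_hand_tally_six_chromosomes():
    # 3 diploids; alt counts per site: 1, 2, 3, 4, 5, 6(fixed), 0
    cols = [
        [1, 0, 0], [1, 1, 0], [1, 1, 1], [2, 1, 1], [2, 2, 1], [2, 2, 2], [0, 0, 0],
    ]
    G = np.array(cols, dtype=np.int8).T
    sfs = folded_afs(make_matrix(G), "sp")
    # minor counts: 1, 2, 3, 2, 1 -> eta = (2, 2, 1)
    assert sfs.counts.tolist() == [2.0, 2.0, 1.0]


def test_folded_excludes_regions_and_chromosomes():
    G = np.ones((4, 4), dtype=np.int8)
    G[0] = [0, 0, 0, 0]
    m = make_matrix(G, positions=[10, 20, 30, 40], chrom=["X", "2L", "2L", "2L"])
    sfs = folded_afs(m, "sp", exclude=["X", ("2L", 25, 35)])
    assert sfs.S == 2


def test_one_snp_per_tag_spectrum():
    m, _ = simulate_population(SimulationConfig(seed=8, n_per_pop=6, n_tags=50))
    tags = group_tag_locations(m)
    sfs = folded_afs(m, "sim", one_per_tag=True, tags=tags, seed=0)
    assert sfs.S <= len(tags)


# ---------------------------------------------------------------------------
# expected spectra


def test_neutral_closed_form():
    for n in (6, 24, 48):
        props = expected_folded_sfs(DemographicModel.standard_neutral(), n)
        xi = 1.0 / np.arange(1, n)
        eta = xi[: n // 2].copy()
        for i in range(1, n // 2 + 1):
            if n - i != i:
                eta[i - 1] += xi[n - i - 1]
        np.testing.assert_allclose(props, eta / eta.sum(), atol=1e-12)


def test_two_epoch_nu_one_degenerates_to_neutral():
    p = expected_folded_sfs(DemographicModel.two_epoch(1.0, 0.4), 24)
    q = expected_folded_sfs(DemographicModel.standard_neutral(), 24)
    np.testing.assert_allclose(p, q, atol=1e-6)


def test_bottle_growth_flat_equals_two_epoch():
    p = expected_folded_sfs(DemographicModel.bottle_growth(2.0, 2.0, 0.4), 24)
    q = expected_folded_sfs(DemographicModel.two_epoch(2.0, 0.4), 24)
    np.testing.assert_allclose(p, q, atol=1e-9)


def test_eigen_transition_matches_matrix_exponential():
    """Death-chain eigendecomposition vs scipy expm, at several times."""
    n = 24
    c, V = _death_chain_eigen(n)
    dim = n - 1
    A = np.zeros((dim, dim))
    for i in range(dim):
        A[i, i] = -c[i]
        if i + 1 < dim:
            A[i, i + 1] = c[i + 1]
    p0 = np.zeros(dim)
    p0[-1] = 1.0
    q = solve_triangular(V, p0, lower=False)
    for tau in (0.01, 0.1, 0.5, 2.0):
        via_eigen = V @ (q * np.exp(-c * tau))
        via_expm = expm(A * tau) @ p0
        np.testing.assert_allclose(via_eigen, via_expm, atol=1e-8)


def test_two_epoch_matches_msprime_oracle():
    """Branch-mode folded SFS from msprime genealogies (MC oracle)."""
    import msprime

    n_anc = 10_000
    demo = msprime.Demography()
    demo.add_population(name="p", initial_size=2 * n_anc)
    demo.add_population_parameters_change(time=0.4 * 2 * n_anc,
                                          initial_size=n_anc, population="p")
    reps = msprime.sim_ancestry(samples={"p": 12}, demography=demo, ploidy=2,
                                num_replicates=3000, random_seed=7)
    tot = np.zeros(12)
    per_rep = []
    for ts in reps:
        sfs = ts.allele_frequency_spectrum(mode="branch", polarised=False,
                                           span_normalise=False)[1:13]
        tot += sfs
        per_rep.append(sfs)
    obs = tot / tot.sum()
    mc_se = np.std([r / r.sum() for r in np.array(per_rep)], axis=0) / np.sqrt(3000)
    exp = expected_folded_sfs(DemographicModel.two_epoch(2.0, 0.4), 24)
    assert np.all(np.abs(obs - exp) < np.maximum(3 * mc_se * 3, 0.01))


@settings(max_examples=25)
@given(
    st.sampled_from(["two_epoch", "exp_growth", "bottle_growth"]),
    st.floats(0.05, 20.0),
    st.floats(0.05, 20.0),
    st.floats(0.01, 4.0),
    st.sampled_from([5, 8, 24]),
)
def test_expected_proportions_sum_to_one(name, nu1, nu2, T, n):
    if name == "bottle_growth":
        model = DemographicModel.bottle_growth(nu1, nu2, T)
    elif name == "two_epoch":
        model = DemographicModel.two_epoch(nu1, T)
    else:
        model = DemographicModel.exp_growth(nu1, T)
    props = expected_folded_sfs(model, n)
    assert props.shape == (n // 2,)
    assert (props > 0).all()
    assert props.sum() == pytest.approx(1.0, abs=1e-8)


def test_exp_growth_vanishing_change_is_neutral():
    p = expected_folded_sfs(DemographicModel.exp_growth(1.0 + 1e-9, 0.5), 24)
    q = expected_folded_sfs(DemographicModel.standard_neutral(), 24)
    np.testing.assert_allclose(p, q, atol=1e-4)


def test_growth_shifts_mass_to_singletons():
    n = 24
    singleton = [
        expected_folded_sfs(DemographicModel.exp_growth(nu, 0.2), n)[0]
        for nu in (1.0, 3.0, 10.0, 30.0)
    ]
    assert np.all(np.diff(singleton) > 0)


def test_sojourn_times_neutral_closed_form():
    T_j = expected_sojourn_times(DemographicModel.standard_neutral(), 10)
    j = np.arange(2, 11)
    np.testing.assert_allclose(T_j, 2.0 / (j * (j - 1)), atol=1e-12)


def test_size_history_roundtrip():
    model = DemographicModel.bottle_growth(5.0, 0.5, 0.8)
    for t in (0.0, 0.1, 0.5, 0.79, 1.5, 4.0):
        lam = model.rescaled_time(t)
        assert model.real_time(lam) == pytest.approx(t, abs=1e-10)


# ---------------------------------------------------------------------------
# fitting


def test_fit_self_consistency():
    """Fitting the model's own expected proportions recovers the params."""
    n = 24
    true = DemographicModel.two_epoch(1.95, 0.421)
    sfs = FoldedSFS(n, expected_folded_sfs(true, n) * 1e4)
    fit = fit_demographic_model(sfs, "two_epoch", starts=20, seed=1)
    assert fit.model.params["nu"] == pytest.approx(1.95, rel=1e-3)
    assert fit.model.params["T"] == pytest.approx(0.421, rel=1e-3)


def test_fit_neutral_has_no_params():
    sfs = FoldedSFS(8, np.array([10.0, 5.0, 3.0, 2.0]))
    fit = fit_demographic_model(sfs, "standard_neutral")
    assert fit.model.params == {}
    assert np.isfinite(fit.loglik)


def test_fit_empty_spectrum_fatal():
    with pytest.raises(ValueError):
        fit_demographic_model(FoldedSFS(8, np.zeros(4)), "two_epoch")


def test_neutral_simulation_two_epoch_mle_near_one():
    rng = np.random.default_rng(5)
    props = expected_folded_sfs(DemographicModel.standard_neutral(), 24)
    sfs = FoldedSFS(24, rng.multinomial(3000, props).astype(float))
    fit = fit_demographic_model(sfs, "two_epoch", starts=10, seed=2)
    ci = bootstrap_ci(sfs, "two_epoch", n_boot=60, seed=3, fit=fit)
    lo, hi = ci["nu"]
    assert lo <= 1.0 <= hi


def test_loglik_is_multinomial():
    sfs = FoldedSFS(8, np.array([7.0, 2.0, 1.0, 0.0]))
    props = np.array([0.5, 0.3, 0.15, 0.05])
    from scipy.stats import multinomial

    expected = multinomial.logpmf([7, 2, 1, 0], 10, props)
    assert multinomial_loglik(sfs, props) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# model comparison


def test_lrt_identical_fits():
    sfs = FoldedSFS(24, expected_folded_sfs(DemographicModel.standard_neutral(), 24) * 1e3)
    f0 = fit_demographic_model(sfs, "standard_neutral")
    f1 = fit_demographic_model(sfs, "two_epoch", starts=6, seed=0)
    table = compare_models_lrt([f0, f1])
    row = table[table["model"] == "two_epoch"].iloc[0]
    assert row["lrt_stat"] == pytest.approx(0.0, abs=0.05)
    assert row["lrt_p"] > 0.9


def test_strong_growth_rejects_neutral():
    """Power: strong recent growth rejects the neutral model."""
    rng = np.random.default_rng(11)
    props = expected_folded_sfs(DemographicModel.exp_growth(20.0, 0.2), 24)
    rejections = 0
    n_rep = 20
    for _ in range(n_rep):
        sfs = FoldedSFS(24, rng.multinomial(800, props).astype(float))
        f0 = fit_demographic_model(sfs, "standard_neutral")
        f1 = fit_demographic_model(sfs, "two_epoch", starts=4,
                                   seed=int(rng.integers(2**31)))
        table = compare_models_lrt([f0, f1])
        if table[table["model"] == "two_epoch"]["lrt_p"].iloc[0] < 0.05:
            rejections += 1
    assert rejections >= 0.95 * n_rep


def test_best_model_prefers_parsimony():
    sfs = FoldedSFS(24, expected_folded_sfs(DemographicModel.standard_neutral(), 24) * 800)
    fits = [fit_demographic_model(sfs, name, starts=4, seed=0)
            for name in ("standard_neutral", "two_epoch")]
    assert best_model_by_lrt(fits).model.name == "standard_neutral"


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_interval_width_shrinks_with_S():
    rng = np.random.default_rng(9)
    true = DemographicModel.two_epoch(2.0, 0.4)
    props = expected_folded_sfs(true, 24)
    widths = []
    for S in (200, 2000):
        sfs = FoldedSFS(24, rng.multinomial(S, props).astype(float))
        fit = fit_demographic_model(sfs, "two_epoch", starts=8, seed=1)
        ci = bootstrap_ci(sfs, "two_epoch", n_boot=60, seed=2, fit=fit)
        widths.append(ci["nu"][1] - ci["nu"][0])
    assert widths[1] < widths[0]


def test_degenerate_sfs_interval_collapses():
    # every resample of a one-class spectrum is identical
    sfs = FoldedSFS(8, np.array([50.0, 0.0, 0.0, 0.0]))
    fit = fit_demographic_model(sfs, "two_epoch", starts=4, seed=0)
    ci = bootstrap_ci(sfs, "two_epoch", n_boot=20, seed=1, fit=fit, starts=0)
    lo, hi = ci["nu"]
    assert hi - lo <= 1e-6 * max(1.0, hi)
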