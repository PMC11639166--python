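"""Stationary-law formulas: shells, partition function, Moran link, modes."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.special import gammaln
from scipy.stats import poisson

from tkmodel import (
    AlphaParameters,
    DistributionTable,
    MoranParameters,
    RateParameters,
    ScaledParameters,
    alpha_from_rates,
    boundary_mass,
    dirichlet_multinomial_pmf,
    local_modes,
    mode_set,
    moran_stationary,
    moran_transitions,
    ode_fixed_point,
    partition_function,
    pi_tilde_conditional,
    pi_tilde_full,
    pi_tilde_table,
    symmetric_exact_pi,
    total_mass_stationary,
)
from tkmodel.stationary import _compositions


def shells(n, d):
    return list(_compositions(n, d))


# -- alpha -------------------------------------------------------------------


@pytest.mark.parametrize(
    "kp,expected",
    [((1.0, 1.0), (0.1, 0.1)), ((1.0, 1.1), (0.1, 0.1 / 1.1))],
)
def test_alpha_under_volume_scaling(kp, expected):
    rates = ScaledParameters(D=0.01, V=20, kappa_prime=kp).to_rates()
    assert alpha_from_rates(rates).alpha == pytest.approx(expected, rel=1e-14)


def test_alpha_symmetric_reduction_and_tag():
    rates = RateParameters(d=3, kappa=(2.0, 2.0, 2.0), lam=(1.0, 2.0, 3.0), delta=0.5)
    ap = alpha_from_rates(rates)
    assert ap.source == "symmetric"
    want = tuple(0.5 * l / (2.0 * 6.0) for l in rates.lam)
    assert ap.alpha == pytest.approx(want)


# -- Dirichlet-multinomial ---------------------------------------------------


def test_dm_single_draw_is_normalized_alpha():
    alpha = AlphaParameters((0.3, 0.5, 1.2))
    for j, e in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
        assert dirichlet_multinomial_pmf(e, 1, alpha) == pytest.approx(
            alpha.alpha[j] / sum(alpha.alpha)
        )


def test_dm_unit_concentrations_are_uniform():
    alpha = AlphaParameters((1.0, 1.0))
    for a1 in range(5):
        assert dirichlet_multinomial_pmf((a1, 4 - a1), 4, alpha) == pytest.approx(0.2)


def test_dm_normalizes_over_shells():
    rng = np.random.default_rng(3)
    for _ in range(8):
        d = int(rng.integers(2, 5))
        n = int(rng.integers(1, 21 if d < 4 else 12))
        alpha = AlphaParameters(tuple(rng.uniform(0.05, 4.0, size=d)))
        total = sum(dirichlet_multinomial_pmf(a, n, alpha) for a in shells(n, d))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_dm_rejects_mass_mismatch():
    with pytest.raises(ValueError):
        dirichlet_multinomial_pmf((1, 1), 3, AlphaParameters((1.0, 1.0)))


# -- partition function ------------------------------------------------------


def test_partition_function_base_cases():
    alpha = (0.2, 0.7)
    assert partition_function(alpha, (1.3, 0.4), 0) == 1.0
    want = (1.3 * 0.2 + 0.4 * 0.7) / 0.9
    assert partition_function(alpha, (1.3, 0.4), 1) == pytest.approx(want, rel=1e-12)


def test_partition_function_symmetric_is_power():
    for n in (0, 3, 17):
        assert partition_function((0.4, 0.9, 0.1), (2.0, 2.0, 2.0), n) == pytest.approx(
            2.0**n, rel=1e-12
        )


def test_partition_function_routes_agree():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(0, 300))
        alpha = tuple(rng.uniform(0.05, 3.0, size=2))
        kappa = tuple(rng.uniform(0.1, 2.0, size=2))
        bf = partition_function(alpha, kappa, n, "bruteforce")
        hg = partition_function(alpha, kappa, n, "hypergeometric")
        assert hg == pytest.approx(bf, rel=1e-10)


def test_partition_function_hypergeometric_needs_two_species():
    with pytest.raises(ValueError):
        partition_function((1.0, 1.0, 1.0), (1.0, 1.0, 1.0), 3, "hypergeometric")


# -- shell-conditional law ---------------------------------------------------


def test_pi_tilde_symmetric_reduces_to_dirichlet_multinomial(symmetric_rates):
    alpha = alpha_from_rates(symmetric_rates)
    for a in [(0, 7), (3, 4), (12, 0), (5, 5)]:
        dm = dirichlet_multinomial_pmf(a, sum(a), alpha)
        assert pi_tilde_conditional(a, symmetric_rates) == pytest.approx(dm, rel=1e-12)


def test_pi_tilde_single_molecule_shell(asymmetric_rates):
    al = alpha_from_rates(asymmetric_rates).alpha
    k = asymmetric_rates.kappa
    want = k[0] * al[0] / (k[0] * al[0] + k[1] * al[1])
    assert pi_tilde_conditional((1, 0), asymmetric_rates) == pytest.approx(want, rel=1e-12)


def test_pi_tilde_normalizes_on_shells(asymmetric_rates):
    for n in (1, 13, 60):
        total = sum(pi_tilde_conditional((i, n - i), asymmetric_rates) for i in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)
    rates3 = RateParameters(d=3, kappa=(0.5, 0.6, 0.7), lam=(1.0, 2.0, 0.5), delta=0.2)
    for n in (1, 7, 15):
        total = sum(pi_tilde_conditional(a, rates3) for a in shells(n, 3))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_pi_tilde_full_composes_poisson_with_independent_formula(symmetric_rates):
    """Symmetric case against the exact product law assembled from scipy
    pieces (Poisson pmf times log-gamma Dirichlet-multinomial)."""
    p = symmetric_rates
    al = alpha_from_rates(p).alpha
    mu = p.mean_mass
    for a in [(0, 0), (2, 3), (0, 17), (25, 14)]:
        n = sum(a)
        lp = (
            poisson.logpmf(n, mu)
            + gammaln(n + 1) - gammaln(a[0] + 1) - gammaln(a[1] + 1)
            + gammaln(sum(al)) - gammaln(n + sum(al))
            + gammaln(al[0] + a[0]) - gammaln(al[0])
            + gammaln(al[1] + a[1]) - gammaln(al[1])
        )
        assert pi_tilde_full(a, p) == pytest.approx(math.exp(lp), rel=1e-12)
        assert symmetric_exact_pi(a, p) == pytest.approx(math.exp(lp), rel=1e-12)


def test_pi_tilde_mass_marginal_is_poisson(asymmetric_rates):
    for n in (0, 5, 37):
        shell_sum = sum(pi_tilde_full((i, n - i), asymmetric_rates) for i in range(n + 1))
        assert shell_sum == pytest.approx(total_mass_stationary(n, asymmetric_rates), rel=1e-12)


def test_symmetric_exact_refuses_asymmetric_rates(asymmetric_rates):
    with pytest.raises(ValueError):
        symmetric_exact_pi((1, 1), asymmetric_rates)


def test_low_concentration_shells_are_u_shaped():
    """Both concentrations below 1 pile shell mass onto the boundary."""
    rates = ScaledParameters(D=0.01, V=20, kappa_prime=(1.0, 1.0)).to_rates()
    for n in (10, 40):
        pmf = [pi_tilde_conditional((i, n - i), rates) for i in range(n + 1)]
        assert np.argmax(pmf) in (0, n)
        assert min(pmf[0], pmf[n]) > max(pmf[1:n])


# -- Moran model -------------------------------------------------------------


def test_neutral_moran_is_dirichlet_multinomial():
    mp = MoranParameters(n=9, kappa=(1.4, 1.4, 1.4), v=0.2, p=(0.5, 0.25, 0.25))
    alpha = tuple(mp.n * mp.v * pj / 1.4 for pj in mp.p)
    for a in [(9, 0, 0), (3, 3, 3), (0, 4, 5)]:
        want = dirichlet_multinomial_pmf(a, 9, AlphaParameters(alpha))
        assert moran_stationary(a, mp) == pytest.approx(want, rel=1e-12)


def solved_stationary(mp):
    """Independent oracle: null space of the finite-chain rate matrix."""
    states = shells(mp.n, mp.d)
    index = {s: k for k, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))
    for s in states:
        for target, rate in moran_transitions(s, mp):
            Q[index[s], index[target]] += rate
            Q[index[s], index[s]] -= rate
    ns = null_space(Q.T)
    assert ns.shape[1] == 1
    v = ns[:, 0]
    v = v / v.sum()
    return states, v


@pytest.mark.parametrize(
    "mp",
    [
        MoranParameters(n=6, kappa=(1.0, 1.7), v=0.4, p=(0.3, 0.7)),
        MoranParameters(n=5, kappa=(0.8, 1.1, 1.9), v=0.25, p=(0.2, 0.5, 0.3)),
        MoranParameters(n=4, kappa=(2.0, 0.5, 1.0), v=1.3, p=(0.6, 0.2, 0.2)),
    ],
)
def test_moran_matches_numerically_solved_chain(mp):
    states, v = solved_stationary(mp)
    tv = 0.5 * sum(abs(moran_stationary(s, mp) - v[k]) for k, s in enumerate(states))
    assert tv <= 1e-10


def test_moran_correspondence_with_tk_conditional_law(symmetric_rates):
    """With mutation rates tied to the inflow/outflow identity and symmetric
    rates, the Moran stationary law is the TK shell-conditional law.

    The Moran reproduction rate is kappa/n per ordered pair while the TK
    catalysis rate is kappa per pair, so the shell-restricted TK chain is a
    Moran chain with fitnesses n*kappa."""
    p = symmetric_rates
    n = 11
    s = p.total_inflow
    v = p.delta  # v*p_j = delta*lam_j/sum(lam) with p_j = lam_j/sum(lam)
    mp = MoranParameters(
        n=n, kappa=tuple(n * k for k in p.kappa), v=v, p=tuple(l / s for l in p.lam)
    )
    for i in range(n + 1):
        assert moran_stationary((i, n - i), mp) == pytest.approx(
            pi_tilde_conditional((i, n - i), p), rel=1e-12
        )


# -- total mass, modes, tables ----------------------------------------------


def test_total_mass_mean_under_scaling():
    rates = ScaledParameters(D=0.01, V=20, kappa_prime=(1.0, 1.0)).to_rates()
    assert rates.mean_mass == pytest.approx(40.0)
    grid = np.arange(200)
    pmf = [total_mass_stationary(n, rates) for n in grid]
    assert int(np.argmax(pmf)) in (39, 40)  # Poisson mode at integer mean ties


def test_mode_set_symmetric_has_swap_symmetry():
    rates = ScaledParameters(D=0.01, V=20, kappa_prime=(1.0, 1.0)).to_rates()
    modes = mode_set(rates)
    assert modes == {(a2, a1) for a1, a2 in modes}
    assert all(0 in a for a in modes)  # boundary modes in the DV<d regime


def test_mode_set_unimodal_regime_tracks_fixed_point():
    sp = ScaledParameters(D=0.01, V=1000, kappa_prime=(1.0, 1.01))
    rates = sp.to_rates()
    modes = mode_set(rates)
    assert len(modes) == 1
    (mode,) = modes
    fp = ode_fixed_point(rates).a_star
    assert abs(mode[0] - fp[0]) < 0.05 * sum(fp)
    assert abs(mode[1] - fp[1]) < 0.05 * sum(fp)


def test_mode_set_rejects_insufficient_truncation():
    rates = ScaledParameters(D=0.01, V=20, kappa_prime=(1.0, 1.0)).to_rates()
    with pytest.raises(ValueError):
        mode_set(rates, eps=1e-4)


def test_local_modes_sit_on_the_boundary_in_dit_regime(dit_scaled):
    rates = dit_scaled.to_rates()
    modes = local_modes(rates)
    assert modes
    assert all(a[0] == 0 or a[1] == 0 for a in modes)


def test_boundary_mass_monotone_in_asymmetry():
    """Growing kappa'_2/kappa'_1 concentrates the proposed law ever harder
    on the boundary resting states (DV < d fixed)."""
    masses = [
        boundary_mass(ScaledParameters(D=0.01, V=20, kappa_prime=(1.0, k2)).to_rates())
        for k2 in (1.0, 1.001, 1.01, 1.05, 1.1)
    ]
    assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))


def test_higher_boundary_mode_is_the_faster_species(dit_scaled):
    rates = dit_scaled.to_rates()
    n = int(rates.mean_mass)
    assert pi_tilde_full((0, n), rates) > pi_tilde_full((n, 0), rates)


def test_distribution_table_roundtrip(tmp_path, dit_scaled):
    table = pi_tilde_table(dit_scaled.to_rates())
    tsv = tmp_path / "pi.tsv"
    table.to_tsv(tsv)
    back = DistributionTable.from_tsv(tsv, truncation_mass=table.truncation_mass,
                                      ceiling=table.ceiling)
    assert back.prob == table.prob  # decimal text round-trip is exact
    js = tmp_path / "pi.json"
    table.to_json(js)
    back2 = DistributionTable.from_json(js)
    assert back2.prob == table.prob
    assert back2.truncation_mass == table.truncation_mass


def test_distribution_table_validates():
    with pytest.raises(ValueError):
        DistributionTable({(0, 0): 0.5, (1, 0): 0.4})  # does not sum to 1
    with pytest.raises(ValueError):
        DistributionTable({(0, 0): 1.5, (1, 0): -0.5})
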