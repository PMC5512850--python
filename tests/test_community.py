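import numpy as np
import pytest

import mutustab as ms
from mutustab.community import fixed_point_residual, per_capita_growth
from mutustab.networks import BipartiteNetwork


# ------------------------------------------------------------- meta/presets

def test_meta_validation():
    with pytest.raises(ValueError):
        ms.MetaParameters(rho_p=1.0)
    with pytest.raises(ValueError):
        ms.MetaParameters(gamma0=-0.1)
    with pytest.raises(ValueError):
        ms.MetaParameters(mutualism="parasitic")


def test_presets_complete_and_consistent():
    assert set(ms.PRESETS) == set("ABCDEFGH")
    for name, p in ms.PRESETS.items():
        meta = ms.MetaParameters.from_preset(name)
        assert meta.rho_p == p.rho_p and meta.mutualism == p.mutualism
    # overrides win
    meta = ms.MetaParameters.from_preset("A", gamma0=0.07)
    assert meta.gamma0 == 0.07


# ------------------------------------------------------------- building blocks

def test_build_competition_structure():
    beta = ms.build_competition(6, 0.2, delta_b=0.1, rng_seed=0)
    assert np.allclose(np.diag(beta), 1.0)
    off = beta[~np.eye(6, dtype=bool)]
    assert (off >= 0.2 * 0.9 - 1e-12).all() and (off <= 0.2 * 1.1 + 1e-12).all()


def test_build_competition_no_spread():
    beta = ms.build_competition(4, 0.3, delta_b=0.0, rng_seed=0)
    off = beta[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 0.3)


def test_build_competition_rejects_rho_one():
    with pytest.raises(ValueError):
        ms.build_competition(4, 1.0)
    beta = ms.build_competition(4, 1.0, allow_unstable=True)
    assert np.allclose(np.diag(beta), 1.0)


def test_build_mutualism_support(sparse_net):
    gp, ga = ms.build_mutualism(sparse_net, 0.2, delta_c=0.1, rng_seed=1)
    a = sparse_net.incidence
    assert (gp[a == 0] == 0).all() and (ga[a.T == 0] == 0).all()
    on = gp[a == 1]
    assert (on >= 0.2 * 0.9 - 1e-12).all() and (on <= 0.2 * 1.1 + 1e-12).all()
    # scale prefactor
    gp2, _ = ms.build_mutualism(sparse_net, 0.2, delta_c=0.1, rng_seed=1, scale=0.5)
    assert np.allclose(gp2, 0.5 * gp)


def test_choose_saturation_obligatory():
    h_p, h_a = ms.choose_saturation("obligatory_animals", 50, 0.25)
    assert h_p == 0.25
    assert h_a == pytest.approx(0.75 / (50 * 0.25 + 1 - 0.25))
    h_p2, h_a2 = ms.choose_saturation("facultative", 50, 0.25, saturation=2.0)
    assert h_p2 == h_a2 == 2.0


def test_draw_abundances_ranges():
    n = ms.draw_abundances(2000, delta_n=0.15, nbar=3.0, rng_seed=0)
    assert n.min() >= 3.0 * 0.85 and n.max() <= 3.0 * 1.15
    assert n.mean() == pytest.approx(3.0, rel=0.01)
    ln = ms.draw_abundances(20000, delta_n=0.3, nbar=2.0,
                            distribution="lognormal", rng_seed=0)
    assert ln.mean() == pytest.approx(2.0, rel=0.02)
    with pytest.raises(ValueError):
        ms.draw_abundances(5, distribution="gamma")


def test_mutualistic_term_closed_form():
    gamma = np.array([[0.5, 0.0]])
    h = np.array([0.2])
    n = np.array([1.0, 7.0])
    m, z = ms.mutualistic_term(gamma, h, n)
    # z = 0.2 * 0.5 = 0.1; M = flux/(1+z) = 0.5/1.1
    assert z[0] == pytest.approx(0.1)
    assert m[0] == pytest.approx(0.5 / 1.1)


def test_mutualistic_term_linear_limit():
    gamma = np.array([[0.5, 0.3]])
    n = np.array([2.0, 1.0])
    m, z = ms.mutualistic_term(gamma, np.array([0.0]), n)
    assert m[0] == pytest.approx(1.3) and z[0] == 0.0


def test_mutualistic_term_saturates():
    gamma = np.array([[1.0]])
    h = np.array([0.5])
    big, _ = ms.mutualistic_term(gamma, h, np.array([1e9]))
    assert big[0] == pytest.approx(1 / 0.5, rel=1e-6)  # ceiling 1/h


# ------------------------------------------------------------- assembly

def test_assembled_equilibrium_is_fixed_point(community_a):
    assert fixed_point_residual(community_a) < 1e-10
    assert np.allclose(ms.full_rhs(community_a, community_a.n_star), 0.0,
                       atol=1e-8)


def test_assembly_deterministic(sparse_net):
    meta = ms.MetaParameters.from_preset("A", gamma0=0.1)
    c1 = ms.assemble_community(sparse_net, meta, rng_seed=5)
    c2 = ms.assemble_community(sparse_net, meta, rng_seed=5)
    assert np.array_equal(c1.alpha, c2.alpha)
    assert np.array_equal(c1.gamma_p, c2.gamma_p)


def test_facultative_alpha_positive(community_a):
    assert (community_a.alpha_p > 0).all()
    assert (community_a.alpha_a > 0).all()
    assert (community_a.regime_p == "weak").all()


def test_obligatory_signs_and_regime(community_obligatory):
    com = community_obligatory
    assert (com.alpha_a < 0).all(), "animals must be obligate"
    assert (com.alpha_p > 0).all()
    assert (com.z_a > 3).all(), "animal saturation factors must exceed 3"
    assert (com.regime_a == "strong").all()
    assert fixed_point_residual(com) < 1e-10


def test_obligatory_violation_raised(sparse_net):
    # unit abundance ratio cannot support obligate animals at gamma0 = 0.1
    meta = ms.MetaParameters.from_preset("E", nbar_p=1.0)
    with pytest.raises(ms.RegimeViolationError):
        ms.assemble_community(sparse_net, meta, rng_seed=0)


def test_obligatory_feasibility_bound_value():
    b = ms.obligatory_feasibility_bound(50, 0.25, 0.1, d_min=1.0)
    assert b == pytest.approx((4 * (50 * 0.25 + 0.75) / 0.1) ** 2)
    assert b == pytest.approx(280900.0)
    with pytest.raises(ValueError):
        ms.obligatory_feasibility_bound(50, 0.25, 0.0)


def test_gamma_zero_decouples_guilds(sparse_net):
    meta = ms.MetaParameters.from_preset("A", gamma0=0.0)
    com = ms.assemble_community(sparse_net, meta, rng_seed=3)
    assert np.allclose(com.gamma_p, 0) and np.allclose(com.gamma_a, 0)
    assert np.allclose(com.alpha_p, com.beta_p @ com.n_p)


def test_per_capita_growth_sign_structure(community_a):
    # doubling everyone's abundance makes every per-capita growth negative
    g = per_capita_growth(community_a, 2.0 * community_a.n_star)
    assert (g < 0).all()


# ------------------------------------------------------------- rescaling

def test_rescale_units_identity_and_involution(community_a):
    com = community_a
    out = ms.rescale_units(com.beta_p, com.beta_a, com.gamma_p, com.gamma_a,
                           com.h_p, com.h_a, com.n_p, com.n_a)
    # already unit-diagonal: rescaling is the identity
    assert np.allclose(out["beta_p"], com.beta_p)
    assert np.allclose(out["n_p"], com.n_p)

    rng = np.random.default_rng(0)
    dp = rng.uniform(0.5, 2.0, com.s_plants)
    da = rng.uniform(0.5, 2.0, com.s_animals)
    beta_p = com.beta_p * dp[None, :]
    beta_a = com.beta_a * da[None, :]
    gamma_p = com.gamma_p * da[None, :]
    gamma_a = com.gamma_a * dp[None, :]
    out = ms.rescale_units(beta_p, beta_a, gamma_p, gamma_a,
                           com.h_p, com.h_a, com.n_p / dp, com.n_a / da)
    assert np.allclose(out["beta_p"], com.beta_p)
    assert np.allclose(out["gamma_p"], com.gamma_p)
    assert np.allclose(out["n_p"], com.n_p)


def test_rescale_units_preserves_fixed_point():
    net = BipartiteNetwork(np.ones((3, 3), dtype=np.int8))
    rng = np.random.default_rng(1)
    # non-unit intraspecific competition
    beta_p = 0.1 * rng.uniform(0.5, 1.5, (3, 3))
    beta_a = 0.1 * rng.uniform(0.5, 1.5, (3, 3))
    np.fill_diagonal(beta_p, rng.uniform(1.0, 3.0, 3))
    np.fill_diagonal(beta_a, rng.uniform(1.0, 3.0, 3))
    gamma_p = 0.05 * rng.uniform(0.5, 1.5, (3, 3))
    gamma_a = 0.05 * rng.uniform(0.5, 1.5, (3, 3))
    h = np.full(3, 0.5)
    n_p = rng.uniform(0.5, 1.5, 3)
    n_a = rng.uniform(0.5, 1.5, 3)
    alpha_p, alpha_a, *_ = ms.solve_growth_rates(
        beta_p, beta_a, gamma_p, gamma_a, h, h, n_p, n_a)
    out = ms.rescale_units(beta_p, beta_a, gamma_p, gamma_a, h, h, n_p, n_a,
                           alpha_p, alpha_a)
    # the rescaled system has the rescaled abundances as its fixed point
    m_p, _ = ms.mutualistic_term(out["gamma_p"], out["h_p"], out["n_a"])
    g_p = out["alpha_p"] - out["beta_p"] @ out["n_p"] + m_p
    assert np.allclose(g_p, 0.0, atol=1e-12)
    assert np.allclose(np.diag(out["beta_p"]), 1.0)
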