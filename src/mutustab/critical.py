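"""Critical direct competition below which mutualism reduces the effective one.

Mutualism has two opposite effects on the effective competition within a
guild: it couples species through shared partners (which adds effective
facilitation and lowers rho^eff) but it also feeds everyone through the
partner guild's mean field (which adds effective competition).  The balance
defines a critical direct competition rho_c: for rho < rho_c mutualism is
net facilitative (rho^eff < rho), for rho > rho_c it is net competitive.

First-order perturbation theory around the mean-field competition matrix
gives a closed form that depends only on the network topology and on
S_0 = (1 - rho)/rho.  Writing M for the regime-dependent correction matrix
(plants' guild; exchange guilds for the animals'),

    weak mutualism:    M_ij = n_ij - d_i d_j / (S_0^A + S^A)
    strong mutualism:  M_ij = (1/d_i^2) [ sum_k a_ik a_jk / d_k^2
                               - d_i (sum_k a_jk / d_k^2) / (S_0^A + S^A) ]

with n_ij the number of shared partners and d the degrees, the first-order
shift of rho^eff changes sign at

    rho_c = (S u - t) / ((S - 1) t),   u = (1/S) sum_ij M_ij,  t = tr M,

which is scale invariant (the gamma0^2 prefactor of the correction cancels).
Both regimes give exactly rho_c = 1 on a fully connected network, so fully
connected mutualism is always (to first order) net facilitative.  The module
also provides a direct numerical route: the self-consistent root of
rho^eff(rho) = rho on assembled communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .community import MetaParameters, assemble_community
from .config import RHO_CRIT_TOL, FIXED_POINT_ITER_TOL
from .effective import effective_system, DegenerateSystemError
from .linearize import equivalent_lv
from .networks import BipartiteNetwork, connectance, random_bipartite

logger = logging.getLogger(__name__)

__all__ = [
    "correction_matrix",
    "RhoCrit",
    "rho_crit_closed_form",
    "rho_eff_of_rho",
    "rho_crit_numeric",
    "rho_crit_fixed_point",
    "rho_crit_zscore",
]


def correction_matrix(
    net: BipartiteNetwork,
    rho_other: float,
    guild: str = "plants",
    regime: str = "weak",
) -> np.ndarray:
    """Regime correction matrix M of the focal guild (scale factors dropped).

    ``regime`` selects the saturation state of the partner guild feeding the
    focal one: "weak" (linear response), "strong" (saturated partners, the
    1/d^2 damping appears on both sides) or "weak_strong" (focal guild weak,
    partners strong: the obligatory-for-animals case seen from the plants).
    """
    a = net.incidence.astype(float)
    if guild == "animals":
        a = a.T
    s_other = a.shape[1]
    d = a.sum(axis=1)
    d_other = a.sum(axis=0)
    if (d == 0).any() or (d_other == 0).any():
        raise ValueError("correction matrix undefined with unconnected species")
    if not 0 < rho_other < 1:
        raise ValueError("partner-guild competition must lie in (0, 1)")
    s0 = (1 - rho_other) / rho_other
    denom = s0 + s_other
    if regime == "weak":
        shared = a @ a.T
        return shared - np.outer(d, d) / denom
    if regime in ("strong", "weak_strong"):
        w = a / d_other[None, :] ** 2  # partner columns damped by 1/d_k^2
        shared = w @ a.T
        col = a @ (1.0 / d_other**2)
        m = shared - np.outer(d, col) / denom
        if regime == "strong":
            m = m / d[:, None] ** 2
        return m
    raise ValueError(f"unknown regime {regime!r}")


@dataclass
class RhoCrit:
    rho_c: float
    censored: str  # "", "at_one" (facilitative everywhere) or "below_zero"
    u: float
    t: float


def rho_crit_closed_form(
    net: BipartiteNetwork,
    rho_other: float | None = None,
    guild: str = "plants",
    regime: str = "weak",
) -> RhoCrit:
    """Critical direct competition from the first-order closed form.

    rho_c = (S u - t)/((S - 1) t) with u the mean and t the trace of the
    correction matrix.  When the returned value falls outside (0, 1) it is
    clamped with a censoring flag: "at_one" means the first-order shift is
    facilitative at every rho in (0, 1) (typical of the fully connected
    network), "below_zero" that it is competitive everywhere (very sparse
    strong mutualism).  M depends on rho_other only through the mean-field
    denominator; by default the partner guild is evaluated at rho_other =
    the tentative rho_c self-consistently (both guilds share rho), iterating
    a few times from 0.5.
    """
    a = net.incidence
    s = net.s_plants if guild == "plants" else net.s_animals

    def rc_at(ro: float) -> tuple[float, float, float]:
        m = correction_matrix(net, ro, guild=guild, regime=regime)
        u = float(m.sum()) / s
        t = float(np.trace(m))
        return (s * u - t) / ((s - 1) * t), u, t

    if rho_other is not None:
        rc, u, t = rc_at(rho_other)
    else:
        # both guilds at the same rho: iterate rho_other = rho_c
        ro = 0.5
        rc, u, t = rc_at(ro)
        for _ in range(100):
            ro_new = min(max(rc, 1e-6), 1 - 1e-6)
            rc, u, t = rc_at(ro_new)
            if abs(ro_new - ro) < 1e-10:
                break
            ro = ro_new
    if rc >= 1:
        return RhoCrit(1.0, "at_one", u, t)
    if rc <= 0:
        return RhoCrit(0.0, "below_zero", u, t)
    return RhoCrit(float(rc), "", u, t)


def rho_eff_of_rho(
    net: BipartiteNetwork,
    meta: MetaParameters,
    rho: float,
    guild: str = "plants",
    deterministic: bool = True,
    rng_seed=None,
):
    """rho^eff of the focal guild at direct competition rho (both guilds).

    With ``deterministic`` the heterogeneity draws are switched off
    (delta_b = delta_c = delta_n = 0) so the map rho -> rho^eff depends only
    on the topology and the meta-parameters.
    """
    kwargs = dict(rho_p=rho, rho_a=rho)
    if deterministic:
        kwargs.update(delta_b=0.0, delta_c=0.0, delta_n=0.0)
    meta_r = MetaParameters(
        gamma0=meta.gamma0, saturation=meta.saturation,
        nbar_p=meta.nbar_p, nbar_a=meta.nbar_a,
        mutualism=meta.mutualism,
        abundance_distribution=meta.abundance_distribution,
        label=meta.label, **kwargs,
    )
    com = assemble_community(net, meta_r, rng_seed=rng_seed)
    eff = effective_system(equivalent_lv(com))
    return eff.guild(guild).rho_eff


def rho_crit_numeric(
    net: BipartiteNetwork,
    meta: MetaParameters,
    guild: str = "plants",
    bracket: tuple[float, float] = (1e-3, 0.999),
    tol: float = RHO_CRIT_TOL,
    deterministic: bool = True,
    rng_seed=None,
) -> RhoCrit:
    """Numerical critical competition: root of g(rho) = rho^eff(rho) - rho.

    Uses deterministic draws by default so the root is a property of the
    topology.  g < 0 everywhere (net facilitative at every rho, e.g. fully
    connected weak mutualism) is censored "at_one"; g > 0 everywhere (net
    competitive at every rho, e.g. very sparse strong mutualism) is censored
    "below_zero".  The expected orientation is facilitative below the root
    and competitive above; the opposite orientation is logged as a hint of
    multiple roots.
    """
    def g(rho: float) -> float:
        return rho_eff_of_rho(net, meta, rho, guild=guild,
                              deterministic=deterministic,
                              rng_seed=rng_seed) - rho

    lo, hi = bracket
    g_lo = g(lo)
    # Near rho = 1 the partner-guild inversion can make the effective
    # intraspecific competition non-positive; shrink the upper end to the
    # largest rho where the reduction is valid.
    g_hi = None
    for _ in range(60):
        try:
            g_hi = g(hi)
            break
        except DegenerateSystemError:
            hi = lo + 0.9 * (hi - lo)
    if g_hi is None:
        raise DegenerateSystemError(
            "effective reduction invalid on the whole bracket"
        )
    if g_lo < 0 and g_hi < 0:
        return RhoCrit(1.0, "at_one", np.nan, np.nan)
    if g_lo > 0 and g_hi > 0:
        return RhoCrit(0.0, "below_zero", np.nan, np.nan)
    if g_lo > 0 > g_hi:
        logger.warning(
            "rho^eff - rho falls through zero (unusual orientation); "
            "possible multiple roots"
        )
    rc = brentq(g, lo, hi, xtol=tol)
    return RhoCrit(float(rc), "", np.nan, np.nan)


def rho_crit_fixed_point(
    net: BipartiteNetwork,
    meta: MetaParameters,
    guild: str = "plants",
    rho_init: float = 0.5,
    tol: float = FIXED_POINT_ITER_TOL,
    damping: float = 1.0,
    max_iter: int = 200,
    deterministic: bool = True,
    rng_seed=None,
) -> float:
    """Self-consistent point of rho^eff(rho) = rho by damped secant iteration.

    The crossing from net facilitation to net competition is a repelling
    fixed point of the naive forward iteration rho <- rho^eff(rho) (the map
    crosses the diagonal from below), so the root of g(rho) = rho^eff - rho
    is found with secant steps instead; mainly a cross-check that the result
    does not depend on the initialisation.
    """
    lo, hi = 1e-6, 1 - 1e-6

    def g(rho: float) -> float:
        return rho_eff_of_rho(net, meta, rho, guild=guild,
                              deterministic=deterministic,
                              rng_seed=rng_seed) - rho

    r0 = min(max(rho_init, lo), hi)
    r1 = min(max(r0 + (0.05 if r0 < 0.5 else -0.05), lo), hi)
    g0, g1 = g(r0), g(r1)
    for _ in range(max_iter):
        if abs(r1 - r0) < tol:
            return float(r1)
        if g1 == g0:
            break
        step = damping * g1 * (r1 - r0) / (g1 - g0)
        r0, g0 = r1, g1
        r1 = min(max(r1 - step, lo), hi)
        g1 = g(r1)
    logger.warning("secant iteration did not converge to %g", tol)
    return float(r1)


def rho_crit_zscore(
    net: BipartiteNetwork,
    n_null: int = 100,
    rng_seed=None,
    guild: str = "plants",
    regime: str = "weak",
    rho_other: float | None = None,
) -> pd.Series:
    """Z-score of the closed-form rho_c against a connectance-matched null.

    The null ensemble is Erdos-Renyi bipartite at the observed connectance
    (networks with unconnected species are redrawn).  Positive Z means the
    observed network sustains facilitative mutualism up to a larger direct
    competition than random networks of equal density.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    obs = rho_crit_closed_form(net, rho_other=rho_other,
                               guild=guild, regime=regime).rho_c
    kappa = connectance(net)
    nulls = []
    attempts = 0
    while len(nulls) < n_null and attempts < 50 * n_null:
        attempts += 1
        nn = random_bipartite(net.s_plants, net.s_animals, kappa, rng)
        if nn.has_empty_species():
            continue
        nulls.append(rho_crit_closed_form(nn, rho_other=rho_other,
                                          guild=guild, regime=regime).rho_c)
    nulls = np.array(nulls)
    mu, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    z = (obs - mu) / sd if sd > 0 else np.nan
    return pd.Series({
        "rho_c": obs, "null_mean": mu, "null_std": sd,
        "z": z, "n_null": len(nulls),
    })
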