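"""Equivalent Lotka-Volterra system at the equilibrium and stability analysis.

Close to the fixed point, the saturating model is equivalent to a
Lotka-Volterra system with effective mutualistic strengths

    gamma^LV_ik = gamma_ik / (1 + z_i)^2

(the derivative of the saturating term at the equilibrium) and effective
growth rates alpha^LV_i = alpha_i + m_i, where the saturation offset
m_i = (1/h_i) (z_i/(1+z_i))^2 restores the fixed point.  The two systems
share the equilibrium and the Jacobian there, so local stability can be
assessed on the community matrix J = diag(N*) A of the LV system, and global
stability is guaranteed when A is diagonally stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .community import Community, assemble_community, MetaParameters, RegimeViolationError
from .config import GAMMA_BRACKET_TOL

__all__ = [
    "EquivalentLV",
    "equivalent_lv",
    "local_stability",
    "diagonal_stability_certificate",
    "critical_gamma_bracket",
    "GammaBracket",
]


@dataclass
class EquivalentLV:
    """Linearization of a community around its equilibrium."""

    community: Community
    z_p: np.ndarray
    z_a: np.ndarray
    gamma_lv_p: np.ndarray
    gamma_lv_a: np.ndarray
    m_p: np.ndarray
    m_a: np.ndarray
    alpha_lv_p: np.ndarray
    alpha_lv_a: np.ndarray
    A: np.ndarray  # full (S^P+S^A)^2 LV interaction matrix
    J: np.ndarray  # community matrix diag(N*) A

    @property
    def s_plants(self) -> int:
        return len(self.z_p)

    @property
    def n_star(self) -> np.ndarray:
        return self.community.n_star


def equivalent_lv(com: Community) -> EquivalentLV:
    z_p, z_a = com.z_p, com.z_a
    gamma_lv_p = com.gamma_p / (1 + z_p[:, None]) ** 2
    gamma_lv_a = com.gamma_a / (1 + z_a[:, None]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        m_p = np.where(com.h_p > 0, (z_p / (1 + z_p)) ** 2 / com.h_p, 0.0)
        m_a = np.where(com.h_a > 0, (z_a / (1 + z_a)) ** 2 / com.h_a, 0.0)
    alpha_lv_p = com.alpha_p + m_p
    alpha_lv_a = com.alpha_a + m_a
    sp, sa = com.s_plants, com.s_animals
    A = np.zeros((sp + sa, sp + sa))
    A[:sp, :sp] = -com.beta_p
    A[:sp, sp:] = gamma_lv_p
    A[sp:, :sp] = gamma_lv_a
    A[sp:, sp:] = -com.beta_a
    J = com.n_star[:, None] * A
    return EquivalentLV(
        community=com, z_p=z_p, z_a=z_a,
        gamma_lv_p=gamma_lv_p, gamma_lv_a=gamma_lv_a,
        m_p=m_p, m_a=m_a,
        alpha_lv_p=alpha_lv_p, alpha_lv_a=alpha_lv_a,
        A=A, J=J,
    )


def lv_rhs(lv: EquivalentLV, n: np.ndarray) -> np.ndarray:
    """Right-hand side of the equivalent LV system."""
    alpha = np.concatenate([lv.alpha_lv_p, lv.alpha_lv_a])
    return n * (alpha + lv.A @ n)


def local_stability(lv: EquivalentLV) -> tuple[bool, float]:
    """Verdict and leading real part of the community-matrix spectrum."""
    if not np.isfinite(lv.J).all():
        raise FloatingPointError("non-finite entries in the community matrix")
    lead = float(np.linalg.eigvals(lv.J).real.max())
    return lead < 0, lead


def diagonal_stability_certificate(A: np.ndarray) -> str:
    """Tri-state diagonal-stability check.

    Returns "certified_stable" when a positive diagonal D with DA + A^T D
    negative definite is found (symmetric-part test, then a diagonal-scaling
    search), "certified_not" when a cheap necessary condition fails (a
    non-negative diagonal entry, or a 2x2 principal minor of -A that is not
    positive), and "inconclusive" otherwise.  The search is a sufficient
    procedure, not a complete LMI solver.
    """
    A = np.asarray(A, float)
    s = A.shape[0]
    d = np.diag(A)
    if (d >= 0).any():
        return "certified_not"
    # -A must be a P-matrix: check 2x2 principal minors
    minors = np.outer(d, d) - A * A.T
    off = ~np.eye(s, dtype=bool)
    if (minors[off] <= 0).any():
        return "certified_not"

    def max_eig(logd: np.ndarray) -> float:
        dd = np.exp(logd)
        m = dd[:, None] * A + A.T * dd[None, :]
        return float(np.linalg.eigvalsh(m).max())

    if max_eig(np.zeros(s)) < 0:
        return "certified_stable"
    res = minimize(max_eig, np.zeros(s), method="Nelder-Mead",
                   options={"maxiter": 200 * s, "xatol": 1e-3, "fatol": 1e-10})
    if res.fun < 0:
        return "certified_stable"
    return "inconclusive"


@dataclass
class GammaBracket:
    """Stability boundaries of the mutualistic strength gamma0."""

    gamma_minus: float | None
    gamma_plus: float | None
    all_stable: bool
    scan: pd.DataFrame  # columns gamma0, leading, verdict


def _scan_verdict(net, meta: MetaParameters, draws, gamma0: float):
    """Stability verdict at one gamma0, reusing frozen random draws."""
    try:
        com = _assemble_with_draws(net, meta, draws, gamma0)
    except RegimeViolationError:
        return "invalid", np.nan
    stable, lead = local_stability(equivalent_lv(com))
    return ("stable" if stable else "unstable"), lead


def _freeze_draws(net, meta: MetaParameters, rng_seed):
    """One realization of the random variables, reused along a gamma0 sweep."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    sp, sa = net.s_plants, net.s_animals
    return dict(
        b_p=rng.uniform(1 - meta.delta_b, 1 + meta.delta_b, (sp, sp)),
        b_a=rng.uniform(1 - meta.delta_b, 1 + meta.delta_b, (sa, sa)),
        c_p=rng.uniform(1 - meta.delta_c, 1 + meta.delta_c, (sp, sa)),
        c_a=rng.uniform(1 - meta.delta_c, 1 + meta.delta_c, (sa, sp)),
        e_p=rng.uniform(1 - meta.delta_n, 1 + meta.delta_n, sp),
        e_a=rng.uniform(1 - meta.delta_n, 1 + meta.delta_n, sa),
    )


def _assemble_with_draws(net, meta: MetaParameters, draws, gamma0: float) -> Community:
    from .community import (
        choose_saturation, solve_growth_rates, Community,
    )
    beta_p = meta.rho_p * draws["b_p"].copy()
    np.fill_diagonal(beta_p, 1.0)
    beta_a = meta.rho_a * draws["b_a"].copy()
    np.fill_diagonal(beta_a, 1.0)
    scale = 1.0 / np.sqrt(meta.nbar_p * meta.nbar_a)
    a = net.incidence.astype(float)
    gamma_p = gamma0 * scale * draws["c_p"] * a
    gamma_a = gamma0 * scale * draws["c_a"] * a.T
    h_p, h_a = choose_saturation(meta.mutualism, net.s_animals, meta.rho_a,
                                 meta.saturation)
    hp = np.full(net.s_plants, h_p)
    ha = np.full(net.s_animals, h_a)
    n_p = meta.nbar_p * draws["e_p"]
    n_a = meta.nbar_a * draws["e_a"]
    alpha_p, alpha_a, z_p, z_a, reg_p, reg_a = solve_growth_rates(
        beta_p, beta_a, gamma_p, gamma_a, hp, ha, n_p, n_a, meta.mutualism
    )
    return Community(
        net=net, meta=meta, beta_p=beta_p, beta_a=beta_a,
        gamma_p=gamma_p, gamma_a=gamma_a, h_p=hp, h_a=ha,
        n_p=n_p, n_a=n_a, alpha_p=alpha_p, alpha_a=alpha_a,
        z_p=z_p, z_a=z_a, regime_p=reg_p, regime_a=reg_a,
    )


def critical_gamma_bracket(
    net,
    meta: MetaParameters,
    rng_seed=None,
    grid: np.ndarray | None = None,
    tol: float = GAMMA_BRACKET_TOL,
) -> GammaBracket:
    """Bracket the stability boundaries gamma0^- < gamma0^+ by bisection.

    A logarithmic grid (default 50 points over [1e-3, 1e2]) is scanned with a
    single frozen realization of the random draws; sign changes of the
    leading-eigenvalue verdict are then bisected to ``tol`` in gamma0.  When
    no unstable point is found the community is reported all_stable on the
    scanned range (the pure-competition end gamma0 -> 0 is always a stable
    anchor for rho < 1).
    """
    if grid is None:
        grid = np.logspace(-3, 2, 50)
    draws = _freeze_draws(net, meta, rng_seed)
    rows = []
    verdicts = []
    for g in grid:
        v, lead = _scan_verdict(net, meta, draws, g)
        verdicts.append(v)
        rows.append((g, lead, v))
    scan = pd.DataFrame(rows, columns=["gamma0", "leading", "verdict"])

    unstable_idx = [i for i, v in enumerate(verdicts) if v == "unstable"]
    if not unstable_idx:
        return GammaBracket(None, None, True, scan)

    def bisect(lo, hi, want_stable_low: bool) -> float:
        # invariant: verdict(lo) != verdict(hi), both valid
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            v, _ = _scan_verdict(net, meta, draws, mid)
            stable_mid = v != "unstable"
            if stable_mid == want_stable_low:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    first_u = unstable_idx[0]
    last_u = unstable_idx[-1]
    gamma_minus = None
    gamma_plus = None
    if first_u > 0 and verdicts[first_u - 1] == "stable":
        gamma_minus = bisect(grid[first_u - 1], grid[first_u], True)
    elif first_u == 0:
        gamma_minus = grid[0]  # unstable from the start of the scan
    if last_u + 1 < len(grid) and verdicts[last_u + 1] == "stable":
        gamma_plus = bisect(grid[last_u], grid[last_u + 1], False)
    return GammaBracket(gamma_minus, gamma_plus, False, scan)


def choose_gamma0(
    nets,
    meta: MetaParameters,
    frac: float = 0.5,
    rng_seed=None,
    fallback: float | None = None,
) -> float:
    """Ensemble gamma0 policy: a fraction of the smallest stable range.

    Simulations are run at a gamma0 that is stable for every network in the
    ensemble: frac times the minimum lower stability boundary.  When no
    network shows an instability window on the scan range, the preset
    fallback value is used (mutualism is then stable at any probed strength).
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    minima = []
    for net in nets:
        br = critical_gamma_bracket(net, meta, rng_seed=rng)
        if br.gamma_minus is not None:
            minima.append(br.gamma_minus)
    if minima:
        return frac * min(minima)
    return fallback if fallback is not None else meta.gamma0
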