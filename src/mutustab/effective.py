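"""Per-guild effective competition, feasibility threshold and vulnerabilities.

Eliminating the animals from the linearized two-guild system leaves a
single-guild competitive system for the plants,

    C^P = beta^P - gamma^LV,P (beta^A)^-1 gamma^LV,A,
    p^P = alpha^LV,P + gamma^LV,P (beta^A)^-1 alpha^LV,A,

with C^P n^P = p^P at the equilibrium (and symmetrically for animals).  After
renormalizing the diagonal of C to one, the effective interspecific
competition rho^eff follows from the leading eigenvalue, S^eff =
(1 - rho^eff)/rho^eff is the biodiversity scale it sets, and the
vulnerability of species i,

    eta_i = 1 - p_i / (<p, v1> v1_i)

(v1 the unit-norm Perron eigenvector of C), measures the deficit of its
productivity relative to the optimal profile.  max_i eta_i <= eta_c =
S^eff/(S^eff + S) is the feasibility condition: it is sufficient for all
abundances to be positive, and under random perturbations it is very nearly
necessary as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EFFECTIVE_RESIDUAL_TOL
from .linearize import EquivalentLV

__all__ = [
    "GuildEffective",
    "EffectiveSystem",
    "effective_system",
    "rho_eff",
    "s_eff",
    "eta_crit",
    "vulnerabilities",
    "leading_eigensystem",
]


class DegenerateSystemError(ValueError):
    """Raised when the effective system has no usable Perron structure."""


def leading_eigensystem(C: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Leading eigenvalue and right eigenvector of a (possibly mildly
    non-symmetric) effective competition matrix.

    Returns (lambda1, v1, degenerate): v1 is scaled to unit 2-norm with
    positive sum; ``degenerate`` flags a complex leading pair or a
    non-positive eigenvector (Perron positivity failure).

    The mode of interest is the one with a positive eigenvector.  For a
    competition matrix (non-negative off-diagonal) that is the Perron mode,
    which also has the largest eigenvalue; when mutualism turns the effective
    off-diagonal negative (net facilitation) the positive-eigenvector mode
    drops below the others, so the selection is "largest eigenvalue among
    real modes with a strictly positive eigenvector", falling back to the
    largest real part (flagged degenerate) when no such mode exists.
    """
    vals, vecs = np.linalg.eig(C)

    def positive_vec(idx: int) -> np.ndarray | None:
        lam = vals[idx]
        if abs(lam.imag) > 1e-9 * max(1.0, abs(lam.real)):
            return None
        v = vecs[:, idx].real
        if v.sum() < 0:
            v = -v
        nrm = np.linalg.norm(v)
        if nrm == 0:
            return None
        v = v / nrm
        return v if (v > 0).all() else None

    order = np.argsort(-vals.real)
    for idx in order:
        v = positive_vec(int(idx))
        if v is not None:
            return float(vals[idx].real), v, False

    # no positive mode: report the leading one and flag it
    idx = int(order[0])
    lam = vals[idx]
    v = vecs[:, idx].real
    if v.sum() < 0:
        v = -v
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise DegenerateSystemError("zero leading eigenvector")
    return float(lam.real), v / nrm, True


def rho_eff(C: np.ndarray) -> float:
    """Effective interspecific competition of a diagonal-normalized matrix.

    With lambda1 the leading eigenvalue and lambda_m the mean of the minor
    eigenvalues, (tr C - lambda1)/(S-1),

        rho_eff = (lambda1 - lambda_m) / (lambda1 + (S-1) lambda_m),

    which inverts the mean-field identity exactly: C = (1-rho) I + rho J
    gives back rho for any S and rho.
    """
    C = np.asarray(C, float)
    s = C.shape[0]
    if s < 2:
        raise ValueError("rho_eff needs at least two species")
    lam1, _, _ = leading_eigensystem(C)
    lam_minor = (np.trace(C) - lam1) / (s - 1)
    return float((lam1 - lam_minor) / (lam1 + (s - 1) * lam_minor))


def s_eff(rho_effective: float) -> float:
    """Biodiversity scale S^eff = (1 - rho^eff)/rho^eff."""
    return (1.0 - rho_effective) / rho_effective


def eta_crit(rho_effective: float, s: int) -> float:
    """Feasibility threshold eta_c = S^eff/(S^eff + S); tends to 1 as the
    effective interspecific competition vanishes."""
    se = s_eff(rho_effective)
    return se / (se + s)


def vulnerabilities(
    C: np.ndarray,
    p: np.ndarray,
    n_c: float = 0.0,
    n_mean: float | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Vulnerability factors, threshold and feasibility verdict.

    eta_i = 1 - p_i/(<p, v1> v1_i) with v1 the unit-norm leading eigenvector;
    their (v1_i)^2-weighted average vanishes identically.  The verdict is
    max_i eta_i <= eta_c, with eta_c shrunk by the factor (1 - n_c/<n>) when
    a positive viability threshold n_c is requested.
    """
    C = np.asarray(C, float)
    p = np.asarray(p, float)
    s = C.shape[0]
    lam1, v1, degenerate = leading_eigensystem(C)
    if degenerate:
        raise DegenerateSystemError("non-positive or complex Perron pair")
    proj = float(p @ v1)
    if proj <= 0:
        raise DegenerateSystemError("non-positive productivity projection")
    eta = 1.0 - p / (proj * v1)
    re = rho_eff(C)
    ec = eta_crit(re, s)
    if n_c > 0:
        if n_mean is None:
            n_mean = float(np.mean(np.linalg.solve(C, p)))
        ec = ec * (1.0 - n_c / n_mean)
    verdict = bool(eta.max() <= ec)
    return eta, ec, verdict


@dataclass
class GuildEffective:
    """Effective single-guild reduction for one guild."""

    guild: str
    C: np.ndarray  # diagonal-normalized effective competition
    p: np.ndarray  # productivities in the same units
    n: np.ndarray  # rescaled equilibrium abundances (C n = p)
    G: np.ndarray  # cross-guild propagation matrix gamma^LV (beta^other)^-1
    lam1: float
    v1: np.ndarray
    rho_eff: float
    s_eff: float
    eta_c: float
    eta: np.ndarray
    feasible: bool
    diag_scale: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False

    @property
    def s(self) -> int:
        return len(self.p)

    @property
    def eta_max(self) -> float:
        return float(self.eta.max())


@dataclass
class EffectiveSystem:
    plants: GuildEffective
    animals: GuildEffective
    lv: EquivalentLV

    def guild(self, name: str) -> GuildEffective:
        if name in ("plants", "P", "p"):
            return self.plants
        if name in ("animals", "A", "a"):
            return self.animals
        raise KeyError(name)


def _reduce_guild(
    guild: str,
    beta_x, beta_y, gamma_x, gamma_y, alpha_x, alpha_y, n_x,
    residual_tol: float,
) -> GuildEffective:
    beta_y_inv = np.linalg.inv(beta_y)
    G = gamma_x @ beta_y_inv
    C = beta_x - G @ gamma_y
    p = alpha_x + G @ alpha_y
    res = np.abs(C @ n_x - p).max() / max(np.abs(p).max(), 1e-300)
    if res > residual_tol:
        raise AssertionError(
            f"effective equilibrium identity violated ({guild}): {res:.2e}"
        )
    # renormalize to units of intraspecific effective competition, C_ii = 1
    d = np.diag(C).copy()
    if (d <= 0).any():
        raise DegenerateSystemError(
            f"non-positive effective intraspecific competition ({guild})"
        )
    ds = np.sqrt(d)
    Cn = C / np.outer(ds, ds)
    pn = p / ds
    nn = n_x * ds
    lam1, v1, degenerate = leading_eigensystem(Cn)
    re = rho_eff(Cn)
    s = len(pn)
    ec = eta_crit(re, s)
    proj = float(pn @ v1)
    if proj <= 0 or degenerate:
        eta = np.full(s, np.nan)
        feasible = False
        degenerate = True
    else:
        eta = 1.0 - pn / (proj * v1)
        feasible = bool(eta.max() <= ec)
    return GuildEffective(
        guild=guild, C=Cn, p=pn, n=nn, G=G, lam1=lam1, v1=v1,
        rho_eff=re, s_eff=s_eff(re), eta_c=ec, eta=eta,
        feasible=feasible, diag_scale=ds, degenerate=degenerate,
    )


def effective_system(
    lv: EquivalentLV,
    residual_tol: float = EFFECTIVE_RESIDUAL_TOL,
) -> EffectiveSystem:
    """Both guilds' effective reductions of a linearized community."""
    com = lv.community
    plants = _reduce_guild(
        "plants", com.beta_p, com.beta_a, lv.gamma_lv_p, lv.gamma_lv_a,
        lv.alpha_lv_p, lv.alpha_lv_a, com.n_p, residual_tol,
    )
    animals = _reduce_guild(
        "animals", com.beta_a, com.beta_p, lv.gamma_lv_a, lv.gamma_lv_p,
        lv.alpha_lv_a, lv.alpha_lv_p, com.n_a, residual_tol,
    )
    return EffectiveSystem(plants=plants, animals=animals, lv=lv)
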