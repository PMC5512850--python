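"""Assembly of the two-guild population-dynamics model.

The model couples S^P plants and S^A animals.  In units where the
intraspecific competition of every species equals one, the dynamics of plant
i reads

    dN_i/dt = N_i [ alpha_i - sum_j beta_ij N_j + M_i(N^A) ],

with a fully connected within-guild competition matrix beta (diagonal 1,
off-diagonal rho * b_ij) and a saturating (Holling type II) mutualistic
growth term

    M_i(N) = (1/h_i) * z_i / (1 + z_i),      z_i = h_i * sum_k gamma_ik N_k,

so that 1/h_i is the maximum mutualistic growth rate and z_i the
dimensionless saturation factor at the given partner abundances.  The animal
equations are obtained by exchanging the guild superscripts.

Feasibility is imposed by construction: equilibrium abundances are drawn
first and the intrinsic growth rates alpha are solved from the fixed-point
equations.  Facultative mutualism has alpha > 0 for everyone; mutualism
obligatory for animals (alpha^A < 0) is reached by giving plants a much
larger abundance scale and animals a large maximum mutualistic growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FIXED_POINT_TOL, STRONG_SATURATION_THRESHOLD, PRESETS, RegimePreset
from .networks import BipartiteNetwork

__all__ = [
    "MetaParameters",
    "Community",
    "build_competition",
    "build_mutualism",
    "choose_saturation",
    "draw_abundances",
    "mutualistic_term",
    "obligatory_feasibility_bound",
    "solve_growth_rates",
    "assemble_community",
    "full_rhs",
    "rescale_units",
    "RegimeViolationError",
]


class RegimeViolationError(ValueError):
    """Growth-rate signs contradict the requested mutualism type."""


@dataclass
class MetaParameters:
    """Meta-parameters of a community draw (rescaled units, beta_ii = 1)."""

    rho_p: float = 0.05
    rho_a: float = 0.05
    gamma0: float = 0.15
    saturation: float = 1.0  # dimensionless handling scale for facultative runs
    delta_b: float = 0.15
    delta_c: float = 0.15
    delta_n: float = 0.15
    nbar_p: float = 1.0
    nbar_a: float = 1.0
    mutualism: str = "facultative"  # or "obligatory_animals"
    abundance_distribution: str = "uniform"  # or "lognormal"
    label: str = ""

    def __post_init__(self) -> None:
        for name, rho in (("rho_p", self.rho_p), ("rho_a", self.rho_a)):
            if not 0 <= rho < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be non-negative")
        for name, d in (("delta_b", self.delta_b), ("delta_c", self.delta_c)):
            if not 0 <= d < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.mutualism not in ("facultative", "obligatory_animals"):
            raise ValueError(f"unknown mutualism type {self.mutualism!r}")

    @classmethod
    def from_preset(cls, preset: str | RegimePreset, **overrides) -> "MetaParameters":
        p = PRESETS[preset] if isinstance(preset, str) else preset
        kwargs = dict(
            rho_p=p.rho_p,
            rho_a=p.rho_a,
            gamma0=p.gamma0,
            saturation=p.saturation,
            delta_b=p.delta_b,
            delta_c=p.delta_c,
            delta_n=p.delta_n,
            nbar_p=p.nbar_ratio,
            nbar_a=1.0,
            mutualism=p.mutualism,
            label=p.label,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class Community:
    """A fully parameterized dynamical system with a feasible equilibrium."""

    net: BipartiteNetwork | None
    meta: MetaParameters
    beta_p: np.ndarray
    beta_a: np.ndarray
    gamma_p: np.ndarray  # S^P x S^A, supported on the incidence
    gamma_a: np.ndarray  # S^A x S^P
    h_p: np.ndarray
    h_a: np.ndarray
    n_p: np.ndarray  # equilibrium abundances
    n_a: np.ndarray
    alpha_p: np.ndarray = field(default=None)
    alpha_a: np.ndarray = field(default=None)
    z_p: np.ndarray = field(default=None)
    z_a: np.ndarray = field(default=None)
    regime_p: np.ndarray = field(default=None)  # "weak"/"strong" per species
    regime_a: np.ndarray = field(default=None)

    @property
    def s_plants(self) -> int:
        return len(self.n_p)

    @property
    def s_animals(self) -> int:
        return len(self.n_a)

    @property
    def n_star(self) -> np.ndarray:
        return np.concatenate([self.n_p, self.n_a])

    @property
    def alpha(self) -> np.ndarray:
        return np.concatenate([self.alpha_p, self.alpha_a])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_competition(
    s: int,
    rho: float,
    delta_b: float = 0.0,
    rng_seed=None,
    allow_unstable: bool = False,
) -> np.ndarray:
    """Fully connected competition matrix: diagonal 1, off-diagonal rho*b_ij.

    b_ij ~ Uniform[1 - delta_b, 1 + delta_b], drawn independently for each
    ordered pair.  rho >= 1 violates the diagonal-dominance intent of the
    model and is rejected unless ``allow_unstable`` (used by tests exploring
    competitive exclusion).
    """
    if rho < 0 or (rho >= 1 and not allow_unstable):
        raise ValueError("rho must lie in [0, 1)")
    rng = _as_rng(rng_seed)
    b = rng.uniform(1 - delta_b, 1 + delta_b, size=(s, s))
    beta = rho * b
    np.fill_diagonal(beta, 1.0)
    return beta


def build_mutualism(
    net: BipartiteNetwork,
    gamma0: float,
    delta_c: float = 0.0,
    rng_seed=None,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutualistic strength matrices supported on the incidence.

    gamma^P_ik = gamma0 * scale * c_ik on links (zero elsewhere) with
    c_ik ~ Uniform[1 - delta_c, 1 + delta_c]; the plant- and animal-side
    draws are independent.  ``scale`` carries the abundance-unit prefactor
    1/sqrt(Nbar^P Nbar^A) used for obligatory mutualism.
    """
    if gamma0 < 0:
        raise ValueError("gamma0 must be non-negative")
    rng = _as_rng(rng_seed)
    a = net.incidence.astype(float)
    c_p = rng.uniform(1 - delta_c, 1 + delta_c, size=a.shape)
    c_a = rng.uniform(1 - delta_c, 1 + delta_c, size=a.T.shape)
    gamma_p = gamma0 * scale * c_p * a
    gamma_a = gamma0 * scale * c_a * a.T
    return gamma_p, gamma_a


def choose_saturation(
    mutualism: str,
    s_animals: int,
    rho_a: float,
    saturation: float = 1.0,
) -> tuple[float, float]:
    """Handling scales (H^P, H^A).

    For mutualism obligatory for animals, the animals' maximum mutualistic
    growth rate 1/H^A must exceed their equilibrium competitive load
    S^A rho^A + 1 - rho^A (at unit animal abundance); H^A is set slightly
    below that ceiling, H^A = 0.75 / (S^A rho^A + 1 - rho^A), and plants,
    which have no such ceiling, get H^P = 0.25.  Facultative communities use
    the dimensionless saturation meta-parameter for both guilds; zero selects
    the exact linear (Lotka-Volterra) limit.
    """
    if mutualism == "obligatory_animals":
        h_a = 0.75 / (s_animals * rho_a + 1 - rho_a)
        h_p = 0.25
        if h_a <= 0 or h_p <= 0:
            raise ValueError("non-positive saturation scale")
        return h_p, h_a
    if saturation < 0:
        raise ValueError("saturation meta-parameter must be non-negative")
    return saturation, saturation


def draw_abundances(
    s: int,
    delta_n: float = 0.15,
    nbar: float = 1.0,
    distribution: str = "uniform",
    rng_seed=None,
) -> np.ndarray:
    """Equilibrium abundances N_i = Nbar * e_i.

    e_i ~ Uniform[1 - delta_n, 1 + delta_n] by default; the lognormal option
    matches e_i = exp(X), X ~ Normal(-delta_n^2/2, delta_n) (unit mean).
    """
    rng = _as_rng(rng_seed)
    if distribution == "uniform":
        if delta_n >= 1:
            raise ValueError("delta_n must be < 1 for uniform abundances")
        e = rng.uniform(1 - delta_n, 1 + delta_n, size=s)
    elif distribution == "lognormal":
        e = rng.lognormal(mean=-0.5 * delta_n**2, sigma=delta_n, size=s)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return nbar * e


def mutualistic_term(
    gamma: np.ndarray, h: np.ndarray, n_other: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Saturating mutualistic growth M and saturation factors z.

    M_i = (1/h_i) z_i/(1+z_i) with z_i = h_i (gamma @ n)_i; the h -> 0 limit
    is the linear Lotka-Volterra term gamma @ n.
    """
    flux = gamma @ n_other
    h = np.broadcast_to(np.asarray(h, dtype=float), flux.shape)
    z = h * flux
    m = np.where(h > 0, np.divide(flux, 1 + z), flux)
    return m, z


def solve_growth_rates(
    beta_p, beta_a, gamma_p, gamma_a, h_p, h_a, n_p, n_a,
    mutualism: str = "facultative",
    strong_threshold: float = STRONG_SATURATION_THRESHOLD,
):
    """Intrinsic growth rates that make (n_p, n_a) a fixed point.

    alpha_i = sum_j beta_ij N_j - M_i(N_other).  Each species is labelled
    weak or strong according to its saturation factor.  For mutualism
    obligatory for animals the sign contract alpha^A < 0, alpha^P > 0 is
    enforced and a RegimeViolationError names the offending species.
    """
    m_p, z_p = mutualistic_term(gamma_p, h_p, n_a)
    m_a, z_a = mutualistic_term(gamma_a, h_a, n_p)
    alpha_p = beta_p @ n_p - m_p
    alpha_a = beta_a @ n_a - m_a
    regime_p = np.where(z_p > strong_threshold, "strong", "weak")
    regime_a = np.where(z_a > strong_threshold, "strong", "weak")
    if mutualism == "obligatory_animals":
        bad_a = np.flatnonzero(alpha_a >= 0)
        bad_p = np.flatnonzero(alpha_p <= 0)
        if bad_a.size or bad_p.size:
            raise RegimeViolationError(
                "obligatory-for-animals regime violated: "
                f"animals with alpha >= 0: {bad_a.tolist()}; "
                f"plants with alpha <= 0: {bad_p.tolist()}"
            )
    return alpha_p, alpha_a, z_p, z_a, regime_p, regime_a


def obligatory_feasibility_bound(
    s_animals: int,
    rho_a: float,
    gamma0: float,
    d_min: float = 1.0,
) -> float:
    """Minimum abundance ratio Nbar^P/Nbar^A for obligatory-animal mutualism.

    An animal is obligate when its intrinsic growth rate is negative, i.e.
    its saturating mutualistic input exceeds its competitive load; with
    H^A = 0.75/(S^A rho^A + 1 - rho^A) that requires a saturation factor
    z_i = H^A gamma0 d_i sqrt(Nbar^P/Nbar^A) > 3 for every animal.  The
    binding case is the smallest (weighted) animal degree d_min, giving

        Nbar^P/Nbar^A > (4 (S^A rho^A + 1 - rho^A) / (gamma0 d_min))^2.
    """
    if gamma0 <= 0 or d_min <= 0:
        raise ValueError("gamma0 and d_min must be positive")
    load = s_animals * rho_a + 1 - rho_a
    return (4.0 * load / (gamma0 * d_min)) ** 2


def assemble_community(
    net: BipartiteNetwork,
    meta: MetaParameters,
    rng_seed=None,
    check_residual: bool = True,
) -> Community:
    """Draw interactions and abundances, then solve the growth rates."""
    rng = _as_rng(rng_seed)
    beta_p = build_competition(net.s_plants, meta.rho_p, meta.delta_b, rng)
    beta_a = build_competition(net.s_animals, meta.rho_a, meta.delta_b, rng)
    scale = 1.0 / np.sqrt(meta.nbar_p * meta.nbar_a)
    gamma_p, gamma_a = build_mutualism(net, meta.gamma0, meta.delta_c, rng, scale)
    h_p, h_a = choose_saturation(
        meta.mutualism, net.s_animals, meta.rho_a, meta.saturation
    )
    n_p = draw_abundances(
        net.s_plants, meta.delta_n, meta.nbar_p, meta.abundance_distribution, rng
    )
    n_a = draw_abundances(
        net.s_animals, meta.delta_n, meta.nbar_a, meta.abundance_distribution, rng
    )
    hp = np.full(net.s_plants, h_p)
    ha = np.full(net.s_animals, h_a)
    alpha_p, alpha_a, z_p, z_a, reg_p, reg_a = solve_growth_rates(
        beta_p, beta_a, gamma_p, gamma_a, hp, ha, n_p, n_a, meta.mutualism
    )
    com = Community(
        net=net, meta=meta, beta_p=beta_p, beta_a=beta_a,
        gamma_p=gamma_p, gamma_a=gamma_a, h_p=hp, h_a=ha,
        n_p=n_p, n_a=n_a, alpha_p=alpha_p, alpha_a=alpha_a,
        z_p=z_p, z_a=z_a, regime_p=reg_p, regime_a=reg_a,
    )
    if check_residual:
        res = fixed_point_residual(com)
        if res > FIXED_POINT_TOL:
            raise AssertionError(f"fixed-point residual {res:.2e} exceeds tolerance")
    return com


def per_capita_growth(com: Community, n: np.ndarray) -> np.ndarray:
    """Bracket term of the dynamics for the stacked state (plants, animals)."""
    sp = com.s_plants
    n_p, n_a = n[:sp], n[sp:]
    m_p, _ = mutualistic_term(com.gamma_p, com.h_p, n_a)
    m_a, _ = mutualistic_term(com.gamma_a, com.h_a, n_p)
    g_p = com.alpha_p - com.beta_p @ n_p + m_p
    g_a = com.alpha_a - com.beta_a @ n_a + m_a
    return np.concatenate([g_p, g_a])


def full_rhs(com: Community, n: np.ndarray) -> np.ndarray:
    """dN/dt for the stacked state vector."""
    return n * per_capita_growth(com, n)


def fixed_point_residual(com: Community) -> float:
    """Max relative residual of the dynamics at the stored equilibrium.

    The per-capita growth is compared with the magnitude of the rate terms it
    balances (|alpha| + |beta N| + |M|), so the measure is meaningful also
    when guilds live on very different abundance and rate scales.
    """
    g = per_capita_growth(com, com.n_star)
    m_p, _ = mutualistic_term(com.gamma_p, com.h_p, com.n_a)
    m_a, _ = mutualistic_term(com.gamma_a, com.h_a, com.n_p)
    scale = np.concatenate([
        np.abs(com.alpha_p) + np.abs(com.beta_p @ com.n_p) + np.abs(m_p),
        np.abs(com.alpha_a) + np.abs(com.beta_a @ com.n_a) + np.abs(m_a),
    ])
    return float(np.max(np.abs(g) / np.maximum(scale, 1e-300)))


def rescale_units(
    beta_p, beta_a, gamma_p, gamma_a, h_p, h_a, n_p, n_a,
    alpha_p=None, alpha_a=None,
):
    """Change abundance units so that every intraspecific competition is 1.

    With n'_i = beta_ii * n_i, beta'_ij = beta_ij / beta_jj and
    gamma'_ik = gamma_ik / beta^(other)_kk, the rescaled system has unit
    diagonal and trajectories that correspond exactly to the original ones
    under the per-species scale map (alpha and h are unchanged).  Applying
    the map twice is the identity.
    """
    beta_p = np.asarray(beta_p, float)
    beta_a = np.asarray(beta_a, float)
    dp = np.diag(beta_p).copy()
    da = np.diag(beta_a).copy()
    if (dp <= 0).any() or (da <= 0).any():
        raise ValueError("intraspecific competition must be positive")
    out = dict(
        beta_p=beta_p / dp[None, :],
        beta_a=beta_a / da[None, :],
        gamma_p=np.asarray(gamma_p, float) / da[None, :],
        gamma_a=np.asarray(gamma_a, float) / dp[None, :],
        h_p=np.asarray(h_p, float).copy(),
        h_a=np.asarray(h_a, float).copy(),
        n_p=dp * np.asarray(n_p, float),
        n_a=da * np.asarray(n_a, float),
        scale_p=dp,
        scale_a=da,
    )
    if alpha_p is not None:
        out["alpha_p"] = np.asarray(alpha_p, float).copy()
    if alpha_a is not None:
        out["alpha_a"] = np.asarray(alpha_a, float).copy()
    return out
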