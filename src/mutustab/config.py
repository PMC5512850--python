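"""Central numerical constants and regime presets.

All tolerances used across the package live here so that they are set in one
place and documented once (see docs/methods.md for the rationale behind each
value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Residual tolerance for the fixed-point identity of an assembled community.
FIXED_POINT_TOL = 1e-10

#: Agreement tolerance between the full model and its Lotka-Volterra
#: linearization (right-hand side and Jacobian at the equilibrium).
LV_MATCH_TOL = 1e-8

#: Residual tolerance for the effective-system equilibrium identity C n = p.
EFFECTIVE_RESIDUAL_TOL = 1e-8

#: Relative abundance below which a species is considered extinct during
#: numerical integration (fraction of its initial abundance).
EXTINCTION_THRESHOLD = 1e-8

#: Convergence criterion for the integrator: maximum relative time-derivative.
CONVERGENCE_TOL = 1e-9

#: Bisection tolerance (in gamma0) for the critical mutualistic strengths.
GAMMA_BRACKET_TOL = 1e-4

#: Bisection tolerance for the critical competition root rho^eff(rho) = rho.
RHO_CRIT_TOL = 1e-6

#: Convergence tolerance of the two-guild critical-competition fixed point.
FIXED_POINT_ITER_TOL = 1e-8

#: Saturation factor above which a species is classified as strongly
#: mutualistic (z >> 1 in the theory; the cut is a reporting convention).
STRONG_SATURATION_THRESHOLD = 1.0

#: Default Metropolis temperature and nestedness tolerance of the link-swap
#: tuner.
TUNER_TEMPERATURE = 1e-3
TUNER_TOLERANCE = 0.01

#: Retry cap when resampling networks that contain unconnected species.
EMPTY_SPECIES_RETRY_CAP = 100


@dataclass(frozen=True)
class RegimePreset:
    """A named combination of meta-parameters (regimes A-H).

    The eight presets cover facultative/obligatory mutualism crossed with
    weak/strong mutualistic saturation and weak/strong direct competition.
    ``saturation`` is the dimensionless handling scale: z_i = saturation *
    gamma0 * d_i at unit abundance, so saturation=100 puts a facultative
    community deep in the strong-mutualistic regime.
    """

    label: str
    mutualism: str  # "facultative" | "obligatory_animals"
    rho_p: float
    rho_a: float
    saturation: float = 1.0
    gamma0: float = 0.2  # fallback when no instability window exists
    gamma0_policy_frac: float = 0.5
    nbar_ratio: float = 1.0  # Nbar^P / Nbar^A
    delta_b: float = 0.15
    delta_c: float = 0.15
    delta_n: float = 0.15
    n_realizations: int = 10
    n_perturbations: int = 50


PRESETS: dict[str, RegimePreset] = {
    "A": RegimePreset("A", "facultative", 0.05, 0.05, saturation=1.0),
    "B": RegimePreset("B", "facultative", 0.05, 0.05, saturation=100.0),
    "C": RegimePreset("C", "facultative", 0.23, 0.23, saturation=1.0),
    "D": RegimePreset("D", "facultative", 0.23, 0.23, saturation=100.0),
    "E": RegimePreset("E", "obligatory_animals", 0.05, 0.05, gamma0=0.1,
                      nbar_ratio=1e6),
    "F": RegimePreset("F", "obligatory_animals", 0.05, 0.05, gamma0=0.2,
                      nbar_ratio=1e6),
    "G": RegimePreset("G", "obligatory_animals", 0.25, 0.25, gamma0=0.1,
                      nbar_ratio=1e6),
    "H": RegimePreset("H", "obligatory_animals", 0.25, 0.25, gamma0=0.2,
                      nbar_ratio=1e6),
}
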