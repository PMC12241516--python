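"""Directional hypotheses and least-cost / coordination optimality predictions.

The hypothesis table encodes, for each measured trait, the direction it is
expected to move toward drier (higher-VPD) sites under least-cost stomatal
optimization, the coordination hypothesis, hydraulic scaling, and the xylem
safety–efficiency trade-off. The quantitative layer predicts χ = ci/ca from
VPD with the least-cost rule and Vcmax from the coordination equilibrium
Ac = Aj at growth conditions; it feeds direction checks only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aci import KineticConstants, arrhenius_scale


@dataclass(frozen=True)
class SiteClimate:
    site_id: str
    mat: float                  # °C
    vpd: float                  # kPa
    map_mm: float               # mm yr⁻¹
    ppfd_index: float = 1.0     # relative light availability
    soil_moisture: float = np.nan   # %
    deciduous_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.vpd <= 0:
            raise ValueError("vpd must be positive")
        if not 0.0 <= self.deciduous_fraction <= 1.0:
            raise ValueError("deciduous_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class OptimalityConstants:
    beta: float = 146.0         # unit cost ratio of the least-cost rule
    phi0: float = 0.085         # intrinsic quantum yield, mol mol⁻¹
    c_a_ref: float = 400.0      # µmol mol⁻¹
    viscosity_ratio: float = 1.0  # η* relative to 25 °C (≈1, minimal T range)
    p_atm_pa: float = 101_325.0

    def __post_init__(self) -> None:
        if min(self.beta, self.c_a_ref, self.viscosity_ratio, self.p_atm_pa) <= 0:
            raise ValueError("optimality constants must be positive")
        if self.phi0 < 0:
            raise ValueError("phi0 must be non-negative")


#: Trait keys of the 14 hypotheses, in presentation order.
HYPOTHESIS_TRAITS = (
    "chi", "vcmax25", "jmax25", "rd25", "asat400", "asat2000",
    "huber", "tlp", "hmax", "kp", "vessel_diameter", "vessel_density",
    "wood_density", "kp_huber_correlation",
)


def expected_directions() -> dict[str, str]:
    """Expected change of each trait toward drier (higher-VPD) sites.

    ``"+"``/``"-"`` are plot-trend hypotheses; the final entry is the sign
    of the interspecific Kp ~ AS/AL correlation expected from the
    conductivity–allocation trade-off.
    """
    return {
        "chi": "-",               # stomata held relatively closed when dry
        "vcmax25": "+",           # compensates low ci (coordination)
        "jmax25": "+",            # acclimates to higher absorbed light
        "rd25": "+",              # maintenance cost of photosynthetic protein
        "asat400": "+",
        "asat2000": "+",
        "huber": "+",             # more sapwood per leaf area supplied
        "tlp": "-",               # more negative turgor-loss point
        "hmax": "-",              # shorter stature, shorter path length
        "kp": "-",                # safety–efficiency trade-off
        "vessel_diameter": "-",
        "vessel_density": "+",
        "wood_density": "+",
        "kp_huber_correlation": "-",
    }


def xi_factor(t: float = 25.0, consts: OptimalityConstants | None = None,
              kin: KineticConstants | None = None) -> float:
    """Least-cost sensitivity ξ = √(β (K + Γ*) / (1.6 η*)), in √Pa.

    K and Γ* are evaluated at temperature ``t`` and converted from
    µmol mol⁻¹ to Pa at the reference atmospheric pressure.
    """
    consts = consts or OptimalityConstants()
    kin = kin or KineticConstants()
    k_pa = kin.km(t) * 1e-6 * consts.p_atm_pa
    gs_pa = kin.gamma_star(t) * 1e-6 * consts.p_atm_pa
    return float(np.sqrt(consts.beta * (k_pa + gs_pa) /
                         (1.6 * consts.viscosity_ratio)))


def predict_chi(vpd_kpa, t: float = 25.0,
                consts: OptimalityConstants | None = None,
                kin: KineticConstants | None = None):
    """Least-cost optimal χ = ξ/(ξ + √D), D the VPD in Pa.

    Strictly decreasing in VPD, increasing in β, bounded in (0, 1).
    """
    vpd_kpa = np.asarray(vpd_kpa, dtype=float)
    if np.any(vpd_kpa <= 0):
        raise ValueError("vpd must be positive")
    xi = xi_factor(t, consts, kin)
    sqrt_d = np.sqrt(vpd_kpa * 1000.0)
    out = xi / (xi + sqrt_d)
    return out.item() if out.ndim == 0 else out


def predict_vcmax_coordination(chi, c_a: float = 400.0, ppfd_abs: float = 800.0,
                               t: float = 25.0,
                               consts: OptimalityConstants | None = None,
                               kin: KineticConstants | None = None):
    """Vcmax25 from the coordination equilibrium Ac = Aj at growth conditions.

    With saturating-light J = φ0·Iabs, equality of the limitation branches
    gives Vcmax = φ0·Iabs·(ci + K)/(4·(ci + 2Γ*))·4 — i.e. proportional to
    absorbed light and rising as ci falls (for K > 2Γ*). The value at the
    growth temperature is normalized to 25 °C.
    """
    consts = consts or OptimalityConstants()
    kin = kin or KineticConstants()
    chi = np.asarray(chi, dtype=float)
    if np.any((chi <= 0) | (chi >= 1)):
        raise ValueError("chi must lie in (0, 1)")
    ci = chi * c_a
    km = kin.km(t)
    gs = kin.gamma_star(t)
    vcmax_t = consts.phi0 * ppfd_abs * (ci + km) / (ci + 2.0 * gs)
    out = arrhenius_scale(vcmax_t, t, 25.0, kin.ea_vcmax, kin.r_gas)
    return out.item() if np.ndim(out) == 0 else out


def predict_jmax(ppfd_abs: float, t: float = 25.0,
                 consts: OptimalityConstants | None = None,
                 kin: KineticConstants | None = None) -> float:
    """Jmax25 proportional to absorbed light (acclimation); reported only."""
    consts = consts or OptimalityConstants()
    kin = kin or KineticConstants()
    jmax_t = 4.0 * consts.phi0 * ppfd_abs
    return float(arrhenius_scale(jmax_t, t, 25.0, kin.ea_jmax, kin.r_gas))
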