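"""Hydraulic trait derivation and the stomatal-supply water balance.

Covers three raw-data reductions and the steady-state balance linking them:

* Hagen–Poiseuille potential sapwood-specific conductivity (Kp) from twig
  vessel anatomy,
* the Huber value (sapwood area per leaf area, AS/AL),
* turgor-loss point (TLP) and osmotic potential at full turgor from
  pressure–volume curves,
* the daytime balance "water loss through stomata equals water transport
  through xylem": E/AL = 1.6·VPDla·Aarea/((ca−ci)·Patm) = Ks·ΔΨmax·(AS/AL)/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WATER_DENSITY = 998.2          # kg m⁻³ at 20 °C
WATER_VISCOSITY = 1.002e-9     # MPa s at 20 °C


@dataclass
class AnatomySection:
    """One stained twig cross-section (pie segment, pith to cambium)."""

    twig_id: str
    species_id: str
    plot_id: str
    vessel_diameters: np.ndarray   # lumen diameters, µm
    section_area: float            # mm²
    twig_dry_mass: float = np.nan  # g
    twig_volume: float = np.nan    # cm³ (soaked)

    def __post_init__(self) -> None:
        self.vessel_diameters = np.asarray(self.vessel_diameters, dtype=float)
        if np.any(self.vessel_diameters <= 0):
            raise ValueError("vessel diameters must be positive")
        if self.section_area <= 0:
            raise ValueError("section area must be positive")


@dataclass
class PVCurve:
    """Pressure–volume points, ordered from full hydration downward."""

    leaf_id: str
    psi: np.ndarray   # MPa, strictly negative
    rwc: np.ndarray   # relative water content, fraction of saturated

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.rwc = np.asarray(self.rwc, dtype=float)
        if len(self.psi) != len(self.rwc):
            raise ValueError("psi and rwc must have equal length")
        if np.any(self.psi >= 0):
            raise ValueError("psi must be strictly negative")


@dataclass
class HydraulicRecord:
    kp: float = np.nan                 # kg m⁻¹ MPa⁻¹ s⁻¹
    vessel_density: float = np.nan     # mm⁻²
    mean_lumen_diameter: float = np.nan  # µm
    huber: float = np.nan              # cm² m⁻²
    tlp: float = np.nan                # MPa
    pi_o: float = np.nan               # MPa
    twig_density: float = np.nan       # g cm⁻³
    wood_density: float = np.nan       # g cm⁻³
    h_max: float = np.nan              # m
    flags: list[str] = field(default_factory=list)


def kp_from_anatomy(section: AnatomySection,
                    water_density: float = WATER_DENSITY,
                    water_viscosity: float = WATER_VISCOSITY,
                    diameter_mode: str = "hydraulic"):
    """Potential conductivity from vessel density and lumen diameter.

    Kp = (π ρw / 128 η) · VD · d⁴ with vessel density VD in m⁻² and a
    representative diameter d in m, yielding kg m⁻¹ MPa⁻¹ s⁻¹.

    ``diameter_mode`` selects d: ``"hydraulic"`` uses the fourth-root mean
    of d⁴ (then Kp equals the per-vessel Poiseuille sum divided by the
    section area, exactly); ``"arithmetic"`` uses the plain mean diameter,
    matching datasets where only the average diameter was recorded.

    Returns ``(kp, vessel_density_mm2, mean_lumen_diameter_um, flags)``.
    """
    flags: list[str] = []
    d_um = section.vessel_diameters
    area_mm2 = section.section_area
    if len(d_um) == 0:
        flags.append("no_vessels")
        return 0.0, 0.0, np.nan, flags
    vd_mm2 = len(d_um) / area_mm2
    mean_d = float(np.mean(d_um))
    if diameter_mode == "hydraulic":
        d_rep_um = float(np.mean(d_um**4) ** 0.25)
    elif diameter_mode == "arithmetic":
        d_rep_um = mean_d
    else:
        raise ValueError(f"unknown diameter mode {diameter_mode!r}")
    vd_m2 = vd_mm2 * 1e6
    d_m = d_rep_um * 1e-6
    kp = (np.pi * water_density / (128.0 * water_viscosity)) * vd_m2 * d_m**4
    return float(kp), float(vd_mm2), mean_d, flags


def huber_value(sapwood_area_cm2: float, leaf_area_m2: float) -> float:
    """Sapwood-to-leaf-area ratio AS/AL in cm² m⁻²."""
    if leaf_area_m2 <= 0 or sapwood_area_cm2 <= 0:
        raise ValueError("sapwood and leaf area must be positive")
    return sapwood_area_cm2 / leaf_area_m2


def twig_density(dry_mass_g: float, soaked_volume_cm3: float) -> float:
    """Twig wood density: oven-dry mass over soaked volume (g cm⁻³)."""
    if soaked_volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    return dry_mass_g / soaked_volume_cm3


@dataclass
class PVFit:
    tlp: float                 # MPa
    pi_o: float                # MPa
    n_linear_points: int
    r_squared: float
    flags: list[str] = field(default_factory=list)


def fit_pv_curve(curve: PVCurve, min_tail: int = 4,
                 r2_threshold: float = 0.9) -> PVFit:
    """Extract turgor-loss point and full-turgor osmotic potential.

    −1/ψ is regressed on the water deficit (1 − RWC) over the post-turgor-
    loss tail. Candidate tails drop 0, 1, 2, … of the wettest points
    (keeping ≥ ``min_tail``); the selected tail is the longest one whose
    R² is within 1e-9 of the best candidate, which is deterministic and
    immune to local R² dips caused by near-collinear pre-loss points.
    π_o is read from the intercept at RWC = 1 and TLP from the fitted line
    evaluated at the wettest retained point — the operational point of
    departure from linearity.
    """
    if len(curve.psi) < 6:
        raise ValueError("fit_pv_curve requires at least 6 points")
    order = np.argsort(curve.rwc)[::-1]       # wettest first
    x = 1.0 - curve.rwc[order]
    y = -1.0 / curve.psi[order]

    def tail_fit(k: int):
        xs, ys = x[k:], y[k:]
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = intercept + slope * xs
        ss_res = float(np.sum((ys - pred) ** 2))
        ss_tot = float(np.sum((ys - np.mean(ys)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return slope, intercept, r2

    candidates = [(k, *tail_fit(k)) for k in range(len(x) - min_tail + 1)]
    best_r2 = max(c[3] for c in candidates)
    k, slope, intercept, r2 = next(c for c in candidates
                                   if c[3] >= best_r2 - 1e-9)

    flags: list[str] = []
    if r2 < r2_threshold:
        flags.append("no_linear_tail")
        return PVFit(np.nan, np.nan, len(x) - k, r2, flags)

    pi_o = -1.0 / intercept
    tlp = -1.0 / (intercept + slope * x[k])
    if tlp > pi_o:        # numerically possible only with degenerate tails
        flags.append("tlp_above_pio")
    return PVFit(float(tlp), float(pi_o), int(len(x) - k), float(r2), flags)


# --- steady-state water balance (leaf-area-specific fluxes) ---------------

def stomatal_water_loss(a_area, c_a, c_i, vpd_la, p_atm):
    """Demand side: E/AL = 1.6·VPDla·Aarea / ((ca − ci)·Patm), mol m⁻² s⁻¹.

    VPDla and Patm must share a pressure unit; ca and ci in µmol mol⁻¹ and
    Aarea in µmol m⁻² s⁻¹ cancel to mol m⁻² s⁻¹.
    """
    a_area, c_a, c_i = np.asarray(a_area, float), np.asarray(c_a, float), np.asarray(c_i, float)
    if np.any(c_a <= c_i):
        raise ValueError("requires c_a > c_i")
    if np.any(np.asarray(p_atm) <= 0):
        raise ValueError("p_atm must be positive")
    out = 1.6 * vpd_la * a_area / ((c_a - c_i) * p_atm)
    return out.item() if out.ndim == 0 else out


def xylem_water_supply(k_s, delta_psi_max, huber_m2_m2, h):
    """Supply side: E/AL = Ks·ΔΨmax·(AS/AL)/h with AS/AL in m² m⁻²."""
    if np.any(np.asarray(h) <= 0):
        raise ValueError("path length h must be positive")
    out = np.asarray(k_s, float) * delta_psi_max * huber_m2_m2 / np.asarray(h, float)
    return out.item() if out.ndim == 0 else out


def gs_ficks(a_area, c_a, c_i):
    """Fick's-law stomatal conductance g_s = Aarea/(ca − ci)."""
    a_area, c_a, c_i = np.asarray(a_area, float), np.asarray(c_a, float), np.asarray(c_i, float)
    if np.any(c_a <= c_i):
        raise ValueError("requires c_a > c_i")
    out = a_area / (c_a - c_i)
    return out.item() if out.ndim == 0 else out


def a_area_from_supply(k_s, delta_psi_max, huber_m2_m2, h, c_a, c_i, vpd_la, p_atm):
    """Invert the balance for carbon gain:
    Aarea = Ks·ΔΨmax·(AS/AL)/(h·1.6·VPDla) · (ca − ci) · Patm."""
    supply = xylem_water_supply(k_s, delta_psi_max, huber_m2_m2, h)
    out = supply / (1.6 * vpd_la) * (np.asarray(c_a, float) - c_i) * p_atm
    return out.item() if np.ndim(out) == 0 else out


def huber_cm2_m2_to_m2_m2(huber_cm2_m2):
    return np.asarray(huber_cm2_m2, float) * 1e-4
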