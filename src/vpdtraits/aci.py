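"""Farquhar–von Caemmerer–Berry (FvCB) photosynthesis model and A-Ci curve fitting.

The module provides the forward C3 assimilation model, least-squares
estimation of (Vcmax, Jmax, Rd) from an A-Ci response curve, Arrhenius
temperature normalization of the fitted capacities to 25 °C, and extraction
of light-saturated assimilation rates at the 400- and 2000-ppm setpoints.

Conventions
-----------
* Concentrations (ci, ca, Kc, Gamma*) in µmol mol⁻¹; Ko and O2 in mmol mol⁻¹.
* Rates in µmol CO2 m⁻² s⁻¹; temperatures in °C; activation energies in J mol⁻¹.
* The default light model assumes saturating PPFD, so J = Jmax. A
  non-rectangular hyperbola is available through :class:`AciConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

T0_K = 273.15

#: CO2 setpoint sequence of the measurement protocol (ppm).
PROTOCOL_SEQUENCE = (400, 300, 200, 100, 500, 400, 600, 800, 1200, 1500, 2000)


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics and activation energies of the FvCB model.

    Defaults follow the widely used Bernacchi-style constant set with
    simple (non-peaked) Arrhenius temperature responses.
    """

    gamma_star25: float = 42.75   # µmol mol⁻¹, CO2 compensation point sans Rd
    kc25: float = 404.9           # µmol mol⁻¹
    ko25: float = 278.4           # mmol mol⁻¹
    o2: float = 210.0             # mmol mol⁻¹
    ea_gamma: float = 37_830.0    # J mol⁻¹
    ea_kc: float = 79_430.0
    ea_ko: float = 36_380.0
    ea_vcmax: float = 65_330.0
    ea_jmax: float = 43_540.0
    ea_rd: float = 46_390.0
    r_gas: float = 8.314          # J mol⁻¹ K⁻¹

    def __post_init__(self) -> None:
        vals = [self.gamma_star25, self.kc25, self.ko25, self.o2,
                self.ea_gamma, self.ea_kc, self.ea_ko, self.ea_vcmax,
                self.ea_jmax, self.ea_rd, self.r_gas]
        if any(v <= 0 for v in vals):
            raise ValueError("all kinetic constants must be positive")
        if self.gamma_star25 >= self.kc25:
            raise ValueError("gamma_star25 must be below kc25")

    def gamma_star(self, t_leaf: float) -> float:
        """Γ* at leaf temperature (µmol mol⁻¹)."""
        return arrhenius_scale(self.gamma_star25, 25.0, t_leaf, self.ea_gamma, self.r_gas)

    def kc(self, t_leaf: float) -> float:
        return arrhenius_scale(self.kc25, 25.0, t_leaf, self.ea_kc, self.r_gas)

    def ko(self, t_leaf: float) -> float:
        return arrhenius_scale(self.ko25, 25.0, t_leaf, self.ea_ko, self.r_gas)

    def km(self, t_leaf: float) -> float:
        """Effective Michaelis constant K = Kc (1 + O/Ko) at t_leaf (µmol mol⁻¹)."""
        return self.kc(t_leaf) * (1.0 + self.o2 / self.ko(t_leaf))


@dataclass
class AciConfig:
    """Tunable choices of the fitting procedure."""

    light_model: str = "saturating"        # "saturating" (J = Jmax) or "nrh"
    theta: float = 0.9                     # NRH curvature
    quantum_yield: float = 0.3             # apparent phi (e- per photon) for NRH
    bounds_vcmax: tuple[float, float] = (1.0, 300.0)
    bounds_jmax: tuple[float, float] = (1.0, 500.0)
    bounds_rd: tuple[float, float] = (0.0, 10.0)
    n_starts: int = 5
    objective_tol: float = 1e-8
    tie_rtol: float = 0.01                 # Ac within 1% of Aj counts as co-limited


@dataclass
class ACiCurve:
    """One leaf's assimilation response to substomatal CO2."""

    leaf_id: str
    tree_id: str
    species_id: str
    plot_id: str
    ca_set: np.ndarray     # setpoint CO2, ppm
    ci: np.ndarray         # realized substomatal CO2, µmol mol⁻¹
    a_net: np.ndarray      # net assimilation, µmol m⁻² s⁻¹
    t_leaf: float          # °C
    ppfd: float            # µmol m⁻² s⁻¹

    def __post_init__(self) -> None:
        self.ca_set = np.asarray(self.ca_set, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)
        self.a_net = np.asarray(self.a_net, dtype=float)
        if not (len(self.ca_set) == len(self.ci) == len(self.a_net)):
            raise ValueError("ca_set, ci and a_net must have equal length")
        if np.any(self.ci <= 0):
            raise ValueError("ci must be positive")
        if self.ppfd <= 0:
            raise ValueError("ppfd must be positive")

    def __len__(self) -> int:
        return len(self.ci)


@dataclass
class PhotoParams:
    """Fitted photosynthetic capacities at leaf temperature and at 25 °C."""

    vcmax_t: float
    jmax_t: float
    rd_t: float
    vcmax25: float = np.nan
    jmax25: float = np.nan
    rd25: float = np.nan
    asat400: float = np.nan
    asat2000: float = np.nan
    rmse: float = np.nan
    n_points: int = 0
    t_leaf: float = 25.0
    limitation: Sequence[str] = field(default_factory=tuple)  # per-point "C"/"J"/"tie"
    flags: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return "nonconvergence" not in self.flags


def arrhenius_scale(value_t: float, t_from: float, t_to: float,
                    ea: float, r_gas: float = 8.314):
    """Rescale a rate measured at ``t_from`` (°C) to ``t_to`` (°C).

    value_to = value_t * exp[(Ea/R) (1/T_from − 1/T_to)] with temperatures
    in kelvin. Exactly invertible: scaling there and back is the identity.
    """
    tf = t_from + T0_K
    tt = t_to + T0_K
    if tf <= 0 or tt <= 0:
        raise ValueError("absolute temperatures must be positive")
    return value_t * np.exp((ea / r_gas) * (1.0 / tf - 1.0 / tt))


def electron_transport(jmax: float, ppfd: float, config: AciConfig | None = None):
    """Realized electron transport rate J for a given light model."""
    config = config or AciConfig()
    if config.light_model == "saturating":
        return jmax
    if config.light_model == "nrh":
        i2 = config.quantum_yield * ppfd
        theta = config.theta
        disc = (i2 + jmax) ** 2 - 4.0 * theta * i2 * jmax
        return (i2 + jmax - np.sqrt(disc)) / (2.0 * theta)
    raise ValueError(f"unknown light model {config.light_model!r}")


def fvcb_limitation_rates(ci, vcmax_t, jmax_t, kin: KineticConstants,
                          t_leaf: float, ppfd: float = 2000.0,
                          config: AciConfig | None = None):
    """Gross Rubisco-limited (Ac) and electron-transport-limited (Aj) rates."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise ValueError("ci must be non-negative")
    gs = kin.gamma_star(t_leaf)
    km = kin.km(t_leaf)
    j = electron_transport(jmax_t, ppfd, config)
    ac = vcmax_t * (ci - gs) / (ci + km)
    aj = j * (ci - gs) / (4.0 * ci + 8.0 * gs)
    return ac, aj


def fvcb_assimilation(ci, vcmax_t, jmax_t, rd_t, kin: KineticConstants | None = None,
                      t_leaf: float = 25.0, ppfd: float = 2000.0,
                      config: AciConfig | None = None):
    """Net assimilation A = min(Ac, Aj) − Rd at leaf temperature.

    Parameters are the capacities *at* ``t_leaf``; kinetics are internally
    scaled from 25 °C to ``t_leaf`` by Arrhenius.
    """
    kin = kin or KineticConstants()
    ac, aj = fvcb_limitation_rates(ci, vcmax_t, jmax_t, kin, t_leaf, ppfd, config)
    return np.minimum(ac, aj) - rd_t


def _start_grid(config: AciConfig) -> list[tuple[float, float, float]]:
    # deterministic multi-start grid spanning the plausible capacity range
    return [
        (20.0, 40.0, 1.0),
        (50.0, 100.0, 1.5),
        (100.0, 200.0, 2.0),
        (150.0, 300.0, 2.0),
        (250.0, 450.0, 3.0),
    ][: config.n_starts]


def fit_aci(curve: ACiCurve, kin: KineticConstants | None = None,
            config: AciConfig | None = None) -> PhotoParams:
    """Estimate (Vcmax, Jmax, Rd) at leaf temperature by joint least squares.

    The model is the hard minimum of the two limitation branches; bounded
    local least squares is run from a deterministic grid of starts and the
    best objective wins, which makes the fit independent of point order.
    Capacities are also returned normalized to 25 °C.

    Raises ``ValueError`` for curves with fewer than 5 valid points.
    Non-convergence and unidentifiable branches are reported through
    ``PhotoParams.flags``, never as silent NaN.
    """
    kin = kin or KineticConstants()
    config = config or AciConfig()
    mask = np.isfinite(curve.ci) & np.isfinite(curve.a_net)
    ci = curve.ci[mask]
    a_obs = curve.a_net[mask]
    if len(ci) < 5:
        raise ValueError("fit_aci requires at least 5 valid points")

    gs = kin.gamma_star(curve.t_leaf)
    km = kin.km(curve.t_leaf)
    fc = (ci - gs) / (ci + km)           # Ac = Vcmax * fc
    fj = (ci - gs) / (4.0 * ci + 8.0 * gs)   # Aj = J * fj

    def model(p):
        vcmax, jmax, rd = p
        j = electron_transport(jmax, curve.ppfd, config)
        return np.minimum(vcmax * fc, j * fj) - rd

    def jacobian(p):
        vcmax, jmax, rd = p
        j = electron_transport(jmax, curve.ppfd, config)
        c_active = vcmax * fc <= j * fj
        out = np.zeros((len(ci), 3))
        out[c_active, 0] = fc[c_active]
        if config.light_model == "nrh":
            i2 = config.quantum_yield * curve.ppfd
            disc = np.sqrt((i2 + jmax) ** 2 - 4.0 * config.theta * i2 * jmax)
            dj_djmax = (1.0 - (i2 + jmax - 2.0 * config.theta * i2) / disc) \
                / (2.0 * config.theta)
        else:
            dj_djmax = 1.0
        out[~c_active, 1] = fj[~c_active] * dj_djmax
        out[:, 2] = -1.0
        return out

    lo = [config.bounds_vcmax[0], config.bounds_jmax[0], config.bounds_rd[0]]
    hi = [config.bounds_vcmax[1], config.bounds_jmax[1], config.bounds_rd[1]]

    best = None
    best_cost = np.inf
    converged = False
    n_agree = 0
    for start in _start_grid(config):
        x0 = np.clip(start, lo, hi)
        try:
            res = least_squares(lambda p: model(p) - a_obs, x0, jac=jacobian,
                                bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:          # pragma: no cover - optimizer blow-up
            continue
        tol = 0.0 if best is None else 1e-6 * max(best_cost, 1e-12)
        if best is None or res.cost < best_cost - tol:
            best_cost = res.cost
            best = res
            converged = res.success
            n_agree = 1
        elif res.cost <= best_cost + tol:
            n_agree += 1
        if best_cost < config.objective_tol * max(1.0, np.mean(a_obs**2)) * 1e-4:
            break  # essentially exact fit; further starts cannot improve
        if n_agree >= 2 and best is not None:
            break  # two starts converged to the same optimum

    flags: list[str] = []
    if best is None or not np.all(np.isfinite(best.x)):
        flags.append("nonconvergence")
        vcmax = jmax = rd = np.nan
        limitation: tuple[str, ...] = ()
        rmse = np.nan
    else:
        if not converged:
            flags.append("nonconvergence")
        vcmax, jmax, rd = best.x
        ac, aj = fvcb_limitation_rates(ci, vcmax, jmax, kin, curve.t_leaf,
                                       curve.ppfd, config)
        limitation = tuple(
            "tie" if abs(c - j) <= config.tie_rtol * max(abs(c), abs(j), 1e-12)
            else ("C" if c < j else "J")
            for c, j in zip(ac, aj)
        )
        if not any(s in ("J", "tie") for s in limitation):
            flags.append("jmax_unidentifiable")
        if not any(s in ("C", "tie") for s in limitation):
            flags.append("vcmax_unidentifiable")
        rmse = float(np.sqrt(2.0 * best.cost / len(ci)))

    params = PhotoParams(vcmax_t=float(vcmax), jmax_t=float(jmax), rd_t=float(rd),
                         rmse=rmse, n_points=int(len(ci)), t_leaf=curve.t_leaf,
                         limitation=limitation, flags=flags)
    return normalize_params(params, kin)


def normalize_params(params: PhotoParams, kin: KineticConstants | None = None) -> PhotoParams:
    """Fill in the 25 °C-normalized capacities of a fitted parameter set."""
    kin = kin or KineticConstants()
    t = params.t_leaf
    return replace(
        params,
        vcmax25=float(arrhenius_scale(params.vcmax_t, t, 25.0, kin.ea_vcmax, kin.r_gas)),
        jmax25=float(arrhenius_scale(params.jmax_t, t, 25.0, kin.ea_jmax, kin.r_gas)),
        rd25=float(arrhenius_scale(params.rd_t, t, 25.0, kin.ea_rd, kin.r_gas)),
    )


def extract_asat(ca_set, a_net, flags: list[str] | None = None) -> tuple[float, float]:
    """Light-saturated assimilation at the 400 and 2000 ppm setpoints.

    Replicate 400-setpoint readings are averaged. A missing setpoint yields
    NaN plus a flag entry (if a ``flags`` list is supplied) rather than an
    exception, so spot records with only the Asat setpoints are acceptable.
    """
    ca_set = np.asarray(ca_set, dtype=float)
    a_net = np.asarray(a_net, dtype=float)
    m400 = np.isclose(ca_set, 400.0)
    m2000 = np.isclose(ca_set, 2000.0)
    if m400.any():
        asat400 = float(np.mean(a_net[m400]))
    else:
        asat400 = np.nan
        if flags is not None:
            flags.append("missing_setpoint_400")
    if m2000.any():
        asat2000 = float(np.mean(a_net[m2000]))
    else:
        asat2000 = np.nan
        if flags is not None:
            flags.append("missing_setpoint_2000")
    return asat400, asat2000


def extract_asat_curve(curve: ACiCurve) -> tuple[float, float]:
    return extract_asat(curve.ca_set, curve.a_net)
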