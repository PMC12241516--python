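"""Seeded generator of a complete synthetic trait study along a VPD gradient.

Emulates the sampling design of a three-site, seven-plot tropical VPD
gradient: plots within a site share a species pool, species composition is
disjoint between sites, species are weighted by log-normal basal areas, and
every raw measurement type of the pipeline (A-Ci curves, spot gas exchange,
leaf δ13C, pressure–volume curves, twig anatomy, branch areas, species
stature/wood density) is produced from plot-level true trait means that
interpolate linearly in VPD between configured wet- and dry-end values.

True values are layered as plot mean + species effect (shared by a species
across the plots of its site) + tree effect + measurement noise, with the
interspecific spread set wider than the intraspecific one. All randomness
flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aci as aci_mod
from . import hydraulics as hyd
from . import isotope as iso
from .aci import ACiCurve, KineticConstants, PROTOCOL_SEQUENCE, arrhenius_scale
from .hydraulics import AnatomySection, PVCurve

SITES = ("ANK", "BOB", "KOG")
PLOTS = ("ANK01", "ANK03", "BOB01", "BOB02", "KOG02", "KOG04", "KOG05")
PLOT_SITE = {p: p[:3] for p in PLOTS}

#: Plot positions along the wet→dry axis, clustered by site: plots of a site
#: are a few hundred metres apart and share a met station, so VPD separates
#: sites far more than plots within a site.
PLOT_FRACTIONS = (0.0, 0.08, 0.42, 0.50, 0.84, 0.92, 1.0)

#: Wet-end and dry-end plot-scale true trait means (units as in the pipeline).
DEFAULT_ENDPOINTS: dict[str, tuple[float, float]] = {
    "chi": (0.85, 0.71),
    "vcmax25": (22.0, 46.0),
    "jmax25": (38.0, 91.0),
    "rd25": (1.7, 2.4),
    "asat400": (4.6, 7.7),
    "asat2000": (15.9, 22.9),
    "huber": (360.0, 902.0),          # cm² m⁻²
    "tlp": (-1.3, -1.6),              # MPa
    "kp": (29.0, 59.0),               # kg m⁻¹ MPa⁻¹ s⁻¹
    "vessel_density": (45.0, 70.0),   # mm⁻²
    "wood_density": (0.55, 0.67),     # g cm⁻³
    "twig_density": (0.50, 0.62),     # g cm⁻³
    "hmax": (45.0, 18.0),             # m
}

#: Hard physical bounds applied to drawn true values.
TRAIT_BOUNDS = {
    "chi": (0.05, 0.98),
    "tlp": (-5.0, -0.2),
    "hmax": (2.0, 80.0),
}


@dataclass
class GradientConfig:
    """Study design and effect/noise sizes of the synthetic gradient."""

    vpd_range: tuple[float, float] = (0.28, 0.72)   # kPa, wet → dry
    mat_range: tuple[float, float] = (25.0, 26.4)   # °C
    map_range: tuple[float, float] = (2050.0, 1200.0)  # mm yr⁻¹
    deciduous_range: tuple[float, float] = (0.02, 0.65)
    ppfd_index_range: tuple[float, float] = (1.0, 1.4)
    species_per_site: int = 12
    trees_per_species: int = 3
    leaves_per_tree: int = 3
    aci_trees_per_species: int = 1     # one A-Ci individual per species per plot
    endpoints: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENDPOINTS))
    species_sd_frac: float = 0.12      # interspecific sd as fraction of wet-dry span
    tree_sd_frac: float = 0.06         # intraspecific (tree) sd, same units
    noise_scale: float = 1.0           # global multiplier on every sd
    basal_area_sigma: float = 0.6      # lognormal sigma of site-level basal areas
    basal_area_plot_sigma: float = 0.15  # per-plot multiplicative jitter
    aci_noise_sd: float = 0.5          # µmol m⁻² s⁻¹ on A
    aci_ci_jitter: float = 5.0         # ppm sd of realized ci around 0.7·setpoint
    asat_noise_sd: float = 0.4         # µmol m⁻² s⁻¹ on spot readings
    rd_noise_sd: float = 0.15          # µmol m⁻² s⁻¹ on dark respiration
    d13c_noise_sd: float = 0.25        # per mil
    rwc_noise_sd: float = 0.005        # relative water content
    pv_elasticity: float = 10.0        # MPa
    pv_apoplastic_fraction: float = 0.15
    pv_points: int = 14
    vessel_diam_sigma: float = 0.2     # lognormal shape of vessel diameters
    section_area_mm2: float = 1.5
    leaf_area_mean_m2: float = 0.08
    t_leaf: float = 30.0               # °C, block temperature of gas exchange
    ppfd: float = 2000.0
    delta_air: float = -8.0

    def __post_init__(self) -> None:
        if self.species_per_site < 1 or self.trees_per_species < 1:
            raise ValueError("need at least one species and one tree")
        if self.noise_scale < 0 or self.species_sd_frac < 0 or self.tree_sd_frac < 0:
            raise ValueError("noise parameters must be non-negative")
        for trait, (lo, hi) in self.endpoints.items():
            if trait not in DEFAULT_ENDPOINTS:
                raise ValueError(f"unknown endpoint trait {trait!r}")

    @property
    def plot_fractions(self) -> np.ndarray:
        return np.asarray(PLOT_FRACTIONS)

    def plot_vpd(self) -> dict[str, float]:
        lo, hi = self.vpd_range
        return dict(zip(PLOTS, lo + (hi - lo) * self.plot_fractions))

    def plot_mean(self, trait: str) -> dict[str, float]:
        wet, dry = self.endpoints[trait]
        return dict(zip(PLOTS, wet + (dry - wet) * self.plot_fractions))

    def trait_scale(self, trait: str) -> float:
        wet, dry = self.endpoints[trait]
        return abs(dry - wet)


def _clip(trait: str, value: float) -> float:
    lo, hi = TRAIT_BOUNDS.get(trait, (-np.inf, np.inf))
    return float(np.clip(value, lo, hi))


def generate_aci_curve(vcmax_t: float, jmax_t: float, rd_t: float,
                       t_leaf: float, rng: np.random.Generator,
                       noise_sd: float = 0.5, ci_jitter: float = 5.0,
                       ppfd: float = 2000.0,
                       kin: KineticConstants | None = None,
                       ids: tuple[str, str, str, str] = ("L", "T", "S", "P"),
                       ) -> ACiCurve:
    """Forward FvCB response at the protocol CO2 sequence.

    Realized ci follows the simple plumbing model ci = 0.7·setpoint plus
    jitter (it stands in for unmodeled stomatal dynamics), and Gaussian
    noise is added to A.
    """
    kin = kin or KineticConstants()
    ca = np.array(PROTOCOL_SEQUENCE, dtype=float)
    ci = 0.7 * ca + rng.normal(0.0, ci_jitter, size=len(ca))
    ci = np.maximum(ci, 5.0)
    a = aci_mod.fvcb_assimilation(ci, vcmax_t, jmax_t, rd_t, kin, t_leaf, ppfd)
    a = a + rng.normal(0.0, noise_sd, size=len(ca))
    leaf, tree, spec, plot = ids
    return ACiCurve(leaf, tree, spec, plot, ca, ci, a, t_leaf, ppfd)


def analytic_tlp(pi_o: float, elasticity: float) -> float:
    """Closed-form turgor-loss point of the generator's PV model (MPa)."""
    return pi_o * elasticity / (elasticity + pi_o)


def pi_o_for_tlp(tlp: float, elasticity: float) -> float:
    """Full-turgor osmotic potential whose analytic TLP equals ``tlp``."""
    return tlp * elasticity / (elasticity - tlp)


def generate_pv_curve(pi_o: float, elasticity: float,
                      rng: np.random.Generator,
                      apoplastic_fraction: float = 0.15,
                      noise_sd: float = 0.0, n_points: int = 14,
                      leaf_id: str = "L") -> tuple[PVCurve, float]:
    """Pressure–volume curve from a linear-turgor osmotic model.

    The symplastic fraction Rs = (RWC − af)/(1 − af) sets the osmotic
    potential π = π_o/Rs; turgor declines linearly with water loss at
    modulus ε and vanishes at the analytic turgor-loss point
    π_o·ε/(ε + π_o), which is also returned as truth. The sampling grid
    always contains the turgor-loss point itself.
    """
    if pi_o >= 0 or elasticity <= 0:
        raise ValueError("pi_o must be negative and elasticity positive")
    af = apoplastic_fraction
    rs_tlp = 1.0 + pi_o / elasticity
    if rs_tlp <= 0:
        raise ValueError("elasticity too small for this pi_o")
    rwc_tlp = af + (1.0 - af) * rs_tlp
    n_pre = max(3, n_points // 3)
    pre = np.linspace(0.995, rwc_tlp, n_pre, endpoint=False)
    post = np.linspace(rwc_tlp, max(rwc_tlp - 0.08, af + 0.05), n_points - n_pre)
    rwc = np.concatenate([pre, post])
    if noise_sd > 0:
        rwc = rwc + rng.normal(0.0, noise_sd, size=len(rwc))
        rwc = np.clip(rwc, af + 0.02, 0.999)
    rs = (rwc - af) / (1.0 - af)
    pi = pi_o / rs
    turgor = np.maximum(0.0, -pi_o - elasticity * (1.0 - rs))
    psi = np.minimum(turgor + pi, -1e-3)
    return PVCurve(leaf_id, psi, rwc), float(analytic_tlp(pi_o, elasticity))


def generate_anatomy(target_kp: float, target_density: float,
                     rng: np.random.Generator,
                     section_area_mm2: float = 1.5,
                     diam_sigma: float = 0.2, exact: bool = False,
                     ids: tuple[str, str, str] = ("W", "S", "P"),
                     ) -> AnatomySection:
    """Twig section whose Poiseuille conductivity hits ``target_kp``.

    The vessel count is Poisson around density·area (deterministic
    rounding, with the section area adjusted so the realized density is
    exact, when ``exact``); lognormal diameters are rescaled so the
    hydraulic-mean Kp equals the target exactly.
    """
    if target_kp <= 0 or target_density <= 0:
        raise ValueError("targets must be positive")
    lam = target_density * section_area_mm2
    if exact:
        count = max(1, int(round(lam)))
        area = count / target_density
    else:
        count = max(1, int(rng.poisson(lam)))
        area = section_area_mm2
    d = rng.lognormal(np.log(60.0), diam_sigma, size=count) if diam_sigma > 0 \
        else np.full(count, 60.0)
    twig, spec, plot = ids
    section = AnatomySection(twig, spec, plot, d, area)
    kp0, *_ = hyd.kp_from_anatomy(section, diameter_mode="hydraulic")
    section.vessel_diameters = d * (target_kp / kp0) ** 0.25
    return section


def generate_study(config: GradientConfig | None = None, seed: int = 0
                   ) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Produce the full raw-data bundle and its generating truth.

    Returns ``(bundle, truth)``: the bundle maps file stems
    (``aci_curves``, ``asat_spot``, ``leaf_isotopes``, ``pv_curves``,
    ``anatomy``, ``branch_areas``, ``species_traits``, ``basal_area``,
    ``climate``) to DataFrames conforming to the pipeline input schemas;
    the truth maps ``plot_means`` and ``species_values`` to the generating
    trait values. Byte-identical for identical (config, seed).
    """
    config = config or GradientConfig()
    rng = np.random.default_rng(seed)
    kin = KineticConstants()
    ns = config.noise_scale

    vpd = config.plot_vpd()
    fractions = dict(zip(PLOTS, config.plot_fractions))
    traits = list(config.endpoints)

    # species pools: disjoint across sites, shared by the plots of a site
    site_species = {s: [f"{s}_sp{j:02d}" for j in range(config.species_per_site)]
                    for s in SITES}
    # interspecific effects, constant for a species across its site's plots
    sp_effect = {
        t: {sp: rng.normal(0.0, ns * config.species_sd_frac * config.trait_scale(t))
            for s in SITES for sp in site_species[s]}
        for t in traits
    }
    # deciduousness assigned at the species level from the site-mean fraction
    lo_d, hi_d = config.deciduous_range
    site_frac = {s: float(np.mean([lo_d + (hi_d - lo_d) * fractions[p]
                                   for p in PLOTS if PLOT_SITE[p] == s]))
                 for s in SITES}
    phenology = {sp: ("deciduous" if rng.random() < site_frac[s] else "evergreen")
                 for s in SITES for sp in site_species[s]}
    # abundances are a site-level property with mild plot-to-plot variation
    site_ba = {sp: rng.lognormal(0.0, config.basal_area_sigma)
               for s in SITES for sp in site_species[s]}

    true_sp_rows = []
    sp_plot_value: dict[tuple[str, str, str], float] = {}
    for p in PLOTS:
        s = PLOT_SITE[p]
        for sp in site_species[s]:
            for t in traits:
                wet, dry = config.endpoints[t]
                v = _clip(t, wet + (dry - wet) * fractions[p] + sp_effect[t][sp])
                sp_plot_value[(p, sp, t)] = v
                true_sp_rows.append(dict(plot_id=p, species_id=sp, trait=t, value=v))

    def tree_value(p: str, sp: str, t: str) -> float:
        sd = ns * config.tree_sd_frac * config.trait_scale(t)
        return _clip(t, sp_plot_value[(p, sp, t)] + (rng.normal(0.0, sd) if sd > 0 else 0.0))

    aci_rows, spot_rows, iso_rows, pv_rows = [], [], [], []
    anat_rows, area_rows, sptrait_rows, ba_rows = [], [], [], []

    for p in PLOTS:
        s = PLOT_SITE[p]
        for sp in site_species[s]:
            ba = float(site_ba[sp]
                       * rng.lognormal(0.0, config.basal_area_plot_sigma))
            ba_rows.append(dict(plot_id=p, species_id=sp, basal_area_m2=ba))
            sptrait_rows.append(dict(
                species_id=sp, plot_id=p, site_id=s,
                hmax_m=tree_value(p, sp, "hmax"),
                wood_density_g_cm3=tree_value(p, sp, "wood_density"),
                phenology=phenology[sp],
            ))
            for k in range(config.trees_per_species):
                tree = f"{p}_{sp}_t{k}"
                # --- A-Ci curve (first tree(s) only, per field protocol) ---
                if k < config.aci_trees_per_species:
                    v25 = tree_value(p, sp, "vcmax25")
                    j25 = tree_value(p, sp, "jmax25")
                    r25 = tree_value(p, sp, "rd25")
                    vt = arrhenius_scale(v25, 25.0, config.t_leaf, kin.ea_vcmax)
                    jt = arrhenius_scale(j25, 25.0, config.t_leaf, kin.ea_jmax)
                    rt = arrhenius_scale(r25, 25.0, config.t_leaf, kin.ea_rd)
                    leaf = f"{tree}_aci"
                    curve = generate_aci_curve(
                        vt, jt, rt, config.t_leaf, rng,
                        noise_sd=ns * config.aci_noise_sd,
                        ci_jitter=ns * config.aci_ci_jitter,
                        ppfd=config.ppfd, kin=kin, ids=(leaf, tree, sp, p))
                    for ca, ci, a in zip(curve.ca_set, curve.ci, curve.a_net):
                        aci_rows.append(dict(
                            leaf_id=leaf, tree_id=tree, species_id=sp, plot_id=p,
                            site_id=s, ca_set_ppm=ca, ci_ppm=ci, a_umol_m2_s=a,
                            tleaf_c=config.t_leaf, ppfd_umol_m2_s=config.ppfd))
                # --- per-leaf measurements ---
                a400_tree = tree_value(p, sp, "asat400")
                a2000_tree = tree_value(p, sp, "asat2000")
                rd_tree_t = arrhenius_scale(tree_value(p, sp, "rd25"),
                                            25.0, config.t_leaf, kin.ea_rd)
                chi_tree = tree_value(p, sp, "chi")
                tlp_tree = tree_value(p, sp, "tlp")
                for m in range(config.leaves_per_tree):
                    leaf = f"{tree}_l{m}"
                    # two lit 400-ppm replicates, one 2000-ppm reading, and a
                    # darkened reading of the same leaf for Rd
                    for ca, a, ppfd in ((400.0, a400_tree, config.ppfd),
                                        (400.0, a400_tree, config.ppfd),
                                        (2000.0, a2000_tree, config.ppfd),
                                        (400.0, -rd_tree_t, 0.0)):
                        sd = config.asat_noise_sd if ppfd > 0 else config.rd_noise_sd
                        spot_rows.append(dict(
                            leaf_id=leaf, tree_id=tree, species_id=sp, plot_id=p,
                            site_id=s, ca_set_ppm=ca,
                            a_umol_m2_s=a + rng.normal(0.0, ns * sd),
                            tleaf_c=config.t_leaf, ppfd_umol_m2_s=ppfd))
                    d13c = iso.delta_leaf_from_big_delta(
                        iso.big_delta_from_chi(chi_tree), config.delta_air)
                    iso_rows.append(dict(
                        leaf_id=leaf, tree_id=tree, species_id=sp, plot_id=p,
                        site_id=s,
                        d13c_leaf_permil=d13c + rng.normal(0.0, ns * config.d13c_noise_sd),
                        delta_air_permil=config.delta_air))
                    pio = pi_o_for_tlp(tlp_tree, config.pv_elasticity)
                    curve_pv, _ = generate_pv_curve(
                        pio, config.pv_elasticity, rng,
                        apoplastic_fraction=config.pv_apoplastic_fraction,
                        noise_sd=ns * config.rwc_noise_sd,
                        n_points=config.pv_points, leaf_id=leaf)
                    pv_rows.append((leaf, tree, sp, p, s,
                                    curve_pv.psi, curve_pv.rwc))
                # --- twig anatomy & density ---
                twig = f"{tree}_w"
                section = generate_anatomy(
                    tree_value(p, sp, "kp"), tree_value(p, sp, "vessel_density"),
                    rng, section_area_mm2=config.section_area_mm2,
                    diam_sigma=config.vessel_diam_sigma, exact=(ns == 0.0),
                    ids=(twig, sp, p))
                td = tree_value(p, sp, "twig_density")
                anat_rows.append((twig, tree, sp, p, s,
                                  section.vessel_diameters, section.section_area,
                                  td * 1.2, 1.2))
                # --- branch areas (Huber value) ---
                hub = tree_value(p, sp, "huber")
                la = float(rng.lognormal(np.log(config.leaf_area_mean_m2), 0.15))
                area_rows.append(dict(
                    branch_id=f"{tree}_b", tree_id=tree, species_id=sp,
                    plot_id=p, site_id=s,
                    sapwood_area_cm2=hub * la, leaf_area_m2=la))

    lo_i, hi_i = config.ppfd_index_range
    climate = pd.DataFrame([
        dict(plot_id=p, site_id=PLOT_SITE[p], vpd_kpa=vpd[p],
             mat_c=config.mat_range[0]
             + (config.mat_range[1] - config.mat_range[0]) * fractions[p],
             map_mm=config.map_range[0]
             + (config.map_range[1] - config.map_range[0]) * fractions[p],
             ppfd_index=lo_i + (hi_i - lo_i) * fractions[p],
             deciduous_fraction=lo_d + (hi_d - lo_d) * fractions[p])
        for p in PLOTS
    ])

    plot_mean_rows = [dict(plot_id=p, trait=t, value=config.plot_mean(t)[p])
                      for p in PLOTS for t in traits]

    def _expand(rows, value_cols):
        # rows: (leaf/twig ids..., per-point arrays/values); repeat ids per point
        id_names = ["unit", "tree_id", "species_id", "plot_id", "site_id"]
        out: dict[str, np.ndarray] = {}
        n_each = [np.size(r[5]) for r in rows]
        for i, name in enumerate(id_names):
            out[name] = np.repeat([r[i] for r in rows], n_each)
        for j, name in enumerate(value_cols):
            vals = [np.broadcast_to(np.asarray(r[5 + j], dtype=float),
                                    (n_each[k],)) for k, r in enumerate(rows)]
            out[name] = np.concatenate(vals)
        return pd.DataFrame(out)

    pv_df = _expand(pv_rows, ["psi_mpa", "rwc"]).rename(columns={"unit": "leaf_id"})
    anat_df = _expand(anat_rows, ["vessel_diameter_um", "section_area_mm2",
                                  "twig_dry_mass_g", "twig_volume_cm3"]
                      ).rename(columns={"unit": "twig_id"})

    bundle = {
        "aci_curves": pd.DataFrame(aci_rows),
        "asat_spot": pd.DataFrame(spot_rows),
        "leaf_isotopes": pd.DataFrame(iso_rows),
        "pv_curves": pv_df,
        "anatomy": anat_df,
        "branch_areas": pd.DataFrame(area_rows),
        "species_traits": pd.DataFrame(sptrait_rows),
        "basal_area": pd.DataFrame(ba_rows),
        "climate": climate,
    }
    truth = {
        "plot_means": pd.DataFrame(plot_mean_rows),
        "species_values": pd.DataFrame(true_sp_rows),
    }
    return bundle, truth


def write_bundle(bundle: dict[str, pd.DataFrame], outdir, truth=None) -> None:
    """Write every bundle table (and optional truth tables) as CSV."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=False)
    if truth:
        for name, df in truth.items():
            df.to_csv(out / f"truth_{name}.csv", index=False)


def read_bundle(indir) -> dict[str, pd.DataFrame]:
    import pathlib

    out = {}
    for path in sorted(pathlib.Path(indir).glob("*.csv")):
        if not path.stem.startswith("truth_"):
            out[path.stem] = pd.read_csv(path)
    return out
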