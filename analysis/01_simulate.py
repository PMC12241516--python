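#!/usr/bin/env python
"""Generate the synthetic VPD-gradient study used by the downstream steps.

Produces the full raw-measurement bundle (A-Ci curves, spot gas exchange,
leaf δ13C, pressure-volume curves, twig anatomy, branch areas, species
stature/wood density, basal areas, plot climate) for the default
three-site / seven-plot design, and the truth tables recording the
generating trait values.
"""

import pathlib

from vpdtraits import synthdata
from vpdtraits.synthdata import GradientConfig

SEED = 42
OUTDIR = pathlib.Path(__file__).resolve().parents[1] / "results" / "synth"


def main() -> None:
    config = GradientConfig()
    bundle, truth = synthdata.generate_study(config, seed=SEED)
    synthdata.write_bundle(bundle, OUTDIR, truth)
    climate = bundle["climate"]
    print(f"simulated {len(climate)} plots across "
          f"{climate['site_id'].nunique()} sites "
          f"(VPD {climate['vpd_kpa'].min():.2f}-{climate['vpd_kpa'].max():.2f} kPa)")
    print(f"species per site: {config.species_per_site}; "
          f"A-Ci curves: {bundle['aci_curves']['leaf_id'].nunique()}; "
          f"PV curves: {bundle['pv_curves']['leaf_id'].nunique()}; "
          f"twig sections: {bundle['anatomy']['twig_id'].nunique()}")
    print(f"raw tables written to {OUTDIR}")


if __name__ == "__main__":
    main()
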