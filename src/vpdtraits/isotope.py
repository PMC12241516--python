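"""Leaf carbon-isotope discrimination and the ci/ca ratio.

δ13C of leaf tissue is converted to photosynthetic discrimination Δ13C
against the atmospheric source, and Δ13C is inverted to the ratio of
leaf-internal to ambient CO2 (χ = ci/ca) with the two-endpoint
fractionation model: diffusional fractionation ``a`` and carboxylation
fractionation ``b`` bracket Δ, and χ interpolates linearly between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default fractionation endpoints (per mil) and atmospheric δ13C.
A_FRAC_DEFAULT = 4.4
B_FRAC_DEFAULT = 27.0
DELTA_AIR_DEFAULT = -8.0


@dataclass
class IsotopeRecord:
    delta_leaf: float          # δ13C of leaf tissue, per mil
    delta_air: float           # atmospheric δ13C, per mil
    big_delta: float           # Δ13C, per mil
    chi: float                 # ci/ca
    out_of_range: bool = False # Δ outside [a, b] / chi outside [0, 1]


def big_delta_from_deltas(delta_leaf, delta_air=DELTA_AIR_DEFAULT):
    """Photosynthetic discrimination Δ13C (per mil).

    Δ = (δ_air − δ_leaf) / (1 + δ_leaf/1000). Exact inverse of
    :func:`delta_leaf_from_big_delta`.
    """
    delta_leaf = np.asarray(delta_leaf, dtype=float)
    if np.any(delta_leaf <= -1000.0):
        raise ValueError("delta_leaf must exceed -1000 per mil")
    out = (delta_air - delta_leaf) / (1.0 + delta_leaf / 1000.0)
    return out.item() if out.ndim == 0 else out


def delta_leaf_from_big_delta(big_delta, delta_air=DELTA_AIR_DEFAULT):
    """Leaf δ13C consistent with a given discrimination (inverse map)."""
    big_delta = np.asarray(big_delta, dtype=float)
    out = (delta_air - big_delta) / (1.0 + big_delta / 1000.0)
    return out.item() if out.ndim == 0 else out


def chi_from_big_delta(big_delta, a_frac=A_FRAC_DEFAULT, b_frac=B_FRAC_DEFAULT):
    """Invert Δ13C to χ = ci/ca with the linear two-endpoint model.

    χ = (Δ − a)/(b − a); values outside [0, 1] are returned as-is so the
    caller can flag (not silently clip) out-of-range records.
    """
    if b_frac <= a_frac:
        raise ValueError("b_frac must exceed a_frac")
    big_delta = np.asarray(big_delta, dtype=float)
    out = (big_delta - a_frac) / (b_frac - a_frac)
    return out.item() if out.ndim == 0 else out


def big_delta_from_chi(chi, a_frac=A_FRAC_DEFAULT, b_frac=B_FRAC_DEFAULT):
    """Forward two-endpoint model: Δ = a + (b − a)·χ."""
    chi = np.asarray(chi, dtype=float)
    out = a_frac + (b_frac - a_frac) * chi
    return out.item() if out.ndim == 0 else out


def derive_record(delta_leaf: float, delta_air: float = DELTA_AIR_DEFAULT,
                  a_frac: float = A_FRAC_DEFAULT,
                  b_frac: float = B_FRAC_DEFAULT) -> IsotopeRecord:
    """Full leaf-level derivation with out-of-range flagging."""
    big_delta = big_delta_from_deltas(delta_leaf, delta_air)
    chi = chi_from_big_delta(big_delta, a_frac, b_frac)
    return IsotopeRecord(
        delta_leaf=float(delta_leaf), delta_air=float(delta_air),
        big_delta=float(big_delta), chi=float(chi),
        out_of_range=not (0.0 <= chi <= 1.0),
    )
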