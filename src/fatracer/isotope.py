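"""Carbon stable-isotope algebra for compound-specific tracer work.

Converts between the three scales used in 13C labelling studies --
delta notation (per mil vs the VPDB standard), the raw 13C/12C ratio, and
atom percent (absolute 13C concentration) -- and applies the
derivatization correction that recovers the carbon mass of a fatty acid
from the mass of its methyl ester (FAME).

The methyl carbon introduced by transesterification comes from (unlabelled)
methanol, so it contributes one mole of pure 12C to the FAME molar mass but
none of the measured enrichment: the carbon-mass correction therefore adds
A_12C to the denominator only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .nomenclature import FattyAcid, fame_composition

__all__ = [
    "IsotopeConstants",
    "IsotopeValue",
    "IsotopeKind",
    "VPDB",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_to_atom_percent",
    "atom_percent_to_ratio",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "atom_percent_excess",
    "carbon_mass",
    "carbon_fraction",
]


@dataclass(frozen=True)
class IsotopeConstants:
    """Physical constants of the carbon isotope system.

    r_standard is the 13C/12C ratio of the Vienna Pee Dee Belemnite (VPDB)
    reference; the atomic masses are in unified atomic mass units.
    """

    r_standard: float = 0.0112372
    a_12c: float = 12.0
    a_13c: float = 13.00335
    a_h: float = 1.00794
    a_o: float = 15.9994

    def __post_init__(self) -> None:
        for name in ("r_standard", "a_12c", "a_13c", "a_h", "a_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.a_13c <= self.a_12c:
            raise ValueError("a_13c must exceed a_12c")


#: Default constants (VPDB ratio 0.0112372, IUPAC atomic masses).
VPDB = IsotopeConstants()


class IsotopeKind(str, Enum):
    delta_permil = "delta"
    atom_percent = "atom_percent"


@dataclass(frozen=True)
class IsotopeValue:
    """A measured isotope value on either the delta or the atom% scale."""

    kind: IsotopeKind
    value: float

    def __post_init__(self) -> None:
        if self.kind is IsotopeKind.atom_percent and not 0.0 <= self.value <= 100.0:
            raise ValueError(f"atom percent {self.value} outside [0, 100]")
        if self.kind is IsotopeKind.delta_permil and self.value <= -1000.0:
            raise ValueError(f"delta {self.value} per mil implies a negative ratio")

    def as_atom_percent(self, constants: IsotopeConstants = VPDB) -> float:
        if self.kind is IsotopeKind.atom_percent:
            return self.value
        return delta_to_atom_percent(self.value, constants)


def delta_to_ratio(delta, constants: IsotopeConstants = VPDB):
    """13C/12C ratio from a delta value (per mil vs the standard)."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta <= -1000 per mil implies a non-physical ratio")
    out = constants.r_standard * (delta / 1000.0 + 1.0)
    return out.item() if out.ndim == 0 else out


def ratio_to_delta(ratio, constants: IsotopeConstants = VPDB):
    """Delta value (per mil) from a 13C/12C ratio."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("negative isotope ratio")
    out = (ratio / constants.r_standard - 1.0) * 1000.0
    return out.item() if out.ndim == 0 else out


def ratio_to_atom_percent(ratio):
    """Atom percent 13C from a 13C/12C ratio: 100 * R / (R + 1)."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("negative isotope ratio")
    out = 100.0 * ratio / (ratio + 1.0)
    return out.item() if out.ndim == 0 else out


def atom_percent_to_ratio(atom_pct):
    """13C/12C ratio from atom percent; inverse of ratio_to_atom_percent."""
    atom_pct = np.asarray(atom_pct, dtype=float)
    if np.any((atom_pct < 0) | (atom_pct >= 100)):
        raise ValueError("atom percent outside [0, 100)")
    frac = atom_pct / 100.0
    out = frac / (1.0 - frac)
    return out.item() if out.ndim == 0 else out


def delta_to_atom_percent(delta, constants: IsotopeConstants = VPDB):
    """Atom percent from delta per mil (chain through the ratio scale)."""
    return ratio_to_atom_percent(delta_to_ratio(delta, constants))


def atom_percent_to_delta(atom_pct, constants: IsotopeConstants = VPDB):
    """Delta per mil from atom percent (exact inverse of the forward chain)."""
    return ratio_to_delta(atom_percent_to_ratio(atom_pct), constants)


def atom_percent_excess(sample_ap, baseline_ap):
    """APE: enrichment of a labelled sample above its unlabelled baseline.

    Signed difference on the atom% scale; zero when the sample sits at the
    baseline, invariant to a common shift of both values.
    """
    sample_ap = np.asarray(sample_ap, dtype=float)
    baseline_ap = np.asarray(baseline_ap, dtype=float)
    for arr, name in ((sample_ap, "sample"), (baseline_ap, "baseline")):
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError(f"{name} atom percent outside [0, 100]")
    out = sample_ap - baseline_ap
    return out.item() if out.ndim == 0 else out


def _fame_molar_mass_terms(
    fa: FattyAcid, atom_pct, constants: IsotopeConstants
) -> tuple:
    """(weighted FA-carbon mass, non-FA-carbon rest mass) of the FAME."""
    _, h_fame, o_fame = fame_composition(fa)
    frac = np.asarray(atom_pct, dtype=float) / 100.0
    w = frac * constants.a_13c + (1.0 - frac) * constants.a_12c
    carbon_term = w * fa.carbons
    rest = constants.a_12c + h_fame * constants.a_h + o_fame * constants.a_o
    return carbon_term, rest


def carbon_fraction(fa: FattyAcid, atom_pct, constants: IsotopeConstants = VPDB):
    """Mass fraction of FAME mass that is fatty-acid carbon.

    The enrichment-weighted carbon mass w = (atom%/100)*A_13C +
    (1 - atom%/100)*A_12C applies to the A carbons of the acid itself; the
    methyl carbon from derivatization enters the denominator as pure 12C.
    """
    atom_pct = np.asarray(atom_pct, dtype=float)
    if np.any((atom_pct < 0) | (atom_pct > 100)):
        raise ValueError("atom percent outside [0, 100]")
    carbon_term, rest = _fame_molar_mass_terms(fa, atom_pct, constants)
    out = carbon_term / (carbon_term + rest)
    return out.item() if out.ndim == 0 else out


def carbon_mass(fame_mass, atom_pct, fa: FattyAcid, constants: IsotopeConstants = VPDB):
    """Carbon mass of a fatty acid from the measured mass of its FAME.

    Parameters
    ----------
    fame_mass : float or array
        FAME-quantified mass per individual (canonically ng ind^-1).
    atom_pct : float or array
        Measured 13C atom percent of the fatty acid.
    fa : FattyAcid
        Identity, fixing the FAME molecular formula.

    Returns
    -------
    Carbon mass in the same mass unit as ``fame_mass``; homogeneous of
    degree 1 in ``fame_mass`` and weakly increasing in ``atom_pct``.
    """
    fame_mass = np.asarray(fame_mass, dtype=float)
    if np.any(fame_mass < 0):
        raise ValueError("negative FAME mass")
    out = fame_mass * carbon_fraction(fa, atom_pct, constants)
    return out.item() if out.ndim == 0 else out
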