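"""Sample containers: one fatty-acid measurement, one sample profile.

A :class:`SampleProfile` is one analysed sample — a diet batch, a pool of
baseline (in-situ) consumers, or a pool of experimental consumers — holding
per-fatty-acid mass and isotope measurements plus bulk carbon/nitrogen and
dry mass.  Masses are kept in canonical units: ng per individual for
consumers, the diet's native per-volume or per-cell unit is converted on
read.  ``mass_kind`` records whether the stored masses are FAME-quantified
masses (the GC-FID measurement) or already carbon masses (as printed in
study tables); the assimilation pipeline applies the derivatization
correction only to the former.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .isotope import IsotopeConstants, IsotopeValue, VPDB
from .nomenclature import FattyAcid, canonical_label, parse_fa_notation


class SampleGroup(str, Enum):
    diet = "diet"
    in_situ = "in_situ"
    experimental = "experimental"


class MassKind(str, Enum):
    fame = "fame"        # FAME-quantified mass; needs the carbon correction
    carbon = "carbon"    # already ng C (e.g. transcribed table values)


@dataclass(frozen=True)
class FAMeasurement:
    """One fatty acid in one sample: mass plus optional isotope value."""

    fa: FattyAcid
    mass: float
    isotope: IsotopeValue | None = None

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"negative mass for {self.fa.label}")

    def atom_percent(self, constants: IsotopeConstants = VPDB) -> float | None:
        if self.isotope is None:
            return None
        return self.isotope.as_atom_percent(constants)


@dataclass
class SampleProfile:
    """All measurements of one sample.

    measurements maps canonical FA label -> FAMeasurement; fatty acids that
    were not detected are simply absent (N.D. is not a zero measurement for
    averaging, but contributes zero mass to sums).
    """

    sample_id: str
    group: SampleGroup
    measurements: dict[str, FAMeasurement] = field(default_factory=dict)
    replicate: int = 0
    n_individuals: int | None = None
    bulk_c: float | None = None
    bulk_n: float | None = None
    dry_mass: float | None = None
    elapsed_days: float = 0.0
    mass_kind: MassKind = MassKind.fame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = SampleGroup(self.group)
        self.mass_kind = MassKind(self.mass_kind)
        # re-key on canonical labels so joins/lookups are stable
        canon: dict[str, FAMeasurement] = {}
        for label, m in self.measurements.items():
            key = canonical_label(label)
            if key in canon:
                raise ValueError(f"duplicate fatty acid {key} in {self.sample_id}")
            canon[key] = m
        self.measurements = canon

    def add(self, label: str, mass: float, isotope: IsotopeValue | None = None) -> None:
        fa = parse_fa_notation(label)
        if fa.label in self.measurements:
            raise ValueError(f"duplicate fatty acid {fa.label} in {self.sample_id}")
        self.measurements[fa.label] = FAMeasurement(fa=fa, mass=mass, isotope=isotope)

    @property
    def labels(self) -> list[str]:
        return list(self.measurements)

    @property
    def tfa_mass(self) -> float:
        """Total fatty acids: the sum of all per-FA masses."""
        return sum(m.mass for m in self.measurements.values())

    def mass_of(self, label: str) -> float:
        """Mass of one FA; absent (not detected) counts as zero for sums."""
        return self.measurements.get(canonical_label(label), _ZERO).mass


class _Zero:
    mass = 0.0


_ZERO = _Zero()
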