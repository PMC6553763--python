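"""Packaged study fixture: mean composition and enrichment tables.

Transcribed mean values (with printed SDs) from the feeding study the
package reanalyses: a 13C-enriched diatom diet (four analysed batches,
reported as per-FA means), in-situ polychaete larvae sampled before the
experiment, and larvae after five days of feeding.  Consumer fatty-acid
masses are carbon masses (ng C per individual) as printed, so the fixture
profiles carry ``mass_kind="carbon"`` and bypass the FAME correction.

The study does not print per-FA enrichment of the unlabelled in-situ
larvae; the fixture places them at natural abundance (delta 13C = -25 per
mil) and encodes the experimental larvae as baseline + printed APE, so the
pipeline reproduces the printed APE values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .isotope import IsotopeKind, IsotopeValue, delta_to_atom_percent
from .profiles import MassKind, SampleGroup, SampleProfile

#: delta 13C assumed for unlabelled consumer lipids (per mil vs VPDB).
NATURAL_ABUNDANCE_DELTA = -25.0

# --- diet (diatom culture): ng C (per-volume scale), atom% 13C, with SDs
DIET_FA = {
    # label: (c_mass, atom_pct, atom_sd)
    "14:0": (9.0, 3.72, 0.53),
    "16:0": (19.0, 3.62, 0.52),
    "16:1(n-7)": (21.0, 3.72, 0.54),
    "16:1(n-5)": (2.0, 3.48, 0.52),
    "16:2(n-4)": (12.0, 3.73, 0.52),
    "16:3(n-4)": (28.0, 3.73, 0.52),
    "18:0": (1.0, 1.87, 0.30),
    "18:1(n-9)": (1.0, 3.19, 0.55),
    "18:1(n-7)": (1.0, 3.26, 0.45),
    "18:2(n-6)": (1.0, 3.68, 0.51),
    "18:4(n-3)": (7.0, 3.76, 0.54),
    "20:5(n-3)": (34.0, 3.74, 0.53),
    "22:6(n-3)": (8.0, 3.76, 0.53),
}

DIET_BULK = {"bulk_c": 577.0, "bulk_n": 117.0, "total_lipid": 116.0}

# --- consumers: carbon masses (ng C per individual)
IN_SITU_FA_MASS = {
    "14:0": 28.0,
    "16:0": 91.0,
    "16:1(n-7)": 20.0,
    "18:0": 49.0,
    "18:1(n-11)": 18.0,
    "18:1(n-9)": 6.0,
    "18:1(n-7)": 26.0,
    "20:1(n-11)": 11.0,
    "20:5(n-3)": 103.0,
    "22:5(n-3)": 73.0,
    "22:6(n-3)": 31.0,
}

IN_SITU_BULK = {"bulk_c": 7668.0, "bulk_n": 1929.0, "dry_mass": 55.0,
                "total_lipid": 632.0}

# experimental larvae: (total c_mass, APE, APE sd)
EXPERIMENTAL_FA = {
    "14:0": (21.0, 0.93, 0.13),
    "16:0": (132.0, 1.21, 0.14),
    "16:1(n-7)": (29.0, 1.67, 0.09),
    "16:2(n-4)": (8.0, 1.94, 0.02),
    "16:3(n-4)": (4.0, 2.01, 0.06),
    "18:0": (57.0, 0.66, 0.11),
    "18:1(n-11)": (31.0, 0.67, 0.10),
    "18:1(n-7)": (33.0, 0.97, 0.11),
    "18:4(n-3)": (3.0, 1.91, 0.09),
    "20:1(n-11)": (17.0, 0.49, 0.08),
    "20:5(n-3)": (119.0, 1.26, 0.12),
    "22:5(n-3)": (99.0, 0.94, 0.11),
    "22:6(n-3)": (53.0, 1.42, 0.10),
}

EXPERIMENTAL_BULK = {"bulk_c": 8511.0, "bulk_n": 2170.0, "dry_mass": 52.0,
                     "total_lipid": 845.0}

ELAPSED_DAYS = 5.0

# --- printed results used as comparison targets (value, sd) -------------
#: Printed per-FA assimilated carbon (ng C ind^-1) and daily turnover (%/d).
PRINTED_C_ASSIM = {
    "14:0": (6.0, 1.0),
    "16:0": (44.0, 4.0),
    "16:1(n-7)": (14.0, 1.0),
    "16:2(n-4)": (4.0, 0.0),
    "16:3(n-4)": (2.0, 1.0),
    "18:0": (20.0, 2.0),
    "18:1(n-11)": (6.0, 1.0),
    "18:1(n-7)": (9.0, 1.0),
    "18:4(n-3)": (2.0, 0.0),
    "20:1(n-11)": (2.0, 0.0),
    "20:5(n-3)": (41.0, 4.0),
    "22:5(n-3)": (25.0, 2.0),
    "22:6(n-3)": (21.0, 2.0),
}
PRINTED_C_TURN = {
    "14:0": (5.0, 1.0),
    "16:0": (7.0, 1.0),
    "16:1(n-7)": (9.0, 0.0),
    "16:2(n-4)": (11.0, 0.0),
    "16:3(n-4)": (11.0, 0.0),
    "18:0": (7.0, 1.0),
    "18:1(n-11)": (4.0, 1.0),
    "18:1(n-7)": (5.0, 1.0),
    "18:4(n-3)": (11.0, 0.0),
    "20:1(n-11)": (3.0, 0.0),
    "20:5(n-3)": (7.0, 1.0),
    "22:5(n-3)": (5.0, 1.0),
    "22:6(n-3)": (8.0, 1.0),
}
#: Printed internal carbon of fed larvae (ng C ind^-1, no SD column printed
#: for several rows; SDs as printed).
PRINTED_INTERNAL_C = {
    "14:0": (16.0, 2.0),
    "16:0": (88.0, 8.0),
    "16:1(n-7)": (16.0, 0.0),
    "16:2(n-4)": (4.0, 0.0),
    "16:3(n-4)": (2.0, 0.0),
    "18:0": (37.0, 6.0),
    "18:1(n-11)": (26.0, 3.0),
    "18:1(n-7)": (24.0, 1.0),
    "18:4(n-3)": (1.0, 1.0),
    "20:1(n-11)": (15.0, 2.0),
    "20:5(n-3)": (77.0, 3.0),
    "22:5(n-3)": (74.0, 6.0),
    "22:6(n-3)": (32.0, 1.0),
}
#: Printed whole-pool and class aggregates.
PRINTED_AGGREGATES = {
    # group: (ape, ape_sd, c_assim, c_assim_sd, c_turn, c_turn_sd)
    "TFA": (1.16, 0.48, 199.0, 21.0, 6.0, 1.0),
    "SFA": (0.95, 0.24, 72.0, 7.0, 7.0, 1.0),
    "MUFA": (0.90, 0.49, 31.0, 3.0, 5.0, 1.0),
    "PUFA": (1.46, 0.44, 97.0, 11.0, 7.0, 1.0),
}
#: Printed whole-pool diet enrichment and 18:0 level (atom%).
PRINTED_L = 3.62
PRINTED_L_18_0 = 1.87
#: Printed whole-pool fatty-acid carbon totals (ng C ind^-1; diet per L).
PRINTED_TFA_C = {"diet": 148.0, "in_situ": 465.0, "experimental": 622.0,
                 "experimental_internal": 423.0}


@dataclass
class TableFixture:
    """The study's mean profiles as ready-to-run sample collections."""

    diet: list[SampleProfile]
    in_situ: list[SampleProfile]
    experimental: list[SampleProfile]

    @property
    def all_profiles(self) -> list[SampleProfile]:
        return self.diet + self.in_situ + self.experimental


def fixture_from_tables() -> TableFixture:
    """Build diet, in-situ and experimental mean profiles from the
    transcribed study tables."""
    baseline_ap = delta_to_atom_percent(NATURAL_ABUNDANCE_DELTA)

    diet = SampleProfile(
        sample_id="diet_mean",
        group=SampleGroup.diet,
        mass_kind=MassKind.carbon,
        bulk_c=DIET_BULK["bulk_c"],
        bulk_n=DIET_BULK["bulk_n"],
        metadata={"total_lipid": DIET_BULK["total_lipid"]},
    )
    for label, (c_mass, atom_pct, _sd) in DIET_FA.items():
        diet.add(label, c_mass, IsotopeValue(IsotopeKind.atom_percent, atom_pct))

    in_situ = SampleProfile(
        sample_id="insitu_mean",
        group=SampleGroup.in_situ,
        mass_kind=MassKind.carbon,
        bulk_c=IN_SITU_BULK["bulk_c"],
        bulk_n=IN_SITU_BULK["bulk_n"],
        dry_mass=IN_SITU_BULK["dry_mass"],
        metadata={"total_lipid": IN_SITU_BULK["total_lipid"]},
    )
    for label, c_mass in IN_SITU_FA_MASS.items():
        in_situ.add(label, c_mass, IsotopeValue(IsotopeKind.atom_percent, baseline_ap))

    experimental = SampleProfile(
        sample_id="experimental_mean",
        group=SampleGroup.experimental,
        mass_kind=MassKind.carbon,
        elapsed_days=ELAPSED_DAYS,
        bulk_c=EXPERIMENTAL_BULK["bulk_c"],
        bulk_n=EXPERIMENTAL_BULK["bulk_n"],
        dry_mass=EXPERIMENTAL_BULK["dry_mass"],
        metadata={"total_lipid": EXPERIMENTAL_BULK["total_lipid"]},
    )
    for label, (c_mass, ape, _sd) in EXPERIMENTAL_FA.items():
        experimental.add(
            label,
            c_mass,
            IsotopeValue(IsotopeKind.atom_percent, baseline_ap + ape),
        )

    return TableFixture(diet=[diet], in_situ=[in_situ], experimental=[experimental])


def printed_assimilation_frame() -> pd.DataFrame:
    """Printed per-FA C_assim / C_turn / internal-C targets with SDs."""
    rows = []
    for label in EXPERIMENTAL_FA:
        ca, ca_sd = PRINTED_C_ASSIM[label]
        ct, ct_sd = PRINTED_C_TURN[label]
        ic, ic_sd = PRINTED_INTERNAL_C[label]
        rows.append(
            {
                "label": label,
                "c_assim": ca,
                "c_assim_sd": ca_sd,
                "c_turn": ct,
                "c_turn_sd": ct_sd,
                "internal_c": ic,
                "internal_c_sd": ic_sd,
            }
        )
    return pd.DataFrame(rows).set_index("label")
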