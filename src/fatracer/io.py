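"""Long-format CSV schema for measurement tables, plus run configuration.

One row per (sample, fatty acid).  Required columns::

    sample_id, group, replicate, n_individuals, elapsed_days,
    fa, mass, mass_unit, iso_kind, iso_value

``group`` is diet / in_situ / experimental; ``mass_unit`` is ng_per_ind,
pg_per_cell or ug_per_L (converted to the ng scale on read); ``iso_kind``
is delta, atom_percent or nd (not determined, empty iso_value).  Optional
columns: ``mass_kind`` (fame | carbon, default fame), ``bulk_c``,
``bulk_n``, ``dry_mass`` (sample-level, repeated per row).  Unknown columns
are preserved in profile metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .isotope import IsotopeConstants, IsotopeKind, IsotopeValue
from .nomenclature import FANotationError, parse_fa_notation
from .profiles import FAMeasurement, MassKind, SampleGroup, SampleProfile

REQUIRED_COLUMNS = [
    "sample_id",
    "group",
    "replicate",
    "n_individuals",
    "elapsed_days",
    "fa",
    "mass",
    "mass_unit",
    "iso_kind",
    "iso_value",
]

_SAMPLE_COLUMNS = ["bulk_c", "bulk_n", "dry_mass", "mass_kind"]

#: factors onto the canonical ng scale
_UNIT_TO_NG = {"ng_per_ind": 1.0, "pg_per_cell": 1e-3, "ug_per_L": 1e3}


class SchemaError(ValueError):
    """Measurement-table violation, reported with the offending rows."""


def read_measurements(path: str | Path) -> list[SampleProfile]:
    """Read a long-format measurement CSV into sample profiles.

    Masses are converted to the ng scale; delta values are kept as such on
    the measurement (converted to atom% lazily where needed); ``nd`` rows
    with no mass are dropped (not detected is not a zero measurement).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    dup = df.duplicated(subset=["sample_id", "fa"], keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup]]  # +2: header + 1-based
        raise SchemaError(f"{path}: duplicate (sample_id, fa) rows at lines {rows}")

    errors: list[str] = []
    profiles: dict[str, SampleProfile] = {}
    extra_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS + _SAMPLE_COLUMNS
    ]
    for idx, row in df.iterrows():
        line = idx + 2
        sid = str(row["sample_id"])
        try:
            group = SampleGroup(str(row["group"]))
        except ValueError:
            errors.append(f"line {line}: unknown group {row['group']!r}")
            continue
        unit = str(row["mass_unit"])
        if unit not in _UNIT_TO_NG:
            errors.append(f"line {line}: unknown mass_unit {unit!r}")
            continue
        iso_kind = str(row["iso_kind"])
        iso: IsotopeValue | None
        if iso_kind == "nd":
            iso = None
        elif iso_kind == "delta":
            iso = IsotopeValue(IsotopeKind.delta_permil, float(row["iso_value"]))
        elif iso_kind == "atom_percent":
            iso = IsotopeValue(IsotopeKind.atom_percent, float(row["iso_value"]))
        else:
            errors.append(f"line {line}: unknown iso_kind {iso_kind!r}")
            continue
        try:
            fa = parse_fa_notation(str(row["fa"]))
        except FANotationError as exc:
            errors.append(f"line {line}: {exc}")
            continue

        if sid not in profiles:
            mass_kind = MassKind(str(row.get("mass_kind", "fame") or "fame")) \
                if "mass_kind" in df.columns else MassKind.fame
            profiles[sid] = SampleProfile(
                sample_id=sid,
                group=group,
                replicate=int(row["replicate"]) if pd.notna(row["replicate"]) else 0,
                n_individuals=(
                    int(row["n_individuals"]) if pd.notna(row["n_individuals"]) else None
                ),
                elapsed_days=(
                    float(row["elapsed_days"]) if pd.notna(row["elapsed_days"]) else 0.0
                ),
                mass_kind=mass_kind,
                bulk_c=_opt_float(row, "bulk_c", df.columns),
                bulk_n=_opt_float(row, "bulk_n", df.columns),
                dry_mass=_opt_float(row, "dry_mass", df.columns),
                metadata={
                    "mass_unit": unit,
                    **{c: row[c] for c in extra_cols if pd.notna(row.get(c))},
                },
            )
        mass_raw = row["mass"]
        if pd.isna(mass_raw):
            if iso is None:
                continue  # fully not-detected row
            errors.append(f"line {line}: isotope value without a mass")
            continue
        mass_ng = float(mass_raw) * _UNIT_TO_NG[unit]
        profiles[sid].measurements[fa.label] = FAMeasurement(
            fa=fa, mass=mass_ng, isotope=iso
        )
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return list(profiles.values())


def _opt_float(row, col: str, columns) -> float | None:
    if col in columns and pd.notna(row.get(col)):
        return float(row[col])
    return None


def write_measurements(profiles, path: str | Path) -> None:
    """Write profiles to the long-format CSV (canonical ng units)."""
    rows = []
    for prof in profiles:
        for label, meas in prof.measurements.items():
            if meas.isotope is None:
                iso_kind, iso_value = "nd", ""
            elif meas.isotope.kind is IsotopeKind.delta_permil:
                iso_kind, iso_value = "delta", meas.isotope.value
            else:
                iso_kind, iso_value = "atom_percent", meas.isotope.value
            rows.append(
                {
                    "sample_id": prof.sample_id,
                    "group": prof.group.value,
                    "replicate": prof.replicate,
                    "n_individuals": prof.n_individuals,
                    "elapsed_days": prof.elapsed_days,
                    "fa": label,
                    "mass": meas.mass,
                    "mass_unit": "ng_per_ind",
                    "iso_kind": iso_kind,
                    "iso_value": iso_value,
                    "mass_kind": prof.mass_kind.value,
                    "bulk_c": prof.bulk_c,
                    "bulk_n": prof.bulk_n,
                    "dry_mass": prof.dry_mass,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def split_groups(
    profiles,
) -> tuple[list[SampleProfile], list[SampleProfile], list[SampleProfile]]:
    """(diet, in_situ, experimental) lists from a mixed collection."""
    diet = [p for p in profiles if p.group is SampleGroup.diet]
    in_situ = [p for p in profiles if p.group is SampleGroup.in_situ]
    experimental = [p for p in profiles if p.group is SampleGroup.experimental]
    return diet, in_situ, experimental


@dataclass
class RunConfig:
    """Tunable parameters of an analysis run, serializable to YAML."""

    r_standard: float = 0.0112372
    a_12c: float = 12.0
    a_13c: float = 13.00335
    a_h: float = 1.00794
    a_o: float = 15.9994
    default_baseline_delta: float = -25.0
    logit_epsilon: float | None = None
    tfa_filter_percent: float = 1.0
    elapsed_days: float | None = None
    output_dir: str = "results"
    seed: int = 0

    @property
    def constants(self) -> IsotopeConstants:
        return IsotopeConstants(
            r_standard=self.r_standard,
            a_12c=self.a_12c,
            a_13c=self.a_13c,
            a_h=self.a_h,
            a_o=self.a_o,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config fields {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def write_ground_truth(truth, path: str | Path) -> None:
    """JSON sidecar of a simulation's exact ground truth."""
    payload = {
        "l_general": truth.l_general,
        "l_18_0": truth.l_18_0,
        "baseline_atom_percent": truth.baseline_atom_percent,
        "elapsed_days": truth.elapsed_days,
        "per_fa": truth.per_fa.to_dict(orient="index"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
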