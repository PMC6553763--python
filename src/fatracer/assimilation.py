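"""Dietary-carbon assimilation and turnover from 13C-labelled feeding data.

The tracer logic: a consumer fed a 13C-enriched diet accumulates label in
each fatty acid in proportion to how much of that acid's carbon pool was
replaced by dietary carbon.  With

* ``APE``  — atom percent excess of the experimental consumer over the
  unlabelled (in-situ) baseline,
* ``L``    — the mean enrichment of the diet's fatty acids (averaged over
  all diet FAs except 18:0, to absorb elongation/desaturation mixing of
  dietary acids; 18:0 gets its own, lower, baseline L_18:0),

the proportion of a fatty acid's carbon that is of dietary origin is
``PA = APE / L``, the assimilated carbon is ``C_assim = C_mass * PA``, and
the daily turnover over a feeding window of ``dt`` days is
``C_turn = 100 * PA / dt`` (% per day).  ``C_mass - C_assim`` is the
internal (pre-existing) carbon of that acid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .isotope import (
    IsotopeConstants,
    VPDB,
    atom_percent_excess,
    carbon_mass,
    delta_to_atom_percent,
)
from .nomenclature import canonical_label, parse_fa_notation, saturation_class
from .profiles import MassKind, SampleProfile

logger = logging.getLogger("fatracer.assimilation")

STEARIC = "18:0"  # the poorly-enriched diet FA with its own baseline

#: Natural-abundance delta 13C assumed for fatty acids with no in-situ
#: baseline measurement (typical marine lipid value).
DEFAULT_BASELINE_DELTA = -25.0

PER_FA_COLUMNS = [
    "label",
    "sat_class",
    "c_mass",
    "atom_pct",
    "baseline_ap",
    "ape",
    "pa",
    "c_assim",
    "c_turn",
    "internal_c",
    "dietary_c",
    "default_baseline",
    "clamped",
]


@dataclass
class EnrichmentBaseline:
    """Diet enrichment levels and the per-FA consumer baseline.

    L is the mean diet atom% over every (fatty acid, batch) observation
    except 18:0; L_18_0 the mean over the 18:0 observations.  The per-FA
    baseline holds the unlabelled consumers' atom% used for APE; acids
    absent from the baseline group fall back to natural abundance at
    ``default_baseline_delta``.
    """

    l_general: float
    l_18_0: float
    per_fa_baseline: dict[str, float] = field(default_factory=dict)
    default_baseline_delta: float = DEFAULT_BASELINE_DELTA
    constants: IsotopeConstants = VPDB

    def __post_init__(self) -> None:
        if self.l_general <= 0:
            raise ValueError("diet enrichment L must be positive")
        for label, ap in self.per_fa_baseline.items():
            if not 0.0 <= ap <= 100.0:
                raise ValueError(f"baseline atom% for {label} outside [0, 100]")
        if self.l_general <= self.l_18_0:
            logger.warning(
                "L (%.3f) not above L_18:0 (%.3f); diet looks unenriched",
                self.l_general,
                self.l_18_0,
            )

    @property
    def default_baseline_ap(self) -> float:
        return delta_to_atom_percent(self.default_baseline_delta, self.constants)

    def l_for(self, label: str) -> float:
        """Enrichment denominator for one FA (18:0 uses its own level)."""
        return self.l_18_0 if canonical_label(label) == STEARIC else self.l_general

    def baseline_for(self, label: str) -> tuple[float, bool]:
        """(baseline atom%, used-default flag) for one FA."""
        key = canonical_label(label)
        if key in self.per_fa_baseline:
            return self.per_fa_baseline[key], False
        return self.default_baseline_ap, True


def diet_baseline(
    diet_profiles: Iterable[SampleProfile],
    insitu_profiles: Iterable[SampleProfile] = (),
    default_baseline_delta: float = DEFAULT_BASELINE_DELTA,
    constants: IsotopeConstants = VPDB,
) -> EnrichmentBaseline:
    """Build the enrichment baseline from diet batches and in-situ consumers.

    L is the unweighted mean of every (FA, batch) atom% observation in the
    diet excluding 18:0 and excluding not-detected entries; L_18:0 averages
    the 18:0 observations.  The per-FA consumer baseline is the per-FA mean
    atom% over the in-situ profiles.
    """
    diet_profiles = list(diet_profiles)
    if not diet_profiles:
        raise ValueError("no diet profiles supplied")

    general: list[float] = []
    stearic: list[float] = []
    for prof in diet_profiles:
        for label, meas in prof.measurements.items():
            ap = meas.atom_percent(constants)
            if ap is None:
                continue
            (stearic if label == STEARIC else general).append(ap)
    if not general:
        raise ValueError("diet profiles contain no non-18:0 enrichment values")
    if not stearic:
        raise ValueError("18:0 not detected in any diet batch")

    per_fa: dict[str, list[float]] = {}
    for prof in insitu_profiles:
        for label, meas in prof.measurements.items():
            ap = meas.atom_percent(constants)
            if ap is not None:
                per_fa.setdefault(label, []).append(ap)

    baseline = EnrichmentBaseline(
        l_general=fmean(general),
        l_18_0=fmean(stearic),
        per_fa_baseline={label: fmean(v) for label, v in per_fa.items()},
        default_baseline_delta=default_baseline_delta,
        constants=constants,
    )
    logger.info(
        "diet baseline: L = %.4f atom%% (n=%d), L_18:0 = %.4f atom%% (n=%d)",
        baseline.l_general,
        len(general),
        baseline.l_18_0,
        len(stearic),
    )
    return baseline


def proportion_assimilated(
    ape: float, fa_label: str, baseline: EnrichmentBaseline
) -> float:
    """PA = APE / L (APE / L_18:0 for stearic acid).

    Negative APE — a sample below its baseline, possible under measurement
    noise — is clamped to zero with a warning, since PA is a proportion.
    Values above 1 are flagged but returned as-is.
    """
    if ape < 0:
        logger.warning("negative APE %.4f for %s clamped to 0", ape, fa_label)
        ape = 0.0
    pa = ape / baseline.l_for(fa_label)
    if pa > 1.0:
        logger.warning("PA %.3f > 1 for %s (enrichment above diet level)", pa, fa_label)
    return pa


@dataclass
class AssimilationResult:
    """Per-FA and aggregate assimilation for one consumer sample.

    ``per_fa`` has one row per fatty acid; ``aggregates`` one row each for
    TFA, SFA, MUFA and PUFA, where masses and carbon terms are sums of their
    member FAs and APE is the unweighted mean of member APEs.
    """

    per_fa: pd.DataFrame
    aggregates: pd.DataFrame
    elapsed_days: float
    sample_id: str = ""


def assimilate_profile(
    profile: SampleProfile,
    baseline: EnrichmentBaseline,
    elapsed_days: float | None = None,
    constants: IsotopeConstants = VPDB,
) -> AssimilationResult:
    """Run the tracer computation for one experimental sample.

    For every fatty acid with an isotope measurement: carbon mass via the
    FAME correction (unless the profile already stores carbon masses),
    APE against the per-FA baseline, PA, assimilated/internal split and
    daily turnover.  Fatty acids without an isotope value are skipped with
    a warning (their origin cannot be partitioned).
    """
    dt = profile.elapsed_days if elapsed_days is None else elapsed_days
    if dt is None or dt <= 0:
        raise ValueError(f"elapsed_days must be positive, got {dt!r}")

    rows = []
    for label, meas in profile.measurements.items():
        fa = meas.fa
        ap = meas.atom_percent(constants)
        if ap is None:
            logger.warning(
                "%s: no isotope value for %s; excluded from assimilation",
                profile.sample_id,
                label,
            )
            continue
        if profile.mass_kind is MassKind.fame:
            c_mass = carbon_mass(meas.mass, ap, fa, constants)
        else:
            c_mass = meas.mass
        baseline_ap, used_default = baseline.baseline_for(label)
        if used_default:
            logger.info(
                "%s: %s absent from baseline group; using natural abundance "
                "(delta %.1f -> %.4f atom%%)",
                profile.sample_id,
                label,
                baseline.default_baseline_delta,
                baseline_ap,
            )
        ape = atom_percent_excess(ap, baseline_ap)
        clamped = ape < 0
        pa = proportion_assimilated(ape, label, baseline)
        ape = max(ape, 0.0)
        c_assim = c_mass * pa
        rows.append(
            {
                "label": label,
                "sat_class": saturation_class(fa).value,
                "c_mass": c_mass,
                "atom_pct": ap,
                "baseline_ap": baseline_ap,
                "ape": ape,
                "pa": pa,
                "c_assim": c_assim,
                "c_turn": 100.0 * pa / dt,
                "internal_c": c_mass - c_assim,
                "dietary_c": c_assim,
                "default_baseline": used_default,
                "clamped": clamped,
            }
        )
    if not rows:
        raise ValueError(f"{profile.sample_id}: no fatty acids with isotope values")
    per_fa = pd.DataFrame(rows, columns=PER_FA_COLUMNS)
    aggregates = _aggregate(per_fa, baseline, dt)
    return AssimilationResult(
        per_fa=per_fa,
        aggregates=aggregates,
        elapsed_days=dt,
        sample_id=profile.sample_id,
    )


def _aggregate(
    per_fa: pd.DataFrame, baseline: EnrichmentBaseline, dt: float
) -> pd.DataFrame:
    """TFA / SFA / MUFA / PUFA rows: carbon terms as sums of member FAs,
    APE as the unweighted mean of member APEs, PA from that APE and the
    general diet level."""
    out = []
    groups = [("TFA", per_fa)] + [
        (cls, per_fa[per_fa["sat_class"] == cls]) for cls in ("SFA", "MUFA", "PUFA")
    ]
    for name, sub in groups:
        if sub.empty:
            out.append(
                {
                    "group": name,
                    "c_mass": 0.0,
                    "ape": np.nan,
                    "pa": np.nan,
                    "c_assim": 0.0,
                    "c_turn": np.nan,
                    "internal_c": 0.0,
                    "dietary_c": 0.0,
                }
            )
            continue
        ape = float(sub["ape"].mean())
        pa = ape / baseline.l_general
        out.append(
            {
                "group": name,
                "c_mass": float(sub["c_mass"].sum()),
                "ape": ape,
                "pa": pa,
                "c_assim": float(sub["c_assim"].sum()),
                "c_turn": 100.0 * pa / dt,
                "internal_c": float(sub["internal_c"].sum()),
                "dietary_c": float(sub["dietary_c"].sum()),
            }
        )
    return pd.DataFrame(out).set_index("group")


@dataclass
class AssimilationSummary:
    """Mean +/- SD across replicate samples, plus the per-replicate results."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    aggregates_mean: pd.DataFrame
    aggregates_sd: pd.DataFrame
    replicates: list[AssimilationResult]
    elapsed_days: float


_NUMERIC = ["c_mass", "atom_pct", "baseline_ap", "ape", "pa", "c_assim", "c_turn",
            "internal_c", "dietary_c"]


def assimilate(
    experimental: Sequence[SampleProfile],
    baseline: EnrichmentBaseline,
    elapsed_days: float | None = None,
    mode: str = "per_replicate",
    constants: IsotopeConstants = VPDB,
) -> AssimilationSummary:
    """Tracer computation over replicate experimental samples.

    ``per_replicate`` (default) computes each replicate independently and
    reports mean +/- SD across replicates.  ``mean_profile`` first averages
    the replicate profiles per FA (absent = excluded from means) and runs
    the computation once on the mean profile.
    """
    experimental = list(experimental)
    if not experimental:
        raise ValueError("no experimental profiles supplied")
    if mode == "mean_profile":
        profile = mean_profile(experimental, constants)
        res = assimilate_profile(profile, baseline, elapsed_days, constants)
        zeros_fa = res.per_fa.set_index("label")[_NUMERIC] * 0.0
        zeros_agg = res.aggregates[["c_mass", "ape", "pa", "c_assim", "c_turn",
                                    "internal_c", "dietary_c"]] * 0.0
        return AssimilationSummary(
            mean=res.per_fa.set_index("label"),
            sd=zeros_fa,
            aggregates_mean=res.aggregates,
            aggregates_sd=zeros_agg,
            replicates=[res],
            elapsed_days=res.elapsed_days,
        )
    if mode != "per_replicate":
        raise ValueError(f"unknown mode {mode!r}")

    results = [
        assimilate_profile(p, baseline, elapsed_days, constants) for p in experimental
    ]
    per = pd.concat([r.per_fa for r in results])
    grouped = per.groupby("label", sort=False)[_NUMERIC]
    agg = pd.concat([r.aggregates for r in results])
    agg_grouped = agg.groupby(level=0, sort=False)
    return AssimilationSummary(
        mean=grouped.mean(),
        sd=grouped.std(ddof=1).fillna(0.0),
        aggregates_mean=agg_grouped.mean(),
        aggregates_sd=agg_grouped.std(ddof=1).fillna(0.0),
        replicates=results,
        elapsed_days=results[0].elapsed_days,
    )


def mean_profile(
    profiles: Sequence[SampleProfile], constants: IsotopeConstants = VPDB
) -> SampleProfile:
    """Average replicate profiles per FA.

    A fatty acid not detected in a replicate is excluded from that FA's
    means (absence is not a zero measurement); isotope values are averaged
    on the atom% scale.
    """
    from .isotope import IsotopeKind, IsotopeValue

    masses: dict[str, list[float]] = {}
    aps: dict[str, list[float]] = {}
    for prof in profiles:
        for label, meas in prof.measurements.items():
            masses.setdefault(label, []).append(meas.mass)
            ap = meas.atom_percent(constants)
            if ap is not None:
                aps.setdefault(label, []).append(ap)
    first = profiles[0]
    out = SampleProfile(
        sample_id="mean(%s)" % ",".join(p.sample_id for p in profiles),
        group=first.group,
        elapsed_days=first.elapsed_days,
        mass_kind=first.mass_kind,
        bulk_c=_opt_mean([p.bulk_c for p in profiles]),
        bulk_n=_opt_mean([p.bulk_n for p in profiles]),
        dry_mass=_opt_mean([p.dry_mass for p in profiles]),
    )
    for label, vals in masses.items():
        iso = None
        if label in aps:
            iso = IsotopeValue(IsotopeKind.atom_percent, fmean(aps[label]))
        out.add(label, fmean(vals), iso)
    return out


def _opt_mean(values: list) -> float | None:
    present = [v for v in values if v is not None]
    return fmean(present) if present else None
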