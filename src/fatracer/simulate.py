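"""Forward simulator of a 13C-enrichment feeding experiment.

Emulates the study design the pipeline is built for: a diatom diet grown on
13C-bicarbonate (per-FA enrichment near 3.6 atom%, stearic acid much lower,
day-to-day batch variation), a pool of unlabelled consumers with ~15 major
fatty acids at ng-per-individual carbon masses, five days of feeding with
FA-specific assimilation, bioconversion of acids that the diet does not
supply, and measurement noise on masses and isotope ratios.

Ground truth is constructed in "pipeline-inverse" form so the tracer
algebra is exactly invertible when noise is off: the experimental atom% of
each fatty acid is baseline + PA * L (L_18:0 for stearic acid) and its
final carbon pool is initial / (1 - PA), i.e. final = initial + assimilated
with the assimilated carbon equal to PA * final.  Bioconverted products
receive carbon transferred from their source's assimilation with an
attenuated effective enrichment (elongation/desaturation fractionates, so
label arrives diluted).  Measured FAME masses are back-computed from carbon
masses through the derivatization correction, closing the loop through the
same equation the pipeline applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

import numpy as np
import pandas as pd

from .isotope import (
    IsotopeConstants,
    IsotopeKind,
    IsotopeValue,
    VPDB,
    atom_percent_to_delta,
    carbon_fraction,
    delta_to_atom_percent,
)
from .nomenclature import canonical_label, parse_fa_notation
from .profiles import MassKind, SampleGroup, SampleProfile

STEARIC = "18:0"


@dataclass(frozen=True)
class DietFA:
    """One dietary fatty acid: share of diet TFA and mean 13C enrichment."""

    pct_tfa: float
    atom_percent: float


@dataclass(frozen=True)
class BioconversionEdge:
    """Transfer of assimilated carbon from a source FA into a product FA.

    ``transfer_fraction`` of the source's assimilated carbon is elongated/
    desaturated into the product; ``attenuation`` (< 1 for fractionating
    conversions) scales the label the product carries relative to a direct
    dietary acid with the same dietary-carbon fraction.
    """

    source: str
    product: str
    transfer_fraction: float
    attenuation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfer_fraction <= 1.0:
            raise ValueError("transfer_fraction outside [0, 1]")
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation outside (0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: log-normal CV on masses, normal SD on delta."""

    mass_cv: float = 0.05
    delta_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.mass_cv < 0 or self.delta_sd < 0:
            raise ValueError("noise parameters must be non-negative")


def _table_shaped_diet() -> dict[str, DietFA]:
    # Diet composition shaped on an enriched diatom culture: EPA-dominated
    # PUFA profile, enrichment ~3.2-3.8 atom% for all FAs except the poorly
    # labelled 18:0 near 1.9 atom%.
    masses = {
        "14:0": (9, 3.72),
        "16:0": (19, 3.62),
        "16:1(n-7)": (21, 3.72),
        "16:1(n-5)": (2, 3.48),
        "16:2(n-4)": (12, 3.73),
        "16:3(n-4)": (28, 3.73),
        "18:0": (1, 1.87),
        "18:1(n-9)": (1, 3.19),
        "18:1(n-7)": (1, 3.26),
        "18:2(n-6)": (1, 3.68),
        "18:4(n-3)": (7, 3.76),
        "20:5(n-3)": (34, 3.74),
        "22:6(n-3)": (8, 3.76),
    }
    total = sum(m for m, _ in masses.values())
    return {
        label: DietFA(pct_tfa=100.0 * m / total, atom_percent=ap)
        for label, (m, ap) in masses.items()
    }


def _default_consumer() -> dict[str, float]:
    # Baseline consumer pool (ng C per individual), major marine-invertebrate
    # FAs dominated by EPA, 16:0 and 22:5(n-3).
    return {
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


def _default_true_pa() -> dict[str, float]:
    # FA-specific proportions of dietary carbon after 5 days of feeding,
    # in the 0.25-0.45 band observed for actively feeding larvae.
    return {
        "14:0": 0.26,
        "16:0": 0.33,
        "16:1(n-7)": 0.46,
        "18:0": 0.35,
        "18:1(n-9)": 0.0,
        "18:1(n-7)": 0.27,
        "20:5(n-3)": 0.35,
        "22:6(n-3)": 0.39,
    }


def _default_influx() -> dict[str, tuple[float, float]]:
    # Diet-only acids appearing in the fed consumer: (final ng C, PA).
    return {
        "16:2(n-4)": (8.0, 0.54),
        "16:3(n-4)": (4.0, 0.56),
        "18:4(n-3)": (3.0, 0.53),
    }


def _default_edges() -> list[BioconversionEdge]:
    return [
        BioconversionEdge("20:5(n-3)", "22:5(n-3)", 0.55, 0.75),
        BioconversionEdge("18:0", "18:1(n-11)", 0.30, 0.60),
        BioconversionEdge("18:1(n-11)", "20:1(n-11)", 0.35, 0.75),
    ]


@dataclass
class SimulationConfig:
    """Full specification of one simulated feeding experiment.

    Defaults describe the study conditions the package targets: five daily
    diet batches, triplicate consumer pools, a five-day feeding window,
    between-batch enrichment variation, 5% mass CV and 0.3 per-mil delta SD.
    """

    seed: int = 0
    n_diet_batches: int = 5
    n_replicates: int = 3
    elapsed_days: float = 5.0
    diet_fa_profile: dict[str, DietFA] = field(default_factory=_table_shaped_diet)
    diet_total_mass: float = 144.0
    batch_atom_sd: float = 0.35  # shared per-batch enrichment shift (atom%)
    fa_atom_jitter_sd: float = 0.08  # per-FA jitter within a batch (atom%)
    consumer_initial: dict[str, float] = field(default_factory=_default_consumer)
    consumer_baseline_delta: float = -25.0
    true_pa: dict[str, float] = field(default_factory=_default_true_pa)
    dietary_influx: dict[str, tuple[float, float]] = field(default_factory=_default_influx)
    bioconversion_edges: list[BioconversionEdge] = field(default_factory=_default_edges)
    noise: NoiseModel = field(default_factory=NoiseModel)
    constants: IsotopeConstants = VPDB

    def __post_init__(self) -> None:
        self.diet_fa_profile = {
            canonical_label(k): v for k, v in self.diet_fa_profile.items()
        }
        self.consumer_initial = {
            canonical_label(k): v for k, v in self.consumer_initial.items()
        }
        self.true_pa = {canonical_label(k): v for k, v in self.true_pa.items()}
        self.dietary_influx = {
            canonical_label(k): tuple(v) for k, v in self.dietary_influx.items()
        }
        total_pct = sum(f.pct_tfa for f in self.diet_fa_profile.values())
        if abs(total_pct - 100.0) > 1e-6:
            raise ValueError(f"diet %TFA sums to {total_pct}, not 100")
        for label, pa in self.true_pa.items():
            if not 0.0 <= pa < 1.0:
                raise ValueError(f"true PA for {label} outside [0, 1): {pa}")
        self._validate_fa_sets()

    def _validate_fa_sets(self) -> None:
        orphans = []
        products = {e.product for e in self.bioconversion_edges}
        for label, pa in self.true_pa.items():
            if label not in self.consumer_initial:
                orphans.append(f"true_pa FA {label} missing from consumer_initial")
            if pa > 0 and label not in self.diet_fa_profile:
                orphans.append(f"assimilated FA {label} missing from diet profile")
        for label in self.dietary_influx:
            if label not in self.diet_fa_profile:
                orphans.append(f"influx FA {label} missing from diet profile")
            if label in self.consumer_initial:
                orphans.append(f"influx FA {label} already in consumer_initial")
        resolved = set(self.true_pa) | set(self.dietary_influx)
        for edge in self.bioconversion_edges:
            if edge.source not in resolved:
                orphans.append(
                    f"bioconversion source {edge.source} has no assimilation "
                    "defined before its edge"
                )
            if edge.product not in self.consumer_initial:
                orphans.append(
                    f"bioconversion product {edge.product} missing from "
                    "consumer_initial"
                )
            resolved.add(edge.product)
        if orphans:
            raise ValueError("inconsistent FA sets: " + "; ".join(orphans))


@dataclass
class GroundTruth:
    """Exact pre-noise quantities the pipeline should recover."""

    l_general: float
    l_18_0: float
    baseline_atom_percent: float
    per_fa: pd.DataFrame  # index label; columns pa, final_c_mass, c_assim,
    #                       c_turn, internal_c, dietary_c, atom_pct, bioconverted
    elapsed_days: float


@dataclass
class SimulationOutput:
    diet: list[SampleProfile]
    in_situ: list[SampleProfile]
    experimental: list[SampleProfile]
    truth: GroundTruth
    config: SimulationConfig


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def _noisy_atom_pct(
    rng: np.random.Generator, ap: float, delta_sd: float, constants: IsotopeConstants
) -> float:
    if delta_sd == 0:
        return ap
    delta = atom_percent_to_delta(ap, constants) + rng.normal(0.0, delta_sd)
    return delta_to_atom_percent(delta, constants)


def simulate_experiment(config: SimulationConfig) -> SimulationOutput:
    """Draw one full synthetic experiment from the configured conditions.

    Returns diet batches, in-situ (baseline) consumer pools, fed
    experimental pools, and the exact ground truth; deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    cns = config.constants
    noise = config.noise

    # -- diet batches: per-batch enrichment shift shared by all FAs of that
    #    batch, small per-FA jitter on top (days differ more than FAs).
    realized: dict[str, list[float]] = {label: [] for label in config.diet_fa_profile}
    diet_profiles: list[SampleProfile] = []
    for b in range(config.n_diet_batches):
        shift = rng.normal(0.0, config.batch_atom_sd) if config.batch_atom_sd else 0.0
        prof = SampleProfile(
            sample_id=f"diet_b{b + 1}",
            group=SampleGroup.diet,
            replicate=b + 1,
            mass_kind=MassKind.fame,
        )
        for label, dfa in config.diet_fa_profile.items():
            jitter = (
                rng.normal(0.0, config.fa_atom_jitter_sd)
                if config.fa_atom_jitter_sd
                else 0.0
            )
            # 18:0 tracks the batch effect at reduced amplitude: a poorly
            # labelled FA moves less in absolute atom% than well labelled ones
            scale = dfa.atom_percent / 3.62 if label == STEARIC else 1.0
            ap_true = float(np.clip(dfa.atom_percent + scale * (shift + jitter), 0.05, 99.0))
            realized[label].append(ap_true)
            c_mass = config.diet_total_mass * dfa.pct_tfa / 100.0
            fa = parse_fa_notation(label)
            fame = c_mass / carbon_fraction(fa, ap_true, cns)
            fame *= _lognormal_factor(rng, noise.mass_cv)
            ap_meas = _noisy_atom_pct(rng, ap_true, noise.delta_sd, cns)
            prof.add(label, fame, IsotopeValue(IsotopeKind.atom_percent, ap_meas))
        diet_profiles.append(prof)

    l_general = fmean(
        ap for label, aps in realized.items() if label != STEARIC for ap in aps
    )
    l_18_0 = fmean(realized[STEARIC])
    baseline_ap = delta_to_atom_percent(config.consumer_baseline_delta, cns)

    # -- exact per-FA truth (pre-noise)
    truth_rows: dict[str, dict] = {}

    def l_for(label: str) -> float:
        return l_18_0 if label == STEARIC else l_general

    for label, pa in config.true_pa.items():
        initial = config.consumer_initial[label]
        final = initial / (1.0 - pa) if pa > 0 else initial
        truth_rows[label] = {"pa": pa, "final_c_mass": final, "bioconverted": False}
    for label, (final, pa) in config.dietary_influx.items():
        truth_rows[label] = {"pa": pa, "final_c_mass": final, "bioconverted": False}
    for edge in config.bioconversion_edges:
        src = truth_rows[edge.source]
        transferred = edge.transfer_fraction * src["pa"] * src["final_c_mass"]
        initial = config.consumer_initial[edge.product]
        final = initial + transferred
        frac_dietary = transferred / final if final > 0 else 0.0
        truth_rows[edge.product] = {
            "pa": edge.attenuation * frac_dietary,
            "final_c_mass": final,
            "bioconverted": True,
        }
    for label, row in truth_rows.items():
        row["atom_pct"] = baseline_ap + row["pa"] * l_for(label)
        row["c_assim"] = row["pa"] * row["final_c_mass"]
        row["dietary_c"] = row["c_assim"]
        row["internal_c"] = row["final_c_mass"] - row["c_assim"]
        row["c_turn"] = 100.0 * row["pa"] / config.elapsed_days

    truth = GroundTruth(
        l_general=l_general,
        l_18_0=l_18_0,
        baseline_atom_percent=baseline_ap,
        per_fa=pd.DataFrame.from_dict(truth_rows, orient="index").sort_index(),
        elapsed_days=config.elapsed_days,
    )

    # -- in-situ consumers at natural abundance
    in_situ: list[SampleProfile] = []
    for r in range(config.n_replicates):
        prof = SampleProfile(
            sample_id=f"insitu_r{r + 1}",
            group=SampleGroup.in_situ,
            replicate=r + 1,
            n_individuals=50,
            mass_kind=MassKind.fame,
        )
        for label, c_mass in config.consumer_initial.items():
            fa = parse_fa_notation(label)
            fame = c_mass / carbon_fraction(fa, baseline_ap, cns)
            fame *= _lognormal_factor(rng, noise.mass_cv)
            ap_meas = _noisy_atom_pct(rng, baseline_ap, noise.delta_sd, cns)
            prof.add(label, fame, IsotopeValue(IsotopeKind.atom_percent, ap_meas))
        in_situ.append(prof)

    # -- experimental consumers after the feeding window
    experimental: list[SampleProfile] = []
    for r in range(config.n_replicates):
        prof = SampleProfile(
            sample_id=f"exp_r{r + 1}",
            group=SampleGroup.experimental,
            replicate=r + 1,
            n_individuals=50,
            elapsed_days=config.elapsed_days,
            mass_kind=MassKind.fame,
        )
        for label, row in truth_rows.items():
            fa = parse_fa_notation(label)
            fame = row["final_c_mass"] / carbon_fraction(fa, row["atom_pct"], cns)
            fame *= _lognormal_factor(rng, noise.mass_cv)
            ap_meas = _noisy_atom_pct(rng, row["atom_pct"], noise.delta_sd, cns)
            prof.add(label, fame, IsotopeValue(IsotopeKind.atom_percent, ap_meas))
        experimental.append(prof)

    return SimulationOutput(
        diet=diet_profiles,
        in_situ=in_situ,
        experimental=experimental,
        truth=truth,
        config=config,
    )


def noise_free(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A copy of ``config`` (or the defaults) with every stochastic term off."""
    from dataclasses import replace

    base = config if config is not None else SimulationConfig()
    return replace(
        base,
        batch_atom_sd=0.0,
        fa_atom_jitter_sd=0.0,
        noise=NoiseModel(mass_cv=0.0, delta_sd=0.0),
        **overrides,
    )
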