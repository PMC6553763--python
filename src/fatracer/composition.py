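"""Fatty-acid composition summaries and profile similarity clustering.

Covers the descriptive side of a fatty-acid trophic-marker study: relative
composition (% of total fatty acids), the share of body carbon held in each
acid, saturation-class sums, molar C:N, and the standard multivariate view
of lipid profiles — Bray–Curtis similarity between samples on (optionally
logit-transformed) compositions, clustered by group-average linkage (UPGMA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .isotope import IsotopeConstants, VPDB, carbon_mass, delta_to_atom_percent
from .nomenclature import parse_fa_notation, saturation_class
from .profiles import MassKind, SampleProfile

logger = logging.getLogger("fatracer.composition")

#: Standard atomic weights used for molar ratios (natural-abundance
#: elements of bulk tissue, distinct from the isotope-system masses).
ATOMIC_WEIGHT_C = 12.011
ATOMIC_WEIGHT_N = 14.007


def relative_composition(profile: SampleProfile) -> dict[str, float]:
    """Percent of total fatty acids per FA; values sum to 100."""
    tfa = profile.tfa_mass
    if not profile.measurements or tfa <= 0:
        raise ValueError(f"{profile.sample_id}: empty or zero-mass profile")
    return {label: 100.0 * m.mass / tfa for label, m in profile.measurements.items()}


def molar_cn_ratio(bulk_c: float, bulk_n: float) -> float:
    """Molar carbon:nitrogen ratio from bulk masses in the same unit."""
    if bulk_c <= 0 or bulk_n <= 0:
        raise ValueError("bulk C and N must both be positive")
    return (bulk_c / ATOMIC_WEIGHT_C) / (bulk_n / ATOMIC_WEIGHT_N)


def permil_body_carbon(
    profile: SampleProfile, constants: IsotopeConstants = VPDB
) -> dict[str, float]:
    """Per-FA carbon mass as per-mil of the sample's bulk carbon.

    FAME-quantified masses are converted to carbon masses first (using each
    acid's measured atom%, or natural abundance when no isotope value is
    present); profiles that already store carbon masses are used directly.
    """
    if profile.bulk_c is None or profile.bulk_c <= 0:
        raise ValueError(f"{profile.sample_id}: bulk carbon missing or zero")
    out = {}
    for label, meas in profile.measurements.items():
        if profile.mass_kind is MassKind.carbon:
            c = meas.mass
        else:
            ap = meas.atom_percent(constants)
            if ap is None:
                ap = delta_to_atom_percent(-25.0, constants)
            c = carbon_mass(meas.mass, ap, meas.fa, constants)
        out[label] = 1000.0 * c / profile.bulk_c
    return out


def class_sums(values: SampleProfile | Mapping[str, float]) -> dict[str, float]:
    """Sum values by saturation class: {SFA, MUFA, PUFA, TFA}.

    Accepts a profile (sums masses) or any mapping of FA label to value
    (masses, assimilated carbon, %TFA ...).  SFA + MUFA + PUFA = TFA by
    construction.
    """
    if isinstance(values, SampleProfile):
        values = {label: m.mass for label, m in values.measurements.items()}
    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for label, value in values.items():
        cls = saturation_class(parse_fa_notation(label)).value
        sums[cls] += value
    sums["TFA"] = sums["SFA"] + sums["MUFA"] + sums["PUFA"]
    return sums


# ---------------------------------------------------------------------------
# similarity clustering
# ---------------------------------------------------------------------------


def logit_percentages(values, epsilon: float | None = None):
    """Logit transform of percentage data: ln(p / (1-p)) with p = value/100.

    Boundary policy: exact 0 and 100 are replaced by ``epsilon`` and
    ``1 - epsilon`` on the proportion scale.  When ``epsilon`` is None it is
    set to half the smallest nonzero proportion in the input, the usual
    empirical choice for compositional zeroes.
    """
    arr = np.asarray(values, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percentages outside [0, 100]")
    p = arr / 100.0
    if epsilon is None:
        nonzero = p[p > 0]
        epsilon = float(nonzero.min()) / 2.0 if nonzero.size else 0.5
    p = np.clip(p, epsilon, 1.0 - epsilon)
    out = np.log(p / (1.0 - p))
    return out.item() if out.ndim == 0 else out


def bray_curtis_similarity(matrix) -> pd.DataFrame:
    """Pairwise Bray–Curtis similarity (%) between sample rows.

    S(x, y) = 100 * (1 - sum|x_i - y_i| / sum(x_i + y_i)) on non-negative
    data.  Matrices containing negative entries (e.g. logit-transformed
    compositions) are shifted by their global minimum first; the shift is
    logged.  A pair of all-zero rows has no defined similarity and is
    rejected.
    """
    df = pd.DataFrame(matrix).astype(float)
    X = df.to_numpy()
    if np.min(X) < 0:
        shift = -float(np.min(X))
        logger.info("shifting matrix by +%.4f to restore non-negativity", shift)
        X = X + shift
    row_sums = X.sum(axis=1)
    if np.any(row_sums == 0) and (row_sums == 0).sum() >= 2:
        raise ValueError("two all-zero samples: Bray-Curtis undefined")
    dissim = pdist(X, metric="braycurtis")
    if np.any(~np.isfinite(dissim)):
        raise ValueError("Bray-Curtis undefined for an all-zero sample pair")
    sim = 100.0 * (1.0 - squareform(dissim))
    np.fill_diagonal(sim, 100.0)
    return pd.DataFrame(sim, index=df.index, columns=df.index)


@dataclass
class Merge:
    """One agglomeration step: the two joined clusters (as tuples of sample
    labels) and the average-linkage similarity at which they join."""

    left: tuple
    right: tuple
    similarity: float

    @property
    def members(self) -> tuple:
        return tuple(self.left) + tuple(self.right)


@dataclass
class ClusterTree:
    """Average-linkage (UPGMA) merge sequence over a similarity matrix."""

    merges: list[Merge]
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix on the dissimilarity scale

    def to_newick(self) -> str:
        """Newick string with branch lengths on the dissimilarity
        (100 - similarity) scale."""
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        def top(node) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:0"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right})"

        return top(tree) + ";"


def average_linkage_cluster(similarity: pd.DataFrame) -> ClusterTree:
    """Cluster samples by group-average linkage on a similarity matrix.

    The similarity matrix (in %, diagonal 100) is converted to
    dissimilarity d = 100 - S; each merge is recorded with the average
    similarity between the joined clusters.
    """
    sim = pd.DataFrame(similarity).astype(float)
    n = sim.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    if sim.shape[0] != sim.shape[1] or not np.allclose(sim.values, sim.values.T):
        raise ValueError("similarity matrix must be square and symmetric")
    labels = [str(i) for i in sim.index]
    dissim = squareform(100.0 - sim.to_numpy(), checks=False)
    Z = hierarchy.linkage(dissim, method="average")

    clusters: dict[int, tuple] = {i: (labels[i],) for i in range(n)}
    merges: list[Merge] = []
    for k, (i, j, height, _size) in enumerate(Z):
        left, right = clusters[int(i)], clusters[int(j)]
        merges.append(Merge(left=left, right=right, similarity=100.0 - float(height)))
        clusters[n + k] = left + right
    return ClusterTree(merges=merges, labels=labels, linkage=Z)


def tfa_filter(
    profiles: Sequence[SampleProfile], threshold_percent: float = 1.0
) -> list[str]:
    """Fatty acids whose mean relative content exceeds the threshold in at
    least one sample group; the retained set applies to all samples."""
    per_group: dict[str, list[dict[str, float]]] = {}
    for prof in profiles:
        per_group.setdefault(prof.group.value, []).append(relative_composition(prof))
    keep: set[str] = set()
    for comps in per_group.values():
        all_labels = {label for c in comps for label in c}
        for label in all_labels:
            mean_pct = float(np.mean([c.get(label, 0.0) for c in comps]))
            if mean_pct > threshold_percent:
                keep.add(label)
    return sorted(keep)


def profile_matrix(
    profiles: Sequence[SampleProfile],
    value: str = "percent",
    threshold_percent: float | None = 1.0,
    logit: bool = False,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Samples-by-FA matrix for similarity analysis.

    ``value`` is ``"percent"`` (% TFA) or ``"mass"`` (absolute).  Fatty
    acids below the mean-relative-content threshold in every group are
    dropped (the conventional > 1 % TFA filter); ``logit=True`` applies the
    logit transform to percentage data.
    """
    if value not in ("percent", "mass"):
        raise ValueError(f"unknown value space {value!r}")
    keep = (
        tfa_filter(profiles, threshold_percent)
        if threshold_percent is not None
        else sorted({label for p in profiles for label in p.measurements})
    )
    rows = {}
    for prof in profiles:
        if value == "percent":
            comp = relative_composition(prof)
        else:
            comp = {label: m.mass for label, m in prof.measurements.items()}
        rows[prof.sample_id] = [comp.get(label, 0.0) for label in keep]
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=keep)
    if logit:
        if value != "percent":
            raise ValueError("logit transform applies to percentage data only")
        mat = pd.DataFrame(
            logit_percentages(mat.to_numpy(), epsilon=epsilon),
            index=mat.index,
            columns=mat.columns,
        )
    return mat
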