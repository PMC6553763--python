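"""Fatty-acid shorthand notation and molecular composition.

Fatty acids are written in the ``A:B(n-X)`` omega shorthand used throughout
lipid trophic-marker work: ``A`` carbon atoms, ``B`` double bonds, and the
double bond nearest the terminal methyl group ``X`` carbons from that end.
Saturated acids (``B = 0``) omit the ``(n-X)`` suffix.  Iso/anteiso branch
prefixes (``i-``, ``ai-``) are carried on the label but do not change the
molecular formula (branching is isomeric, not compositional).

A free fatty acid with A carbons and B double bonds has formula
C_A H_(2A-2B) O_2; its methyl ester (FAME), the form actually quantified on
a GC column after transesterification, gains one carbon and two hydrogens:
C_(A+1) H_(2A-2B+2) O_2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum


class SaturationClass(str, Enum):
    """Saturation class of a fatty acid: 0, 1 or >=2 double bonds."""

    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"


_FA_RE = re.compile(
    r"""^
    (?:(?P<branch>a?i)-)?          # optional iso / anteiso prefix
    (?P<carbons>\d+)
    :
    (?P<double_bonds>\d+)
    (?:\(n-(?P<omega>\d+)\))?      # omega position, only for unsaturated FAs
    $""",
    re.VERBOSE,
)

# Trailing common-name aliases as printed in composition tables, e.g.
# "20:5(n-3)-EPA"; they are display sugar and stripped before parsing.
_ALIAS_RE = re.compile(r"[-–—](?P<alias>[A-Za-z]+)$")


class FANotationError(ValueError):
    """Raised for a malformed or chemically impossible shorthand label."""


@dataclass(frozen=True)
class FattyAcid:
    """Parsed identity of a fatty acid.

    Attributes
    ----------
    carbons : int
        Number of carbon atoms A in the free acid.
    double_bonds : int
        Number of C=C double bonds B.
    omega : int or None
        Position (n-X) of the double bond nearest the terminal methyl;
        ``None`` for saturated acids.
    branch_prefix : str or None
        ``"i"`` or ``"ai"`` when the label carried an iso/anteiso prefix.
    """

    carbons: int
    double_bonds: int
    omega: int | None = None
    branch_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise FANotationError(f"carbon count {self.carbons} < 2")
        if self.double_bonds < 0:
            raise FANotationError(f"negative double bond count {self.double_bonds}")
        if self.double_bonds >= self.carbons:
            raise FANotationError(
                f"{self.double_bonds} double bonds impossible with "
                f"{self.carbons} carbons"
            )
        if self.double_bonds == 0 and self.omega is not None:
            raise FANotationError("saturated acid cannot carry an (n-X) position")
        if self.double_bonds >= 1 and self.omega is None:
            raise FANotationError("unsaturated acid requires an (n-X) position")
        if self.omega is not None and self.omega <= 0:
            raise FANotationError(f"(n-{self.omega}) position must be positive")

    @property
    def label(self) -> str:
        """Canonical shorthand, e.g. ``"20:5(n-3)"`` or ``"i-15:0"``."""
        core = f"{self.carbons}:{self.double_bonds}"
        if self.omega is not None:
            core += f"(n-{self.omega})"
        if self.branch_prefix:
            core = f"{self.branch_prefix}-{core}"
        return core

    # -- molecular composition -------------------------------------------

    @property
    def fa_formula(self) -> tuple[int, int, int]:
        """(C, H, O) atom counts of the free acid: C_A H_(2A-2B) O_2."""
        return (self.carbons, 2 * self.carbons - 2 * self.double_bonds, 2)

    @property
    def fame_formula(self) -> tuple[int, int, int]:
        """(C, H, O) atom counts of the methyl ester."""
        return fame_composition(self)

    @property
    def saturation(self) -> SaturationClass:
        return saturation_class(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_fa_notation(text: str) -> FattyAcid:
    """Parse an ``A:B(n-X)`` shorthand label into a :class:`FattyAcid`.

    Accepts optional ``i-``/``ai-`` branch prefixes and strips trailing
    common-name aliases attached with a dash (``"20:5(n-3)-EPA"``).

    Raises
    ------
    FANotationError
        If the label is malformed or violates B < A / X > 0.
    """
    if not isinstance(text, str):
        raise FANotationError(f"expected a string label, got {type(text).__name__}")
    cleaned = text.strip()
    cleaned = _ALIAS_RE.sub("", cleaned)
    m = _FA_RE.match(cleaned)
    if m is None:
        raise FANotationError(f"unrecognized fatty-acid notation: {text!r}")
    omega = m.group("omega")
    return FattyAcid(
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("double_bonds")),
        omega=int(omega) if omega is not None else None,
        branch_prefix=m.group("branch"),
    )


def canonical_label(text: str) -> str:
    """Canonical form of a shorthand label (parse + reformat)."""
    return parse_fa_notation(text).label


def fame_composition(fa: FattyAcid) -> tuple[int, int, int]:
    """Atom counts (C, H, O) of the fatty-acid methyl ester.

    Transesterification replaces the acid proton with a methyl group:
    one extra carbon, two extra hydrogens, oxygens unchanged at 2.
    """
    a, b = fa.carbons, fa.double_bonds
    return (a + 1, 2 * a - 2 * b + 2, 2)


def saturation_class(fa: FattyAcid) -> SaturationClass:
    """SFA (B=0), MUFA (B=1) or PUFA (B>=2)."""
    if fa.double_bonds == 0:
        return SaturationClass.SFA
    if fa.double_bonds == 1:
        return SaturationClass.MUFA
    return SaturationClass.PUFA
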