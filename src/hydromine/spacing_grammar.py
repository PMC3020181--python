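"""The CN{k} cysteine-spacing notation: parsing, rendering, spacing-based class rules.

A spacing pattern records the five variable non-cysteine runs of the
eight-cysteine motif and is written ``CN{s1}CCN{s2}CN{s3}CN{s4}CCN{s5}C``,
where ``N`` is any amino acid other than cysteine.  A run of length 1 is
written as a bare ``N`` and a run of length 0 is omitted.

Spacing-based classification codifies two observations about the surveyed
hydrophobins: class I patterns share a Cys5-Cys6 spacer of exactly five
residues (as in SC3, EAS and MPG1), while the single class II pattern has
the near-fixed spacing typified by ATEG_04730 and the HFBI/HFBII family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .motif_scan import CysteineTopology

CLASS_I_SPACING = "classI_spacing"
CLASS_II_SPACING = "classII_spacing"
ATYPICAL_SPACING = "atypical"

__all__ = [
    "SpacingPattern",
    "SpacingClassRule",
    "PatternParseError",
    "parse_pattern",
    "pattern_from_topology",
    "classify_spacing",
    "CLASS_I_SPACING",
    "CLASS_II_SPACING",
    "ATYPICAL_SPACING",
]


class PatternParseError(ValueError):
    """Raised when a string is not a valid CN{k} spacing pattern."""


@dataclass(frozen=True)
class SpacingPattern:
    """The five variable spacer lengths of an eight-cysteine motif."""

    spacers: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.spacers) != 5 or any(s < 0 for s in self.spacers):
            raise ValueError("spacers must be 5 non-negative integers")

    def render(self) -> str:
        """Canonical CN{k} string; k=1 renders as ``N``, k=0 as nothing."""
        def run(k: int) -> str:
            if k == 0:
                return ""
            if k == 1:
                return "N"
            return f"N{{{k}}}"

        s1, s2, s3, s4, s5 = self.spacers
        return f"C{run(s1)}CC{run(s2)}C{run(s3)}C{run(s4)}CC{run(s5)}C"

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class SpacingClassRule:
    """Spacing-based class acceptance regions.

    ``class1_s4``: Cys5-Cys6 spacer lengths diagnostic of class I spacing.
    ``class2_template``: per-spacer (min, max) bands a pattern must fully
    satisfy to count as class II spacing; the default is a +/-1 band around
    the canonical class II pattern (10, 11, 16, 8, 10).  Class II takes
    precedence in any overlap so that the rare class II call stays
    conservative and deterministic.
    """

    class1_s4: frozenset[int] = frozenset({5})
    class2_template: tuple[tuple[int, int], ...] = (
        (9, 11),
        (10, 12),
        (15, 17),
        (7, 9),
        (9, 11),
    )

    def __post_init__(self) -> None:
        if len(self.class2_template) != 5:
            raise ValueError("class2_template must have 5 (min, max) pairs")
        for lo, hi in self.class2_template:
            if hi < lo:
                raise ValueError(f"invalid class2 band ({lo}, {hi})")


# One token per variable run: "N{k}" (k >= 2), bare "N" (k = 1) or nothing (k = 0).
_RUN = r"(N\{\d+\}|N|)"
_PATTERN_RE = re.compile(
    rf"^C{_RUN}CC{_RUN}C{_RUN}C{_RUN}CC{_RUN}C$"
)


def _run_length(token: str) -> int:
    if token == "":
        return 0
    if token == "N":
        return 1
    return int(token[2:-1])


def parse_pattern(text: str) -> SpacingPattern:
    """Parse a CN{k} spacing-pattern string.

    Raises :class:`PatternParseError` on anything that does not match the
    strict grammar ``C run CC run C run C run CC run C``.
    """
    if not text:
        raise PatternParseError("empty pattern string")
    m = _PATTERN_RE.match(text)
    if m is None:
        raise PatternParseError(f"not a valid spacing pattern: {text!r}")
    spacers = tuple(_run_length(tok) for tok in m.groups())
    pattern = SpacingPattern(spacers=spacers)  # type: ignore[arg-type]
    if pattern.render() != text:
        # e.g. "N{1}" or "N{0}" instead of the canonical forms
        raise PatternParseError(f"non-canonical run token in: {text!r}")
    return pattern


def pattern_from_topology(topology: "CysteineTopology") -> SpacingPattern:
    """Project a scanned cysteine topology onto its spacing pattern."""
    return SpacingPattern(spacers=tuple(topology.spacers))  # type: ignore[arg-type]


def classify_spacing(
    pattern: SpacingPattern, rule: SpacingClassRule = SpacingClassRule()
) -> str:
    """Assign a spacing class: class II template first, then the class I s4 test.

    Returns one of ``"classII_spacing"``, ``"classI_spacing"``, ``"atypical"``.
    """
    if all(
        lo <= s <= hi for s, (lo, hi) in zip(pattern.spacers, rule.class2_template)
    ):
        return CLASS_II_SPACING
    if pattern.spacers[3] in rule.class1_s4:
        return CLASS_I_SPACING
    return ATYPICAL_SPACING
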