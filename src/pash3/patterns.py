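"""Gapped sampling patterns (spaced seeds) and their self-overlap tables.

A gapped pattern is a binary mask over a window of ``span`` basepairs; the
'1' positions are sampled when forming a k-mer key, the '0' positions are
ignored.  Two sequences match at a pair of positions when every *sampled*
base agrees; gapped positions never participate in the match definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "GappedPattern",
    "PatternError",
    "parse_pattern",
    "sample_kmer",
    "overlap_table",
    "DEFAULT_MAPPING_PATTERN",
    "DEFAULT_BISULFITE_PATTERN",
    "default_pattern",
]

#: Default mask for regular mapping (weight 11, span 19).
DEFAULT_MAPPING_PATTERN = "1110110110001101010"

#: Default mask for bisulfite mapping (weight 12, span 18).
DEFAULT_BISULFITE_PATTERN = "111010110100110111"

_VALID_BASES = frozenset("ACGT")


class PatternError(ValueError):
    """Raised for malformed pattern strings."""


@dataclass(frozen=True)
class GappedPattern:
    """An ordered set of sampled offsets within a fixed span.

    Attributes
    ----------
    offsets:
        Strictly increasing 0-based sampled positions; the first is always 0
        and the last is ``span - 1``.
    span:
        Total mask length in basepairs.
    weight:
        Number of sampled positions (``len(offsets)``).
    """

    offsets: tuple[int, ...]
    span: int
    weight: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.offsets:
            raise PatternError("pattern has no sampled positions")
        if list(self.offsets) != sorted(set(self.offsets)):
            raise PatternError("offsets must be strictly increasing")
        if self.offsets[0] != 0:
            raise PatternError("first sampled offset must be 0")
        if self.offsets[-1] != self.span - 1:
            raise PatternError("last sampled offset must be span - 1")
        if self.weight == 0:
            object.__setattr__(self, "weight", len(self.offsets))
        elif self.weight != len(self.offsets):
            raise PatternError("weight does not match number of offsets")

    @property
    def mask(self) -> str:
        """The 0/1 string rendering of this pattern."""
        bits = ["0"] * self.span
        for x in self.offsets:
            bits[x] = "1"
        return "".join(bits)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.mask


def parse_pattern(text: str) -> GappedPattern:
    """Parse a 0/1 mask string into a :class:`GappedPattern`.

    Raises
    ------
    PatternError
        If the string is empty, contains a non-binary character, or has a
        leading/trailing '0'; the message names the offending position.
    """
    if not text:
        raise PatternError("empty pattern string")
    for i, ch in enumerate(text):
        if ch not in "01":
            raise PatternError(f"non-binary character {ch!r} at position {i}")
    if text[0] != "1":
        raise PatternError("leading '0' at position 0: pattern must start with '1'")
    if text[-1] != "1":
        raise PatternError(
            f"trailing '0' at position {len(text) - 1}: pattern must end with '1'"
        )
    offsets = tuple(i for i, ch in enumerate(text) if ch == "1")
    return GappedPattern(offsets=offsets, span=len(text))


def default_pattern(bisulfite: bool = False) -> GappedPattern:
    """The built-in mask for the given mode, normalized for parsing.

    The regular-mapping default string ends in '0'; trailing zeros carry no
    sampled positions, so they are dropped before parsing (the sampled
    offsets are unchanged).  User-supplied masks must satisfy the strict
    :func:`parse_pattern` contract.
    """
    mask = DEFAULT_BISULFITE_PATTERN if bisulfite else DEFAULT_MAPPING_PATTERN
    return parse_pattern(mask.rstrip("0"))


def sample_kmer(seq: str, pos: int, pattern: GappedPattern) -> Optional[str]:
    """Extract the sampled-base key at ``pos``, or ``None`` if unusable.

    A position is unusable when the mask does not fit inside ``seq`` or any
    *sampled* base is not one of A/C/G/T.  Non-sampled positions are never
    inspected.
    """
    if pos < 0 or pos + pattern.span > len(seq):
        return None
    chars = []
    for x in pattern.offsets:
        ch = seq[pos + x]
        if ch not in _VALID_BASES:
            return None
        chars.append(ch)
    return "".join(chars)


def overlap_table(pattern: GappedPattern) -> list[int]:
    """Self-overlap counts ``ovl(d)`` for ``d = 0 .. span``.

    Two placements of the pattern overlapping by ``d`` bases are shifted by
    ``s = span - d``; ``ovl(d)`` is the number of sampled positions the two
    placements share, i.e. ``|offsets ∩ (offsets + s)|``.  ``ovl(0) == 0``
    and ``ovl(span) == weight``.
    """
    offs = set(pattern.offsets)
    table = []
    for d in range(pattern.span + 1):
        s = pattern.span - d
        table.append(len(offs & {x + s for x in pattern.offsets}))
    return table
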