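"""Degenerate block-consensus patterns and sequence scanning.

NMN deamidase families are fingerprinted by short conserved blocks whose
consensus strings mix strictly conserved residues, majority residues,
alternative sets, physicochemical classes and wildcards.  This module
implements that pattern language:

=============  =====================================================
token          meaning
=============  =====================================================
``G``          majority residue (counts toward the score, no veto)
``G!``         strictly conserved residue (a mismatch vetoes the hit)
``[TD]``       alternative residue set (``[TD]!`` makes it strict)
``c``/``h``/``p``  charged / hydrophobic / polar residue class
``x``          wildcard (ignored by the score)
=============  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional
import warnings

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Physicochemical class membership. The legend behind the class codes does
#: not enumerate members, so a standard partition is fixed here once:
#: c = charged, h = hydrophobic, p = small polar.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "c": frozenset("DEKRH"),
    "h": frozenset("AVLIMFWCY"),
    "p": frozenset("STNQG"),
}


class PatternSyntaxError(ValueError):
    """Raised when a consensus string cannot be tokenized."""


@dataclass(frozen=True)
class PositionSpec:
    """One column of a motif: the allowed residues and whether it vetoes.

    ``class_code`` / ``wildcard`` record how the position was written so the
    pattern can be rendered back to the grammar losslessly.
    """

    allowed: frozenset[str]
    strict: bool = False
    class_code: Optional[str] = None
    wildcard: bool = False

    def __post_init__(self) -> None:
        if self.wildcard:
            if self.strict:
                raise ValueError("wildcard positions are never strict")
            return
        if not self.allowed:
            raise ValueError("allowed set must be non-empty")
        bad = self.allowed - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residues in position spec: {sorted(bad)}")

    def matches(self, residue: str) -> bool:
        """True if ``residue`` satisfies this position. 'X' never matches
        a non-wildcard position (conservative for functionality calls)."""
        if self.wildcard:
            return True
        return residue in self.allowed


@dataclass(frozen=True)
class MotifPattern:
    """An ordered run of :class:`PositionSpec` with an identifier."""

    id: str
    positions: tuple[PositionSpec, ...]
    lineage_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError(f"pattern {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_informative(self) -> int:
        """Number of non-wildcard positions (the score denominator)."""
        return sum(1 for p in self.positions if not p.wildcard)

    @property
    def strict_offsets(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.positions) if p.strict)


@dataclass(frozen=True)
class MotifMatch:
    """A placement of a pattern on a sequence.

    ``start``/``end`` are 0-based half-open; ``score`` is the fraction of
    non-wildcard positions matched (strict positions are all satisfied by
    construction).
    """

    pattern_id: str
    sequence_id: str
    start: int
    end: int
    score: float
    matched_subsequence: str


def parse_pattern(text: str, id: str, lineage_tag: Optional[str] = None) -> MotifPattern:
    """Parse a consensus string in the block grammar into a pattern.

    Raises :class:`PatternSyntaxError` naming the offending offset for
    unknown characters or empty brackets.
    """
    positions: list[PositionSpec] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "x":
            positions.append(PositionSpec(allowed=frozenset(), wildcard=True))
            i += 1
        elif ch in RESIDUE_CLASSES:
            allowed = RESIDUE_CLASSES[ch]
            i += 1
            strict = i < n and text[i] == "!"
            if strict:
                i += 1
            positions.append(PositionSpec(allowed=allowed, strict=strict, class_code=ch))
        elif ch == "[":
            close = text.find("]", i)
            if close == -1:
                raise PatternSyntaxError(f"unclosed bracket at offset {i} in {text!r}")
            inner = text[i + 1 : close]
            if not inner:
                raise PatternSyntaxError(f"empty bracket at offset {i} in {text!r}")
            bad = set(inner) - AMINO_ACIDS
            if bad:
                raise PatternSyntaxError(
                    f"unknown residue {sorted(bad)} in bracket at offset {i} in {text!r}"
                )
            i = close + 1
            strict = i < n and text[i] == "!"
            if strict:
                i += 1
            positions.append(PositionSpec(allowed=frozenset(inner), strict=strict))
        elif ch in AMINO_ACIDS:
            i += 1
            strict = i < n and text[i] == "!"
            if strict:
                i += 1
            positions.append(PositionSpec(allowed=frozenset(ch), strict=strict))
        else:
            raise PatternSyntaxError(f"unknown character {ch!r} at offset {i} in {text!r}")
    if not positions:
        raise PatternSyntaxError(f"empty pattern {text!r}")
    return MotifPattern(id=id, positions=tuple(positions), lineage_tag=lineage_tag)


def render_pattern(pattern: MotifPattern) -> str:
    """Render a pattern back to the grammar (inverse of :func:`parse_pattern`)."""
    out: list[str] = []
    for p in pattern.positions:
        if p.wildcard:
            out.append("x")
            continue
        if p.class_code is not None:
            tok = p.class_code
        elif len(p.allowed) == 1:
            tok = next(iter(p.allowed))
        else:
            tok = "[" + "".join(sorted(p.allowed)) + "]"
        if p.strict:
            tok += "!"
        out.append(tok)
    return "".join(out)


def _relax(pattern: MotifPattern) -> MotifPattern:
    """Copy of ``pattern`` with all strictness dropped (used to *locate* a
    degraded block before checking individual residues)."""
    return MotifPattern(
        id=pattern.id,
        positions=tuple(
            PositionSpec(p.allowed, False, p.class_code, p.wildcard) for p in pattern.positions
        ),
        lineage_tag=pattern.lineage_tag,
    )


def scan(
    sequence: str,
    pattern: MotifPattern,
    min_score: float = 0.7,
    window: Optional[tuple[int, int]] = None,
    sequence_id: str = "",
) -> list[MotifMatch]:
    """Slide ``pattern`` over ``sequence`` and return qualifying matches.

    A window position qualifies when every strict position matches exactly
    and score = matched non-wildcard / total non-wildcard >= ``min_score``.
    Matches are sorted by start, then descending score.  Overlaps are kept.
    Residues outside the 20-letter alphabet (plus 'X') trigger a warning and
    count as mismatches.
    """
    if not 0 < min_score <= 1:
        raise ValueError("min_score must be in (0, 1]")
    if not sequence:
        return []
    unknown = set(sequence) - AMINO_ACIDS - {"X"}
    if unknown:
        warnings.warn(
            f"sequence {sequence_id or '<anon>'} contains non-amino-acid letters "
            f"{sorted(unknown)}; treated as mismatches",
            stacklevel=2,
        )
    L = len(pattern)
    n_inf = pattern.n_informative
    lo, hi = 0, len(sequence) - L
    if window is not None:
        lo = max(lo, window[0])
        hi = min(hi, window[1] - L)
    matches: list[MotifMatch] = []
    for s in range(lo, hi + 1):
        ok = True
        hits = 0
        for off, spec in enumerate(pattern.positions):
            if spec.wildcard:
                continue
            if spec.matches(sequence[s + off]):
                hits += 1
            elif spec.strict:
                ok = False
                break
        if not ok:
            continue
        score = hits / n_inf if n_inf else 1.0
        if score >= min_score:
            matches.append(
                MotifMatch(
                    pattern_id=pattern.id,
                    sequence_id=sequence_id,
                    start=s,
                    end=s + L,
                    score=score,
                    matched_subsequence=sequence[s : s + L],
                )
            )
    matches.sort(key=lambda m: (m.start, -m.score))
    return matches


def best_match(
    sequence: str,
    pattern: MotifPattern,
    min_score: float = 0.7,
    window: Optional[tuple[int, int]] = None,
    relaxed: bool = False,
) -> Optional[MotifMatch]:
    """Highest-scoring match (ties to the leftmost), or None.

    With ``relaxed=True`` strict positions no longer veto — this locates a
    mutated block so that individual residues can then be inspected.
    """
    pat = _relax(pattern) if relaxed else pattern
    hits = scan(sequence, pat, min_score=min_score, window=window)
    if not hits:
        return None
    return max(hits, key=lambda m: (m.score, -m.start))
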