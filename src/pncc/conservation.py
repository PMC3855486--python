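"""Per-column information content, conserved-block detection and consensus
strings on multiple alignments.

This is the sequence-logo arithmetic behind the block inventory: a column's
conservation is measured as R = log2(20) - H, where H is the Shannon entropy
of its residue frequencies (gaps excluded), optionally with the small-sample
correction (s-1)/(2 ln2 n).  Contiguous high-information runs become
conserved blocks; their consensus is rendered in the block grammar and
matched against the catalog.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .catalog import CatalogEntry
from .motif import (
    AMINO_ACIDS,
    RESIDUE_CLASSES,
    MotifPattern,
    PositionSpec,
    parse_pattern,
)

LOG2_20 = math.log2(20.0)


@dataclass(frozen=True)
class Alignment:
    """A gapped protein multiple alignment (rows of equal length)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    lineage: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        L = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, expected {L}"
                )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.rows]


@dataclass(frozen=True)
class ConservedBlock:
    start_col: int
    end_col: int                 # half-open
    mean_information: float
    consensus: MotifPattern
    assigned_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end_col <= self.start_col:
            raise ValueError("end_col must exceed start_col")


def column_information(column: Sequence[str], correction: bool = False) -> float:
    """Information content of one alignment column in bits.

    Gaps are excluded from the frequency denominator; columns that are more
    than half gaps (or all gaps) score 0.  The optional correction subtracts
    (s-1)/(2 ln2 n) with s=20 and n the non-gap count; the result is floored
    at 0.
    """
    if len(column) == 0:
        raise ValueError("empty column")
    residues = [c for c in column if c != "-"]
    n = len(residues)
    if n == 0 or n * 2 < len(column):
        return 0.0
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    H = -sum((k / n) * math.log2(k / n) for k in counts.values())
    R = LOG2_20 - H
    if correction:
        R -= (20 - 1) / (2 * math.log(2) * n)
    return max(R, 0.0)


def detect_blocks(
    alignment: Alignment,
    min_bits: float = 2.0,
    max_low_cols: int = 1,
    min_len: int = 3,
    correction: bool = False,
    strict_threshold: float = 0.95,
    majority_threshold: float = 0.6,
) -> list[ConservedBlock]:
    """Find maximal runs of conserved columns.

    A block is a run of columns with information >= ``min_bits`` tolerating
    at most ``max_low_cols`` consecutive sub-threshold columns in its
    interior; it is trimmed to start and end on above-threshold columns and
    discarded if shorter than ``min_len``.
    """
    if min_bits <= 0 or min_len <= 0:
        raise ValueError("thresholds must be positive")
    bits = [
        column_information(alignment.column(j), correction=correction)
        for j in range(alignment.n_cols)
    ]
    blocks: list[ConservedBlock] = []
    j = 0
    n = alignment.n_cols
    while j < n:
        if bits[j] < min_bits:
            j += 1
            continue
        start = j
        end = j + 1            # half-open end of the current block
        low_run = 0
        k = j + 1
        while k < n:
            if bits[k] >= min_bits:
                end = k + 1
                low_run = 0
            else:
                low_run += 1
                if low_run > max_low_cols:
                    break
            k += 1
        if end - start >= min_len:
            mean_info = sum(bits[start:end]) / (end - start)
            cons = consensus_string(
                alignment,
                (start, end),
                strict_threshold=strict_threshold,
                majority_threshold=majority_threshold,
            )
            blocks.append(
                ConservedBlock(
                    start_col=start,
                    end_col=end,
                    mean_information=mean_info,
                    consensus=cons,
                )
            )
        # every column in (end-1, k] is sub-threshold, so resume after k
        j = k + 1
    return blocks


def consensus_string(
    alignment: Alignment,
    block: tuple[int, int],
    strict_threshold: float = 0.95,
    majority_threshold: float = 0.6,
) -> MotifPattern:
    """Render a column range as a pattern in the block grammar.

    Per column: one residue at >= ``strict_threshold`` -> strict literal;
    at >= ``majority_threshold`` -> plain literal; the top two residues
    jointly >= ``majority_threshold`` -> bracket set; a single
    physicochemical class at >= ``majority_threshold`` -> class code;
    otherwise wildcard.  Gaps are excluded from the denominators.
    """
    if not 0.5 <= majority_threshold < strict_threshold <= 1:
        raise ValueError("need 0.5 <= majority_threshold < strict_threshold <= 1")
    start, end = block
    tokens: list[str] = []
    for j in range(start, end):
        residues = [c for c in alignment.column(j) if c != "-" and c in AMINO_ACIDS]
        if not residues:
            tokens.append("x")
            continue
        n = len(residues)
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top, top_n = ranked[0]
        if top_n / n >= strict_threshold:
            tokens.append(top + "!")
        elif top_n / n >= majority_threshold:
            tokens.append(top)
        elif len(ranked) >= 2 and (top_n + ranked[1][1]) / n >= majority_threshold:
            pair = sorted([top, ranked[1][0]], key=lambda r: -counts[r])
            tokens.append("[" + "".join(pair) + "]")
        else:
            for code, members in RESIDUE_CLASSES.items():
                if sum(counts.get(r, 0) for r in members) / n >= majority_threshold:
                    tokens.append(code)
                    break
            else:
                tokens.append("x")
    return parse_pattern("".join(tokens), id=f"cols[{start},{end})")


def _positional_agreement(consensus: MotifPattern, pattern: MotifPattern) -> float:
    """Best ungapped-overlap agreement between a detected consensus and a
    catalog pattern, as a fraction of the catalog pattern's length.

    Two position specs agree when their allowed sets intersect (wildcards
    agree with anything).  The consensus slides over the pattern to absorb
    small boundary shifts; overhangs count as disagreement.
    """
    nc, np_ = len(consensus), len(pattern)
    best = 0.0
    for shift in range(-(np_ - 1), nc):
        agree = 0
        for i in range(np_):
            j = shift + i
            if j < 0 or j >= nc:
                continue
            a, b = consensus.positions[j], pattern.positions[i]
            if a.wildcard or b.wildcard or (a.allowed & b.allowed):
                agree += 1
        best = max(best, agree / np_)
    return best


def label_blocks(
    blocks: list[ConservedBlock],
    catalog: list[CatalogEntry],
    domain_tag: Optional[str] = None,
    min_agreement: float = 0.5,
) -> list[ConservedBlock]:
    """Assign each detected block the best-matching catalog entry.

    Ties in agreement are broken in favour of the assignment that keeps
    canonical block order increasing along the blocks' coordinates; blocks
    with no entry above ``min_agreement`` keep a null label.
    """
    pool = [e for e in catalog if domain_tag is None or e.domain_tag == domain_tag]
    out: list[ConservedBlock] = []
    last_order = 0
    for blk in sorted(blocks, key=lambda b: b.start_col):
        scored: list[tuple[float, CatalogEntry]] = []
        for e in pool:
            s = _positional_agreement(blk.consensus, e.pattern)
            if s >= min_agreement:
                scored.append((s, e))
        if not scored:
            out.append(replace(blk, assigned_label=None))
            continue
        best_score = max(s for s, _ in scored)
        tied = [e for s, e in scored if s == best_score]
        ordered = [e for e in tied if e.canonical_order_index > last_order]
        pick = min(
            ordered or tied,
            key=lambda e: (e.canonical_order_index, e.id),
        )
        last_order = pick.canonical_order_index
        out.append(replace(blk, assigned_label=pick.id))
    return out
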