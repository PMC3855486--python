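"""The conserved-block inventory of the NMN deamidase family.

Seven blocks fingerprint the MocF domain (M-I..M-VII), two the interdomain
segment (i-I, i-II) and nine the CinA/PncC domain (P-I..P-IX).  Inactive
lineages carry documented variant forms of several blocks; the catalog ships
those variants alongside the canonical patterns, together with the key
functional residues each block contributes to the active site.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional

from .motif import MotifMatch, MotifPattern, best_match, parse_pattern, render_pattern

CINA_LINEAGES = (
    "2.1", "2.2.1.1", "2.2.1.2", "2.2.2.1", "2.2.2.2", "2.2.2.3",
    "2.2.3.1", "2.2.3.2", "2.2.3.3", "2.2.3.4",
)
#: All named terminal lineage labels of the two-origin classification.
LINEAGES = ("1.1", "1.2", "1.3") + CINA_LINEAGES

#: Active-site residues of the CinA domain in 2A9S numbering.
CINA_KEY_RESIDUES_2A9S = {
    31: ("S", "NMN amide contact"),
    46: ("G", "active-site wall"),
    48: ("S", "active-site wall"),
    58: ("Y", "catalytic tyrosine"),
    60: ("N", "amide positioning"),
    63: ("K", "catalytic lysine"),
    105: ("S/T", "NMN amino-group contact"),
    106: ("G", "NMN amino-group contact"),
    120: ("G", "near-pocket glycine"),
    145: ("R", "phosphate binding"),
}

#: The same ten positions in the numbering of the O. iheyensis enzyme.
CINA_KEY_RESIDUES_OIPNCC = {
    281: ("E", "active site"),
    282: ("S", "NMN amide contact"),
    284: ("T", "active site"),
    286: ("G", "active site"),
    299: ("S", "active-site wall"),
    309: ("Y", "catalytic tyrosine"),
    314: ("K", "catalytic lysine"),
    356: ("S/T", "NMN amino-group contact"),
    357: ("G", "NMN amino-group contact"),
    394: ("R", "phosphate binding"),
}

#: MocF-domain key residues in 3KBQ numbering.
MOCF_KEY_RESIDUES_3KBQ = {
    44: ("D", "catalytic aspartate, strict across all lineages"),
    75: ("D", "pyrophosphate binding"),
    114: ("K", "substrate-facing"),
    115: ("M", "substrate-facing"),
    148: ("P", "phosphate binding"),
    149: ("G", "phosphate binding"),
}


@dataclass(frozen=True)
class KeyResidue:
    offset: int                 # 0-based offset inside the block pattern
    residues: frozenset[str]    # accepted residue(s) at that offset
    role: str
    reference: str              # e.g. "2A9S:S31"


@dataclass(frozen=True)
class CatalogEntry:
    pattern: MotifPattern
    domain_tag: str             # mocf | interdomain | cina
    canonical_order_index: int
    key_residues: tuple[KeyResidue, ...] = ()
    variant_of: Optional[str] = None
    note: str = ""

    @property
    def id(self) -> str:
        return self.pattern.id

    @property
    def canonical_id(self) -> str:
        """The canonical block this entry represents (itself if canonical)."""
        return self.variant_of or self.pattern.id

    def __post_init__(self) -> None:
        for kr in self.key_residues:
            if kr.offset >= len(self.pattern):
                raise ValueError(
                    f"{self.id}: key residue offset {kr.offset} outside pattern"
                )


class CatalogError(ValueError):
    pass


def _parse_key_residues(cell: str) -> tuple[KeyResidue, ...]:
    if cell in (".", ""):
        return ()
    out = []
    for item in cell.split(";"):
        off, residues, role, ref = item.split("|")
        out.append(KeyResidue(int(off), frozenset(residues), role, ref))
    return tuple(out)


def load_catalog(path: Optional[str] = None) -> list[CatalogEntry]:
    """Load the shipped block catalog (or a user TSV with the same columns)."""
    if path is None:
        source = resources.files("pncc").joinpath("data/block_catalog.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        if row["id"] in seen:
            raise CatalogError(f"duplicate catalog id {row['id']!r}")
        seen.add(row["id"])
        lineage = None if row["lineage"] == "." else row["lineage"]
        variant_of = None if row["variant_of"] == "." else row["variant_of"]
        pattern = parse_pattern(row["pattern"], id=row["id"], lineage_tag=lineage)
        entries.append(
            CatalogEntry(
                pattern=pattern,
                domain_tag=row["domain"],
                canonical_order_index=int(row["order"]),
                key_residues=_parse_key_residues(row["key_residues"]),
                variant_of=variant_of,
                note=row["note"],
            )
        )
    _validate(entries)
    return entries


def _validate(entries: list[CatalogEntry]) -> None:
    by_id = {e.id: e for e in entries}
    for e in entries:
        if e.variant_of is not None and e.variant_of not in by_id:
            raise CatalogError(f"{e.id}: variant_of {e.variant_of!r} not in catalog")
    mocf = [e for e in entries if e.domain_tag == "mocf" and e.variant_of is None]
    cina = [e for e in entries if e.domain_tag == "cina" and e.variant_of is None]
    if [e.canonical_order_index for e in sorted(mocf, key=lambda e: e.canonical_order_index)] != list(range(1, 8)):
        raise CatalogError("canonical MocF blocks must be ordered 1..7")
    if [e.canonical_order_index for e in sorted(cina, key=lambda e: e.canonical_order_index)] != list(range(1, 10)):
        raise CatalogError("canonical CinA blocks must be ordered 1..9")


def get_entry(catalog: list[CatalogEntry], entry_id: str) -> CatalogEntry:
    for e in catalog:
        if e.id == entry_id:
            return e
    raise KeyError(entry_id)


def canonical_entries(catalog: list[CatalogEntry], domain_tag: str) -> list[CatalogEntry]:
    out = [e for e in catalog if e.domain_tag == domain_tag and e.variant_of is None]
    return sorted(out, key=lambda e: e.canonical_order_index)


def scan_catalog(
    sequence: str,
    catalog: list[CatalogEntry],
    min_score: float = 0.7,
    sequence_id: str = "",
) -> dict[str, list[MotifMatch]]:
    """Scan one sequence against every catalog entry; keyed by entry id."""
    from .motif import scan

    return {
        e.id: scan(sequence, e.pattern, min_score=min_score, sequence_id=sequence_id)
        for e in catalog
    }


def export_json(catalog: list[CatalogEntry]) -> str:
    """Full catalog as JSON for downstream tools."""
    payload = [
        {
            "id": e.id,
            "domain": e.domain_tag,
            "order": e.canonical_order_index,
            "lineage": e.pattern.lineage_tag,
            "variant_of": e.variant_of,
            "pattern": render_pattern(e.pattern),
            "key_residues": [
                {
                    "offset": kr.offset,
                    "residues": sorted(kr.residues),
                    "role": kr.role,
                    "reference": kr.reference,
                }
                for kr in e.key_residues
            ],
            "note": e.note,
        }
        for e in catalog
    ]
    return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Inactivating signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InactivatingSignature:
    """A documented combination of substitutions/deletions predicting loss of
    deamidase activity.  The predicate sees the sequence and its full catalog
    scan (entry id -> matches)."""

    lineage: str
    name: str
    description: str
    predicate: Callable[[str, dict[str, list[MotifMatch]]], bool] = field(compare=False)


#: Blocks deleted outright in the decayed two-domain branch; everything else
#: survives in some form in every lineage and can anchor an interval.
_DECAY_BLOCKS = ("P-III", "P-V", "P-VII")


def _anchor_chain(
    matches: dict[str, list[MotifMatch]], catalog: list[CatalogEntry]
):
    """Ordered-chain placements of the six anchor CinA block families
    (canonical id -> placement).

    The chain solves block placement globally (canonical order,
    non-overlap); excluding the three decay-deleted blocks from it keeps
    chance hits of their short patterns from competing with genuine anchor
    placements.  Presence or absence of P-III/P-V/P-VII is then judged
    inside the interval between their anchor neighbours.
    """
    from .classify import _best_chain  # deferred: classify imports this module

    anchors = [
        e for e in canonical_entries(catalog, "cina") if e.id not in _DECAY_BLOCKS
    ]
    chain = _best_chain(matches, anchors, catalog)
    return {p.canonical_id: p for p in chain}


def _anchor_window(
    seq: str, placements, order_of: dict[str, int], block_id: str
) -> tuple[int, int]:
    """Sequence interval where ``block_id`` is expected, bounded by the
    nearest placed anchors on either side."""
    lo, hi = 0, len(seq)
    target = order_of[block_id]
    for cid, p in placements.items():
        if order_of[cid] < target:
            lo = max(lo, p.end)
        elif order_of[cid] > target:
            hi = min(hi, p.start)
    return lo, hi


def _matched_in(
    matches: dict[str, list[MotifMatch]], entry_id: str, window: tuple[int, int]
) -> bool:
    return any(
        window[0] <= m.start and m.end <= window[1]
        for m in matches.get(entry_id, [])
    )


def inactivating_signatures(catalog: list[CatalogEntry]) -> list[InactivatingSignature]:
    p3 = get_entry(catalog, "P-III").pattern
    order_of = {
        e.id: e.canonical_order_index
        for e in canonical_entries(catalog, "cina")
    }

    def ydej(seq: str, matches: dict[str, list[MotifMatch]]) -> bool:
        # Y58F + N60D double substitution in the P-III block.  The canonical
        # strict tyrosine vetoes matching, so the mutated block is either the
        # shipped double-mutant variant or a relaxed-located canonical P-III
        # whose two offsets are inspected.  An intact canonical P-III at its
        # expected locus rules the signature out.
        placements = _anchor_chain(matches, catalog)
        narrow = _anchor_window(seq, placements, order_of, "P-III")
        p1, p6 = placements.get("P-I"), placements.get("P-VI")
        wide = (p1.end if p1 else 0, p6.start if p6 else len(seq))
        # if the narrow window holds no P-III evidence at all, the nearest
        # anchor was likely coincidental; retry between P-I and P-VI
        for window in (narrow, wide):
            if window[1] - window[0] < len(p3):
                continue
            if _matched_in(matches, "P-III", window):
                return False
            if _matched_in(matches, "P-III/2.2.2.2", window):
                return True
            loc = best_match(seq, p3, min_score=0.5, window=window, relaxed=True)
            if loc is not None:
                return seq[loc.start] == "F" and seq[loc.start + 2] == "D"
        return False

    def yfay(seq: str, matches: dict[str, list[MotifMatch]]) -> bool:
        # Gene decay of the two-domain inactive branch: P-III, P-V and P-VII
        # are deleted outright while P-I/P-II survive only as degraded forms.
        placements = _anchor_chain(matches, catalog)
        blocks_gone = not any(
            _matched_in(matches, b, _anchor_window(seq, placements, order_of, b))
            for b in _DECAY_BLOCKS
        )
        placed_as = {p.entry_id for p in placements.values()}
        variant_present = bool(placed_as & {"P-I/2.2.1.2", "P-II/2.2.1.2"})
        return blocks_gone and variant_present

    def fungal(seq: str, matches: dict[str, list[MotifMatch]]) -> bool:
        # Fungal P-I carries alanine at the S31-homologous offset.
        p1 = _anchor_chain(matches, catalog).get("P-I")
        return p1 is not None and p1.entry_id == "P-I/2.2.3.4"

    return [
        InactivatingSignature(
            lineage="2.2.2.2",
            name="YdeJ-like",
            description="Y58F and N60D point mutations in block P-III; "
            "P-II replaced by the DTP form",
            predicate=ydej,
        ),
        InactivatingSignature(
            lineage="2.2.1.2",
            name="YfaY-like",
            description="blocks P-III, P-V and P-VII deleted; P-I/P-II present "
            "only as degraded variants",
            predicate=yfay,
        ),
        InactivatingSignature(
            lineage="2.2.3.4",
            name="fungal-split",
            description="alanine replaces the catalytic-pocket serine in block P-I",
            predicate=fungal,
        ),
    ]
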