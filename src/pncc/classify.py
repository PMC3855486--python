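"""Domain-architecture calling, functionality prediction and lineage
assignment for NMN deamidase sequences.

A sequence is scanned against the full block catalog; blocks found in
canonical order decide the architecture (single CinA, MocF+CinA fusion,
N-terminally extended CinA, split CinA, MocF only); the ten active-site
residue checks and the documented inactivating signatures decide
functionality; and a decision table over architecture, functionality,
fingerprint scores and optional taxonomy hints assigns one of the named
lineages of the two-origin classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .catalog import (
    CatalogEntry,
    InactivatingSignature,
    canonical_entries,
    get_entry,
    inactivating_signatures,
    scan_catalog,
)
from .motif import MotifMatch, best_match


class Architecture(str, Enum):
    CINA_ONLY = "CINA_ONLY"
    MOCF_CINA = "MOCF_CINA"
    CINA_NEXT_SHORT = "CINA_NEXT_SHORT"
    CINA_NEXT_LONG = "CINA_NEXT_LONG"
    MOCF_ONLY = "MOCF_ONLY"
    SPLIT_CINA = "SPLIT_CINA"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ClassifierConfig:
    min_score: float = 0.7
    min_mocf_blocks: int = 4      # of 7
    min_cina_blocks: int = 5      # of 9
    short_extension_max: int = 80
    cina_only_extension_max: int = 30
    split_gap_min: int = 40
    min_sequence_length: int = 50


@dataclass
class BlockPlacement:
    canonical_id: str
    entry_id: str                 # canonical id or the variant that matched
    start: int
    end: int
    score: float
    n_informative: int = 0        # non-wildcard positions of the matched pattern


@dataclass
class DomainArchitecture:
    call: Architecture
    evidence: list[BlockPlacement] = field(default_factory=list)
    extension_length: Optional[int] = None

    @property
    def cina_span(self) -> Optional[tuple[int, int]]:
        cina = [p for p in self.evidence if p.canonical_id.startswith("P-")]
        if not cina:
            return None
        return (min(p.start for p in cina), max(p.end for p in cina))


@dataclass
class FunctionalCall:
    verdict: str                                  # active | inactive | indeterminate
    checks: dict[str, str] = field(default_factory=dict)   # role -> pass/fail/absent
    fired_signatures: list[str] = field(default_factory=list)
    reason: str = ""

    def __post_init__(self) -> None:
        if self.verdict == "active" and self.fired_signatures:
            raise ValueError(
                "a record cannot be active while an inactivating signature fired"
            )
        if self.verdict == "active" and any(v != "pass" for v in self.checks.values()):
            raise ValueError("active verdict requires every key-residue check to pass")


@dataclass
class ClassificationRecord:
    sequence_id: str
    length: int
    architecture: DomainArchitecture
    functional_call: FunctionalCall
    lineage: str                                  # label or "unassigned"
    confidence: float
    lineage_scores: dict[str, float] = field(default_factory=dict)
    taxonomy_hint_used: bool = False


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

def _best_chain(
    matches: dict[str, list[MotifMatch]],
    entries: list[CatalogEntry],
    catalog: list[CatalogEntry],
) -> list[BlockPlacement]:
    """Longest chain of distinct canonical blocks placed at non-overlapping,
    canonically ordered positions.  A block counts as present through its
    canonical pattern or any lineage variant."""
    candidates: list[list[BlockPlacement]] = []
    for e in entries:
        variants = [v for v in catalog if v.variant_of == e.id]
        placements = []
        for ent in [e, *variants]:
            for m in matches.get(ent.id, []):
                placements.append(
                    BlockPlacement(
                        e.id, ent.id, m.start, m.end, m.score,
                        ent.pattern.n_informative,
                    )
                )
        # order decides ties below: best score first, canonical before
        # variants, more specific (informative) patterns before weaker ones,
        # then leftmost — the first state reaching the maximal
        # (length, score) wins
        placements.sort(
            key=lambda p: (
                -p.score,
                p.entry_id != p.canonical_id,
                -p.n_informative,
                p.start,
            )
        )
        candidates.append(placements)

    # DP over blocks in canonical order, maximizing chain length and
    # preferring higher total score at equal length.
    best_by_placement: list[dict[int, tuple[int, float, Optional[tuple[int, int]]]]] = []
    for bi, placements in enumerate(candidates):
        states: dict[int, tuple[int, float, Optional[tuple[int, int]]]] = {}
        for pi, p in enumerate(placements):
            best_prev: tuple[int, float, Optional[tuple[int, int]]] = (1, p.score, None)
            for bj in range(bi):
                for pj, (cnt, sc, _) in best_by_placement[bj].items():
                    q = candidates[bj][pj]
                    if q.end <= p.start:
                        cand = (cnt + 1, sc + p.score, (bj, pj))
                        if (cand[0], cand[1]) > (best_prev[0], best_prev[1]):
                            best_prev = cand
            states[pi] = best_prev
        best_by_placement.append(states)

    best_key: Optional[tuple[int, int]] = None
    best_val = (0, 0.0)
    for bi, states in enumerate(best_by_placement):
        for pi, (cnt, sc, _) in states.items():
            if (cnt, sc) > best_val:
                best_val = (cnt, sc)
                best_key = (bi, pi)
    chain: list[BlockPlacement] = []
    while best_key is not None:
        bi, pi = best_key
        chain.append(candidates[bi][pi])
        best_key = best_by_placement[bi][pi][2]
    chain.reverse()
    return chain


def call_architecture(
    sequence: str,
    matches: dict[str, list[MotifMatch]],
    catalog: list[CatalogEntry],
    config: ClassifierConfig = ClassifierConfig(),
) -> DomainArchitecture:
    """Decide the domain architecture from ordered block matches."""
    if len(sequence) < config.min_sequence_length:
        warnings.warn(
            f"sequence shorter than {config.min_sequence_length} residues; "
            "architecture UNKNOWN",
            stacklevel=2,
        )
        return DomainArchitecture(call=Architecture.UNKNOWN)

    mocf_chain = _best_chain(matches, canonical_entries(catalog, "mocf"), catalog)
    cina_chain = _best_chain(matches, canonical_entries(catalog, "cina"), catalog)
    mocf_present = len(mocf_chain) >= config.min_mocf_blocks
    cina_present = len(cina_chain) >= config.min_cina_blocks
    evidence = (mocf_chain if mocf_present else []) + (cina_chain if cina_present else [])

    if mocf_present and cina_present:
        cina_start = min(p.start for p in cina_chain)
        if max(p.end for p in mocf_chain) <= cina_start:
            return DomainArchitecture(call=Architecture.MOCF_CINA, evidence=evidence)
        # tolerate coincidental hits of short MocF patterns inside the CinA
        # region: the MocF domain counts only upstream of the CinA chain
        upstream = [p for p in mocf_chain if p.end <= cina_start]
        if len(upstream) >= config.min_mocf_blocks:
            return DomainArchitecture(
                call=Architecture.MOCF_CINA, evidence=upstream + cina_chain
            )
        return DomainArchitecture(call=Architecture.UNKNOWN, evidence=evidence)
    if cina_present:
        extension = cina_chain[0].start
        order_of = {
            e.id: e.canonical_order_index for e in canonical_entries(catalog, "cina")
        }
        for prev, nxt in zip(cina_chain, cina_chain[1:]):
            # a genuine spacer separates nearly adjacent blocks; a long gap
            # spanning several missing blocks is block loss, not a split
            close_in_order = (
                order_of[nxt.canonical_id] - order_of[prev.canonical_id] <= 2
            )
            if close_in_order and nxt.start - prev.end >= config.split_gap_min:
                return DomainArchitecture(
                    call=Architecture.SPLIT_CINA,
                    evidence=evidence,
                    extension_length=extension,
                )
        if extension <= config.cina_only_extension_max:
            call = Architecture.CINA_ONLY
        elif extension <= config.short_extension_max:
            call = Architecture.CINA_NEXT_SHORT
        else:
            call = Architecture.CINA_NEXT_LONG
        return DomainArchitecture(call=call, evidence=evidence, extension_length=extension)
    if mocf_present:
        return DomainArchitecture(call=Architecture.MOCF_ONLY, evidence=mocf_chain)
    return DomainArchitecture(call=Architecture.UNKNOWN)


# ---------------------------------------------------------------------------
# Functionality
# ---------------------------------------------------------------------------

#: Canonical blocks carrying the ten active-site residue checks.
_CHECK_BLOCKS = ("P-I", "P-II", "P-III", "P-VI", "P-VII", "P-VIII")


def _locate_block(
    sequence: str,
    entry: CatalogEntry,
    arch: DomainArchitecture,
    matches: dict[str, list[MotifMatch]],
    catalog: list[CatalogEntry],
) -> Optional[MotifMatch]:
    # the ordered-chain placement of the canonical pattern is authoritative
    for p in arch.evidence:
        if p.canonical_id == entry.id and p.entry_id == entry.id:
            return MotifMatch(
                pattern_id=p.entry_id, sequence_id="", start=p.start, end=p.end,
                score=p.score, matched_subsequence=sequence[p.start : p.end],
            )
    # otherwise search only between the neighbouring placed CinA blocks,
    # so that coincidental hits of short degenerate patterns elsewhere
    # cannot displace the true (mutated) block
    order_of = {
        e.id: e.canonical_order_index
        for e in catalog
        if e.variant_of is None and e.domain_tag == "cina"
    }
    target = order_of[entry.id]

    def _window(min_order_gap: int) -> tuple[int, int]:
        lo, hi = 0, len(sequence)
        for p in arch.evidence:
            o = order_of.get(p.canonical_id)
            if o is None or abs(o - target) < min_order_gap:
                continue
            if o < target:
                lo = max(lo, p.end)
            elif o > target:
                hi = min(hi, p.start)
        span = arch.cina_span
        if span is not None:
            lo = max(lo, span[0] - 10)
            hi = min(hi, span[1] + 10) if hi == len(sequence) else hi
        return lo, hi

    def _key_agreement(m: MotifMatch) -> int:
        return sum(
            1
            for kr in entry.key_residues
            if sequence[m.start + kr.offset] in kr.residues
        )

    from .motif import _relax, scan

    # search between immediate neighbours first; if that yields nothing the
    # neighbour placement itself may be coincidental, so retry between the
    # next-nearest placed blocks
    for min_order_gap in (1, 2):
        lo, hi = _window(min_order_gap)
        if hi - lo < len(entry.pattern):
            continue
        for pat in (entry.pattern, _relax(entry.pattern)):
            hits = scan(sequence, pat, min_score=0.5, window=(lo, hi))
            if hits:
                return max(hits, key=lambda m: (m.score, _key_agreement(m), -m.start))
    return None


def call_functionality(
    sequence: str,
    matches: dict[str, list[MotifMatch]],
    catalog: list[CatalogEntry],
    arch: DomainArchitecture,
    signatures: Optional[list[InactivatingSignature]] = None,
) -> FunctionalCall:
    """Active-site residue checklist plus inactivating-signature screen.

    Verdict: every check passes -> active; any signature fires -> inactive;
    otherwise indeterminate (including unresolved 'X' at a key position).
    """
    has_cina = arch.call in (
        Architecture.CINA_ONLY,
        Architecture.MOCF_CINA,
        Architecture.CINA_NEXT_SHORT,
        Architecture.CINA_NEXT_LONG,
        Architecture.SPLIT_CINA,
    )
    if not has_cina:
        return FunctionalCall(verdict="indeterminate", reason="no CinA domain")

    if signatures is None:
        signatures = inactivating_signatures(catalog)
    fired = [s.name for s in signatures if s.predicate(sequence, matches)]

    checks: dict[str, str] = {}
    for block_id in _CHECK_BLOCKS:
        entry = get_entry(catalog, block_id)
        loc = _locate_block(sequence, entry, arch, matches, catalog)
        for kr in entry.key_residues:
            label = f"{block_id}:{kr.reference}"
            if loc is None:
                checks[label] = "absent"
                continue
            residue = sequence[loc.start + kr.offset]
            if residue == "X":
                checks[label] = "absent"
            elif residue in kr.residues:
                checks[label] = "pass"
            else:
                checks[label] = "fail"

    if fired:
        return FunctionalCall(verdict="inactive", checks=checks, fired_signatures=fired)
    if all(v == "pass" for v in checks.values()):
        return FunctionalCall(verdict="active", checks=checks)
    return FunctionalCall(
        verdict="indeterminate",
        checks=checks,
        reason="key-residue checklist incomplete without an inactivating signature",
    )


# ---------------------------------------------------------------------------
# Lineage assignment
# ---------------------------------------------------------------------------

#: Hint resolution inside the two fingerprint-degenerate candidate sets.
#: These lineages are separated phylogenetically, not by block fingerprints,
#: so an externally supplied phylum/genus hint (never inferred from sequence)
#: breaks the tie.
MOCF_CINA_ACTIVE_HINTS = {
    "firmicutes": "1.2",
    "bacteroidetes": "1.1",
    "spirochaetes": "1.1",
    "thermotogae": "1.1",
    "cyanobacteria": "2.1",
    "aquificae": "2.1",
    "fusobacteria": "2.1",
    "chlorobi": "2.1",
    "gammaproteobacteria": "2.2.1.1",
    "shewanella": "2.2.1.1",
    "mycobacterium": "2.2.2.3",
    "actinobacteria": "2.2.2.3",
}

CINA_ONLY_ACTIVE_HINTS = {
    "gammaproteobacteria": "2.2.2.1",
    "escherichia": "2.2.2.1",
    "alphaproteobacteria": "2.2.3.1",
    "rhizobiales": "2.2.3.1",
    "agrobacterium": "2.2.3.1",
}


def _fingerprint_scores(
    sequence: str,
    matches: dict[str, list[MotifMatch]],
    catalog: list[CatalogEntry],
    candidates: Sequence[str],
    domain_tags: Sequence[str],
) -> dict[str, float]:
    """Mean best-match score per candidate lineage, preferring that
    lineage's variant pattern for blocks that have one."""
    scores = {}
    for lineage in candidates:
        per_block = []
        for e in catalog:
            if e.variant_of is not None or e.domain_tag not in domain_tags:
                continue
            variant = next(
                (
                    v
                    for v in catalog
                    if v.variant_of == e.id and v.pattern.lineage_tag == lineage
                ),
                None,
            )
            ent = variant or e
            hits = matches.get(ent.id, [])
            per_block.append(max((m.score for m in hits), default=0.0))
        scores[lineage] = sum(per_block) / len(per_block) if per_block else 0.0
    return scores


def assign_lineage(
    sequence: str,
    matches: dict[str, list[MotifMatch]],
    catalog: list[CatalogEntry],
    arch: DomainArchitecture,
    func: FunctionalCall,
    taxonomy_hint: Optional[str] = None,
    exemplars: Optional[dict[str, str]] = None,
) -> tuple[str, float, dict[str, float], bool]:
    """Decision table over architecture and functionality.

    Returns (lineage, confidence, per-candidate scores, hint_used).
    Confidence is the margin between the top two fingerprint scores (1.0 for
    architecture-determined branches, 0.0 for hint-resolved ties).
    """
    a = arch.call
    direct = {
        Architecture.MOCF_ONLY: "1.3",
        Architecture.CINA_NEXT_SHORT: "2.2.3.2",
        Architecture.CINA_NEXT_LONG: "2.2.3.3",
        Architecture.SPLIT_CINA: "2.2.3.4",
    }
    if a in direct:
        return direct[a], 1.0, {}, False
    if a == Architecture.MOCF_CINA and func.verdict == "inactive":
        return "2.2.1.2", 1.0, {}, False
    if a == Architecture.CINA_ONLY and func.verdict == "inactive":
        return "2.2.2.2", 1.0, {}, False

    if a == Architecture.MOCF_CINA and func.verdict == "active":
        candidates = ("1.1", "1.2", "2.1", "2.2.1.1", "2.2.2.3")
        hint_map = MOCF_CINA_ACTIVE_HINTS
        tags = ("mocf", "cina")
    elif a == Architecture.CINA_ONLY and func.verdict == "active":
        candidates = ("2.2.2.1", "2.2.3.1")
        hint_map = CINA_ONLY_ACTIVE_HINTS
        tags = ("cina",)
    else:
        return "unassigned", 0.0, {}, False

    scores = _fingerprint_scores(sequence, matches, catalog, candidates, tags)
    ranked = sorted(scores.items(), key=lambda kv: -kv[1])
    margin = ranked[0][1] - ranked[1][1] if len(ranked) > 1 else ranked[0][1]
    if margin > 1e-9:
        return ranked[0][0], margin, scores, False
    # tie: taxonomy hint, then nearest exemplar, then unassigned
    if taxonomy_hint:
        mapped = hint_map.get(taxonomy_hint.strip().lower())
        if mapped in candidates:
            return mapped, 0.0, scores, True
    if exemplars:
        from .phylo import pairwise_align

        tied = [lin for lin, s in scores.items() if abs(s - ranked[0][1]) <= 1e-9]
        best_lin, best_ident = None, -1.0
        for lin in sorted(tied):
            if lin not in exemplars:
                continue
            ident = pairwise_align(sequence, exemplars[lin], mode="global").identity
            if ident > best_ident:
                best_lin, best_ident = lin, ident
        if best_lin is not None:
            return best_lin, 0.0, scores, False
    return "unassigned", 0.0, scores, False


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def classify_sequence(
    sequence_id: str,
    sequence: str,
    catalog: list[CatalogEntry],
    taxonomy_hint: Optional[str] = None,
    exemplars: Optional[dict[str, str]] = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassificationRecord:
    matches = scan_catalog(
        sequence, catalog, min_score=config.min_score, sequence_id=sequence_id
    )
    arch = call_architecture(sequence, matches, catalog, config)
    func = call_functionality(sequence, matches, catalog, arch)
    lineage, confidence, scores, hint_used = assign_lineage(
        sequence, matches, catalog, arch, func,
        taxonomy_hint=taxonomy_hint, exemplars=exemplars,
    )
    return ClassificationRecord(
        sequence_id=sequence_id,
        length=len(sequence),
        architecture=arch,
        functional_call=func,
        lineage=lineage,
        confidence=confidence,
        lineage_scores=scores,
        taxonomy_hint_used=hint_used,
    )


def classify_sequences(
    records: Sequence[tuple[str, str]],
    catalog: Optional[list[CatalogEntry]] = None,
    taxonomy: Optional[dict[str, str]] = None,
    exemplars: Optional[dict[str, str]] = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> list[ClassificationRecord]:
    """Classify a FASTA-style list of (id, sequence) pairs."""
    if catalog is None:
        from .catalog import load_catalog

        catalog = load_catalog()
    hints = taxonomy or {}
    return [
        classify_sequence(
            rid, seq, catalog,
            taxonomy_hint=hints.get(rid), exemplars=exemplars, config=config,
        )
        for rid, seq in records
    ]
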