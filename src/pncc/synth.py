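"""Labeled synthetic panels of NMN deamidase sequences and kinetic datasets.

Sequences are assembled lineage by lineage from the catalog's block patterns:
a sampled N-terminal leader, block realizations joined by random linkers, and
a C-terminal tail.  Strict positions and key functional residues are never
mutated (purifying selection on catalytic residues); all other block
positions receive substitution noise at a configurable rate.  Inactive
lineages realize their documented degraded block variants, and the fungal
lineage inserts a long spacer inside the CinA block series.  Every record
carries a complete truth row (lineage, architecture, functionality, taxonomy
hint, block coordinates), and single-lineage panels yield an exact
known-truth alignment by construction.

Length classes emulated (means, residues): single-domain ~165, N-terminal
extension ~220, two-domain ~420, MocF-only ~170.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import CatalogEntry, get_entry, load_catalog
from .conservation import Alignment
from .motif import AMINO_ACIDS

AA = "".join(sorted(AMINO_ACIDS))

#: Representative phylum/genus hint emitted per lineage (the classifier uses
#: hints only to break fingerprint ties, per the lineage decision table).
LINEAGE_HINTS = {
    "1.1": "bacteroidetes",
    "1.2": "firmicutes",
    "1.3": "archaea",
    "2.1": "cyanobacteria",
    "2.2.1.1": "gammaproteobacteria",
    "2.2.1.2": "gammaproteobacteria",
    "2.2.2.1": "gammaproteobacteria",
    "2.2.2.2": "gammaproteobacteria",
    "2.2.2.3": "mycobacterium",
    "2.2.3.1": "alphaproteobacteria",
    "2.2.3.2": "helicobacter",
    "2.2.3.3": "proteobacteria",
    "2.2.3.4": "fungi",
}

TRUTH_ARCHITECTURE = {
    "1.1": "MOCF_CINA",
    "1.2": "MOCF_CINA",
    "1.3": "MOCF_ONLY",
    "2.1": "MOCF_CINA",
    "2.2.1.1": "MOCF_CINA",
    "2.2.1.2": "MOCF_CINA",
    "2.2.2.1": "CINA_ONLY",
    "2.2.2.2": "CINA_ONLY",
    "2.2.2.3": "MOCF_CINA",
    "2.2.3.1": "CINA_ONLY",
    "2.2.3.2": "CINA_NEXT_SHORT",
    "2.2.3.3": "CINA_NEXT_LONG",
    "2.2.3.4": "SPLIT_CINA",
}

#: Documented inactive lineages (plus the MocF-only archaeal lineage, which
#: has no CinA domain to judge).
TRUTH_FUNCTIONALITY = {
    lin: (
        "inactive"
        if lin in ("2.2.1.2", "2.2.2.2", "2.2.3.4")
        else "indeterminate" if lin == "1.3" else "active"
    )
    for lin in TRUTH_ARCHITECTURE
}

TARGET_LENGTHS = {
    "MOCF_CINA": 420,
    "CINA_ONLY": 165,
    "CINA_NEXT_SHORT": 220,
    "CINA_NEXT_LONG": 220,
    "SPLIT_CINA": 220,
    "MOCF_ONLY": 170,
}


@dataclass(frozen=True)
class GeneratorConfig:
    lineage: str
    n: int = 20
    seed: int = 0
    substitution_rate: float = 0.05
    indel_rate: float = 0.0          # per-residue indels, linkers only
    protect_key_residues: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must be in [0, 1)")
        if self.lineage not in TRUTH_ARCHITECTURE:
            raise ValueError(f"unknown lineage {self.lineage!r}")


@dataclass
class Segment:
    """One region of a generated sequence (block or linker)."""

    kind: str                       # "block" | "linker"
    entry_id: Optional[str]         # catalog id for blocks
    domain_tag: Optional[str]
    start: int
    end: int


@dataclass
class LabeledPanel:
    records: list[tuple[str, str]]          # (id, sequence)
    truth: pd.DataFrame                     # one row per record
    segments: dict[str, list[Segment]]
    lineage: str
    seed: int


# ---------------------------------------------------------------------------
# Region plans: (kind, payload) where payload is an entry id for blocks and a
# (lo, hi) inclusive length range for linkers.  Ranges are chosen so that
# total lengths emulate the family's length classes.
# ---------------------------------------------------------------------------

_MOCF_CANON = ["M-I", "M-II", "M-III", "M-IV", "M-V", "M-VI", "M-VII"]
_CINA_CANON = ["P-I", "P-II", "P-III", "P-IV", "P-V", "P-VI", "P-VII", "P-VIII", "P-IX"]


def _interleave(blocks: Sequence[str], gaps: Sequence[tuple[int, int]]):
    plan = []
    for i, b in enumerate(blocks):
        plan.append(("block", b))
        if i < len(blocks) - 1:
            plan.append(("linker", gaps[i]))
    return plan


def _mocf_plan(lineage: str, gap: tuple[int, int]):
    blocks = ["M-IV/1.3" if (lineage == "1.3" and b == "M-IV") else b for b in _MOCF_CANON]
    return _interleave(blocks, [gap] * 6)


def _cina_plan(lineage: str):
    if lineage == "2.2.1.2":
        # P-III, P-V and P-VII deleted; degraded variants elsewhere
        return [
            ("block", "P-I/2.2.1.2"), ("linker", (6, 14)),
            ("block", "P-II/2.2.1.2"), ("linker", (22, 30)),
            ("block", "P-IV/2.2.1.2"), ("linker", (22, 30)),
            ("block", "P-VI/2.2.1.2"), ("linker", (22, 30)),
            ("block", "P-VIII"), ("linker", (6, 14)),
            ("block", "P-IX"),
        ]
    if lineage == "2.2.2.2":
        # milder decay: point-mutated P-III, replaced P-II/P-IV/P-VI, lost P-VIII
        return [
            ("block", "P-I"), ("linker", (8, 14)),
            ("block", "P-II/2.2.2.2"), ("linker", (8, 14)),
            ("block", "P-III/2.2.2.2"), ("linker", (8, 14)),
            ("block", "P-IV/2.2.2.2"), ("linker", (8, 14)),
            ("block", "P-V"), ("linker", (8, 14)),
            ("block", "P-VI/2.2.2.2"), ("linker", (8, 14)),
            ("block", "P-VII"), ("linker", (16, 24)),
            ("block", "P-IX"),
        ]
    if lineage == "2.2.3.4":
        # fungal: variant P-I/P-III/P-IV and a long spacer splitting the domain
        return [
            ("block", "P-I/2.2.3.4"), ("linker", (7, 13)),
            ("block", "P-II"), ("linker", (7, 13)),
            ("block", "P-III/2.2.3.4"), ("linker", (7, 13)),
            ("block", "P-IV/2.2.3.4"), ("linker", (52, 68)),
            ("block", "P-V"), ("linker", (7, 13)),
            ("block", "P-VI"), ("linker", (7, 13)),
            ("block", "P-VII"), ("linker", (7, 13)),
            ("block", "P-VIII"), ("linker", (7, 13)),
            ("block", "P-IX"),
        ]
    gap = (6, 14) if TRUTH_ARCHITECTURE[lineage] == "MOCF_CINA" else (7, 13)
    return _interleave(_CINA_CANON, [gap] * 8)


def _region_plan(lineage: str) -> list[tuple[str, object]]:
    arch = TRUTH_ARCHITECTURE[lineage]
    if arch == "MOCF_ONLY":
        return (
            [("linker", (5, 12))]
            + _mocf_plan(lineage, gap=(10, 16))
            + [("linker", (4, 8)), ("block", "i-I/1.3"), ("linker", (8, 14))]
        )
    if arch == "MOCF_CINA":
        return (
            [("linker", (5, 12))]
            + _mocf_plan(lineage, gap=(11, 19))
            + [
                ("linker", (28, 36)), ("block", "i-I"),
                ("linker", (30, 38)), ("block", "i-II"),
                ("linker", (30, 38)),
            ]
            + _cina_plan(lineage)
            + [("linker", (5, 15))]
        )
    leader = {
        "CINA_ONLY": (18, 26),
        "CINA_NEXT_SHORT": (62, 78),
        "CINA_NEXT_LONG": (81, 91),
        "SPLIT_CINA": (18, 26),
    }[arch]
    return (
        [("linker", leader)]
        + _cina_plan(lineage)
        + [("linker", (7, 13))]
    )


# ---------------------------------------------------------------------------
# Sequence realization
# ---------------------------------------------------------------------------

def _realize_template(entry: CatalogEntry, rng: np.random.Generator) -> tuple[str, set[int]]:
    """One concrete residue per pattern position, plus the protected offsets
    (strict positions and key residues, which substitution noise never touches)."""
    residues = []
    for spec in entry.pattern.positions:
        if spec.wildcard:
            residues.append(AA[rng.integers(len(AA))])
        elif len(spec.allowed) == 1:
            residues.append(next(iter(spec.allowed)))
        else:
            choices = sorted(spec.allowed)
            residues.append(choices[rng.integers(len(choices))])
    protected = set(entry.pattern.strict_offsets)
    protected.update(kr.offset for kr in entry.key_residues)
    return "".join(residues), protected


def _mutate(template: str, protected: set[int], rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return template
    out = list(template)
    for i, res in enumerate(out):
        if i in protected:
            continue
        if rng.random() < rate:
            alt = AA.replace(res, "")
            out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def _linker(lo: int, hi: int, indel_rate: float, rng: np.random.Generator) -> str:
    length = int(rng.integers(lo, hi + 1))
    chars = [AA[rng.integers(len(AA))] for _ in range(length)]
    if indel_rate > 0:
        edited: list[str] = []
        for c in chars:
            r = rng.random()
            if r < indel_rate / 2:
                continue                                  # deletion
            edited.append(c)
            if r > 1 - indel_rate / 2:
                edited.append(AA[rng.integers(len(AA))])  # insertion
        chars = edited
    return "".join(chars)


def generate_lineage_sequences(
    config: GeneratorConfig, catalog: Optional[list[CatalogEntry]] = None
) -> LabeledPanel:
    """Generate ``config.n`` labeled sequences for one lineage.

    Block realizations share a per-panel template (so that 'x' and class
    positions are conserved within the panel, as they are within a clade of
    close homologs) and diverge by per-sequence substitution noise.
    """
    if catalog is None:
        catalog = load_catalog()
    rng = np.random.default_rng(config.seed)
    plan = _region_plan(config.lineage)
    templates: dict[str, tuple[str, set[int]]] = {}
    for kind, payload in plan:
        if kind == "block" and payload not in templates:
            entry = get_entry(catalog, str(payload))
            tmpl, protected = _realize_template(entry, rng)
            if not config.protect_key_residues:
                protected = set(entry.pattern.strict_offsets)
            templates[str(payload)] = (tmpl, protected)

    by_id = {e.id: e for e in catalog}
    records: list[tuple[str, str]] = []
    segments: dict[str, list[Segment]] = {}
    truth_rows = []
    for i in range(config.n):
        seq_id = f"{config.lineage}|syn{i:03d}"
        parts: list[str] = []
        segs: list[Segment] = []
        pos = 0
        for kind, payload in plan:
            if kind == "linker":
                lo, hi = payload  # type: ignore[misc]
                s = _linker(lo, hi, config.indel_rate, rng)
                segs.append(Segment("linker", None, None, pos, pos + len(s)))
            else:
                entry_id = str(payload)
                tmpl, protected = templates[entry_id]
                s = _mutate(tmpl, protected, config.substitution_rate, rng)
                segs.append(
                    Segment("block", entry_id, by_id[entry_id].domain_tag, pos, pos + len(s))
                )
            parts.append(s)
            pos += len(s)
        seq = "".join(parts)
        records.append((seq_id, seq))
        segments[seq_id] = segs
        blocks_json = json.dumps(
            [[g.entry_id, g.start, g.end] for g in segs if g.kind == "block"]
        )
        truth_rows.append(
            {
                "id": seq_id,
                "lineage": config.lineage,
                "architecture": TRUTH_ARCHITECTURE[config.lineage],
                "functionality": TRUTH_FUNCTIONALITY[config.lineage],
                "taxonomy_hint": LINEAGE_HINTS[config.lineage],
                "length": len(seq),
                "blocks": blocks_json,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return LabeledPanel(
        records=records, truth=truth, segments=segments,
        lineage=config.lineage, seed=config.seed,
    )


def generate_panel(
    lineages: Sequence[str],
    n_per_lineage: int = 10,
    seed: int = 0,
    substitution_rate: float = 0.05,
    catalog: Optional[list[CatalogEntry]] = None,
) -> LabeledPanel:
    """Concatenate single-lineage panels (seeds derived per lineage)."""
    if catalog is None:
        catalog = load_catalog()
    panels = [
        generate_lineage_sequences(
            GeneratorConfig(
                lineage=lin,
                n=n_per_lineage,
                seed=(seed * 1009 + k) % (2**31 - 1),
                substitution_rate=substitution_rate,
            ),
            catalog,
        )
        for k, lin in enumerate(lineages)
    ]
    records = [r for p in panels for r in p.records]
    truth = pd.concat([p.truth for p in panels], ignore_index=True)
    segments = {k: v for p in panels for k, v in p.segments.items()}
    return LabeledPanel(
        records=records, truth=truth, segments=segments,
        lineage="mixed", seed=seed,
    )


def generate_truth_alignment(panel: LabeledPanel, domain: Optional[str] = None) -> Alignment:
    """Exact alignment of a single-lineage panel from construction coordinates.

    Segments are padded on the right to the panel-wide maximum, so block
    columns align exactly.  ``domain`` restricts the alignment to the span
    from the first to the last block of that domain tag (e.g. ``"mocf"`` or
    ``"cina"``), including the linkers in between.
    """
    if panel.lineage == "mixed":
        raise ValueError("truth alignments are defined for single-lineage panels")
    seg_lists = [panel.segments[rid] for rid, _ in panel.records]
    n_seg = len(seg_lists[0])
    if any(len(s) != n_seg for s in seg_lists):
        raise ValueError("inconsistent segment structure in panel")
    lo, hi = 0, n_seg - 1
    if domain is not None:
        idx = [
            k
            for k in range(n_seg)
            if seg_lists[0][k].kind == "block" and seg_lists[0][k].domain_tag == domain
        ]
        if not idx:
            raise ValueError(f"no blocks with domain tag {domain!r}")
        lo, hi = idx[0], idx[-1]
    widths = [
        max(s[k].end - s[k].start for s in seg_lists) for k in range(n_seg)
    ]
    ids, rows = [], []
    for (rid, seq), segs in zip(panel.records, seg_lists):
        row = []
        for k in range(lo, hi + 1):
            g = segs[k]
            piece = seq[g.start : g.end]
            row.append(piece + "-" * (widths[k] - len(piece)))
        ids.append(rid)
        rows.append("".join(row))
    return Alignment(ids=tuple(ids), rows=tuple(rows), lineage=panel.lineage)


def truth_block_columns(panel: LabeledPanel, domain: Optional[str] = None) -> list[tuple[str, int, int]]:
    """Ground-truth (entry_id, start_col, end_col) in truth-alignment columns."""
    seg_lists = [panel.segments[rid] for rid, _ in panel.records]
    n_seg = len(seg_lists[0])
    lo, hi = 0, n_seg - 1
    if domain is not None:
        idx = [
            k
            for k in range(n_seg)
            if seg_lists[0][k].kind == "block" and seg_lists[0][k].domain_tag == domain
        ]
        lo, hi = idx[0], idx[-1]
    widths = [max(s[k].end - s[k].start for s in seg_lists) for k in range(n_seg)]
    out = []
    col = 0
    for k in range(lo, hi + 1):
        g = seg_lists[0][k]
        if g.kind == "block":
            out.append((g.entry_id, col, col + widths[k]))
        col += widths[k]
    return out


# ---------------------------------------------------------------------------
# Kinetic datasets
# ---------------------------------------------------------------------------

def generate_kinetic_dataset(
    model: str,
    params,
    grid: Sequence[float],
    noise_cv: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Initial-rate table v = law(S) * (1 + eps), eps ~ N(0, noise_cv).

    ``params`` is an :class:`~pncc.kinetics.MMParams` or
    :class:`~pncc.kinetics.HillParams` matching ``model`` ('mm' | 'hill').
    """
    from . import kinetics

    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if any(s <= 0 for s in grid):
        raise ValueError("substrate grid must be positive")
    law = {"mm": kinetics.mm_rate, "hill": kinetics.hill_rate}[model]
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        for S in grid:
            v = law(params, float(S))
            noisy = v * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else v
            rows.append({"concentration": float(S), "rate": float(noisy), "replicate": rep})
    return pd.DataFrame(rows)
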