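"""FASTA / aligned-FASTA / TSV / JSON input-output.

FASTA parsing and writing go through Biopython; the aligned variant enforces
equal row lengths.  Classification reports are written both as TSV (one row
per sequence) and JSON (full evidence), and validated against a shipped
structural schema.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import ClassificationRecord
from .conservation import Alignment, ConservedBlock
from .motif import AMINO_ACIDS, render_pattern


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; duplicate ids are an error, residues
    outside the 20-letter alphabet (plus X) a warning."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - AMINO_ACIDS - {"X", "-"}
        if bad:
            warnings.warn(
                f"record {rec.id!r} contains non-amino-acid characters {sorted(bad)}",
                stacklevel=2,
            )
        records.append((rec.id, seq))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, wrap: int = 60) -> None:
    seqs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqs)


def read_alignment(path: str | Path, lineage: str | None = None) -> Alignment:
    """Aligned FASTA -> Alignment; ragged rows raise naming the offender."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"empty alignment file {path}")
    L = len(records[0][1])
    for rid, row in records:
        if len(row) != L:
            raise ValueError(
                f"alignment row {rid!r} has length {len(row)}, expected {L}"
            )
    return Alignment(
        ids=tuple(r for r, _ in records),
        rows=tuple(s for _, s in records),
        lineage=lineage,
    )


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sequence id -> phylum/genus hint."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed taxonomy line: {line!r}")
        out[parts[0]] = parts[1]
    return out


def read_rate_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns concentration, rate [, replicate]."""
    df = pd.read_csv(path, sep="\t")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def record_to_dict(rec: ClassificationRecord) -> dict:
    return {
        "id": rec.sequence_id,
        "length": rec.length,
        "architecture": rec.architecture.call.value,
        "extension_length": rec.architecture.extension_length,
        "functionality": rec.functional_call.verdict,
        "fired_signatures": rec.functional_call.fired_signatures,
        "checks": rec.functional_call.checks,
        "lineage": rec.lineage,
        "confidence": rec.confidence,
        "lineage_scores": rec.lineage_scores,
        "taxonomy_hint_used": rec.taxonomy_hint_used,
        "blocks": [
            {
                "block": p.canonical_id,
                "matched_as": p.entry_id,
                "start": p.start,       # 0-based half-open
                "end": p.end,
                "start_1based": p.start + 1,
                "score": p.score,
            }
            for p in rec.architecture.evidence
        ],
    }


def records_to_table(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.sequence_id,
                "length": rec.length,
                "architecture": rec.architecture.call.value,
                "functionality": rec.functional_call.verdict,
                "lineage": rec.lineage,
                "confidence": rec.confidence,
                "signatures": ";".join(rec.functional_call.fired_signatures),
                "n_blocks": len(rec.architecture.evidence),
            }
        )
    return pd.DataFrame(rows)


def write_classification_report(
    records: Sequence[ClassificationRecord],
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> dict:
    payload = {"records": [record_to_dict(r) for r in records]}
    validate_report(payload)
    if tsv_path is not None:
        records_to_table(records).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2))
    return payload


def blocks_to_table(blocks: Sequence[ConservedBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start": b.start_col,
                "end": b.end_col,
                "mean_bits": b.mean_information,
                "consensus": render_pattern(b.consensus),
                "label": b.assigned_label,
            }
            for b in blocks
        ]
    )


_TYPES = {"string": str, "number": (int, float), "integer": int,
          "boolean": bool, "object": dict, "array": list, "null": type(None)}


def _check(node, schema, path="$") -> None:
    t = schema.get("type")
    if t is not None:
        types = t if isinstance(t, list) else [t]
        if not any(isinstance(node, _TYPES[x]) for x in types):
            raise ValueError(f"{path}: expected {t}, got {type(node).__name__}")
    if isinstance(node, dict):
        for key in schema.get("required", []):
            if key not in node:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in node:
                _check(node[key], sub, f"{path}.{key}")
    if isinstance(node, list) and "items" in schema:
        for k, item in enumerate(node):
            _check(item, schema["items"], f"{path}[{k}]")


def validate_report(payload: dict) -> None:
    """Structural validation of a classification report against the shipped
    schema (required keys and types)."""
    schema = json.loads(
        resources.files("pncc").joinpath("data/classification_schema.json").read_text()
    )
    _check(payload, schema)
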