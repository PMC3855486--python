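"""Detect and label conserved blocks on the simulated lineage alignments.

Expects the alignments written by 01_simulate_panels.py.  The MocF-only
archaeal alignment should reconstruct blocks M-I..M-VII (seven blocks) and
the single-domain alignment blocks P-I..P-IX (nine), matching the block
inventory of the family.
"""

from pathlib import Path

from pncc.catalog import load_catalog
from pncc.conservation import column_information, detect_blocks, label_blocks
from pncc.io import blocks_to_table, read_alignment

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    catalog = load_catalog()
    by_canonical = {e.id: e.canonical_id for e in catalog}
    for lineage, domain, expected in [("1_3", "mocf", 7), ("2_2_3_1", "cina", 9)]:
        aln = read_alignment(RESULTS / f"alignment_{lineage}_{domain}.fasta")
        blocks = label_blocks(detect_blocks(aln), catalog, domain_tag=domain)
        table = blocks_to_table(blocks)
        table["canonical"] = [by_canonical.get(b.assigned_label) for b in blocks]
        out = RESULTS / f"blocks_{lineage}_{domain}.tsv"
        table.to_csv(out, sep="\t", index=False)
        labels = list(table["canonical"])
        status = "OK" if len(blocks) == expected else "UNEXPECTED"
        print(f"lineage {lineage.replace('_', '.')} {domain}: {len(blocks)} blocks "
              f"(expected {expected}, {status}): {labels}")
        bits = [column_information(aln.column(j)) for j in range(aln.n_cols)]
        import pandas as pd

        pd.DataFrame({"column": range(aln.n_cols), "bits": bits}).to_csv(
            RESULTS / f"column_bits_{lineage}_{domain}.tsv", sep="\t", index=False
        )


if __name__ == "__main__":
    main()
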