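"""Generate the labeled synthetic panels used by the downstream analyses.

Writes to results/: a 13-lineage mixed panel (FASTA + truth + taxonomy
hints) and known-truth alignments for the archaeal MocF-only lineage (1.3)
and the canonical single-domain lineage (2.2.3.1).
"""

from pathlib import Path

from pncc.catalog import load_catalog
from pncc.io import write_fasta
from pncc.synth import (
    TRUTH_ARCHITECTURE,
    GeneratorConfig,
    generate_lineage_sequences,
    generate_panel,
    generate_truth_alignment,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 42
NOISE = 0.05


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    catalog = load_catalog()

    panel = generate_panel(
        sorted(TRUTH_ARCHITECTURE), n_per_lineage=10, seed=SEED,
        substitution_rate=NOISE, catalog=catalog,
    )
    write_fasta(panel.records, RESULTS / "panel_13_lineages.fasta")
    panel.truth.to_csv(RESULTS / "panel_13_lineages.truth.tsv", sep="\t", index=False)
    with open(RESULTS / "panel_13_lineages.taxonomy.tsv", "w") as fh:
        for rid, hint in zip(panel.truth["id"], panel.truth["taxonomy_hint"]):
            fh.write(f"{rid}\t{hint}\n")
    print(f"panel: {len(panel.records)} sequences over 13 lineages "
          f"(seed {SEED}, {NOISE:.0%} substitution noise)")

    for lineage, domain in [("1.3", "mocf"), ("2.2.3.1", "cina")]:
        single = generate_lineage_sequences(
            GeneratorConfig(lineage=lineage, n=20, seed=SEED, substitution_rate=NOISE),
            catalog,
        )
        aln = generate_truth_alignment(single, domain=domain)
        name = f"alignment_{lineage.replace('.', '_')}_{domain}.fasta"
        write_fasta(list(zip(aln.ids, aln.rows)), RESULTS / name)
        print(f"alignment: lineage {lineage} / {domain} domain, "
              f"{aln.n_rows} rows x {aln.n_cols} columns -> {name}")


if __name__ == "__main__":
    main()
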