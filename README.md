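# pncc — molecular classification of NMN deamidases

NMN deamidase (PncC, EC 3.5.1.42) converts nicotinamide mononucleotide to
nicotinic acid mononucleotide and ammonia, feeding the Preiss–Handler route
of bacterial NAD⁺ salvage. The family is fingerprinted by short conserved
sequence blocks: seven in the N-terminal MocF domain (M-I..M-VII), two in
the interdomain segment (i-I, i-II) and nine in the catalytic CinA/PncC
domain (P-I..P-IX). Which blocks a sequence carries, in which variant form,
and whether its active-site residues (S31, G46, S48, Y58, N60, K63, S/T105,
G106, G120, R145 in 2A9S numbering) are intact decides its domain
architecture, its predicted functionality, and its place among the named
phylogenetic lineages (1.1–1.3, 2.1, 2.2.x.y) of the family's two origins.

This package implements that classification scheme as a tested pipeline for
computational biologists working on NAD⁺ metabolism or protein-family
curation:

- `pncc.motif` — a degenerate pattern language for block consensus strings
  (`G[TD]E!xxxG!xxx[DN]TxN!`: strict `!` positions veto, majority positions
  score, `[..]` alternatives, `c`/`h`/`p` residue classes, `x` wildcards)
  and a scanner over protein sequences.
- `pncc.catalog` — the complete block inventory with per-lineage variants,
  key active-site residues, and the documented inactivating signatures
  (YdeJ-like Y58F+N60D, YfaY-like block deletion, fungal S→A in P-I).
- `pncc.conservation` — per-column information content
  R = log₂20 − H (the sequence-logo height basis), conserved-block
  detection on alignments, and consensus rendering in the block grammar.
- `pncc.classify` — architecture calling (CinA-only, MocF+CinA fusion,
  short/long N-extension, split CinA, MocF-only), the ten-residue
  functionality checklist, and the lineage decision table.
- `pncc.phylo` — affine-gap global/local alignment (BLOSUM62, gap open 11 /
  extend 1), p-distance and Poisson distances, Saitou–Nei neighbor joining
  and bootstrap supports.
- `pncc.kinetics` — Michaelis–Menten and Hill fitting for the coupled
  glutamate-dehydrogenase assay (ε₃₆₀ = 4320 M⁻¹cm⁻¹), rate/unit
  conversions, and ligand-efficiency arithmetic (LE1 = score / heavy atoms).
- `pncc.synth` — a generator of labeled synthetic panels per lineage with
  known-truth alignments and noisy kinetic datasets, so the whole pipeline
  is testable without downloads.

## Worked example

```python
from pncc import load_catalog, classify_sequences
from pncc.synth import GeneratorConfig, generate_lineage_sequences

catalog = load_catalog()
panel = generate_lineage_sequences(
    GeneratorConfig(lineage="2.2.2.2", n=3, seed=11, substitution_rate=0.0),
    catalog,
)
for rec in classify_sequences(panel.records, catalog):
    print(rec.sequence_id, rec.architecture.call.value,
          rec.functional_call.verdict, rec.functional_call.fired_signatures,
          rec.lineage)
```

prints

```
2.2.2.2|syn000 CINA_ONLY inactive ['YdeJ-like'] 2.2.2.2
2.2.2.2|syn001 CINA_ONLY inactive ['YdeJ-like'] 2.2.2.2
2.2.2.2|syn002 CINA_ONLY inactive ['YdeJ-like'] 2.2.2.2
```

— three simulated single-domain sequences carrying the documented
Y58F+N60D double mutation are called CinA-only in architecture, inactive by
the YdeJ-like signature, and assigned to lineage 2.2.2.2.

The `analysis/` scripts run the full study on synthetic data and write
their tables under `results/`: `01_simulate_panels.py` (labeled panels),
`02_detect_blocks.py` (reconstructs the 7 MocF and 9 CinA blocks from
alignments), `03_classify_panel.py` (13-lineage confusion matrix;
99–100% recovery at 5% substitution noise), `04_phylogeny.py` (NJ +
bootstrap separating two synthetic clades at 100% support) and
`05_kinetics.py` (refits Km = 0.18 mM, kcat = 0.38 s⁻¹, Hill nH = 2.6
from noisy synthetic assays; LE1(NMN) = −5.548).

A command-line interface mirrors these steps:

```bash
pncc simulate --lineage 1.3 -n 20 --seed 42 --out-prefix panel
pncc blocks panel.aln.fasta --domain mocf --out blocks.tsv
pncc classify panel.fasta --taxonomy hints.tsv --out-tsv report.tsv
pncc tree alignment.fasta --bootstrap 1000 --seed 1 --out tree.nwk
pncc kinetics-fit rates.tsv --model mm --e0 1.0 --out fit.json
```

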