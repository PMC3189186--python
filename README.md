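# pishift

Isoelectric-point (pI) divergence analysis for ortholog protein families.

`pishift` computes mature-protein pI values from sequence with a
Henderson–Hasselbalch charge model solved by bisection, flags ortholog
families whose pI has shifted unusually far between two species using the
non-parametric threshold `2 × (Q3 − median)` of the absolute pI
differences, estimates permutation significance of individual shifts,
tests whether positively selected alignment sites are enriched among
ionizable (charge-affecting) residues with a one-sided Fisher exact test,
and counts minimum acidic/neutral/basic state changes on a species tree
by exact small parsimony. A synthetic-data module generates every input
with known ground truth.

## Layout

| module | role |
|---|---|
| `pishift.seqio` | FASTA / aligned-FASTA / Clustal / TSV readers and writers, signal-peptide cleavage, gap-consistent alignable-region extraction |
| `pishift.isoelectric` | charge model, bisection pI solver, pKa tables, PTM charge groups |
| `pishift.shift_analysis` | pairwise pI differences, shift threshold, permutation p-values, discretization, parsimony counts |
| `pishift.selection_enrichment` | site charge classification, selected-site calls, Fisher/chi² enrichment |
| `pishift.synthetic_data` | random proteins, pI-targeted mutation, planted-outlier proteomes, planted-enrichment selection tables |
| `pishift.pipeline` / `pishift.cli` | end-to-end orchestration, config, `pishift` command |

## CLI

```sh
# per-protein pI table (TSV: id, species, family, length, pI, net_charge_at_pH7)
pishift pi --fasta proteins.fasta [--cleavage cleavage.tsv] [--ptm ptm.tsv] \
           [--pka pka.tsv] [--use-ptms] --out pi_table.tsv

# shift analysis for one species pair
pishift shift --pi-table pi_table.tsv --species-a human --species-b mouse \
              [--nperm 1000] [--seed 42] [--perm-mode protein|threshold] --out shift.tsv

# enrichment of selected sites among ionizable residues
pishift enrich --alignment aln.fasta --slr sites.tsv --ref-species human \
               [--alpha 0.05] [--test fisher|chi2] --out enrichment.json

# parsimony state-change counts on a species tree
pishift parsimony --tree tree.nwk --states states.tsv [--bounds 6.8,7.2]

# synthetic data with ground truth
pishift simulate proteome|selection|family --spec spec.txt --seed 42 --out-dir sim/

# full pipeline from a manifest (key = path) file
pishift run --manifest manifest.txt [--config config.txt] --out-dir out/
```

FASTA headers follow `family|species|id` (delimiter configurable). The
manifest keys are `fasta`, `cleavage`, `ptm`, `species_a`, `species_b`,
`alignment`, `alignment_format`, `selection_table`, `ref_species`,
`tree`. Config files are flat `key = value` text; see
`pishift.config.Config` for all keys and defaults.

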