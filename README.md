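# wrkyevo

Comparative genomics of WRKY transcription-factor family evolution within
a closely related plant genus (rice-like: ~10 species, 12 chromosomes,
~15 Myr of divergence).  The package implements the full analysis chain
used in genus-scale WRKY studies:

* **scan** — WRKY domain detection: heptapeptide variants (`WRKYGQK`,
  `WRKYGEK`, `WRKYGKK`, degenerate `WKKY/WRMC/WSKY/WVKY` cores), paired
  `C-x(4,5)-C … H-x-[HC]` zinc fingers, and a calibrated PSSM screen;
* **classify** — group assignment (Ia/Ib, IIa–IIe, III, IV) from
  zinc-finger type and subgroup literals, after representative-isoform
  selection;
* **homology** — reciprocal-best-hit orthology (exact Smith–Waterman,
  BLOSUM62), within-species paralog pairs, tandem vs segmental
  duplication calls, 0–1 scaled synteny positions;
* **reconcile** — NJ gene trees with bootstrap, weak-edge NNI
  rearrangement, and duplication–loss reconciliation under weighted
  parsimony (c_D = 1.5, c_L = 1.0);
* **arch_events** — domain-architecture event inference on the species
  tree (N/C-terminal domain loss, domain tandem duplication, two-gene
  fusion) via domain-affinity characters and Sankoff parsimony;
* **selection** — codon models M0, M1a/M2a, M7/M8 and the two-ratio
  branch model (GY94 rates, Felsenstein pruning), LRTs, NG86 dN/dS, and
  per-site empirical-Bayes identification of positively selected sites;
* **simulate** — a synthetic-genome generator (birth–death gene families
  on a dated species tree, group-specific domain templates, injected
  architecture events, GY94 sequence evolution, GFF3 annotation) with a
  complete ground-truth log, so every stage above is testable without
  any downloads.

## Worked example

```bash
wrkyevo pipeline --config config.yml --outdir run1 --seed 7
```

with `config.yml`:

```yaml
simulate:
  n_families: 14
reference_species: osaj
n_bootstrap: 50
max_selection_groups: 2
```

The run directory then contains the simulated genome
(`proteins.faa`, `cds.fna`, `annotation.gff3`, `truth.json`) and one
table per stage.  On the run above, the log reports

```
simulate: 14 families, 156 genes, 165 events
scan: 156 proteins with calls, 222 domains
classify: 156 WRKY genes
homology: 131 orthologs, 33 paralog pairs
reconcile: 12 families, 29 duplication nodes
events: 5 architecture event calls
selection: 2 single-copy groups fitted, 2 branch tests
```

meaning: 156 genes were detected and classified into groups
(`group_counts.tsv` is the per-species × per-group census with genes/Mb
densities), 33 within-species paralog pairs were split into tandem and
segmental modes (`paralogs.tsv`), 29 gene-duplication nodes were mapped
onto species-tree branches (`duplication_screen.tsv`), 7 architecture
events were called with their branch placements and ambiguity flags
(`arch_events.tsv`, here 5 calls), and two single-copy ortholog groups received the
full M0/M1a/M2a/M7/M8 treatment (`selection_fits.tsv`, `lrt.tsv`,
`gene_calls.tsv` with the positive/conserved verdicts, e.g.
`osaj__f02n8  conserved  p_m1a_m2a=1  p_m7_m8=1` under the default
purifying simulation profile).  Each stage is also available as its own
subcommand (`simulate`, `scan`, `classify`, `homology`, `reconcile`,
`events`, `selection`) over the same run directory.

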