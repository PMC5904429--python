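# barcodelim

Molecular species delimitation from DNA barcodes: uncorrected pairwise
p-distances with per-species intra/interspecific summaries, a bootstrapped
neighbor-joining (NJ) tree, and character-based delimitation via *pure*
diagnostic nucleotide sites.

## The problem

Integrative taxonomy of small insect groups routinely pairs morphology with a
COI barcode analysis: a few dozen specimens, a handful of putative species,
one ~650-bp mitochondrial alignment. Three questions are asked of the
molecular data:

1. **Distances.** Are conspecific sequences much closer to each other than to
   anything else? For each species *S* the pipeline summarises the p-distance
   — the proportion of differing nucleotide sites,
   `p = n_mismatch / n_compared` with *pairwise deletion* of columns where
   either sequence is missing — over all conspecific pairs (intraspecific) and
   all pairs against other ingroup specimens (interspecific), as
   min / max / mean ± SD. The *barcode gap* for *S* is
   `inter_min − intra_max`; a positive gap supports the species limit.
2. **Tree.** Does each putative species form a clade? The pipeline builds the
   Saitou–Nei NJ tree from the p-distance matrix and attaches nonparametric
   bootstrap percentages (column resampling; a clade's support is the
   percentage of replicate trees containing its bipartition), with optional
   outgroup rooting.
3. **Characters.** Which sites diagnose each species? A *pure* diagnostic
   character for *S* is a column where every non-missing specimen of *S*
   carries one fixed state that occurs in no other species — a
   character-based species boundary independent of any distance threshold.

A synthetic-data generator plants known species structure (ancestral
divergence, per-species fixed diagnostic columns, Poisson intraspecific
polymorphism, terminal missing-data runs) so the whole pipeline is testable
end-to-end with no downloads.

## Worked example

Simulate a study-sized dataset (9 species, 35 specimens, 662 sites) and run
every stage:

```bash
barcodelim simulate --seed 1 --out sim
# 35 sequences x 662 sites -> sim/alignment.fasta
barcodelim all --alignment sim/alignment.fasta --metadata sim/metadata.tsv \
    --bootstrap 500 --seed 1 --out run
```

The exit summary lists one delimitation verdict per species:

```
   species monophyletic  clade_support  n_pure_diagnostics  has_diagnostic  barcode_gap_positive
species_01          yes            100                  13            True                  True
species_02          yes            100                  18            True                  True
...
species_09          yes            100                  13            True                  True
```

Every planted species is recovered as a clade with bootstrap 100, carries at
least 12 pure diagnostic sites, and shows a positive barcode gap. The run
directory holds the full reports — `species_summary.tsv` is the per-species
distance table (proportions, 4 decimals, `NA` where undefined, e.g. the SD of
a single conspecific pair):

```
species     N  intra_min  intra_max  intra_mean  intra_sd  inter_min  inter_max  inter_mean  inter_sd
species_01  7  0.0015     0.0091     0.0048      0.0021    0.0468     0.1097     0.0874      0.0166
species_02  3  0.0065     0.0068     0.0067      0.0001    0.0485     0.1147     0.0883      0.0193
```

so intraspecific distances sit under 1%, interspecific ones at 5–11%.
`tree.nwk` is the NJ tree with bootstrap labels (values below
`--min-display-support`, default 50, are left off the rendered labels only),
`diagnostics.tsv` the (species, position, state) diagnostic list, and
`diagnostic_grid.tsv`/`diagnostic_mask.tsv` the specimen-by-position state
grid with its shading mask. Subcommands `distances`, `tree`, `diagnose` and
`simulate` run the stages independently.

To analyse your own data, supply an aligned FASTA plus a tab-separated
metadata table with columns `specimen_id`, `species` and optionally `sex`,
`accession`, `locality`; the FASTA id (up to the first whitespace) is the
join key. Repeat `--outgroup LABEL` to name outgroup species: they root the
tree and are excluded from distance summaries and the diagnostic scan.

`scripts/fetch_genbank.py` (network required) downloads the 39 published COI
accessions of the *Scaptodrosophila coracina* group study this pipeline
mirrors, aligns them with MAFFT and writes them into `data/real/` in the
accepted input dialect.

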