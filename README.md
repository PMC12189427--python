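# recland

Broad-scale recombination landscapes from cytological crossover maps.

`recland` converts per-cell MLH1-focus observations along synaptonemal-complex
(SC) axes into cM/Mb recombination tracks on fixed-size genomic interval grids
(2.5 Mb by default), computes GC content, CpG-island counts and gene density on
the same grids, and quantifies their association with recombination rate by
Spearman rank correlation — per chromosome and pooled, with an optional
zero-recombination exclusion mode for strongly polarised landscapes. A
simulator generates genomes, annotations and focus datasets with planted,
recoverable structure so the full pipeline is testable without any downloads.

## Layout

| module | purpose |
| --- | --- |
| `recland.coordinates` | interval grids; SC-axis fraction ⇄ bp ⇄ interval index; orientation inversion; homology/arm masks |
| `recland.recmap` | focus tables; binning; `cM_i = 50·f_i/N`; cM/Mb rates; track summaries |
| `recland.features` | GC content, observed/expected CpG, CpG-island calling (length > 200 bp, GC ≥ 0.5, obs/exp ≥ 0.6), per-interval feature tracks |
| `recland.association` | Spearman correlations (exact permutation p for n ≤ 10), zero-interval exclusion, pooled scopes, significance matrix |
| `recland.synthetic_data` | genome + focus simulators (homogeneous-terminal vs polarized regimes), end-to-end recovery reports |
| `recland.io` / `recland.cli` | FASTA/GFF3/BED/TSV/YAML readers & writers, `recland` command-line interface |

## CLI

```bash
# simulate a small dataset and run the whole analysis
recland all --out-dir run1 --n-chromosomes 3 --chrom-length 10000000 \
    --interval-size 2500000 --n-cells 130 --co-mean 2 \
    --coupling-rho 0.8 --couple-foci --seed 1

# or stage by stage
recland simulate  --out-dir run1 ...
recland recmap    --foci run1/foci.tsv --chrom-config run1/chromosomes.yaml --out run1/recmap.tsv
recland features  --fasta run1/genome.fa --annotation run1/genes.gff3 \
                  --chrom-config run1/chromosomes.yaml \
                  --out-track run1/features.tsv --out-cgi-bed run1/cgi.bed
recland correlate --rec-track run1/recmap.tsv --feat-track run1/features.tsv \
                  --mode nonzero_only --pooled chr1,chr2,chr3 --out run1/associations.tsv
```

The focus-table dialect is a TSV with columns
`cell_id  chromosome  sc_length_um  position  position_unit`
(one row per focus; `position_unit` is `fraction` or `um`) plus
`# n_cells <chrom> <N>` header comments recording the number of SCs scored,
which includes cells without any focus on that chromosome.

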