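# polybinmap

Ultra-dense recombination bin maps for low-coverage allopolyploid F2
populations.

The pipeline takes per-site allele-count tables (pileup-derived TSV) for two
inbred parents and a low-coverage F2 population and produces, stage by stage:

1. **SNP discovery** — parental site calls (depth ≥ 10, ≥ 3 reads and ≥ 20 %
   per reported allele) and classification of interspecific SNPs into
   *simple* / *hemi* / *complex*; only simple SNPs are mapped.
2. **Two-step genotyping** — initial per-site calls (depth ≥ 4, ≥ 1 read per
   allele), similarity-score block partitioning within scaffolds (threshold
   0.7), and sliding-window Bayesian imputation: reads are pooled over
   consecutive same-block sites to ≥ 40, and the genotype is the maximum
   posterior under binomial likelihoods with per-parent error rates
   E1 = 0.058 / E2 = 0.02 and F2 priors 0.25 : 0.25 : 0.5.
3. **Linkage mapping** — recombination bins (identical complete genotype
   vectors), pairwise recombination fractions by EM with LOD scores,
   grouping (r < 0.4, LOD ≥ 6), ordering (classical-MDS seriation + 2-opt)
   and Kosambi map distances.
4. **Scaffold correction & anchoring** — 201-bp SNP segments, mis-assembly
   breakpoints between stable runs of ≥ 10 same-bin segments
   (homoeologous / interchromosomal / intrachromosomal), chimera splitting,
   and AGP pseudomolecule layout.
5. **Landscape** — cM/Mb recombination profiles (suppression < 1.0 cM/Mb),
   50-kb SNP-density scans with SNP-poor region calls (≥ 20 contiguous low
   windows), and centromere localization from repeat-homology hits filtered
   at ≥ 80 % identity / e-value ≤ 1e-20 (order-statistic 95 % CI of the
   median hit position).
6. **Comparative** — synteny-block chaining against a reference genome and
   reciprocal-translocation / simple-translocation / inversion calls.

A fully synthetic F2 generator (`polybinmap.simulate`) produces parental
genomes, meiosis, read counts with the same error structure, injected
chimeric scaffolds and centromere-clustered homology hits, with complete
ground truth — it backs the entire test suite.

## CLI

One subcommand per stage, driven by a single YAML config
(`PipelineConfig.to_yaml` writes a template; `--seed` overrides the config
seed):

```sh
polybinmap simulate  --config cfg.yaml --out sim/
polybinmap discover  --parent1 sim/parent1.counts.tsv --parent2 sim/parent2.counts.tsv --out disc/
polybinmap genotype  --snps disc/snps.tsv --counts-dir sim/counts --out geno/
polybinmap map       --imputed geno/unambiguous.tsv --out map/
polybinmap anchor    --imputed geno/unambiguous.tsv --site-bins map/site_bins.tsv \
                     --map-file map/map.txt --lengths sim/scaffold_lengths.tsv --out anchor/
polybinmap landscape --anchored-bins anchor/anchored_bins.tsv --snps disc/snps.tsv \
                     --lengths sim/scaffold_lengths.tsv --out landscape/
polybinmap centromere --hits sim/hits.tsv --out centromere/
polybinmap compare   --anchors anchors.tsv --home home.tsv --out compare/
```

`genotype` writes three matrices: `initial.tsv` (per-site calls),
`imputed.tsv` (windowed calls) and `unambiguous.tsv` (windowed calls with
low-confidence entries masked) — the last is the input for `map`.

Coordinate conventions: internal coordinates are 0-based half-open; BED
outputs are 0-based half-open, all other tabular files 1-based inclusive,
and every file states its dialect in a header comment.

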