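# repdiv

TCR-β repertoire characterization toolkit: clonotype-table I/O, UMI-depth
rarefaction, diversity and clonality indices, V/D/J usage, repertoire
overlap, CDR3 amino-acid composition and self-reactivity indices,
spectratype statistics, cohort comparison machinery, and a synthetic V(D)J
repertoire simulator with known ground truth.

## What it computes

- **I/O** (`repdiv.io_clonotypes`): AIRR Rearrangement TSV and MiXCR-style
  clone tables; gene-name normalization (`TRBV12.2*01` → `TRBV12-2`);
  productive-only filtering; merge-by-clonotype-key with exact round-trip.
- **Rarefaction** (`repdiv.subsample`): without-replacement (multivariate
  hypergeometric) subsampling to fixed UMI depths (default 4,000–12,000),
  replicate evaluation of any named index.
- **Diversity** (`repdiv.diversity`): richness, Shannon–Wiener (nats),
  Simpson (both D and 1−D reported), D50 (percent of unique clonotypes),
  Chao1 (classic, bias-corrected when f2 = 0), Top100, Hill-number curves
  `qD` over q ∈ [0, 8], rank-abundance and cumulative-frequency curves.
- **Segments** (`repdiv.segments`): V/D/J usage on total (count-weighted)
  and unique (clonotype-weighted) sequences; V–J and V–D–J combination
  matrices with exact marginals; per-gene two-group tests (t, Wilcoxon
  rank-sum, chi-squared) with BH/Bonferroni correction.
- **Overlap** (`repdiv.overlap`): overlap coefficient
  `|X∩Y|/min(|X|,|Y|)` on nucleotide species (configurable key mode), plus
  VDJTOOLS-style F2 (geometric-mean frequency sum), R (Pearson of log10
  shared frequencies) and D (normalized shared-clonotype count), and
  1−overlap distance matrices.
- **AA features** (`repdiv.aa_features`): 20-residue composition,
  Bhattacharyya distance, positional composition, hydrophobic-doublet index
  at CDR3 positions 6–7 (length class 13 by default), cysteine index near
  the CDR3 apex.
- **Spectratype** (`repdiv.spectratype`): nucleotide-length histograms,
  thresholded complexity score, frequency-weighted skewness.
- **Stats** (`repdiv.stats_compare`): feature-matrix assembly
  (Shannon, Simpson, total/unique sequence counts by default), z-scored PCA
  with deterministic sign convention, two-group tests, Dunnett many-to-one.
- **Simulator** (`repdiv.simulate`): stub-based junction assembly
  (per-segment cores + geometric trims + biased N-insertions), productive
  filtering, configurable clone-size laws (uniform / geometric / power-law /
  log-normal), multinomial UMI sampling, deterministic per-sample seeds,
  cohort generation with usage / expansion group effects and ground-truth
  bookkeeping.

## CLI

```sh
repdiv simulate --seed 1 --n-clonotypes 200 --depth 12000 --out sim.tsv
repdiv subsample --depth 4000 --seed 17 in.tsv out.tsv
repdiv diversity --indices shannon,simpson_diversity,d50,chao1,top100 in.tsv
repdiv segments --axis V --weighting total in1.tsv in2.tsv
repdiv overlap --key-mode nt in1.tsv in2.tsv
repdiv aafeatures in.tsv
repdiv spectratype in.tsv
repdiv compare --feature shannon --group-a a1.tsv --group-a a2.tsv \
               --group-b b1.tsv --group-b b2.tsv
repdiv run --config pipeline.yaml --out outdir/
```

`repdiv run` takes a YAML config with either a sample sheet
(`samples: sheet.tsv` with columns `sample_id  file  group  subset`) or a
`simulate:` block, plus optional `rarefaction:` and `compare:` sections; it
emits tidy TSV tables and a `manifest.json` recording every setting in
effect. Reruns with the same seed are byte-identical.

```yaml
seed: 7
simulate:
  n_samples_per_group: 4
  n_clonotypes: 200
  depth: 12000
  groups:
    WT: {}
    KO: {clone_size_law: powerlaw}
rarefaction:
  depths: [4000, 6000, 8000, 10000, 12000]
  replicates: 10
  indices: [shannon, simpson_diversity, d50]
```

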