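# methylseg

Context-aware segmentation of plant whole-genome bisulfite sequencing
(WGBS) methylomes and population-scale calling of differentially
methylated regions (DMRs).

## Who this is for

Plant epigenomics groups with per-cytosine methylation tables (bismark
coverage files, MethylDackel bedGraphs, or a generic counts TSV) for two
to hundreds of samples, who want context-specific DMRs — CG, CHG and CHH
— without committing to sample groupings in advance. Plant methylomes
violate the assumptions of mammalian DMR callers: methylation occurs in
three sequence contexts with very different rate distributions (CG
near-binary, CHG around 50%, CHH around 30% among methylated sites), and
most of the genome carries no methylation at all. `methylseg` learns
those distributions from the data instead of assuming them.

## Method

The pipeline has four stages.

1. **Methylomes.** Each sample's table is parsed into per-cytosine counts
   (k methylated of n total reads) with CG/CHG/CHH context from the table
   itself or from a reference FASTA.

2. **Segmentation.** A two-state hidden Markov model classifies the
   genome into LOW and HIGH methylation states. Each covered cytosine is
   an observation scored by a beta-binomial emission
   P(k | n, α, β) = C(n,k)·B(k+α, n−k+β)/B(α,β),
   with a separate (α, β) pair per state and per sequence context —
   six pairs in all, sharing one state path. The beta layer captures
   the variability of the underlying methylation level across sites and
   cells; the binomial layer captures read sampling. Parameters are
   trained per sample (or on one reference sample) by Baum–Welch EM;
   posterior decoding yields each sample's methylated regions (MRs).

3. **Candidates.** All samples' MRs are projected onto the genome; an
   interval sweep gives the MR frequency at every base. Breakpoints where
   the frequency changes by at least `min_freq_change` of the cohort are
   retained, and stretches between retained breakpoints covered by at
   least one MR become candidate regions — a minimum epiallele-frequency
   filter that confines statistics to loci where methylation states
   actually differ across the population.

4. **Testing.** Per candidate and context, each sample is summarised by
   its pooled rate Σk/Σn. An iterative k-means scan (k = 2..k_max)
   groups the samples; the smallest k whose cluster means are all
   separated by `min_meth_diff` is accepted. Groups are compared with a
   beta-binomial likelihood-ratio test (one shared fit vs independent
   per-cluster fits; χ² reference with 2(k−1) df), corrected by
   Benjamini–Hochberg across all tests performed. A region is a DMR in a
   context only if it passes both the FDR level and the minimum
   methylation difference. Shared group labels in the sample sheet switch
   testing to supervised mode.

## Worked example

Generate a ground-truthed synthetic cohort (6 samples in two groups of
three, 4 planted DMRs) and run the pipeline end to end:

```bash
methylseg simulate --preset two_group --n-dmrs 4 --n-samples 6 --seed 3 --outdir demo/data
methylseg run --samplesheet demo/data/samplesheet.tsv --seed 3 --outdir demo/run
```

which prints

```
wrote 6 samples to demo/data
pipeline complete; DMRs in demo/run/dmrs.bed
```

`demo/run/dmrs.bed` then contains one row per called DMR, e.g.

```
#chrom	start	end	context	k	assignment	cluster_means	max_diff	lr_stat	p_value	q_value	significant
Chr1	8409	9000	CHH	2	2,2,2,1,1,1	0.105703,0.807335	0.701632	30.5102	2.370281e-07	7.110844e-07	1
```

reading: the region Chr1:8409–9000 is a CHH-context DMR; k-means split
the six samples into two clusters (samples 1–3 vs 4–6, the planted
groups) with mean methylation 0.81 vs 0.11 — a 0.70 difference matching
the planted effect — and the likelihood-ratio statistic 30.5 gives
q ≈ 7e-7. `demo/run/matrix.tsv` holds the DMR × sample methylation-rate
matrix for downstream heatmaps/PCA, `demo/run/mrs/` the per-sample MR
BED files, and `demo/run/models/` the trained HMM parameters as
inspectable text.

The same stages are available as library calls
(`methylseg.simulate_methylomes`, `baum_welch`, `decode_regions`,
`mr_frequency_profile`, `segment_candidates`, `test_candidates`) and as
separate subcommands (`segment`, `candidates`, `test`, `validate`).

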