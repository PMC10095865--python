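# Methods

This note documents the models, the tunable parameters, the synthetic
data the test suite relies on, and the numerical and design choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The segmentation model

The genome of one sample is modelled as a two-state Markov chain over
covered cytosines: LOW (unmethylated background) and HIGH (methylated
region). The observation at a cytosine is its read pair (k, n) — k
methylated calls out of n reads — and is scored by a beta-binomial

P(k | n, α, β) = C(n,k) · B(k+α, n−k+β) / B(α, β),

evaluated in log-gamma space. The beta-binomial arises by integrating a
Beta(α, β)-distributed latent methylation level against binomial read
sampling; it is the natural model for plant methylomes where, away from
the near-binary CG context, per-site levels vary continuously. Each of
the six (state, context) combinations keeps its own (α, β), while the
state path is shared across contexts: a methylated region is one genomic
phenomenon observed through three context-specific lenses. This is the
design that lets CHH sites with rates near 0.3 support the same HIGH
state that near-1.0 CG sites support.

Assumptions and their limits:

- Transitions are homogeneous in site index, not in genomic distance.
  To keep the model from bridging unsequenced or cytosine-free gaps,
  runs of covered sites separated by more than `desert_distance`
  (default 2,000 bp) are decoded as independent chains with the model's
  initial distribution. A distance-dependent transition kernel would be
  the finer alternative; it is out of scope here.
- Both strands are interleaved into one positional sequence. Optional
  CG destranding (pooling symmetric pairs) is not applied by default.
- Two states only. Intermediate methylation (e.g. gene-body CG
  gradients) is absorbed by the emission dispersion, not by extra
  states.

## Training

Baum–Welch EM with scaled forward–backward recursions (numba-compiled;
per-position scaling, so chains of millions of sites do not underflow).
The M-step for initial and transition probabilities uses the standard
expected-count ratios. Emission shapes have no closed-form update; each
(state, context) pair maximises the expected complete-data
log-likelihood by L-BFGS-B on (log α, log β), warm-started at the
current values (so the EM ascent property is preserved exactly: the
optimiser result is only accepted if it improves the expected objective)
and additionally started from a method-of-moments estimate on
posterior-weighted rates. Observations are grouped by unique
(context, k, n) so the emission update costs O(unique pairs), not
O(sites).

Numerical choices:

- Shape bounds: α, β ∈ [1e-6, 1e6]. The lower bound is the
  overdispersion floor at which the distribution is effectively
  degenerate; the upper bound is the binomial limit.
- Initialisation (fixed, so training is deterministic without random
  restarts): LOW at mean 0.02 / dispersion 0.1, HIGH at mean 0.8 /
  dispersion 0.2 for every context; self-transitions 0.99 (LOW) and
  0.95 (HIGH); initial distribution = the stationary distribution of
  that transition matrix.
- Convergence: relative log-likelihood improvement below `tol = 1e-4`,
  or `max_iter = 100`.
- Contexts with fewer than 100 covered sites keep their initial
  emissions (with a warning): there is not enough data to learn a rate
  distribution, and a wild fit would corrupt the shared state path.
- States are relabelled after training if EM swapped them, so HIGH
  always carries the larger (data-weighted) emission mean. All-zero
  data is flagged `no high state support` rather than failing.

## Decoding

Per-site posterior decoding by default: maximal runs of consecutive
sites with P(HIGH) ≥ `posterior_cutoff` (default 0.5) become methylated
regions (MRs); runs with fewer than `min_sites` (default 5) covered
cytosines are discarded. MR boundaries span the first to last member
site (0-based, half-open). Posterior decoding is preferred over Viterbi
because the per-site posterior is itself a useful MR attribute (the
reported mean posterior); Viterbi is available behind a flag.

## Candidate regions

MRs from all samples enter an interval sweep (+1 at starts, −1 at
ends); the running sum is the MR frequency profile, identical to
per-base counting. A breakpoint is retained where the frequency steps by
at least ⌈`min_freq_change` · n_samples⌉; a stretch between adjacent
retained breakpoints whose frequency stays ≥ 1 becomes a candidate.
Candidates longer than `max_segment_length` (default 10 kb) are split
recursively at their largest internal non-retained step (ties leftmost);
candidates with fewer than `min_sites_per_segment` (default 10) covered
cytosines are dropped.

`min_freq_change` (default 0.20) is a minor-epiallele-frequency floor:
a variant carried by fewer than 20% of samples never produces a retained
breakpoint pair and is discarded before testing. Together with
`min_meth_diff` it is one of the two parameters that dominate the number
of called DMRs; both should be set by the biological question, not
treated as fixed truths. A consequence worth knowing: in very small
cohorts a methylation variant carried by k samples is only visible if at
least ⌈0.2·n⌉ of their decoded boundaries coincide at a base; with n < 10
a single staggered boundary can hide a real variant. This is the filter
working as specified, and the reason the recovery experiments below run
at population scale (10 samples).

Samples without an MR in a candidate still contribute counts to testing
— their low methylation is half of the signal; only MR carriers are
recorded as supporting samples.

## Testing

The observational unit is one (Σk, Σn) per sample per region per
context — pooled counts, not per-read or per-site values — so the test
models between-sample biological variance instead of read-level
pseudo-replication. Samples with pooled coverage below
`min_cov_per_sample` (default 3) are ineligible for that region/context.

Grouping: one-dimensional k-means for k = 2..`k_max` (default 3), best
of `n_init = 10` runs started from quantile centroids plus seeded
jitter; the chosen k is the smallest whose sorted cluster means are all
separated by `min_meth_diff` (default 0.20). No qualifying k leaves the
region untested in that context. Sample-sheet group labels switch to
supervised grouping with identical downstream testing.

Test: likelihood-ratio of independent per-cluster beta-binomial fits
against one pooled fit, referred to χ² with 2(k−1) degrees of freedom
(two free shapes per extra cluster), clipped at zero. Benjamini–
Hochberg correction runs across all (region, context) tests actually
performed; untestable combinations do not enter the family. The final
DMR call is dual: q ≤ `fdr_level` (default 0.05) AND maximum pairwise
cluster-mean difference ≥ `min_meth_diff`. A `bonferroni` correction
mode and the `bonferroni_threshold(m, level)` utility are provided for
family-wise workflows (e.g. downstream association scans).

### Calibration of the unsupervised test

With a fixed, data-independent grouping the χ² reference is close to
calibrated (the unit suite asserts rejection near the nominal level on
beta-binomial nulls). The full unsupervised path is a different matter:
k-means chooses the most separated partition of the very data that is
then tested, so conditional on a region passing the `min_meth_diff`
gate, p-values are strongly anti-conservative — a structural
double-dipping effect, not an implementation defect. One acceptance-
level test measures this honestly on 2,000 null regions (mean 0.7,
between-sample intraclass correlation 0.05, region coverage ~50) and is
expected to fail its nominal band; the number it computes is also
reported by `scripts/acceptance.py` as
`unsupervised_null_rejection_rate`. Practical false-positive control in
the pipeline does not rest on those p-values alone but on the
conjunction of candidate pre-selection (nulls that reach testing are
regions where samples share methylation), the effect-size floor, and
FDR correction — the matched-null end-to-end experiment (below) calls
zero DMRs. Users who need calibrated p-values should use supervised
grouping or split samples for grouping and testing.

## Synthetic data

The generator mirrors the segmentation model so every stage can be
scored against known truth. Cytosine positions are placed by
per-context densities and shared across samples, as positions are in a
real reference; defaults CG 0.04, CHG 0.04, CHH 0.10 per bp approximate
A. thaliana base composition counting both strands. Sites inside
configured MR blocks are latently HIGH, elsewhere LOW; per-site levels
are drawn from the state/context beta distribution (HIGH means CG 0.85,
CHG 0.50, CHH 0.30 — echoing the plant context hierarchy — with
dispersion 0.2; LOW means 0.02–0.03); coverage is Poisson (default mean
10) and counts binomial. Planted DMRs replace the beta mean inside the
interval for the affected group, keeping dispersion fixed.

What the generator does not emulate — and what passing tests therefore
do not show about real data:

- Coverage has no positional autocorrelation and no mappability holes.
- Planted context-specific DMRs are context-pure: the interval carries
  only the target context's cytosines, so a single-context differential
  signal is decodable as a methylation state. Real context-specific
  DMRs sit in mixed-context sequence, where a difference confined to
  one sparse context can be diluted by the shared state path.
- No bisulfite conversion failure, mapping bias, or strand asymmetry;
  an optional conversion-failure pre-correction hook exists but default
  pipelines apply none.
- Between-sample variance within a state arises only from independent
  per-site beta draws; there are no sample-level random effects outside
  planted DMRs.

Presets: `arabidopsis_like` places ~20% of a 300 kb toy genome in
methylated blocks, `rice_like` ~33%, reproducing the sparse-vs-dense
genome contrast the segmenter must handle.

## Problem sizes in the test and acceptance runs

Chosen as the package's own benchmark sizes: EM parameter recovery uses
one 50k-site chain from a known model (emission means within 0.05,
self-transitions within 0.02); segmentation recovery uses the
`arabidopsis_like` preset (~54k sites/sample, base-level F1 ≥ 0.90);
the end-to-end experiment plants 100 two-group DMRs (effect 0.7,
coverage 10x, 10 samples) plus a matched no-effect dataset; the null
calibration study uses 2,000 regions. The pipeline itself streams
per-chromosome and has been run on inputs two orders of magnitude
larger.

## Known limitations

- Homogeneous transitions make MR boundary precision density-dependent:
  boundaries land on covered cytosines, so sparse stretches blur edges.
- The k-selection rule ("smallest k with all adjacent gaps above the
  floor") cannot discover more clusters than `k_max` and treats the
  floor as a hard constraint; gradual clines collapse to k = 1.
- Unsupervised p-values after grouping are anti-conservative (see
  calibration section).
- No DMP (single-cytosine) calling; no GWAS stage beyond the Bonferroni
  threshold utility; no BAM processing — the pipeline starts from
  per-cytosine tables produced by standard extractors.
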