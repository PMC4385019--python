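# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions for degenerate inputs.

## Probe design

Gene probes are 60-mers tiled backward from the 3′-most base of the
transcript (up to `k = 2` non-overlapping probes), because hybridization
targets are oligo-dT-primed cDNAs that may be 3′-biased. A gene shorter
than 60 bp yields no probes (logged); between 60 and 119 bp, one probe.
LTR-retrotransposons are tiled across their whole length at one probe per
500-bp window, each probe the central 60-mer of its window, the last
clipped to stay inside the element — ⌈len/500⌉ probes in total.

**Locus specificity.** A hybrid with up to three mismatches is treated as
stable, so a probe is locus specific iff exactly one ungapped 60-bp window
in the genome (both strands; the design locus counts as that one window,
and overlapping self-windows at nonzero offset count separately) lies
within Hamming distance 3. The search uses pigeonhole seeding: the probe's
four disjoint 15-mers are looked up exactly in a genome k-mer index; any
window within 3 mismatches must share at least one seed, so seed lookup
plus direct Hamming verification is exact. GC% and a Wallace-rule Tm
(2(A+T) + 4(G+C) °C) are reported per probe; no hard GC/Tm filter is
applied by default because no threshold is defensible a priori — optional
bounds exist in `filter_probes`.

## Array processing

Stages run in the order *spatial correction → quantile normalization →
summarization → testing*.

* **Spatial correction.** Per sample, the local background at each probe is
  the Gaussian-distance-weighted median of log2 intensities within 3
  bandwidths (KD-tree neighborhood); the deviation of this local background
  from the array-wide median is subtracted from the probe's log2 value.
  Default bandwidth: 10% of the grid diagonal — small enough to track a
  smooth wash gradient, large enough that the weighted median (a robust
  estimator) is not dominated by single probes. A spatially uniform array
  passes through unchanged; a single-probe array is returned as is.
* **Quantile normalization.** Every sample column is mapped onto the mean
  of the sorted columns; ties receive the mean of the reference values
  their ranks span, which makes the transform invariant to row order. Its
  assumption — all samples share one intensity distribution — is only
  approximately true when few features are DE; see *Limitations*.
* **Summarization.** Per feature and sample, the mean of its probes' log2
  intensities, optionally restricted to locus-specific probes (features
  left with none are excluded and logged). TE results are reported at locus
  level and rolled up to families: a family is DE when ≥ 1 member locus is
  DE. A value-level family mean (`summarize_families`) is also available.
* **Testing.** Per feature, a one-way two-group ANOVA F-test on the 3 + 3
  log2 replicate values (identical to the two-sided equal-variance t-test),
  with log2FC = mean(iron) − mean(control). Zero within-group variance with
  equal means is reported as F = 0, p = 1 (no evidence of an effect); with
  unequal means as F = ∞, p = 0. Raw p-values are Benjamini–Hochberg
  adjusted (step-up, adj₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j clipped at 1). Calls use
  inclusive boundaries: up iff log2FC ≥ 1 and p_adj ≤ 0.05; down iff
  log2FC ≤ −1 and p_adj ≤ 0.05.
* **Reporting.** The share of DE features that are up-regulated is rounded
  to one decimal; the share of all TE loci that are DE to the nearest
  integer; both are `None` when the denominator is zero.

## CRE occurrence statistics

Motifs are IUPAC degenerate consensi. `scan_motif` counts every window
matching the consensus on the forward strand plus every window matching the
reverse-complement consensus (equivalently, the reverse strand), overlaps
allowed, positions reported 1-based on the forward strand. An `N` in the
*sequence* matches only an `N` motif symbol; an `N` in the *motif* matches
any base.

Significance uses a zero-order background model with per-window match
probability q = ∏ⱼ Σ_{b∈allowedⱼ} f_b. The trial count is
n = 2(L − w + 1) over both strands, **except** for motifs whose IUPAC
pattern equals its own reverse complement (RY, TATA, …): for those the two
strand scans match identical windows, so the raw count is exactly doubled
and the model collapses to n = L − w + 1 trials with the halved count.
Two significance levels are computed because they answer different
questions:

* **per sequence** — exact upper-tail binomial P(X ≥ c | n, q); a CRE "has
  a significant occurrence" in a promoter/LTR when p ≤ 0.05. This drives
  the per-gene distinct-CRE counts, the complexity classification, and the
  ABA-CRE summary. A count of 0 gives p = 1; q = 0 with a positive count is
  an error; q = 1 (motif all-N) gives p = 1.
* **per sequence set** — pooled trials N = Σᵢ nᵢ, expectation E = Nq,
  Z = (obs − E)/√(Nq(1−q)), p from the standard normal upper tail. sd = 0
  flags the record as undefined. A frequency-preserving shuffle null
  (`shuffle_null`) is provided as an empirical cross-check of the analytic
  moments and tail.

The default background is estimated from the analyzed sequence set itself
(`background="set"`); uniform or explicit frequencies are options. The
binomial model ignores overlap dependence between windows, which makes it
slightly conservative-to-neutral for non-periodic motifs; calibration on
null sequences stays at or below a 6% per-sequence rate at α = 0.05. The
0.05 cutoff is applied per motif without multiple-testing adjustment across
the catalog, matching common CRE-screening practice; BH can be applied to
the set-level p column by the caller if desired.

**Complexity classification.** For up-regulated genes, c_g = number of
distinct CREs with a significant per-sequence occurrence in the 1-kb
upstream region; μ and σ (population SD) are computed over all such genes;
complex ⟺ c_g ≥ μ + 2σ, simple ⟺ c_g ≤ μ − 2σ, otherwise normal. σ = 0
labels everything normal with a warning. The CRE identity sets of the three
groups are partitioned into the 7 exclusive Venn regions.

**LTR distribution test.** For one CRE, a 2×2 chi-square (significant
occurrence vs not × up-regulated vs not, no continuity correction) over the
LTR population; any expected cell < 1 triggers a logged fallback to
Fisher's exact test. In scaled-down synthetic runs with few up-regulated
loci the fallback is the common path.

**Bundled catalog.** `ferrex/data/cre_catalog.tsv` is a small toy catalog
of plant-CRE-style IUPAC motifs (ABA-responsive ABRE variants flagged in
the annotation column, plus TATA/GATA/GT1/W-box/RY-type elements) intended
for tests and demonstrations, not as a substitute for a curated database.

## qPCR validation

ΔCt = mean(Ct_target − Ct_reference) within each condition (replicates
averaged before differencing, per-replicate RQ available as an option);
ΔΔCt = ΔCt_iron − ΔCt_control; RQ = 2^(−ΔΔCt), so log2 RQ = −ΔΔCt.
Amplification efficiency is fixed at 2 per cycle (the Livak assumption);
no efficiency correction is applied. Validation is the Pearson correlation
between array log2FC and qPCR log2 RQ with the two-sided t-based p-value;
incomplete pairs are dropped and logged; zero variance in either vector is
an error. The same one-way ANOVA F-test used for expression serves the
replicate-level micronutrient comparisons.

## Synthetic-data generator

The generator emulates the modeled study design: two conditions × three
biological replicates, 1000-bp promoters, LTR-retrotransposon loci with two
LTRs, planted DE features at |log2FC| = 2, and planted CRE motifs in
up-regulated promoters/LTRs. Defaults (chosen once, with units):

| parameter | default | rationale |
|---|---|---|
| n_genes / n_te_loci / n_te_families | 400 / 100 / 20 | scaled-down genome that keeps every stage non-trivial at interactive runtimes |
| promoter_len | 1000 bp | the 1-kb upstream convention of the analysis |
| gene_len / ltr_len / te_internal_len | 900 / 350 / 1300 bp | typical rice transcript and LTR element proportions |
| grid | 40 × 40 | holds the 1200 designed probes with spare cells |
| n_reps_per_condition | 3 | the study design |
| frac_up / frac_down | 0.055 / 0.0025 | ~5.5% of genes DE, strongly up-skewed, as in the modeled experiment; a small DE share also keeps quantile normalization's assumption approximately valid |
| effect_log2fc | 2.0 | planted effects comfortably above the |log2FC| ≥ 1 call boundary |
| noise_sd | 0.3 log2 units | realistic replicate-level array noise |
| probe_affinity_sd | 0.5 log2 units | sequence-dependent probe affinity, constant across samples |
| spatial_bias_amplitude | 1.0 log2 units peak-to-peak | a visible but correctable wash gradient (linear plane by default, radial optional) |
| background_freqs | A/T 0.31, C/G 0.19 | AT-rich plant intergenic composition |
| planted_motifs | ABRE-like `ACGTGKC`, rate 2/sequence, in up promoters and up LTRs | gives the CRE stages a recoverable planted signal |
| qpcr_noise_sd / ct_offset | 0.3 cycles / 30 | typical Ct magnitudes and technical noise |

Statuses are assigned in exact proportions, not sampled. Intensities are
built on the log2 scale — feature baseline N(10, 1) + probe affinity +
condition effect + bias surface b(x, y) + N(0, noise_sd) — and exported as
2^x fluorescence so the pipeline's own log transform is exercised. Probes
are scattered over the grid uniformly at random so spatial bias is not
confounded with feature identity. Planted motif copies (concrete words
sampled from the IUPAC consensus with background-weighted letters) are
inserted at uniform positions without mutual overlap; the copy count per
sequence has expectation exactly the configured rate. Ct values are
ct_offset − log2(expression) + noise, with the first null gene serving as
the zero-effect reference. One master seed drives named per-component
`SeedSequence` streams, so all outputs are byte-identical across runs.

GFF3 coordinates are 1-based inclusive; the promoter is the
`promoter_len` bases immediately 5′ of the feature start on its strand
(for minus-strand genes, the bases after the feature end, reverse
complemented).

What the generator does **not** emulate: linkage between neighboring
features, dye or batch effects, probe saturation or background floor,
sequence evolution within TE families, replicate-specific spatial bias
shapes, and motif positional preference within promoters. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the stated model, not performance on raw scanner data.

## Numerical conventions and problem sizes

Tolerances in tests are exact where arithmetic is exact (quantile identity,
BH, ΔΔCt at zero noise, Venn counts) and statistical otherwise (3-SE bands
for Monte-Carlo means, ±1 percentage point for the type-I rate over 10⁵
null tests, KS p > 0.01 for p-value uniformity over 500 simulations). The
default test suite and the acceptance script use scaled-down problem sizes
(hundreds of features, tens of seeds, 10⁴ motif–sequence null pairs) chosen
so the statistical assertions have adequate power at interactive runtimes;
all sizes are parameters of the config objects.

## Known limitations

* Quantile normalization attenuates large planted effects when the DE share
  is large and one-sided (its identical-distributions assumption fails);
  at the default ~5.5% DE share the attenuation is mild (planted log2FC 2.0
  estimated around 1.6–1.9), but recall of planted features then depends on
  the BH threshold reached, and at 3 + 3 replicates the F-test has only 4
  denominator df — occasional planted features are missed on p-value, not
  on fold change.
* The binomial occurrence null ignores window overlap dependence; for
  highly periodic motifs (e.g. mononucleotide runs) counts are
  overdispersed and the per-sequence p is anti-conservative. The bundled
  catalog avoids such motifs; the shuffle null is the model-free
  cross-check.
* The set-level Z uses a normal approximation; for very rare motifs
  (E ≲ 5) its tail differs from the discrete truth by a few percent —
  visible in the shuffle comparison.
* `per_sequence_significance` treats sequence length as fixed and ignores
  `N` runs (an `N` simply never matches a concrete symbol, slightly
  deflating counts relative to trials).
* The complexity thresholds μ ± 2σ are descriptive, not inferential; with
  small up-regulated sets the "simple" class is often empty.
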