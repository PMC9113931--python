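# Methods

## The enrichment model

Somatic SNV calls define a bipartite graph: samples on one side, genomic
bins on the other, one edge per variant. Writing `d_s` for a sample's
variant count in the scanned territory, `d_b` for a bin's variant count and
`E` for the total, the randomization null places each of sample *s*'s `d_s`
variants independently into bins with probability

* `q_b = d_b / E` (**configuration null**, default) — conditions on the
  observed activity of every bin, so the statistic measures whether the
  *focal cohort's share* of a bin's activity is excessive relative to the
  other cohorts; loci that are hypermutable in every cohort do not score;
* `q_b = L_b / L_tot` (**uniform null**) — expected hits proportional to
  bin length; an absolute-hotspot mode.

Sample *s* then hits bin *b* at least once with probability
`p_sb = 1 − (1 − q_b)^{d_s}`. The per-bin, per-cohort statistic is the
number of cohort samples with ≥ 1 variant in the bin — a sum of independent
but non-identical Bernoulli indicators, i.e. Poisson-binomial. Using the
carrier count rather than raw variant multiplicity is what makes the
Poisson-binomial null well defined per cohort; the raw count is reported
alongside for transparency. `d_s` is always computed over the same
territory the bins tile (genome-wide degrees for a genome-wide scan,
regional degrees for a regional fine scan), so the null is conditioned
consistently.

**Ceiling of the statistic.** The carrier count saturates at the cohort
size. Once every focal sample hits a planted hotspot, further increases of
the local mutation rate only inflate `d_b` — and with it the
configuration-null expectation — so the Z-score plateaus and can decline.
Monotonicity of Z in planted signal strength therefore holds below carrier
saturation, which is where the test operates; carrier counts themselves are
monotone throughout.

## Tail computation

* **Exact kernel** (`pb_pmf_exact`): the O(n²) dynamic-programming
  convolution `new[k] = old[k](1−p_i) + old[k−1]p_i`. Every update is a
  convex combination of non-negative terms, so the kernel is numerically
  stable far beyond 10⁴ trials. Used for cohorts of ≤ 200 samples (the
  switch point `exact_max_n` is configurable).
* **Bi-binomial approximation** (`bibinomial_tail`): the trial
  probabilities are partitioned by deterministic one-dimensional two-means
  (centroids initialized at min/max and iterated to convergence; the split
  minimizes exactly the variance inflation incurred by the next step), each
  group is replaced by a binomial at the group mean, and the upper tail of
  the convolution of the two binomials approximates the Poisson-binomial
  tail. Means, SDs and Z-scores are always computed from the exact moments
  of the `p_i`, never from the approximation.

**Operating envelope.** Mean-matching inflates each group's variance
(`n·p̄(1−p̄) ≥ Σ p_i(1−p_i)`), so the approximate tail is slightly
conservative, and at the extreme point `k = n` the approximation gives
`Π p̄_g^{n_g} ≥ Π p_i` (AM ≥ GM), which for very short, heterogeneous
vectors can exceed half a decade of log-error. This is precisely the regime
the dispatcher never sends to the approximation: vectors of ≤ 200 trials
use the exact kernel. Within its operating range (> 200 trials, tails down
to 10⁻¹⁰, observation points up to ≈ 4 SD above the mean) the measured
worst log10 error over thousands of random two-level, enrichment-style and
beta-distributed probability vectors is about 0.4–0.55 depending on the
draw, i.e. P values are accurate within a factor of ≈ 3 at the deepest
evaluated tails and much better in the bulk — adequate for a statistic
whose decisions are made at Z ≥ 3 and −log10 P ≥ 2/10.

Degenerate nulls (all `p_i ∈ {0,1}`, SD = 0) define Z = 0 when the observed
count equals the mean and ±∞ otherwise; `k = 0` returns an upper tail of
exactly 1. −log10 P is floored at 10⁻³⁰⁰ before taking logs.

## Cluster calling

Per-bin Z-scores from several bin sizes (default 5–10 bp, all integer
sizes) are reduced to a per-base maximum-Z profile. Bases with focal
profile ≥ `z_hi` (default 3) are merged into clusters across gaps of up to
`merge_gap` bp (default 2); a cluster is *focal-specific* when the
background cohort's maximum Z over the cluster stays below `z_lo` (default
2), otherwise *shared*; background-only clusters are reported as
*background*. The thresholds are configurable and recorded in output
headers; they are reporting thresholds, not filters applied to the
underlying tables.

## Coordinates and variant-level filters

VCF input is 1-based; all internal intervals are 0-based half-open, and the
conversion happens exactly once at parse. Printed 1-based inclusive ranges
(e.g. `chr11:69450872-69458025`) convert as `[start−1, end)`, so the
printed end position is the last contained base. Only single-nucleotide
substitutions enter the analysis — every statistic downstream is
substitution-based — and indels are counted and logged at parse, never
silently dropped. Records are kept when their filter column contains PASS
and their population allele frequency is unknown or ≤ 0.5%; an unknown
frequency means the variant was absent from the population database, and
excluding those would delete the somatic calls the analysis is about.
A variant is *coding* when it overlaps the CDS of any supplied transcript;
UTRs, introns and promoters count as non-coding, keeping protein-level
selection out of the regulatory analysis.

## AID context rules

On the strand carrying the mutated base, c-AID means C→T or C→G with the C
at position 3 of a WRCY 4-mer, nc-AID means A→C or A→G with the A at
position 2 of a WA 2-mer (W = A/T, R = A/G, Y = C/T). Both strands are
scanned — on the plus strand the minus-strand rules read G→A/C inside RGYW
and T→G/C followed by W. Contexts are read from the reference sequence,
since AID acts on the unmutated template. When a substitution satisfies
both rules, c-AID takes precedence (WRCY is the canonical AID hotspot);
within one label the plus strand is reported first. Variants within 3 bp of
a contig edge are unclassifiable and return `none` with a warning.

## Signatures

Spectra use the standard pyrimidine-centric 96-class scheme
(substitution-major ordering C>A, C>G, C>T, T>A, T>C, T>G; flanking bases
alphabetical within each class); purine-reference substitutions are folded
in by reverse complement. NMF minimizes the generalized Kullback-Leibler
divergence by multiplicative updates — the de-facto standard for mutational
signatures — with defaults `k = 2`, `n_starts = 20` seeded restarts,
`max_iter = 10⁴`, relative tolerance 10⁻⁸. The KL objective is asserted
non-increasing at every iteration; signatures are renormalized to
row-stochastic form with exposures rescaled compensatingly, so exposures
are in mutation counts. Cosine similarities to a reference catalogue are
always reported in full; the `above_background` flag (default threshold
0.75) is advisory, since "background" is not sharply defined for catalogue
comparisons.

## Binding-site impact

PWMs are parsed from JASPAR PFM files; probabilities use a pseudocount of
0.8 split by the background composition (default uniform), and scores are
log2 odds against the background. Each variant is scored over a window of
`pad = 15` bases either side of the mutated position, taking the best match
over all offsets and both strands (ties break to the smallest offset, plus
strand first), once on the reference window and once with the alternate
base substituted. A score gain above `delta_min` (default 0, i.e. strict
sign) is a constructive call, a loss a destructive one. Scores are
comparable only within a motif; across motifs only the maximum of
wild-type/mutant scores is used, to pick the best-matching motif of a
cluster. Per-cluster summaries report the majority class per motif with
ties resolving to neutral.

## Subtype grouping

Samples are clustered on the marker-gene submatrix with 1 − Pearson
correlation distance and average linkage, cut into two groups; the group
with the higher mean signed marker score receives the positive (classical)
label. These defaults are declared, not canonical — the distance/linkage
are configurable. Non-nodal samples with ≥ `min_cluster_muts = 2` mutations
in focal-specific binding-site clusters and ≥ `min_noncoding = 10`
regulatory non-coding mutations form the mutated group; the rule is
monotone in both counts. Expression values are consumed as given
(normalization, differential expression and gene-set testing are outside
this package's scope); the module emits a sample ranking by a named gene's
expression for external tools.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, at
desk scale:

* territory: one synthetic chromosome, default 10 kb (a stand-in for the
  ~18 kb regulatory region a regional scan would cover);
* cohorts: default 50 focal + 150 background samples — the same order of
  imbalance as a disease cohort inside a larger tumor collection, sized so
  the full test suite runs in seconds;
* per-sample variant counts: negative-binomial with mean 20 and dispersion
  0.3 (variance = μ + 0.3 μ²), giving the sample heterogeneity that makes
  the Poisson-binomial null non-degenerate;
* background placement: positions are drawn to match a per-cohort
  trinucleotide signature mixture (two built-in truth profiles: an AID-like
  C>T/C>G profile at W-flanked cytosines and a replication-like T>C
  profile); a configurable fraction of variants (default 0.3) is instead
  planted directly into classical-AID WRCY contexts;
* hotspots: planted intervals multiply the focal cohort's local rate; each
  cohort sample gains Poisson((m−1)·rate·L/L_tot) extra variants, so the
  carriage probability implied by a multiplier m is 1 − exp(−λ) and the
  expected Z is computable in closed form;
* binding-site clusters: destructive mode writes a PWM consensus into the
  genome and draws variants that change its most informative columns to
  their least-favoured base; constructive mode writes a near-site with two
  mismatches and draws variants restoring the consensus;
* expression: genes × samples normal noise (SD 1) around a baseline, a
  3-SD marker separation between the two planted subtypes, and a +2 shift
  of the focal gene in exactly the samples that satisfy the mutated-group
  rule on the generated variants;
* a toy single-exon transcript with a 150 bp CDS is written into the
  territory so consequence calling has coding variants to classify.

Everything is reproducible from the seed, and a truth manifest records the
planted clusters, per-variant origins, signature profiles and subtype
labels. The generator does **not** emulate read-level noise, germline
contamination, mappability or trinucleotide composition of a real genome,
nor the scale of a multi-thousand-genome cohort; passing closed-loop tests
therefore demonstrates correctness of the statistics and bookkeeping, not
performance on real WGS data.

## Problem sizes used in tests and the acceptance script

Exact-kernel checks enumerate all 2ⁿ outcomes for 200 random vectors with
n ≤ 12 and compare the constant-p case to the binomial closed form up to
n = 500. Bi-binomial fidelity is measured on 1,000 random mixed-probability
vectors of 201–500 trials with observation points up to 4 SD above the
mean. Null calibration uses 200 samples, two cohorts, a 10 kb territory and
10 bp bins, with 10⁴ Monte-Carlo re-placements on 20 bin configurations as
a cross-check. Hotspot recovery uses 100 seeded replicates of a 100 bp ×10
hotspot; signature recovery 50 samples × 3,000 variants; binding-site
recovery 100 seeded replicates of one constructive and one destructive
planting. These sizes keep the full suite and the acceptance script within
about a minute each on a single CPU while leaving each statistic far from
its trivial regime.

## Known limitations

* The bipartite null assumes independent placement conditioned on degrees;
  it is validated internally by permutation, not against a rewiring-based
  randomization.
* Enrichment P values are reported raw (−log10), with an optional
  Benjamini-Hochberg column; the "highly significant" flag at −log10 P ≥ 10
  is a flag, not a filter.
* Binding-site calls depend on the supplied PWM set; no de-novo motif
  discovery, positional-bias statistics or ChIP evidence is used.
* The two-group expression clustering assumes the marker signature
  separates the subtypes; it does not estimate the number of groups.
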