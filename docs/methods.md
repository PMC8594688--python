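# Methods

This note documents the models and procedures implemented in
`methgwas`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
make results reproducible.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open; Bismark-style call
tables and GWAS position columns (1-based) are shifted on read, BED
output is written unchanged. Abutting intervals merge (half-open
adjacency), which makes the merged representation canonical and
simplifies PMD window joining. Chromosome order comes from the layout
file, never lexicographic sorting — the cyclical-permutation test needs
one fixed genome-wide variant ordering. CpG rows are taken as the unit
as given in the input file; no destranding or plus/minus merging is
performed.

## HMR detection

A CpG (pooled over the group's samples, ≥ 5× coverage) is
*hypomethylated* when its level is strictly below `hypo_level` (0.20).
Seed windows of `window` = 200 bp are placed at every `step` = 50 bp
offset; a seed qualifies when its covered CpGs are ≥ `hypo_fraction`
(0.80) hypomethylated and at least one is present. A qualifying seed is
extended rightward in 50-bp increments while the criterion holds over
the *whole* extended span; the failing step is not included. Extension
is rightward only — leftward growth is captured because every grid
position is itself a seed. Accepted spans are trimmed to their
outermost hypomethylated CpGs (so boundaries are data-supported, not
grid-aligned), merged, and kept when they hold ≥ `min_cpgs` (5) covered
CpGs. Group-level detection pools read counts across samples rather
than intersecting per-sample calls: pooling is commutative, uses all
reads, and yields one HMR set per group.

Note the 80% rule admits minority methylated CpGs, so a reported HMR's
pooled mean level is *not* guaranteed below 0.20; the guaranteed
invariant (and the tested one) is the ≥ 80% hypomethylated-CpG
fraction.

## PMD detection

Per sample, each chromosome is tiled with non-overlapping 20-kb
windows; the window symbol is 1 when the pooled level is strictly above
`level_threshold` (0.60), 0 when at or below, missing when no covered
CpG falls inside (a level of exactly 60% therefore maps to 0). A
two-state hidden Markov model with Bernoulli emissions on the binary
symbols — background emitting 1 with probability e_B, PMD emitting 0
with probability e_P — is fitted per chromosome by Baum–Welch (at most
100 iterations, log-likelihood tolerance 1e-6) from a fixed
initialisation (e_B = e_P = 0.9, self-transitions 0.9, uniform start),
then decoded by Viterbi; ties prefer background. Missing windows are
skipped in the emission likelihood but do not break runs: the model
runs on the compressed non-missing sequence and decoded runs are mapped
back across interior gaps. Chromosomes whose non-missing symbols are
all identical cannot constrain two states and fall back to plain
threshold runs, with a logged notice. Maximal PMD-state runs spanning
≥ `min_windows` (3) windows become intervals snapped to window
boundaries.

Consensus over samples is base-wise: bases inside per-sample PMDs of at
least `min_support` (3) samples are kept, and surviving runs must again
span ≥ 3 windows. Base-wise depth (rather than interval identity) is
robust to ragged per-sample boundaries; since per-sample calls are
window-aligned, consensus runs are too, and the ≥ 3-window filter is a
plain length check.

Posterior (forward–backward) decoding instead of Viterbi would be a
defensible alternative; Viterbi was fixed because it returns one
coherent path and is checkable against exhaustive path enumeration,
which the test suite does on chromosomes of ≤ 12 windows (alongside an
independent Viterbi cross-check via hmmlearn at identical parameters).

## Tile-based differential methylation

The genome is tiled into non-overlapping 500-bp windows (or single
CpGs for DMC analysis); counts are summed per sample within each tile.
A tile enters testing only if every sample has ≥ 1 read and each
group's pooled coverage is ≥ 10 — the minimal gate that keeps the GLM
well-posed. The test is the binomial logistic regression
logit(π_j) = β₀ + β₁ g_j over samples j; with a binary covariate the
alternative model's MLEs are exactly the pooled group proportions, so
the likelihood-ratio statistic is computed in closed form on pooled
counts and referred to χ²₁ (a statsmodels GLM reproduces it to 1e-6 in
the tests). No overdispersion correction is applied — a known
limitation shared with default logistic DMR callers; between-sample
variability beyond binomial will inflate the statistic on real data.

Multiple testing uses Benjamini–Hochberg across the tested units
(a π₀-scaled variant, Storey estimate at λ = 0.5, is exposed as
`method="bh_pi0"`). DMRs are tiles with q below the chosen cutoff
(0.05 … 1e-10 are conventional) **and** |difference| > 5 percentage
points, where the difference is between pooled group proportions; both
thresholds are strict. Gain/loss is the sign of (group 1 − group 2).

## GWAS marker-set enrichment

T_sum = Σ t² over variants inside the feature (half-open containment;
a variant at the feature's end coordinate is outside). The null
statistic rotates the genome-ordered t² vector — chromosomes
concatenated in layout order — by an offset k uniform on {1,…,n−1} and
re-sums at the same index positions, preserving both the t² multiset
and the local correlation structure. The empirical p-value uses the
add-one rule p = (r + 1)/(n_perm + 1) with r counting rotations ≥ the
observed sum; this deviates from a plain "proportion greater" by never
returning 0 and by counting ties conservatively. With n ≤ n_perm all
n − 1 nontrivial rotations are enumerated exactly and flagged, which
makes toy-scale results deterministic. Features containing no variant
are reported as untestable rather than p = 1.

## Hypergeometric set enrichment

For the window-set test, m is the number of tested windows, m_g the
number with p < p₀ genome-wide, m_f the number mapped to a term, and
T_count the term's significant windows;
T_count ~ Hyper(m, m_g, m_f) under the null of random placement.
Defining m_g as the count of *tested* windows passing p₀ keeps all
margins on one universe — the only reading under which the statistic is
hypergeometric. p₀ = 0.01 by default (an arbitrary but conventional
screening threshold); genes are extended ±10 kb to capture regulatory
flanks; terms with < 10 annotated genes are dropped. Tails are
one-sided upper (enrichment) and computed through the log-survival
function, which survives p-values far below float underflow of the
naive sum. The gene-set variant applies the same tail to
(|universe|, term∩universe, |query|, term∩query). BH adjustment across
terms in both.

## Integration statistics

- **Global group comparison**: across CpGs covered in every sample of
  both groups, the paired two-sided t-test on per-locus differences of
  pooled group levels (an unpaired Welch option exists). Zero-variance
  differences short-circuit to t = 0, p = 1.
- **Fold enrichment** of features in an element track:
  (overlap/feature_bp)/(element_bp/genome_bp); scale-invariant, 0 when
  disjoint.
- **DMR-set overlap**: one-sided Fisher exact test, i.e. the
  hypergeometric upper tail P(X ≥ shared) on (total tiles, set A,
  set B), in log space; the published 145,173/7,866/4,906/755 example
  gives p = 3.48e-151. The direction is one-sided because the claim is
  enrichment; at this magnitude the two-sided value is numerically
  indistinguishable.
- **Gain vs loss**: two-sided Mann–Whitney on panels of enrichment
  values (e.g. −log₁₀ p across traits × cutoffs); exact null when both
  panels have n ≤ 10 without ties, tie-corrected normal approximation
  otherwise.
- **Candidate genes**: tiles significant and gaining (> +5 points) in
  both contrasts are assigned to genes via gene body or promoter
  overlap; the promoter is 2 kb upstream of the TSS, strand-aware (the
  value is a convention, configurable); per gene and trait the top SNP
  within the gene span ± 250 kb is reported when p < 1e-5 (window
  configurable; published candidate SNPs sit up to ~300 kb from their
  DMRs, motivating the default).

## Synthetic data

The generator emulates the statistical structure of sperm WGBS at the
scale the analyses consume: CpG positions with geometric spacing (mean
100 bp genome-wide), zero-truncated Poisson coverage (mean 10; a
gamma-Poisson dispersion knob exists and defaults off), binomial
methylated counts at the local true level — 0.75 baseline, 0.05 in
planted HMR blocks, 0.40 in planted PMDs (≥ 60 kb, i.e. three
detection windows), and group-specific levels on planted 500-bp tiles.
CpG density inside planted HMR blocks is elevated (mean spacing 30 bp):
hypomethylated regions are CpG-island-like by nature, and because
detected boundaries are trimmed to covered CpGs, recovery of a block is
limited by the span between its first and last CpG — at background
density a 1-kb block would lose ~18% of its bases to edge gaps for
purely geometric reasons. Planted PMDs align to the 20-kb window grid,
matching the detector's resolution; sub-window offsets are
unrecoverable by construction and would only blur the scoring. GWAS
statistics are b = t, se = 1 with t ~ N(δ, 1) inside enriched
intervals and N(0, 1) outside — the minimal structure faithful to a
test that consumes only t². Positions are shared across samples, as in
a real reference alignment. All substreams derive from one seed.

What the generator does **not** emulate: linkage disequilibrium between
variants (rotation-based inference is exercised under independence, so
the type-I checks validate the machinery, not LD robustness),
read-level error or bisulfite non-conversion, biological
between-sample dispersion beyond binomial, non-CpG contexts, and
chromosome-scale covariates (GC, replication timing). Passing recovery
tests therefore demonstrates correctness of the algorithms under their
own model assumptions, not performance on real sperm WGBS.

## Validation benchmarks and problem sizes

`methgwas.validation` (used by the tests and by
`scripts/acceptance.py`) fixes these scales: sum-test calibration on
1e5 null variants × 200 random 100-variant features at 1,000 rotations;
power over 50 replicates of a δ = 2, ~500-variant feature; HMR
recovery over 20 seeds of six 1-kb blocks on a 0.5-Mb chromosome; PMD
recovery over 20 seeds of two 100-kb domains carried by 4 of 6 samples
on a 2-Mb chromosome; DMR calibration on ~1e4 tiles (3 vs 3, 10×) and
recall on 50 planted 30-point tiles (20×). These sizes give stable
pass/fail behaviour at second-scale runtimes while keeping every Monte
Carlo standard error well inside the asserted bands.

## Known limitations

- The logistic LRT is anti-conservative under real biological
  overdispersion; a beta-binomial extension is the natural upgrade.
- HMR seed/extension behaviour at pathological CpG spacings (single
  isolated hypomethylated CpGs at exact grid boundaries) follows the
  documented convention but has no external reference implementation
  to compare against.
- The q-value adjustment is BH, not the SLIM estimator used by some
  DMR callers; BH is more conservative, and DMR-set downstream results
  are insensitive to the cutoff family.
- Consensus PMDs require ≥ 3 supporting samples regardless of group
  size; for very small cohorts the parameter should be lowered
  explicitly.
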