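# Methods

## Study design being modeled

The pipeline targets pooled two-group TMT phosphoproteomics: equal protein
amounts per group are pooled before labeling, so quantification collapses
to a single disease/control ratio per phosphosite. There are no per-sample
replicate columns, which shapes two central choices below (fold-change
thresholds instead of moderated per-site statistics, and set-membership
permutation instead of phenotype permutation).

## Differential calling

Ratios are compared to fixed fold-change thresholds (default up > 1.3,
down < 0.77) with *strict* inequalities: a site at exactly 1.3 or 0.77 is
unchanged. No per-site p-values or multiple-testing correction are
computed — with one pooled ratio per site there is no within-site variance
estimate to moderate.

Residue-breakdown percentages are rounded to the nearest integer (the
pie-chart convention); exact fractions are kept alongside. The
constitution comparison (proteins with 1 / 2 / ≥3 regulated sites, up vs
down) uses Pearson's χ² without continuity correction at df = 2. A
multiplicity bin that is empty in *both* directions has expected and
observed 0 and contributes nothing to the Pearson sum; it is dropped and
df kept at the 2×3 design value. The test refuses to run when a direction
has no proteins or fewer than two bins remain populated. A protein with
sites of both statuses appears in both rows — the counts are per-status.

## Motif enrichment

Foreground is the regulated sites of one central residue; background is
*all* identified sites with that central residue (not restricted by
status), which isolates regulation-associated composition from the
proteome-wide background. Padding `_` at protein termini is excluded from
both numerator and denominator of every positional column, so column
totals vary by position near termini.

The per-cell statistic is a one-sided binomial test of enrichment; the
log2 enrichment uses a pseudocount of 0.5 on all four counts to avoid
infinities (the test itself is un-pseudocounted). Cells with zero
background count are untested (NaN) and excluded from the
Benjamini–Hochberg correction. Depletion is visible as negative log2
enrichment but is not tested. Below 10 foreground windows a small-sample
warning is emitted — tyrosine profiles typically trigger it.

Deliberately out of scope: motif-x-style recursive residue fixing; this is
a single-pass positional analysis.

## Kinase–substrate prediction

Peptide similarity uses a fixed BLOSUM62 matrix for all kinases. Training
kinase-specific matrices is out of scope; the fixed-matrix score is the
mean over the kinase's known substrate windows of the summed positional
substitution values, with any `_` pairing contributing 0.

Threshold calibration maps stringency to an empirical false-positive rate
on background windows: threshold = k-th largest background score,
k = ⌈fpr·n⌉, and emission uses ≥, so up to score ties exactly k of n
background windows reach the cutoff. "Medium" stringency is FPR 6%
(high/low ≈ 2%/10%), flag-configurable. The calibration background is
drawn from proteome S/T/Y-centered windows, *not* from the query site
table: in a dataset where true substrates are enriched, calibrating on
the query windows would push the threshold into the true-substrate score
range and defeat the target FPR.

Residue compatibility is enforced per profile ({S,T} or {Y} central
residues); incompatible sites are skipped silently at debug-log level.
The PPI filter acts at the protein level (kinase protein ↔ substrate
protein), with self-phosphorylation exempt.

## Enrichment engine

The running sum follows the standard weighted Kolmogorov–Smirnov form:
hits increment by |r|^p normalized over hit weights, misses decrement by
1/(N − N_h); default weight p = 1, with p = 0 exposed for analytic
checks. ES is the signed maximum deviation; when the positive peak and
the negative trough tie in magnitude (possible on the p = 0 lattice), the
positive side is chosen — an explicit rule, because otherwise float
summation order decides the sign.

Null model: random same-size member sets drawn from the ranked universe
(set-membership permutation), the only exchangeable unit in a one-ratio
design. Nominal p is the same-sign tail frequency with a (b+1)/(n+1)
continuity correction, so p ∈ (0, 1] and never exactly 0. NES divides ES
by the mean |null ES| of the same sign; FDR q is the pooled-null NES
ratio, computed separately for the positive and negative sides and
monotonized so a more extreme NES never receives a larger q. Sets
overlapping fewer than 3 or more than 500 ranked items are skipped with a
warning. Kinase direction labels use nominal p < 0.05 by default;
a *positive* kinase is one whose substrates show a predominant increase
in phosphorylation.

ORA uses the exact hypergeometric upper tail with BH correction across
sets; hits must be a subset of the declared universe.

## Synthetic data generator

What it emulates: a pooled TMT experiment over a random proteome
(uniform lengths 200–600, i.i.d. residues at average vertebrate
frequencies, recorded in output metadata), with

* ~2.5 sites per protein (matching the sites-per-protein ratio of deep
  human phosphoproteome atlases) and central residues S:T:Y =
  0.84:0.14:0.02;
* synthetic kinases planted as short linear motifs: a primary anchor
  position written into every substrate window (e.g. P at +1 for the
  proline-directed kinase) and two secondary positions written into every
  other substrate. Real kinase motifs have one decisive anchor with
  partial flanking preferences; enforcing secondaries in all substrates
  would make them statistically indistinguishable from the anchor and the
  planted motif would no longer have a unique strongest cell;
* log2 ratio = true shift + N(0, σ₀) baseline + N(0, σ_noise)
  measurement noise, applied to *every* site (the baseline is biological
  ratio dispersion, so the null (Δ = 0) distribution is homogeneous
  across sites). Substrates of active kinases shift +Δ, of inactive
  kinases −Δ. Defaults: Δ = 1.0, σ₀ = 0.25, σ_noise = 0.5 log2 units —
  stipulated values, as pooled designs publish no per-site ratio
  distribution to fit;
* localization probabilities ~ Beta(20, 1) (mode at 1; ~0.3% fall below
  the 0.75 class-I cutoff) and search scores ~ Gamma(4, 30) (~5% below
  the >40 filter), so the quality filters are genuinely exercised;
* PPI evidence containing every true kinase–substrate protein pair plus
  10% random decoy interactors per kinase.

What it does **not** emulate: raw spectra, TMT reporter channels and
isotope impurity, missing values, peptide-level ambiguity, correlated
sites within a protein, or kinase cross-talk. Passing recovery tests on
this generator therefore demonstrates the statistical machinery is
correct and calibrated — not that real tissue data will be as separable.

All randomness flows through per-stage child streams of the config seed,
so each generator operation is independently deterministic.

## Numerical and interface choices

* Site tables are 1-based positions, MaxQuant header aliases accepted;
  duplicate (protein, position) rows collapse to the highest localization
  probability; the score filter is strictly `>`, the localization filter
  `≥` (class-I convention, configurable — which localization cutoff, if
  any, the original search applied is typically unstated).
* Ranked lists break value ties by ascending item id; all permutation
  routines require an explicit seed.
* Pipeline runs write a manifest of SHA-256 output hashes; identical
  (config, seed) reproduce identical manifests. Single-threaded by design.

## Problem sizes

Default validation runs use 200 proteins (~500 sites), 3 kinases × 20
substrates, 1000 permutations, and 20 seeded replicates for recovery
rates; null calibration uses 400 random sets at 500 permutations. These
sizes give binomial confidence intervals tight enough for the calibration
checks while keeping a full validation run in the tens of seconds.

## Known limitations

* Fixed BLOSUM62 similarity understates specificity for kinases whose
  selectivity lies in disfavored residues; per-kinase matrices are the
  established remedy and are out of scope.
* NES-as-activity inherits GSEA's dependence on set size and ranking
  metric; activities are comparable within one run, not across datasets.
* The kinase–site "correlation" is structural direction concordance along
  a predicted edge; a pooled one-ratio design cannot support per-sample
  correlation.
* With one ratio per site, fold-change thresholds conflate effect size
  and noise; the thresholds are conventions, not error-controlled calls.
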