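# Methods

`calpcleave` models the substrate specificity of the conventional
calpains (calpain-1/-2, C1/C2), Ca²⁺-dependent cysteine proteases that
perform limited proteolysis. Its object of study is the cleavage-site
window: the ten residues N-terminal (P10…P1) and ten C-terminal
(P1′…P10′) of a scissile bond, cleaved between P1 and P1′. The package
answers two questions about any bond: *will* calpain cleave it (a
probability), and *how efficiently* (a catalytic efficiency
k_cat/K_m in M⁻¹s⁻¹, the specificity constant of the pseudo-first-order
regime [S] ≪ K_m where v = (k_cat/K_m)·[E]·[S]).

## Featurization

Windows are extracted with 1-based bond coordinates (`bond_after = i`
cleaves between residues i and i+1; Pk sits at i−k+1, Pk′ at i+k).
Positions outside the sequence are MISSING, handled uniformly — the
one 19-mer in a 20-mer library needs no special case. Each occupied
position maps onto numeric amino-acid scales: AAindex entries,
molecular-property tables supplied as 20-value TSVs, or
secondary-structure probabilities. The last are *per-window inputs*
(from an external structure predictor), never computed here; they enter
through a sidecar mapping rather than a residue lookup.

Descriptor pre-selection mirrors the modelling pipeline: per position,
the scale whose values correlate best (largest squared Pearson r) with
measured k_cat/K_m; and, for interpreting a fitted model, scales ranked
by the sum of their Pearson-r and Spearman-ρ ranks against a
per-residue contribution profile (ρ is kept alongside r because several
published scales have outlier-heavy distributions). Ranking uses the
signed statistics, descending: the question asked is "which scale does
this profile follow", not "which scale or its negation". Ties break
lexicographically on descriptor id everywhere; this makes every
selection deterministic.

## Binary cleavability classifier

The classifier is the classical binary-QSAR construction: features are
z-scored, rotated onto principal components (components retained until
≥ 98% of variance is explained, configurable), each retained component
is discretized into equal-width bins (default 10) spanning the training
range, and smoothed class-conditional bin frequencies are combined
under naive independence with the class prior through Bayes' rule.
Smoothing adds 0.5 pseudo-counts per bin (configurable); it bounds all
stored probabilities inside (0, 1) and sets the scale of the tolerance
in the closed-form posterior checks. Out-of-range scores at prediction
time clip to the edge bins.

Two thresholds exist and are deliberately distinct: the *cut-off* (0.5
on the 0/1 response coding) binarizes training responses, while the
*classification threshold* converts posterior probabilities to calls —
0.5 by default, 0.95 in high-positive-predictive-value mode for
protein scanning.

Model quality uses leave-one-out cross-validated accuracy (XA); each
fold refits everything (scaling, PCA, histograms), and a fold whose
training half degenerates to one class predicts from the prior.
Backward elimination greedily removes the feature whose removal
maximizes XA and selects the smallest feature set with XA above the
floor (default 0.7); if nothing clears the floor the best step is
returned flagged. The default position range is P6–P6′: wider ranges
discard too many incomplete windows and shorter ones too much sequence
context.

## PLS efficiency regression

k_cat/K_m is regressed on descriptor features with partial least
squares (NIPALS PLS1 on standardized predictors, hand-written so that
the thousands of refits inside cross-validation loops stay cheap; the
test suite pins it against both the closed-form least-squares solution
at full rank and an independent reference PLS implementation). The
response is raw k_cat/K_m, not its log: the contribution analysis
below is additive in M⁻¹s⁻¹. Components are chosen to maximize
leave-one-out cross-validated r² (Xr²), capped at min(8, rank).
Backward elimination follows the classifier's rule with an Xr² floor
of 0.6.

Features may span one position or a pair of adjacent positions; a
paired feature evaluates as the sum of the per-residue descriptor at
the two member positions. Whenever a member position is unknown —
contribution profiles, subsequence scoring, prediction on a window
truncated at a pair's partner — it is marginalized as the descriptor's
unweighted 20-residue mean. Subsequence scores additionally replace
entirely out-of-range single-position features by that mean, so scores
of equal-range subsequences are comparable; because the model is
additive, the best subsequence over a range decomposes into
per-position argmaxes (a property the tests exploit against exhaustive
enumeration).

Outlier handling refits once after removing rows with standardized
residual magnitude above 2.5 and refuses if more than 20% of rows
would be flagged. The intercept is fit from data and reported, but all
contribution profiles are intercept-free differences.

## Kinetics estimation

The measurement design is an 8-channel isobaric labeling of one
digestion time point (900 s) at a dilution series of initial substrate
concentrations (3.3–20 µM per peptide across channels 114–119, enzyme
2.5 µM), a no-enzyme reference channel (113) carrying the library, and
a standard channel (121) carrying the synthesized fragment peptides at
5 µM. Initial velocities come from two printed formulas: full-length
decay, v₀ = ([S]₀(n) − Iₙ/I₁₁₃·[S]₀(113))/t, and fragment appearance,
v₀ = Iₙ/I₁₂₁·5·10⁻⁶ M/t. k_cat/K_m is 1/(b·[E]ₜ) with b the unweighted
least-squares slope of 1/v₀ on 1/[S]₀ (Lineweaver–Burk); an
Eadie–Hofstee estimator is provided for comparison, with its two
degenerate regimes (exactly first-order data collapse to the mean of
v₀/[S]₀; saturated data are not estimable). Non-positive velocities
are dropped from regressions and counted; replicate [S]₀ channels
enter as separate points.

Two deliberate additions sit on top of the printed formulas:

* **Depletion correction.** The measured v₀ is a finite-time average
  rate, so the raw estimate equals (1 − e^(−k[E]t))/([E]t) rather than
  k — a 20%/60% underestimate at k = 200/1000 M⁻¹s⁻¹ under these
  conditions. `correct_depletion=True` inverts that first-order
  relation exactly; with it, noise-free simulated data are recovered to
  machine precision at any k. The raw formula remains the default,
  matching the printed definition.
* **Route selection.** `method="auto"` measures the species whose
  amount actually changed: fragment appearance below 50% conversion,
  full-length decay above. At high conversion the fragment signal
  saturates (its sensitivity to k falls as (1−x)/x) while the residual
  substrate still responds; at low conversion the reverse holds.

The simulator generates first-order decay S(t) = S₀e^(−k[E]t) and its
complementary fragment under the channel design, with multiplicative
log-normal noise (median-one) of a given CV on each enzyme-channel
intensity. The normalization channels (113, 121) are left exact: all
eight reporters of an isobaric spectrum share one acquisition, so only
ratios to the normalization channel are measurable, and the simulator
expresses all measurement noise in those ratios. Control-peptide
standardization (geometric mean of the three controls per channel) is
implemented for real data, where it removes per-channel labeling
bias; on simulated data it is a no-op by construction. The simulator
does not emulate the excess variance the full-length signals show in
real acquisitions, nor spectral interference or isotope-purity
effects — recovery results bound estimator error, not instrument
error.

## Specificity statistics

Frequency profiles count residues per position (missing positions
leave that position's denominator) and report
r = log₁₀(observed/background) against the Swiss-Prot 2012_9
composition (Ala 8.67% … Tyr 3.03%). A residue absent at a position
carries a −∞ sentinel; logo export floors it at a display value, and
profile correlations exclude such cells pairwise with a reported
count. The log base only rescales logos. Inference uses the t-test
for a correlation coefficient (t = r√((n−2)/(1−r²))), the pooled
uncorrected two-proportion Z-test, the one-proportion Z-test against
p₀ = 1/(L−1) for cleavage-position bias (≈5% per bond for 20-mers),
the binomial point probability (1−p)ⁿ for a residue's complete
absence, and Welch's unequal-variance t-test with Satterthwaite
degrees of freedom. No multiple-testing correction is applied by
default; a Bonferroni helper exists. A generic per-position descriptor
contrast (Welch test on a scale's values at one position between two
site sets) covers enzyme-preference comparisons.

## Synthetic data and decoys

The library generator emulates the study design: 87 20-mer peptides
(defaults) drawn i.i.d. from the background composition, windows
complete over P6–P6′ (9 per 20-mer, 801 rows at 89 peptides), true
k_cat/K_m from a planted linear model over descriptor features plus
multiplicative log-normal noise, clipped at zero, and binary labels by
thresholding. What it does not emulate: real libraries are *selected*
(sites centered, hydrophobicity-filtered), residues within a peptide
are not i.i.d., and cleavability is not exactly linear-plus-threshold
in any small descriptor set — so passing recovery tests demonstrates
correctness of the estimators under their assumed model, not
performance on real substrate data.

Decoy construction takes the C-terminal 20-mers of proteome entries
(≥ 20 residues), removes tails whose *reversed* sequence shares any
contiguous 4-residue block with a core database, then those whose
forward sequence does, and samples 4,000 survivors uniformly without
replacement (seeded). "Block" means any contiguous length-4 substring,
matched exactly and case-insensitively; the reversal applies to the
tail itself. The filter is monotone in the core database.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` with explicit
seeds; every generator is deterministic under its seed. PCA signs are
fixed (largest-magnitude loading positive). Zero-variance features
z-score with unit scale; zero-variance descriptor columns are excluded
from selection with a warning; constant tables rank worst. Probability
arithmetic in the classifier runs in log space. Standard errors of
kinetic estimates propagate from the regression slope by the delta
method (divided by 1−x under depletion correction).

Problem sizes in the test suite (n = 800 classification rows, n = 119
regression rows, 100-seed recovery batches, 1,000 null simulations)
were chosen to match the scale of the study design the package
mirrors while keeping the default suite comfortably runnable on one
CPU.

## Known limitations

* The classifier is *a* binary-QSAR implementation; numeric parity
  with any proprietary implementation of the scheme is not claimed,
  only agreement with the published construction and closed-form
  Bayes behavior within smoothing tolerance.
* Permutation importance is the interpretability statistic; it is not
  the "importance" number proprietary tools print.
* Reversed-sequence negatives are a convention, not ground truth —
  some reversed windows may be genuinely cleavable.
* k_cat/K_m estimates at conversions approaching 100% are
  ill-conditioned even with the depletion correction; the SE reports
  this but cannot repair it.
* Counts reconstructed from printed percentages (for proportion
  tests on published tallies) are approximate to rounding.
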