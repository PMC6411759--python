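# Methods

## Peptide representation

Peptides are strings over the 20 standard amino acids. Input longer than 25
residues is truncated to its first 25 (with a warning); non-standard letters
(B, J, O, U, X, Z) are rejected with a diagnostic naming the symbol and
position rather than silently remapped, because every downstream table and
encoder is defined on the standard alphabet only. For encoding, sequences
are left-aligned in a fixed 25-symbol window with `-` gaps as a suffix; for
positional enrichment analysis, the first 15 N-terminal positions are used
with missing positions coded `O` (biological activity of short
anti-inflammatory peptides concentrates in the N-terminal region, so the
analysis window is anchored there). Labels arrive either as one FASTA per
class or as a two-column `id<TAB>label` file.

## Encoders

**KSAAP.** For spacing k ∈ {0..4} and ordered pair (a,b), the feature is
the number of index pairs (i, i+k+1) whose symbols are a and b, divided by
the number of pairs in which neither symbol is a gap. Consequences that the
tests rely on: each k-block is non-negative and sums to 1 whenever any valid
pair exists, and the encoding is invariant to the amount of gap padding.
Pair order is lexicographic (AA, AC, …, YY) over the alphabetical residue
order, k-blocks concatenated in increasing k; both orders are frozen so
serialized models remain portable. Dimension 5×400 = 2000.

**pKSAAP.** The same construction on a position-specific scoring matrix.
Raw log-odds scores are squashed elementwise by the logistic map
M = 1/(1+e^(−x)), and the (k, a, b) feature is Σᵢ M[i,a]·M[i+k+1,b]/(L−k−1)
over the L−k−1 valid positions. Design choices here were genuinely open:
the squash-then-mean-of-products form was chosen because it reduces
*exactly* to KSAAP when M is a one-hot encoding of the sequence (the
degenerate "profile equals sequence" case), which gives a checkable
identity and a principled fallback — peptides lacking a PSSM file are
encoded via their one-hot self-profile, with a logged warning, so the
pipeline runs without a profile-search step. Profiles are parsed from
PSI-BLAST ASCII files (first 20 score columns; the residue column order is
read from the file header and re-ordered to alphabetical).

**AAindex.** Position-major lookup: for each of the 25 window positions,
the 8 physicochemical index values of the residue there; gap positions
contribute zeros. Dimension 25×8 = 200. The 8 shipped default scales
(Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, Grantham polarity,
side-chain volume, isoelectric point, Chou–Fasman helix and sheet
propensities, net charge) are deliberately diverse standard scales; any
8-row table can be substituted via TSV, and rows may be min-max scaled to
[0,1] (the default; note that tree ensembles are invariant to per-feature
monotone scaling, so this choice affects readability, not accuracy). A
known ambiguity: an L×20 per-position one-hot-style AAindex variant exists
in the literature; this package fixes the 25×8 selected-index form.

**Structural tables.** Readers/encoders only — structure predictors are
external. SPIDER2-flavor tables carry 8 channels per residue (ASA; phi,
psi, theta, tau backbone angles; coil/strand/helix probabilities), PEP2D
tables 3 (helix/sheet/coil probabilities, validated to sum to 1 ± 1e-6 per
row). Encoding flattens position-major over the 25-window, zero-filling
missing positions and truncating longer tables with a warning; angle
channels are divided by 180 to land in [−1, 1] so no channel dominates
split selection by scale.

## Classifier

Each active encoder trains a `RandomForestClassifier` (scikit-learn) with
1000 gini trees and √K features per split — n=1000 is large enough for
stable vote fractions, and √K is the standard default where the source
recipe leaves k unspecified. The encoder score is the fraction of trees
voting positive.

**Fusion.** Weights live on the probability simplex, discretized at 0.05.
The search enumerates every lattice vector (C(24,4) = 10,626 for five
encoders) and keeps the one maximizing the Mann–Whitney AUC of the fused
score on *out-of-fold* cross-validation scores; pooled out-of-fold AUC is
used (fold-wise averaging of the search objective is the other defensible
choice; pooled is simpler and uses every pairwise comparison). Ties are
broken by the first vector in the lexicographic enumeration, making the
result deterministic. Resubstitution scores never enter the search or the
calibration — that would bias the fused AUC and the cutoffs optimistically.

**Calibration.** With the rule "positive iff score ≥ cutoff", specificity
at cutoff c is the fraction of negatives scoring below c. For each target
(0.9/0.8/0.7 by default, strictest first) the cutoff is the smallest
candidate — the observed out-of-fold scores plus one value just above the
maximum — whose achieved specificity meets the target. Cutoffs are
therefore non-increasing from high to low, achieved specificity likewise,
and the three calls are monotone per peptide. If a target is only reachable
above every observed score, the cutoff is set there with a warning (no
peptide is then called at that level); achieved specificities are always
recorded next to the targets.

## Evaluation

Sn, Sp, Ac and MCC come from the confusion table; a metric whose
denominator is zero is reported as missing, never coerced to 0. AUC uses
the rank formulation with ties counted ½ (identical to the trapezoidal ROC
area without ties, well-defined with them). Cross-validation is stratified
(the folds are described only as random and equal-sized in the source
protocol; stratification reduces variance and keeps per-fold class ratios
within one sample of the global ratio — a documented deviation), every
sample is scored exactly once out-of-fold, and reported CV metrics are
fold averages with missing per-fold metrics skipped.

**Positional enrichment.** Two procedures compare peptide classes over the
15-position analysis window. (1) Welch's unequal-variance t-test on
per-peptide residue-presence indicators, per (position, residue) cell —
the computation behind two-sample sequence logos; cells with zero variance
in both groups yield no flag. (2) Kruskal–Wallis tests on per-position
real-valued profiles (e.g. mean squashed PSSM conservation, a chosen
residue's PSSM column, or a physicochemical channel of the residue at each
position), Bonferroni-corrected across the 15 positions
(p' = min(1, 15p)); positions where all values tie get p = 1, and NaN
entries (positions beyond a peptide's length) are dropped. Corrected flags
are by construction a subset of uncorrected ones.

## Synthetic data generator

The generator emulates what the method assumes about its inputs, and only
that: lengths on [4, 25] from a shifted binomial with mean 15; residues
uniform over the 20 amino acids (a Swiss-Prot-like natural-frequency
background is available, but uniform keeps the effect-0 null *exactly*
exchangeable); class-specific planted motifs as position→residue maps —
defaults: leucine at positions 5, 7, 10, 11, 15 for positives, and
D/T/V-type enrichment at N-terminal positions for negatives, following the
enriched/depleted pattern typical of anti-inflammatory versus inactive
peptides. A planted residue's sampling weight is multiplied by
e^(effect_size), so effect 0 is the null and effect 3 (the "strong" default)
gives the planted residue probability ≈ 0.51 at its positions.

Synthetic PSSMs are N(0,1) noise plus +c on the native residue and −c
elsewhere (c = concentration, default 2.0): after squashing they are noisy
one-hots whose sharpness grows with c, so pKSAAP converges to KSAAP as
c → ∞ — another checkable identity. Synthetic structural tables are
class-uninformative by design (Dirichlet secondary-structure rows, uniform
angles, half-normal ASA), which makes them a negative control: fusion
weight landing on them would indicate leakage.

What passing synthetic tests does *not* show: real AIP data have correlated
residue positions, compositional signal beyond planted positions, homology
structure between peptides, and informative (not noise) structural
features. In particular, under a purely positional planted motif the
positional AAindex encoder is structurally at least as informative as the
pair-composition encoders, and the grid search often gives it the largest
weight — on real data reported encoder orderings differ. Recovery results
here validate the machinery, not field performance.

## Problem sizes and numerical choices

The benchmark used by the test suite and the acceptance script
(`aipkit.benchmark.holdout_benchmark`) generates 300+300 peptides, splits
them into stratified halves, fits with 5-fold internal CV and 200-tree
forests, and reports AUC on the held-out half — sizes chosen so the whole
analytic suite runs at desk scale while keeping the null AUC band
[0.4, 0.6] at roughly ±3 binomial standard errors for 150+150 held-out
peptides. Enrichment error rates are measured at 200+200 peptides per
group over repeated seeds; the Welch null false-flag rate is estimated by
pooling positions, residues and seeds (the minimum-variance estimate of
the procedure's size; per-position empirical rates scatter around it by
binomial noise). Forest defaults stay at 1000 trees for production use.

All randomness flows from explicit integer seeds (master seed → derived
per-fold/per-encoder/per-record seeds below 2^31); identical seeds give
bit-identical encodings, scores, weights and files. Information-gain
discretization uses 10 equal-width bins over the observed range
(configurable); log base 2 throughout, so IG is in bits and never exceeds
the label entropy.

## Known limitations

- PSI-BLAST, SPIDER2- and PEP2D-style tools are not run; only their output
  files are read. Redundancy reduction (CD-HIT-style identity filtering) is
  likewise out of scope.
- The default physicochemical table is a generic 8-scale set; users with a
  preferred index selection should supply their own TSV.
- Specificity-anchored cutoffs are estimated from out-of-fold training
  scores; on a shifted test distribution the realized specificities will
  drift from their targets.
- The information-gain ranking is for interpretation; selection by top-N IG
  is exposed but not used by the default model, as it does not reliably
  improve fused performance.
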