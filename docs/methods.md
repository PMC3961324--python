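# Methods

## Problem and data model

`softpr` evaluates binary classifiers on *weighted* test data. Each data
point i carries a classifier score s_i and a pair of non-negative weights
(w_fg,i, w_bg,i) expressing its mass in the foreground and background
class — soft class labels, experimental confidence measures, or
multiplicities. Hard-labeled data is the special case
(w_fg, w_bg) ∈ {(1,0), (0,1)}.

For a threshold t the prediction rule is *foreground iff s_i ≥ t* (fixed
package-wide; it matters only when a threshold coincides with a score).
Confusion-matrix entries are accumulated weights:
TP(t) = Σ_{s_i ≥ t} w_fg,i, FP(t) = Σ_{s_i ≥ t} w_bg,i, and so on. By
construction TP + FN = R_fg (total foreground weight) and
FP + TN = W_bg (total background weight) at every threshold. Sweeping t
over the distinct scores — tied scores merged into one step, plus a
sentinel above the maximum at which nothing is predicted — gives the
*supporting points*, computed in one pass from cumulative sums over the
score-sorted points. Points with w_fg = w_bg = 0 carry no information and
are dropped with a logged count.

## Continuous AUC-PR

Between adjacent supporting points A and B (TP_A < TP_B), the confusion
matrices are interpolated linearly, so FP is linear in TP with slope
s = (FP_B − FP_A)/(TP_B − TP_A). In terms of the recall p = TP/R_fg the
precision along the piece is the hyperbola

    prec(p) = p / (a·p + b),   a = 1 + s,   b = (FP_A − s·TP_A)/R_fg,

and the exact area of the piece is

    (pB − pA − (b/a)·(ln(a·pB + b) − ln(a·pA + b))) / a    if b ≠ 0,
    (pB − pA) / a                                          if b = 0.

The logarithm is natural (the closed form integrates 1/(a·p + b)). The
full AUC-PR walks the supporting points from zero recall to full recall,
summing piece areas; pairs with equal TP bound vertical PR segments of
zero area but still advance the segment anchor, so the curve's lower
envelope is preserved. Because no step size appears anywhere, the formula
applies unchanged to real-valued (weighted) confusion matrices.

Numerical choices: the b = 0 branch is taken when
|b| ≤ 1e-12·max(1, |a·pB|), since the logarithmic form cancels
catastrophically as b → 0 while its limit is (pB − pA)/a. Accumulated
AUCs are clamped to [0, 1] against round-off. The closed form is checked
in the tests against a Simpson-quadrature oracle that integrates the
linearly interpolated matrices directly (1e-9 absolute tolerance on
1,000 random segments).

## Discrete interpolations (unweighted data)

For hard-labeled data the classical interpolation inserts intermediate
confusion matrices at unit steps of TP with FP interpolated linearly
(*discrete-TP*), or symmetrically at unit steps of FP (*discrete-FP*),
and applies the trapezoidal rule over (recall, precision). Both are
implemented for integer-valued confusion matrices only; fractional
weights raise an error, because no natural unit step exists — this is
precisely the gap the continuous form closes. Integer-valued entries also
arise from multiplicity weights, where a unit step still corresponds to
one data point, so integrality rather than strict 0/1-ness is the gate.

The trapezoid's zero-recall end is anchored at recall 0 with the
*limiting* precision of the first TP-increasing piece: along the
interpolation ray from the empty prediction set the precision is the
constant ΔTP/(ΔTP + ΔFP), and if false positives accrue before the first
true positive the limit is 0. This matches the continuous method, which
integrates from recall 0 as a limit; truncating the curve at the recall
of the first positive instead would bias the comparison by up to
(precision)/R_fg. All intermediate points of both discrete methods lie
exactly on the continuous hyperbola (verified to 1e-12), and segments
with equal TP/FP ratio at both ends are horizontal, where all three
methods coincide exactly.

ROC curves interpolate linearly, so AUC-ROC is the plain trapezoid over
(FPR, TPR) supporting points — exact for weighted and unweighted data,
and equal to the (weighted) pairwise rank statistic, which the tests
check to 1e-12.

## Extremes, normalization, baselines

For fixed weights, the maximal AUC-PR over all scorings is attained by
ranking points by descending foreground confidence w_fg/(w_fg + w_bg)
(well-defined when w_bg = 0, monotone-equivalent to w_fg/w_bg), the
minimal by the reverse order. Equal-confidence points lie on a common
constant-precision hyperbola, so their internal order is irrelevant;
ties are broken stably by input index. No closed form exists for the
extreme values themselves; they are computed by scoring the sorted order
and integrating. For unweighted data the maximum is exactly 1; whenever
some point carries mass in both classes the maximum is strictly below 1
(full recall then forces background mass into the final precision) and
the minimum strictly above 0. The ordering rule is validated in the
tests against a stochastic search (5,000 random orderings plus
adjacent-transposition hill climbing) rather than assumed.

The normalized AUC-PR is (AUC − min)/(max − min), clamped only for
round-off below 1e-9; equal extremes (all points equally confident) make
normalization undefined and raise an error.

The random baseline scores the points i.i.d. uniform(0, 1) — almost
surely a random total order — m times (default 1,000) and summarizes the
continuous AUC-PR ensemble by median and quartiles (linear interpolation
between order statistics, for reproducibility). The median sits near the
class ratio R_fg/(R_fg + W_bg), the known expectation for a random
classifier, and the extremes bound every draw.

## Synthetic data generators

The generators emulate the three study designs the package's claims rest
on; none of them models real score distributions, so passing tests show
internal consistency of the method under controlled conditions, not
field performance on any particular dataset.

**Gaussian scores with binning** (`ScoreSimConfig`): per replicate a
foreground mean μ ~ Normal(1.64, 1.0); foreground scores Normal(μ, 1),
background Normal(0, 1); defaults 10 fg / 100 bg points (class ratio
1:10; 1.64 is the matching upper Gaussian quantile). Redrawing μ each
replicate spreads the replicate AUCs over most of the attainable range.
Scores are discretized to `n_bins` equal-width bins over the pooled
observed range (bin midpoints become scores), controlling score
uniqueness; the spread of μ (1.0) and the replicate count (10,000) are
free parameters of the design, fixed here once and exposed in the
config. The binning convention (equal width, pooled range, midpoints) is
likewise a design choice; only the number of distinct scores matters for
the comparison.

**Interpolation-difference experiment**: per replicate,
|AUC(discrete-TP) − AUC(continuous)| on the same sample. At the smallest
setting (10 fg, 10 bins) the maximum over 10,000 replicates is ≈ 0.03
with the bulk below 0.01; at 1,000 fg points or 1,000 bins it collapses
by orders of magnitude — the two interpolations agree wherever the
supporting points are dense.

**Beta-mixture soft labels** (`WeightSimConfig`): w_fg drawn from
0.9·Beta(1.2, 8) + 0.1·Beta(8, 1.5), w_bg = 1 − w_fg, for 10,000 points;
hard label foreground iff w_fg ≥ 0.5. The mixture parameters are a
design choice producing a bimodal weight histogram and a hard class
ratio near 1:9. The good/permuted/bad construction draws one
class-conditional Gaussian score pool (background mean 0, foreground
mean the upper Gaussian quantile of the realized foreground fraction,
sd 1) and assigns the sorted scores within each hard class to points
ordered by w_fg ascending, randomly, or descending. The three score
vectors are permutations within each hard class, so hard-label
evaluation cannot distinguish them, while weighted AUC-PR and AUC-ROC
order them strictly good > permuted > bad on every tested seed. The
good classifier still sits below the global maximum because the two
classes are sorted separately.

**Logistic soft labels and threshold stability**: a signal x gets
w_fg = 1/(1 + exp(−slope·(x − t))) (weight 0.5 exactly at the labeling
threshold t). The stability experiment draws a latent signal
x ~ Normal(0, 1) for 500 points, classifiers x + noise (noise sd 0.25–2),
and compares AUC-PR computed at two labeling thresholds (1.0 and 2.0,
i.e. a lenient and a strict class border) with soft versus hard labels.
The correlation of the weighted AUC-PR across the two thresholds
(≈ 0.99) exceeds the unweighted one (≈ 0.87–0.91): soft labeling damps
the arbitrariness of the class border. The problem sizes here are chosen
so the full study runs in seconds.

## Degenerate inputs and tie-breaking

- Empty samples, non-finite scores, negative weights: rejected with the
  offending row named.
- Zero foreground mass: recall undefined, error; zero background mass:
  ROC undefined, error (PR still works).
- All scores tied: two supporting points; the PR curve is the single
  segment ending at (1, class ratio), AUC-PR = class ratio, AUC-ROC = ½.
- Score ties: merged into one threshold step; no intermediate matrix
  exists inside a tie group.
- Serialization uses 17 significant digits; curve TSVs round-trip
  bit-exactly (readers use round-trip float parsing).

## Known limitations

- The discrete methods accept any integer-valued confusion matrices and
  cannot tell multiplicity weights from unit weights; callers who want
  strict hard-label semantics should check `WeightedSample.is_unweighted`.
- Extreme orderings are exact under the confidence-ratio ordering rule;
  the package provides no independent proof, only the stochastic-search
  validation in the test suite.
- The random baseline is Monte Carlo; its quartiles carry O(1/√m) noise.
- No confidence intervals, partial AUCs, or multi-class support.
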