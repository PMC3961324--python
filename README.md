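# softpr

Precision-recall and ROC curves — with exact area under the PR curve —
for binary classifiers evaluated on **weighted (soft-labeled) test
data**, as well as on ordinary hard-labeled data.

## Why

Test labels are often uncertain: each data point i comes with
non-negative weights (w_fg,i, w_bg,i) expressing its mass in the
foreground and background class (soft labels, confidence measures, or
multiplicities). Confusion matrices for such data are real-valued, and
the classical PR-curve interpolation — intermediate points at unit steps
of the true positives — has no natural step size anymore. `softpr`
computes the PR curve piecewise exactly instead: between adjacent
supporting points A and B the precision is the hyperbola

    prec(p) = p / (a·p + b),    a = 1 + s,  b = (FP_A − s·TP_A)/R_fg,
    s = (FP_B − FP_A)/(TP_B − TP_A),  p = TP/R_fg (recall),

whose area has the closed form

    (pB − pA − (b/a)·(ln(a·pB + b) − ln(a·pA + b))) / a     (b ≠ 0).

This needs no step size, so it applies to weighted and unweighted data
alike. The package also provides:

- the discrete interpolations along true positives (Davis–Goadrich) and
  along false positives, for integer-valued confusion matrices;
- trapezoidal AUC-ROC (exact, since ROC interpolation is linear);
- the attainable **maximum and minimum AUC-PR** for a given weighting
  (rank points by foreground confidence w_fg/(w_fg+w_bg), descending or
  ascending), the **normalized AUC-PR**, and Monte-Carlo
  random-classifier baselines (median ≈ class ratio);
- synthetic-data generators and the simulation studies that demonstrate
  when discrete and continuous interpolation differ and why weighted
  evaluation can separate classifiers that hard labels cannot.

## Worked example

The packaged six-point dataset (`softpr.datasets`) has scores
2.54, 2.37, 1.56, 1.35, 0.06, −1.08 with soft weights and hard labels:

```python
from softpr import *
from softpr.datasets import worked_example_weighted

sample = worked_example_weighted()
cm = confusion_at_threshold(sample, 1.5)
print(cm.tp, cm.fp, cm.fn, cm.tn)   # 2.04 0.96 0.83 2.17

pts = supporting_points(sample)
print(auc_pr_continuous(pts).auc)   # 0.7898646970011165
print(auc_roc(pts).auc)             # 0.7755173603767074

ext = extreme_aucs(sample)
print(ext.max_auc, ext.min_auc)     # 0.8724244036515226 0.303025675038734
print(normalized_auc_pr(auc_pr_continuous(pts).auc, ext))  # 0.8550054601429402
```

At threshold 1.5 the weighted confusion matrix accumulates 2.04 units of
foreground weight above the threshold against 0.96 background units.
The weighted AUC-PR of 0.790 sits between the worst (0.303) and best
(0.872) values any scoring could achieve with these weights — note the
maximum is below 1, because soft-labeled points carry mass in both
classes — giving a normalized AUC-PR of 0.855.

The same table read with hard labels gives integer matrices
(TP=2, FP=1, FN=1, TN=2) and AUC-PR 0.851 (continuous) vs 0.850
(discrete-TP): on unweighted data the interpolations nearly agree.

Command line, equivalently:

```sh
$ softpr auc --input src/softpr/data/worked_example.tsv \
        --mode weighted --method continuous
{"method": "continuous", "auc": 0.7898646970011165, "n_points": 6, "n_segments": 6}
```

Other subcommands: `softpr curve` (supporting points as TSV),
`softpr extremes` (attainable AUC-PR range plus random baseline),
`softpr simulate` (the packaged simulation experiments). Input is TSV:
`score<TAB>w_fg<TAB>w_bg` (weighted) or `score<TAB>label` (unweighted).

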