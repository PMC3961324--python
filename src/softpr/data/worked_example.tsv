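# Six-point worked example: classifier scores with hard class labels and
# soft class weights.  At threshold 1.5 the weighted confusion matrix is
# TP=2.04 FP=0.96 FN=0.83 TN=2.17; the unweighted one is TP=2 FP=1 FN=1 TN=2.
score	label	w_fg	w_bg
2.54	fg	0.9	0.1
2.37	fg	0.92	0.08
1.56	bg	0.22	0.78
1.35	bg	0.07	0.93
0.06	fg	0.67	0.33
-1.08	bg	0.09	0.91
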