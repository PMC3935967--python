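"""Scaled-down low-confidence ("dawn region") re-ranking experiment.

Generates disjoint train/validation/test targets whose raw threading scores
are heavily corrupted, fits the SVR quality predictor, selects the M-score
weight on validation, and compares selection metrics on the held-out
targets.  Expect the Z-score row (threading alone) to show a low Top1% and a
poor average rank, and the M-score row to recover most of the gap to the
P-score row.  The full-scale version of this experiment is what
scripts/acceptance.py runs.
"""

from meftop import run_dawn_region_experiment

result = run_dawn_region_experiment(n_train=8, n_val=4, n_test=10,
                                    decoys_per_target=25, seed=5)
print(result.summary())
print("""
columns: Top1% = share of targets whose top-ranked model is native-like
(TM > 0.4); avg_rank = mean true-quality rank of the selected model;
mean_cc = per-target Pearson correlation between the metric and true TM.""")
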