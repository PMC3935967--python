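"""Train the quality predictor and re-rank one target's decoy pool.

Trains the weighted SVR on a few generated targets, then ranks a fresh
target's 30 decoys by Z-score (threading only), P-score (predicted quality)
and M-score (combined).  The printed TM column is the true quality of each
selected model -- higher is better; with a noisy raw score the M-score
selection should beat the Z-score selection.
"""

import numpy as np

from meftop import DecoySet, rank_models
from meftop.pipeline import train_on_targets
from meftop.synthetic_fixtures import FixtureSpec, generate_benchmark, make_target

train_targets = generate_benchmark(FixtureSpec(n_targets=5, decoys_per_target=25, seed=10))
scorer = train_on_targets(train_targets)
scorer.config.mscore_weight = 4.0

target = make_target("demo", ["H10", "E6", "E6", "H10", "H8"], seed=99, decoys_per_target=30)
decoys = DecoySet(target.target_id, target.decoys, raw_scores=target.raw_scores,
                  profile=target.profile)
tm = dict(zip([d.model_id for d in target.decoys], target.tm_labels))

print(f"{'metric':8s} {'top pick':12s} {'its true TM':>12s}")
for metric in ("z", "p", "m"):
    best = rank_models(decoys, scorer=scorer, metric=metric)[0]
    print(f"{metric:8s} {best.model_id:12s} {tm[best.model_id]:12.3f}")
best_possible = max(tm.values())
print(f"{'oracle':8s} {'(true best)':12s} {best_possible:12.3f}")
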