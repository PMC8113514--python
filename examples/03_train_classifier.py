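"""Step 2 at desk scale: train the 3D-CNN and the logistic baseline.

Labeled crossings come from two phantom videos; blocks are shortened to
64 frames here so the example runs in about a minute — the canonical
16x16x200 geometry is exercised by the full benchmark
(microflow.benchmark.parameter_recovery).
"""

import numpy as np

from microflow import benchmark
from microflow import flow_classifier as fc

crossings = benchmark.crossing_dataset(n_videos=2, seed=11, n_frames=80, block_frames=64)
print(f"{len(crossings)} labeled crossings from 2 phantoms")

rng = np.random.default_rng(0)
order = rng.permutation(len(crossings))
train, test = order[: int(0.7 * len(order))], order[int(0.7 * len(order)):]

blocks = np.concatenate([crossings[i].blocks for i in train])
labels = np.concatenate([[int(crossings[i].label)] * len(crossings[i].blocks) for i in train])
print(f"training on {len(blocks)} pixel blocks of shape {blocks.shape[1:]}")

config = fc.CNNConfig(input_shape=blocks.shape[1:], max_epochs=8, seed=0)
model, history = fc.train_cnn(blocks, labels, config)
print("per-epoch training loss :", [round(l, 3) for l in history.loss])
print("per-epoch error rate    :", [round(e, 3) for e in history.error_rate])

baseline = fc.train_logistic_baseline(blocks, labels, seed=0)

correct = base_correct = 0
for i in test:
    truth = crossings[i].label
    correct += fc.decide_vessel(model.predict_proba(crossings[i].blocks)).vessel_flowing == truth
    base_correct += fc.decide_vessel(baseline.predict_proba(crossings[i].blocks)).vessel_flowing == truth
print(f"held-out vessel-level accuracy: CNN {correct / len(test):.2f}, "
      f"logistic baseline {base_correct / len(test):.2f} (n={len(test)})")
print("the majority rule aggregates per-pixel probabilities per crossing")
print("(at this miniature scale the CNN/baseline ordering can fluctuate; "
      "microflow.benchmark.parameter_recovery runs the ~300-crossing version)")
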