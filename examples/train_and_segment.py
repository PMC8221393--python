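"""Train the reduced U-net on randomized phantom slices and evaluate it.

A demonstration run (96 slices, 30 epochs, a few minutes on one CPU core);
the full protocol in scripts/acceptance.py uses 200 slices and 40 epochs.
"""

import numpy as np

from cardiomorph import mechanics, phantom, unet

images, masks = phantom.training_slices(range(96))
train_idx, val_idx = unet.split_train_val(list(range(96)), 0.8, seed=0)

model = unet.build_unet(unet.UNetSpec.reduced(), seed=0)
tspec = unet.TrainSpec(epochs=30, batch_size=8, learning_rate=1e-3, seed=0)
model, history = unet.train(model, images[train_idx], masks[train_idx], tspec)
print(f"loss: {history[0]:.4f} (first epoch) -> {history[-1]:.4f} (last)")

preds = np.stack(
    [unet.threshold(unet.predict(model, images[i])) for i in val_idx]
)
truths = np.stack([masks[i] > 0 for i in val_idx])
per_slice = [mechanics.dice(p, t) for p, t in zip(preds, truths)]
print(f"held-out Dice over {len(per_slice)} slices: "
      f"per-slice mean {np.mean(per_slice):.3f}, pooled {mechanics.dice(preds, truths):.3f}")
print("(per-slice Dice is heavy-tailed: slices cutting the heart's poles")
print(" have tiny or empty lumens; the pooled score weights pixels equally)")
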