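"""Shared fixtures: fast-profile phantoms and trained U-nets.

Everything is generated at run time from seeds; no stored image data.
``reference_run`` is the full 200-slice / 40-epoch training protocol — it
is expensive (minutes), so every test needing a *well-trained* network
shares the one session instance; ``small_model`` is a seconds-scale run
used only where prediction quality is not asserted.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiomorph import phantom, unet
from cardiomorph.containers import CineSequence


@pytest.fixture(scope="session")
def fast_params():
    """Default 4-dpf phantom at the 4 μm fast pitch."""
    return phantom.preset(4, pitch=4.0)


@pytest.fixture(scope="session")
def fast_truth_cine(fast_params):
    """Ground-truth chamber maps for one full cycle (no rendering)."""
    n = fast_params.frames_per_cycle
    frames = [phantom.make_truth(fast_params, k) for k in range(n)]
    return CineSequence(frames, fast_params.frame_interval, fast_params.period)


@pytest.fixture(scope="session")
def reference_run():
    """The standard training protocol: 200 phantom slices (128×128, fast
    profile), 80/20 split, reduced U-net, 40 epochs of Adam at lr 1e-3.

    Returns (model, held-out Dice scores, loss history).
    """
    from cardiomorph.mechanics import dice

    images, masks = phantom.training_slices(range(200), size=128, pitch=4.0)
    idx_train, idx_val = unet.split_train_val(list(range(200)), 0.8, seed=0)
    model = unet.build_unet(unet.UNetSpec.reduced(), seed=0)
    tspec = unet.TrainSpec(epochs=40, batch_size=8, learning_rate=1e-3, seed=0)
    model, history = unet.train(model, images[idx_train], masks[idx_train], tspec)
    scores = np.array(
        [dice(unet.predict(model, images[i]) >= 0.5, masks[i] > 0) for i in idx_val]
    )
    return model, scores, history


@pytest.fixture(scope="session")
def small_model():
    """A quickly trained U-net for plumbing tests (no quality contract)."""
    images, masks = phantom.training_slices(range(24))
    model = unet.build_unet(unet.UNetSpec.reduced(), seed=0)
    spec = unet.TrainSpec(epochs=10, batch_size=8, learning_rate=1e-3, seed=0)
    model, history = unet.train(model, images, masks, spec)
    return model, history
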