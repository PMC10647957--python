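"""Unsupervised training of a small localization network.

Trains on a few synthetic pairs with the negated-MI loss (no ground-truth
transforms are ever shown to the network) and then registers one of the
pairs in a single forward pass.
"""

import numpy as np

from mireg import (MILossConfig, NetworkConfig, TrainConfig, register_pair,
                   train)
from mireg.benchmark import make_benchmark_pairs, _downsample

pairs = make_benchmark_pairs(n_pairs=6, size=128, seed=5)
small = [(_downsample(f), _downsample(m)) for f, m, _ in pairs]

cfg = TrainConfig(learning_rate=3e-4, epochs=120, batch_size=4, seed=5,
                  loss=MILossConfig(n_bins=32))
net_cfg = NetworkConfig(input_size=(64, 64), conv_filters=(8, 16, 16, 16, 16))
net, history = train(small, net_cfg, cfg)
print("training loss: %.3f -> %.3f bits (negated MI + bending penalty)"
      % (history.train_loss[0], history.train_loss[-1]))

fixed, moving = small[0]
truth = pairs[0][2]
warped, params, field = register_pair(net, fixed, moving)
# translations live in grid pixels: at the 2x-downsampled resolution the
# true translation is half its 128-grid value (the linear part carries over)
truth_64 = truth.params.as_array() * [1, 1, 1, 1, 0.5, 0.5]
print("one-shot prediction:", np.round(params.as_array(), 3))
print("ground truth       :", np.round(truth_64, 3))
print("field shape %s; mean |displacement| %.2f px"
      % (field.shape, np.sqrt((field ** 2).sum(-1)).mean()))
# A falling (more negative) loss means the network's warps raise the MI
# between the fixed images and its warped moving images across the corpus.
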