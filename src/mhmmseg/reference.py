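"""Worked-example similarity map for one cross-sectional ray.

An 18-sample ray that starts in the lumen, crosses the intima into a
calcified plaque and ends in the adventitia, together with the posterior
state probabilities P(T | phi, F') a single-feature HMM assigns to each
sample. Used in examples and as a fixed decoding check: the position-wise
argmax must reproduce the annotated state column.
"""

from __future__ import annotations

import numpy as np

from .rays import STATE_NAMES

__all__ = ["EXAMPLE_SIMILARITY_MAP", "EXAMPLE_STATES", "EXAMPLE_STATE_NAMES"]

#: columns: P(lumen), P(intima), P(pathology), P(adventitia) per ray sample.
EXAMPLE_SIMILARITY_MAP = np.array([
    [0.943, 0.055, 0.002, 0.000],
    [0.901, 0.098, 0.001, 0.000],
    [0.842, 0.153, 0.004, 0.001],
    [0.801, 0.195, 0.002, 0.002],
    [0.744, 0.254, 0.001, 0.001],
    [0.706, 0.290, 0.002, 0.002],
    [0.301, 0.593, 0.101, 0.005],
    [0.001, 0.643, 0.151, 0.205],
    [0.007, 0.301, 0.572, 0.120],
    [0.001, 0.165, 0.732, 0.102],
    [0.002, 0.044, 0.812, 0.142],
    [0.001, 0.020, 0.509, 0.470],
    [0.001, 0.006, 0.401, 0.592],
    [0.002, 0.002, 0.303, 0.693],
    [0.001, 0.001, 0.265, 0.733],
    [0.001, 0.002, 0.115, 0.882],
    [0.000, 0.001, 0.109, 0.890],
    [0.000, 0.000, 0.043, 0.957],
])

#: annotated state per sample: 6x lumen, 2x intima, 4x pathology, 6x adventitia.
EXAMPLE_STATES = np.array([0] * 6 + [1] * 2 + [2] * 4 + [3] * 6)

EXAMPLE_STATE_NAMES = STATE_NAMES
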