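"""Published benchmark confusion matrices for lower-limb motion recognition.

Row-normalized percentage confusion matrices (rows = true class, columns =
predicted class) reported for a wearable FES-sEMG recognition system: the
HHT-image dual-task network and the four-time-domain-feature LDA baseline,
both evaluated on balanced six-motion test data. They serve as reference
inputs for :func:`fessemg.evaluation.metrics_from_normalized`, which
reproduces the system's published per-class precision/recall/F1 and overall
accuracy (93.33% for the network, 87.08% for the LDA baseline) by arithmetic
alone.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix
from .labels import MOTIONS

#: HHT-image dual-task network, motion task (row-normalized, percent)
HHT_NET_MOTION = ConfusionMatrix(
    matrix=np.array([
        [97.3, 0.9, 0.6, 0.5, 0.4, 0.3],
        [2.2, 94.8, 2.3, 0.1, 0.1, 0.5],
        [0.7, 1.7, 92.4, 1.9, 2.6, 0.7],
        [1.7, 0.9, 1.7, 91.3, 3.2, 1.2],
        [2.4, 1.0, 2.2, 2.5, 90.8, 1.1],
        [0.5, 1.8, 1.5, 1.3, 1.6, 93.3],
    ]),
    class_labels=list(MOTIONS),
    normalized=True,
)

#: four time-domain features + LDA baseline, motion task
TDF_LDA_MOTION = ConfusionMatrix(
    matrix=np.array([
        [90.7, 2.1, 1.9, 2.1, 1.9, 1.3],
        [2.6, 89.9, 2.5, 1.9, 1.4, 1.7],
        [2.5, 3.2, 85.6, 2.8, 3.1, 2.8],
        [2.9, 3.2, 2.6, 83.7, 4.7, 2.9],
        [3.7, 1.8, 3.9, 3.9, 84.9, 1.8],
        [2.2, 3.1, 1.9, 2.2, 2.9, 87.7],
    ]),
    class_labels=list(MOTIONS),
    normalized=True,
)
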