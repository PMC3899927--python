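"""Small bundled example data.

The worked example is a published 10 control + 10 test excerpt of log2
intensities for two genes measured on an Agilent one-color array
(SurePrint design 028004_D_F_20101102): MACF1, a small-fold-change /
small-variance gene whose t-test is significant although its fold change
is near 1, and TREM2, a large-fold-change / large-variance gene whose
t-test is weak although it is clearly up-regulated.  The pair illustrates
why fold-change-based ranking and t-type testing can disagree.
"""

from __future__ import annotations

import numpy as np

from .matrix import ExpressionMatrix, from_groups

MACF1_CONTROL = np.array([
    11.1435, 11.2860, 11.2249, 11.1258, 11.0325,
    11.1108, 11.3377, 11.1821, 11.0675, 11.2381,
])
MACF1_TEST = np.array([
    11.0375, 11.0792, 10.9673, 11.0367, 11.1054,
    10.9261, 11.0433, 10.9484, 10.9412, 10.8385,
])
TREM2_CONTROL = np.array([
    6.2856, 6.4891, 5.7799, 6.1081, 6.3129,
    6.3208, 6.4826, 6.2005, 5.8922, 6.2148,
])
TREM2_TEST = np.array([
    11.6792, 8.1128, 6.6253, 6.8334, 7.6417,
    7.5133, 5.9633, 7.4631, 6.5666, 7.6020,
])


def worked_example() -> ExpressionMatrix:
    """Two-gene, 10+10-sample log2-intensity matrix (MACF1, TREM2)."""
    return from_groups(
        ["MACF1", "TREM2"],
        np.vstack([MACF1_CONTROL, TREM2_CONTROL]),
        np.vstack([MACF1_TEST, TREM2_TEST]),
    )
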