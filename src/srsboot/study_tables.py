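"""Published per-lesion count tables from the source study.

Contingency tables of progressed vs non-progressed lesion counts,
reconstructed from the study's printed per-category lesion totals and
progression percentages.  Rows are (progressed, not progressed); columns
follow the category order noted per table.  Used by the acceptance
report and tests to recompute the published univariate statistics.
"""

from __future__ import annotations

import numpy as np

TOTAL_BMS = 123

#: primary cancer active: columns (yes, no)
PRIMARY_ACTIVE = np.array([[5, 22], [50, 46]])

#: primary site: columns (lung, breast, renal, colorectal, skin, other)
SITE_TOTALS = np.array([70, 14, 15, 10, 9, 5])
SITE_PROGRESSED = np.array([9, 5, 2, 4, 6, 1])
PRIMARY_SITE = np.vstack([SITE_PROGRESSED, SITE_TOTALS - SITE_PROGRESSED])

#: histology: columns (adenocarcinoma, NSCLC, melanoma, squamous, other)
HISTOLOGY_TOTALS = np.array([65, 36, 9, 8, 5])
HISTOLOGY_PROGRESSED = np.array([13, 4, 6, 4, 0])
HISTOLOGY = np.vstack([HISTOLOGY_PROGRESSED, HISTOLOGY_TOTALS - HISTOLOGY_PROGRESSED])

#: prescription: columns (15Gy/1fx, 18Gy/1fx, 21Gy/1fx, 24Gy/3fx)
PRESCRIPTION_TOTALS = np.array([5, 36, 72, 10])
PRESCRIPTION_PROGRESSED = np.array([0, 11, 10, 6])
PRESCRIPTION = np.vstack(
    [PRESCRIPTION_PROGRESSED, PRESCRIPTION_TOTALS - PRESCRIPTION_PROGRESSED]
)

#: scanner models pooled over acquisition configurations:
#: columns (Vision, Avanto, Expert, Sonata, SignaHDxt)
SCANNER_TOTALS = np.array([39, 45, 29, 9, 1])
SCANNER_PROGRESSED = np.array([11, 5, 9, 2, 0])
SCANNER_ALL = np.vstack([SCANNER_PROGRESSED, SCANNER_TOTALS - SCANNER_PROGRESSED])

#: the three majority scanner models only: columns (Vision, Avanto, Expert)
SCANNER_MAJOR = SCANNER_ALL[:, :3]


def overall_progression_percent() -> float:
    """Overall progression prevalence (%) from the per-site counts."""
    return 100.0 * SITE_PROGRESSED.sum() / TOTAL_BMS
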