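"""Bundled demonstration inputs.

The demographics table of the four-group artist cohort (controls, painters,
dancers, pianists) is shipped as printed summary statistics — means, SDs and
group sizes for age and years of artistic training, plus gender counts — so
the summary-statistic tests in :mod:`rsfcnet.stats` can be exercised on a
real demographic table without any participant-level data.
"""

from __future__ import annotations

import numpy as np

from .stats import SummaryStat

GROUP_NAMES = ["control", "painter", "dancer", "pianist"]

# gender counts (male, female) per group, in GROUP_NAMES order
GENDER_COUNTS = np.array([[12, 15], [12, 16], [13, 17], [12, 17]])

# group sizes after exclusions = male + female counts
GROUP_SIZES = {name: int(row.sum()) for name, row in zip(GROUP_NAMES, GENDER_COUNTS)}

AGE_SUMMARY = {
    "control": SummaryStat(mean=24.5, sd=3.1, n=27),
    "painter": SummaryStat(mean=23.0, sd=2.5, n=28),
    "dancer": SummaryStat(mean=19.7, sd=2.1, n=30),
    "pianist": SummaryStat(mean=21.8, sd=2.1, n=29),
}

TRAINING_YEARS_SUMMARY = {
    "painter": SummaryStat(mean=11.3, sd=4.1, n=28),
    "dancer": SummaryStat(mean=11.2, sd=3.8, n=30),
    "pianist": SummaryStat(mean=15.9, sd=2.4, n=29),
}
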