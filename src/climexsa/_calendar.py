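"""Climatological calendar constants shared by the climate and hydrology
modules: a 365-day year of monthly normals resampled onto a 52 x 7-day week
grid."""

import numpy as np

#: Days per month of a 365-day climatological year.
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: Cumulative day at the midpoint of each month (day 0 = Jan 1).
MONTH_MIDPOINTS = (
    np.cumsum(np.concatenate([[0], DAYS_IN_MONTH[:-1]])) + DAYS_IN_MONTH / 2.0
)
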