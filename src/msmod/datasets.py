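"""Small published reference tables bundled with the package.

These are printed summary statistics (not raw data) from a published
moderation analysis of trait creativity and resting-state microstate
parameters in an undergraduate cohort (n = 334 after screening,
df2 = 329), used as fixed inputs for verifying the multiple-testing
machinery against numbers computed independently of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["creativity_moderation_family"]

# Uncorrected interaction p-values of the 24-test family (4 durations,
# 4 occurrences, 4 contributions, 12 directed transitions) together with
# the published BH-corrected column. The duration_ms2 entry was printed
# only as "< 0.001"; it is stored at 5e-4, and any value at or below
# 0.001 leaves the other 23 adjusted values unchanged because it stays
# first in the sort order.
_FAMILY = [
    # parameter, delta_r2, f_value, p_uncorrected, p_fdr_published
    ("duration_ms1", 0.004, 1.548, 0.214, 0.278),
    ("duration_ms2", 0.046, 17.691, 0.0005, 0.005),
    ("duration_ms3", 0.007, 2.440, 0.119, 0.226),
    ("duration_ms4", 0.007, 2.411, 0.122, 0.226),
    ("occurrence_ms1", 0.014, 5.090, 0.024, 0.082),
    ("occurrence_ms2", 0.002, 0.060, 0.807, 0.807),
    ("occurrence_ms3", 0.022, 8.061, 0.005, 0.030),
    ("occurrence_ms4", 0.012, 4.372, 0.037, 0.111),
    ("contribution_ms1", 0.007, 2.397, 0.123, 0.226),
    ("contribution_ms2", 0.026, 9.598, 0.002, 0.024),
    ("contribution_ms3", 0.003, 1.122, 0.290, 0.316),
    ("contribution_ms4", 0.001, 0.299, 0.585, 0.610),
    ("transition_ms1_ms2", 0.005, 1.623, 0.204, 0.278),
    ("transition_ms1_ms3", 0.004, 1.274, 0.260, 0.297),
    ("transition_ms1_ms4", 0.016, 5.887, 0.016, 0.064),
    ("transition_ms2_ms1", 0.004, 1.514, 0.220, 0.278),
    ("transition_ms2_ms3", 0.004, 1.295, 0.256, 0.297),
    ("transition_ms2_ms4", 0.023, 8.652, 0.004, 0.030),
    ("transition_ms3_ms1", 0.009, 3.178, 0.076, 0.182),
    ("transition_ms3_ms2", 0.006, 2.202, 0.139, 0.226),
    ("transition_ms3_ms4", 0.005, 1.633, 0.202, 0.278),
    ("transition_ms4_ms1", 0.010, 3.739, 0.054, 0.144),
    ("transition_ms4_ms2", 0.018, 6.766, 0.009, 0.047),
    ("transition_ms4_ms3", 0.006, 2.179, 0.141, 0.226),
]


def creativity_moderation_family() -> pd.DataFrame:
    """The published 24-test interaction family as a DataFrame.

    Columns: parameter, delta_r2, f_value, p_uncorrected and the
    published FDR-corrected value (for comparison only — the package
    recomputes the correction from the uncorrected column).
    """
    return pd.DataFrame(
        _FAMILY,
        columns=["parameter", "delta_r2", "f_value", "p_uncorrected", "p_fdr_published"],
    )
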