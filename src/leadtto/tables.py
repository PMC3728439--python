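"""Published summary statistics used as packaged inputs.

These are the per-state summary statistics, arm counts and exclusion counts
printed in the source study's results tables (two general-population samples,
one testing a lead-time contrast, one a visual-aid contrast).  The raw
respondent-level data were never deposited, so these printed aggregates are
the only real-data inputs available: they seed the aggregate cross-arm
regression, the grand-mean and proportion checks, and the simulator's
default state means.
"""

from __future__ import annotations

# The ten EQ-5D-5L states, in the two five-state blocks respondents were
# randomized to.
BLOCK_1 = ("12112", "52221", "33133", "44113", "53555")
BLOCK_2 = ("21111", "11221", "52324", "55523", "11145")
ALL_STATES = tuple(sorted(BLOCK_1 + BLOCK_2))

# Per-state mean (SD) TTO values by study arm.
# Lead-time contrast sample: standard arm LT=10/UT=5, experimental LT=5/UT=5.
CHINA_TABLE3 = {
    "11145": {"standard": (0.32, 0.60), "experimental": (0.41, 0.42)},
    "11221": {"standard": (0.49, 0.53), "experimental": (0.59, 0.41)},
    "12112": {"standard": (0.50, 0.50), "experimental": (0.53, 0.47)},
    "21111": {"standard": (0.50, 0.56), "experimental": (0.60, 0.42)},
    "33133": {"standard": (0.32, 0.59), "experimental": (0.43, 0.46)},
    "44113": {"standard": (0.36, 0.54), "experimental": (0.34, 0.46)},
    "52221": {"standard": (0.38, 0.60), "experimental": (0.47, 0.46)},
    "52324": {"standard": (0.22, 0.66), "experimental": (0.37, 0.43)},
    "53555": {"standard": (0.19, 0.64), "experimental": (0.34, 0.46)},
    "55523": {"standard": (0.20, 0.63), "experimental": (0.24, 0.51)},
}

# Visual-aid contrast sample: both arms LT=10/UT=5; experimental arm shows
# the unhealthy-time bar raised.
SINGAPORE_TABLE3 = {
    "11145": {"standard": (0.14, 0.72), "experimental": (0.04, 0.75)},
    "11221": {"standard": (0.49, 0.60), "experimental": (0.60, 0.49)},
    "12112": {"standard": (0.57, 0.58), "experimental": (0.46, 0.71)},
    "21111": {"standard": (0.56, 0.63), "experimental": (0.68, 0.48)},
    "33133": {"standard": (0.32, 0.66), "experimental": (0.36, 0.70)},
    "44113": {"standard": (0.02, 0.81), "experimental": (0.15, 0.74)},
    "52221": {"standard": (0.08, 0.74), "experimental": (0.26, 0.69)},
    "52324": {"standard": (0.06, 0.74), "experimental": (0.05, 0.79)},
    "53555": {"standard": (-0.14, 0.84), "experimental": (-0.11, 0.74)},
    "55523": {"standard": (-0.13, 0.82), "experimental": (-0.21, 0.81)},
}

# Task counts and counts of non-negative values per arm (Better-than-dead
# "Yes" rows), and counts of trade-time exhaustion.
TASK_COUNTS = {
    "china": {"standard": 964, "experimental": 870},
    "singapore": {"standard": 972, "experimental": 919},
}
NONNEGATIVE_COUNTS = {
    "china": {"standard": 783, "experimental": 754},
    "singapore": {"standard": 754, "experimental": 743},
}
EXHAUSTION_COUNTS = {
    "china": {"standard": 0, "experimental": 4},
    "singapore": {"standard": 21, "experimental": 21},
}

# Exclusion accounting: participants completing the survey, participants who
# gave all five states the same value, and tasks completed within 1 s.
EXCLUSION_COUNTS = {
    "china": {"n_participants": 406, "n_allsame": 38, "n_fast_tasks": 6},
    "singapore": {"n_participants": 407, "n_allsame": 28, "n_fast_tasks": 4},
}

# Participants retained per arm.
ARM_SIZES = {
    "china": {"standard": 194, "experimental": 174},
    "singapore": {"standard": 195, "experimental": 184},
}

STATES_PER_RESPONDENT = 5


def table3_pairs(study: str = "china"):
    """(experimental mean, standard mean) per state, for the aggregate fit."""
    table = CHINA_TABLE3 if study == "china" else SINGAPORE_TABLE3
    states = sorted(table)
    x = [table[s]["experimental"][0] for s in states]
    y = [table[s]["standard"][0] for s in states]
    return states, x, y


def state_means(study: str = "china", arm: str = "experimental"):
    """Per-state mean values for one arm, as a dict state -> mean."""
    table = CHINA_TABLE3 if study == "china" else SINGAPORE_TABLE3
    return {s: table[s][arm][0] for s in table}
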