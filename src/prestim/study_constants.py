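"""Published group-level summary statistics and design constants.

These are the printed inputs to the summary-statistic analyses: group
sizes, recognition-sensitivity and rate summaries per cohort, and the
stimulation design parameters.  The no-entrainment (NE) cohort comes from
an earlier study with a static pre-stimulus fixation cross.
"""

import math

GROUP_SIZE = 35

#: d' mean and SD per cohort (recognition sensitivity).
DPRIME_SUMMARY = {
    "theta": (1.28, 0.55),
    "alpha": (1.46, 0.60),
    "control": (1.18, 0.50),
    "ne": (1.27, 0.53),
}

#: Hit-rate summaries in percent.
HIT_RATE_SUMMARY = {
    "alpha": (61.498, 14.443),
    "control": (49.792, 15.029),
    "ne": (52.662, 13.724),
}

#: False-alarm-rate summaries in percent.
FA_RATE_SUMMARY = {
    "alpha": (13.9, 6.67),
    "control": (13.0, 5.73),
    "ne": (12.8, 6.1),
}

#: JZS prior scale ("medium" Cauchy width).
PRIOR_SCALE = math.sqrt(2.0) / 2.0

# Design constants
STIM_FREQUENCIES = {"theta": 5.0, "alpha": 9.0}
FRAME_RATE = 240.0
ENCODING_TRIALS_PER_RUN = 47
RUNS = 3
ENCODING_TRIALS_TOTAL = RUNS * ENCODING_TRIALS_PER_RUN      # 141
RECOGNITION_TRIALS_TOTAL = 2 * ENCODING_TRIALS_TOTAL        # 282
SEQUENTIAL_K_START = 15
SEQUENTIAL_K_MAX = 35
BF_THRESHOLDS = (3.0, 1.0 / 3.0)
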