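"""Published reference values from the original case-control study this
pipeline models (19 chronic musculoskeletal pain patients vs. 32 healthy
controls performing the three-color balloon task).

These numbers serve two purposes: desk-checkable recomputations (the LOOIC
weights follow exactly from the printed LOOIC values; the t statistics follow
from the printed group summaries), and side-by-side context columns in the
generated report.  Nothing in the estimation code reads them.
"""

from __future__ import annotations

from .behavior_stats import GroupSummary

# LOOIC values per group and model; lower is better.
LOOIC = {
    "control": {"EWMVM": 3251.459, "RFPM": 3298.085},
    "patient": {"EWMVM": 2137.184, "RFPM": 2224.345},
}

# Printed LOOIC (Akaike) weights for the winning EWMVM model.
LOOIC_WEIGHT_EWMVM = {"control": 1.000, "patient": 1.000}

# Adjusted-score group summaries (n, mean, sd) per balloon condition, and the
# printed t/p of the two-tailed between-group comparison.
ADJUSTED_SCORES = {
    "blue": {
        "patient": GroupSummary("patient", 19, 3.27, 0.76),
        "control": GroupSummary("control", 32, 3.09, 1.45),
        "t": 0.53,
        "p": 0.604,
    },
    "green": {
        "patient": GroupSummary("patient", 19, 7.89, 3.00),
        "control": GroupSummary("control", 32, 10.35, 4.56),
        "t": -2.30,
        "p": 0.026,
    },
    "red": {
        "patient": GroupSummary("patient", 19, 18.79, 14.80),
        "control": GroupSummary("control", 32, 20.98, 14.24),
        "t": -0.51,
        "p": 0.609,
    },
}

# Fitted EWMVM group parameter values.  phi is printed in the burst-belief
# convention (prior probability that a pump bursts the balloon); the models
# here parameterize the complementary not-burst belief.
GROUP_PARAMETERS_EWMVM = {
    "patient": {"phi_burst": 0.044, "eta": 0.0016, "gamma": -0.010, "tau": 5.32, "lam": 2.32},
    "control": {"phi_burst": 0.037, "eta": 0.049, "gamma": 0.004, "tau": 6.94, "lam": 2.807},
}

# Channel-wise optical contrast: the deficit localized to channel 4.
FNIRS_CHANNEL4 = {"t": -3.049, "p_uncorrected": 0.0037}
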