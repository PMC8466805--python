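"""Published inputs from the CFPS-2018 rural-child insurance study.

These are the printed group-level numbers the package treats as inputs:
the descriptive-table group means by enrollment arm and the sample
bookkeeping counts.  They let the descriptive arithmetic (control-minus-
treatment differences, enrollment share) be recomputed without access to
the restricted microdata.
"""

#: (treatment-group mean, control-group mean) per variable, as printed
TABLE1_GROUP_MEANS = {
    "whz": (-0.185, -0.376),
    "waz": (0.022, -0.091),
    "haz": (0.020, -0.069),
    "bmi": (18.283, 18.944),
    "child_gender": (0.539, 0.501),
    "child_age": (7.813, 5.765),
    "mother_age": (34.211, 32.694),
    "mother_education": (2.676, 3.057),
    "log_income_pc": (8.994, 9.079),
    "living_area": (0.332, 0.455),
    "region": (2.047, 1.816),
}

#: enrollment bookkeeping: insured / uninsured children
N_TREATED = 4760
N_CONTROL = 792

#: rows whose printed differences are exactly consistent with the printed
#: means (the remaining rows were evidently computed on unrounded data)
EXACT_DIFFERENCE_ROWS = [
    "whz",
    "bmi",
    "child_age",
    "mother_age",
    "mother_education",
    "log_income_pc",
    "living_area",
]
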