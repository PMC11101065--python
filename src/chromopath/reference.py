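"""Reference cohort statistics for H&E breast-pathology image classification.

These are the reported class-conditional feature summaries and fitted model
coefficients from a 2,723-image institutional cohort of H&E-stained breast
sections (2,214 infiltrating ductal carcinoma, 509 benign adenosis /
fibroadenoma).  The slide set itself is not public, so these summaries serve
two roles here: they parameterize the synthetic-data generator's default
class-conditional distributions, and they provide fixed inputs for
consistency checks (reproducing the cohort's t statistics from its summary
cells, and its odds-ratio table from its coefficients).

Channel means are in intensity units (0-255); entropy is in bits.
"""

from __future__ import annotations

FEATURES = ("avg_r", "avg_g", "avg_b", "entropy")

#: Full-cohort class-conditional summaries: n, mean, SD per feature.
COHORT_SUMMARY = {
    "malignant": {
        "n": 2214,
        "mean": {"avg_r": 219.969, "avg_g": 202.0238, "avg_b": 220.340, "entropy": 5.425},
        "sd": {"avg_r": 5.137, "avg_g": 13.060, "avg_b": 8.827, "entropy": 0.573},
    },
    "benign": {
        "n": 509,
        "mean": {"avg_r": 226.308, "avg_g": 219.060, "avg_b": 228.996, "entropy": 4.146},
        "sd": {"avg_r": 6.265, "avg_g": 17.180, "avg_b": 7.237, "entropy": 0.984},
    },
}

#: Reported full-cohort t statistics (benign-minus-malignant convention).
COHORT_T = {"avg_r": 24.031, "avg_g": 24.893, "avg_b": 20.591, "entropy": -38.890}

#: Training-partition (70%) class-conditional summaries.
TRAINING_SUMMARY = {
    "malignant": {
        "n": 1541,
        "mean": {"avg_r": 219.908, "avg_g": 201.866, "avg_b": 220.278, "entropy": 5.430},
        "sd": {"avg_r": 5.226, "avg_g": 13.183, "avg_b": 8.825, "entropy": 0.579},
    },
    "benign": {
        "n": 366,
        "mean": {"avg_r": 226.730, "avg_g": 220.272, "avg_b": 229.530, "entropy": 4.084},
        "sd": {"avg_r": 5.965, "avg_g": 16.253, "avg_b": 6.650, "entropy": 0.958},
    },
}

#: Reported training-partition t statistics (malignant-minus-benign).
TRAINING_T = {"avg_r": -21.825, "avg_g": -22.896, "avg_b": -18.825, "entropy": 34.653}

#: Reported multivariable logistic coefficients (malignant = 1): the final
#: model keeps the red channel, blue channel and entropy; green was dropped
#: during selection.  ``se`` are the reported standard errors.
REFERENCE_MODEL = {
    "const": {"beta": -47.265, "se": 6.657},
    "avg_r": {"beta": 0.226, "se": 0.032},
    "avg_b": {"beta": -0.073, "se": 0.018},
    "entropy": {"beta": 2.998, "se": 0.201},
}

#: Reported odds-ratio table for the model above.
REFERENCE_OR = {
    "avg_r": {"or": 1.254, "ci": (1.178, 1.335)},
    "avg_b": {"or": 0.930, "ci": (0.898, 0.963)},
    "entropy": {"or": 20.047, "ci": (13.523, 29.718)},
}


def reference_coefficients() -> dict[str, float]:
    """The reference model as a plain {name: beta} map (incl. ``const``)."""
    return {k: v["beta"] for k, v in REFERENCE_MODEL.items()}
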