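"""Synthetic reconstructions of the study's sample conditions.

These presets encode the reported molar compositions, labeling levels and
DNP enhancements for Brachypodium root samples as generator inputs, so the
analysis chain can be exercised end-to-end on synthetic data with known
ground truth.  They are *synthetic reconstructions*: fractions not reported
for a condition were completed so each composition sums to 1 while
preserving the reported values and fold changes.
"""

from __future__ import annotations

from .synth import SampleModel

#: Molar composition (fraction) of the 13C-labeled lignin per
#: (genotype, precursor) root condition.
STUDY_COMPOSITIONS: dict[tuple[str, str], dict[str, float]] = {
    ("WT", "Phe"): {"G": 0.52, "S": 0.20, "H": 0.10, "FA": 0.18, "pCA": 0.0},
    ("C3H", "Phe"): {"G": 0.39, "S": 0.19, "H": 0.10, "FA": 0.32, "pCA": 0.0},
    ("WT", "Tyr"): {"G": 0.40, "S": 0.20, "H": 0.10, "FA": 0.30, "pCA": 0.0},
    ("C3H", "Tyr"): {"G": 0.40, "S": 0.15, "H": 0.26, "FA": 0.19, "pCA": 0.0},
}

#: 13C-labeling fraction of labelable lignin carbons per root condition.
STUDY_LABELING: dict[tuple[str, str], float] = {
    ("WT", "Phe"): 0.31,
    ("WT", "Tyr"): 0.13,
    ("C3H", "Phe"): 0.21,
    ("C3H", "Tyr"): 0.12,
}

#: DNP enhancement factors (on/off) observed per root condition.
STUDY_EPSILON: dict[tuple[str, str], float] = {
    ("WT", "Phe"): 11.0,
    ("WT", "Tyr"): 8.0,
    ("C3H", "Phe"): 42.0,
    ("C3H", "Tyr"): 18.0,
}

#: G/FA : S area splits from two-component deconvolution of WT roots.
STUDY_GS_SPLIT: dict[str, tuple[float, float]] = {
    "Phe": (87.0, 13.0),
    "Tyr": (71.0, 29.0),
}


def study_model(
    genotype: str, precursor: str, tissue: str = "root", **overrides
) -> SampleModel:
    """Sample model for a study condition (root tissue only)."""
    key = (genotype, precursor)
    if key not in STUDY_COMPOSITIONS:
        raise KeyError(f"no preset for genotype={genotype!r} precursor={precursor!r}")
    params = {
        "composition": STUDY_COMPOSITIONS[key],
        "labeling_fraction": STUDY_LABELING[key],
        "genotype": genotype,
        "precursor": precursor,
        "tissue": tissue,
    }
    params.update(overrides)
    return SampleModel(**params)


def control_model(genotype: str = "WT", tissue: str = "root", **overrides) -> SampleModel:
    """Unlabeled control: everything at natural abundance (p = 0)."""
    params = {
        "composition": STUDY_COMPOSITIONS[("WT", "Phe")],
        "labeling_fraction": 0.0,
        "genotype": genotype,
        "precursor": "",
        "tissue": tissue,
    }
    params.update(overrides)
    return SampleModel(**params)
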