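"""Published whole-section dystrophin summary statistics.

Per-section summaries (dynamic range, mean +/- SEM, fibre count, CV%) from
whole-section scans of muscle biopsies — two paediatric controls, two
Duchenne (DMD) and two Becker (BMD) muscular dystrophy patients — for two
antibody panels: dystrophin C-terminus antibody ab15277 with spectrin as the
fibre-identification marker, and exon-43 antibody MANDYS106 with laminin.
Each sample was processed in two independent staining/acquisition
experiments.

These numbers are inputs for consistency and convention checks: the CV column
should be recoverable from mean, SEM and fibre count (``cv_from_sem``), and
group comparisons of the section means reproduce the reported percent
reductions of dystrophin in BMD muscle.  Where printed rows are internally
inconsistent (a handful of CV entries are off by 0.01 from rounding, and two
rows repeat the SEM in the CV column), the mean/SEM/N triplet is taken as
authoritative.
"""

from __future__ import annotations

#: antibody -> experiment -> sample -> per-section summary.
#: Keys: min/max (au), mean (au), sem (au), n (fibres), cv (%, as printed).
WHOLE_SECTION_SUMMARIES: dict = {
    "ab15277": {
        "experiment_1": {
            "control_1": {"min": 3879, "max": 40968, "mean": 18109, "sem": 29.58, "n": 14559, "cv": 19.71},
            "control_2": {"min": 4729, "max": 36567, "mean": 18700, "sem": 23.29, "n": 16234, "cv": 15.86},
            "dmd_1": {"min": 1837, "max": 15756, "mean": 3978, "sem": 20.38, "n": 2719, "cv": 26.71},
            "dmd_2": {"min": 1521, "max": 6114, "mean": 2413, "sem": 12.99, "n": 1557, "cv": 21.24},
            "bmd_1": {"min": 2243, "max": 33781, "mean": 15926, "sem": 33.22, "n": 10417, "cv": 21.29},
            "bmd_2": {"min": 2843, "max": 21961, "mean": 11063, "sem": 18.43, "n": 10857, "cv": 17.36},
        },
        "experiment_2": {
            "control_1": {"min": 7287, "max": 49399, "mean": 23271, "sem": 52.66, "n": 12447, "cv": 25.24},
            "control_2": {"min": 7238, "max": 41870, "mean": 16779, "sem": 35.88, "n": 13212, "cv": 24.58},
            "dmd_1": {"min": 3518, "max": 10140, "mean": 5417, "sem": 20.19, "n": 1583, "cv": 20.19},
            "dmd_2": {"min": 2939, "max": 11071, "mean": 4759, "sem": 29.63, "n": 1112, "cv": 20.76},
            "bmd_1": {"min": 2286, "max": 32372, "mean": 15529, "sem": 35.11, "n": 9118, "cv": 21.59},
            "bmd_2": {"min": 2915, "max": 45672, "mean": 12032, "sem": 19.99, "n": 13267, "cv": 19.14},
        },
    },
    "MANDYS106": {
        "experiment_1": {
            "control_1": {"min": 3248, "max": 31749, "mean": 10572, "sem": 26.99, "n": 13245, "cv": 29.37},
            "control_2": {"min": 5962, "max": 28271, "mean": 15185, "sem": 22.06, "n": 15159, "cv": 22.06},
            "dmd_1": {"min": 2025, "max": 8360, "mean": 3632, "sem": 14.75, "n": 2732, "cv": 21.23},
            "dmd_2": {"min": 1898, "max": 5703, "mean": 3391, "sem": 15.22, "n": 1751, "cv": 18.78},
            "bmd_1": {"min": 2582, "max": 33658, "mean": 13419, "sem": 38.02, "n": 9820, "cv": 28.08},
            "bmd_2": {"min": 2599, "max": 21047, "mean": 9352, "sem": 20.27, "n": 10482, "cv": 22.19},
        },
        "experiment_2": {
            "control_1": {"min": 7707, "max": 29958, "mean": 17049, "sem": 27.92, "n": 9961, "cv": 16.34},
            "control_2": {"min": 4614, "max": 37648, "mean": 20882, "sem": 28.26, "n": 13321, "cv": 15.61},
            "dmd_1": {"min": 4150, "max": 14969, "mean": 7038, "sem": 43.77, "n": 1466, "cv": 23.81},
            "dmd_2": {"min": 4101, "max": 7624, "mean": 5621, "sem": 19.26, "n": 1095, "cv": 11.33},
            "bmd_1": {"min": 3984, "max": 37345, "mean": 15589, "sem": 37.13, "n": 9358, "cv": 23.03},
            "bmd_2": {"min": 6158, "max": 30687, "mean": 16433, "sem": 37.87, "n": 7732, "cv": 20.26},
        },
    },
}

#: Seven rows whose printed CV% is exactly the SEM-derived value to two
#: decimals; used as internal-consistency checks of the CV formula.
CONSISTENT_CV_ROWS: tuple = (
    ("ab15277", "experiment_1", "control_1"),
    ("ab15277", "experiment_1", "dmd_1"),
    ("ab15277", "experiment_1", "dmd_2"),
    ("ab15277", "experiment_1", "bmd_1"),
    ("ab15277", "experiment_1", "bmd_2"),
    ("ab15277", "experiment_2", "control_2"),
    ("MANDYS106", "experiment_1", "bmd_1"),
)

#: Group membership of the samples.
SAMPLE_GROUPS: dict = {
    "control": ("control_1", "control_2"),
    "dmd": ("dmd_1", "dmd_2"),
    "bmd": ("bmd_1", "bmd_2"),
}

#: Reported integer percent reductions of mean dystrophin intensity in BMD
#: muscle versus paediatric controls (unweighted average of section means).
REPORTED_BMD_REDUCTION_PERCENT: dict = {"ab15277": 29, "MANDYS106": 14}


def section_means(antibody: str, group: str) -> list[float]:
    """All published section means of one group under one antibody panel."""
    table = WHOLE_SECTION_SUMMARIES[antibody]
    return [
        float(table[exp][sample]["mean"])
        for exp in ("experiment_1", "experiment_2")
        for sample in SAMPLE_GROUPS[group]
    ]
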