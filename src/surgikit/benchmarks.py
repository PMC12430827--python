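"""Published per-class benchmark figures for two real-time detectors.

Per-class precision, sensitivity and F1 (all in percent) reported for the
RTMDet and PP-YOLOE detectors on a ten-class gynecological-laparoscopic
instrument test set, plus the summary figures of an external validation
set from an independent center. These printed values are inputs for the
aggregation arithmetic in :mod:`surgikit.evaluation` (macro averages, the
two F1 conventions); they are not produced by this package.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .evaluation import ClassMetrics, MetricsReport, aggregate
from .records import DEFAULT_LABELS

#: class name -> (precision %, sensitivity %, F1 %)
PerClassTable = Dict[str, Tuple[float, float, float]]

RTMDET_TEST_SET: PerClassTable = {
    "bipolar_forceps_1": (95.49, 97.15, 96.31),
    "bipolar_forceps_2": (94.41, 92.39, 93.39),
    "hook_electrode_monopolar": (88.35, 94.11, 91.14),
    "needle_holder": (94.94, 97.04, 95.98),
    "ultrasound_knife": (95.89, 98.32, 97.09),
    "grasping_forceps": (90.19, 97.16, 93.55),
    "scissors": (89.23, 93.41, 91.27),
    "suction_irrigation_tube": (77.44, 95.08, 85.36),
    "myoma_grasping_forceps": (99.26, 81.71, 89.63),
    "myoma_drill": (92.32, 96.56, 94.39),
}

PPYOLOE_TEST_SET: PerClassTable = {
    "bipolar_forceps_1": (93.21, 96.33, 94.74),
    "bipolar_forceps_2": (92.55, 93.12, 92.83),
    "hook_electrode_monopolar": (89.11, 90.35, 89.73),
    "needle_holder": (92.77, 95.13, 93.94),
    "ultrasound_knife": (96.32, 97.55, 96.93),
    "grasping_forceps": (89.03, 95.49, 92.15),
    "scissors": (89.91, 94.15, 91.98),
    "suction_irrigation_tube": (79.01, 90.76, 84.48),
    "myoma_grasping_forceps": (91.11, 83.88, 87.35),
    "myoma_drill": (93.55, 93.74, 93.64),
}

#: External-validation summary (%, macro precision / sensitivity); the
#: independent center lacked two instrument classes, so its macro averages
#: run over eight defined classes.
EXTERNAL_VALIDATION_SUMMARY = {"macro_precision": 87.57, "macro_sensitivity": 93.37}


def table_to_class_metrics(table: PerClassTable) -> List[ClassMetrics]:
    """Convert a printed percent table to ClassMetrics fractions.

    The printed F1 column is carried as-is (divided by 100) so that
    mean-of-F1 aggregation reproduces the printed summary row rather than
    recomputing F1 from rounded precision/sensitivity.
    """
    out = []
    for name, (p, s, f1) in table.items():
        out.append(
            ClassMetrics(DEFAULT_LABELS.id_of(name), p / 100.0, s / 100.0, f1 / 100.0)
        )
    return out


def aggregate_table(table: PerClassTable) -> MetricsReport:
    """Macro-aggregate a printed per-class table (result as fractions)."""
    return aggregate(table_to_class_metrics(table))
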