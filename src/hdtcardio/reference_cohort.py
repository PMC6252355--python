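"""Group-level summary statistics of the 60-day head-down-tilt bed-rest cohort.

Mean (SD) of each hemodynamic and autonomic index in the supine and sitting
position, before (BDC-7) and after (R+10) bed rest, for the control (CTRL,
n = 11) and countermeasure-training (TRAIN, n = 12) groups.  These printed
cohort statistics serve two roles: they are the inputs for the delta-score
worked examples, and they seed the synthetic cohort generator's baseline
defaults so simulated cohorts live on the study's scale.

Frequency-domain powers are stored on the log10 scale they are reported on
(log ms^2 for the R-R bands, log mmHg^2 for DBP-LF).
"""

from __future__ import annotations

import pandas as pd

# (index, timepoint, group, posture) -> (mean, sd)
_CELLS = {
    ("HR", "BDC-7", "CTRL", "supine"): (58.5, 7.4),
    ("HR", "BDC-7", "CTRL", "sitting"): (69.1, 8.3),
    ("HR", "BDC-7", "TRAIN", "supine"): (64.2, 9.1),
    ("HR", "BDC-7", "TRAIN", "sitting"): (70.4, 7.8),
    ("HR", "R+10", "CTRL", "supine"): (62.7, 7.6),
    ("HR", "R+10", "CTRL", "sitting"): (70.2, 5.9),
    ("HR", "R+10", "TRAIN", "supine"): (62.1, 10.5),
    ("HR", "R+10", "TRAIN", "sitting"): (68.2, 7.8),
    ("SV", "BDC-7", "CTRL", "supine"): (106.7, 18.7),
    ("SV", "BDC-7", "CTRL", "sitting"): (81.5, 14.0),
    ("SV", "BDC-7", "TRAIN", "supine"): (101.6, 14.1),
    ("SV", "BDC-7", "TRAIN", "sitting"): (76.8, 12.5),
    ("SV", "R+10", "CTRL", "supine"): (101.3, 17.9),
    ("SV", "R+10", "CTRL", "sitting"): (75.6, 11.8),
    ("SV", "R+10", "TRAIN", "supine"): (94.6, 15.9),
    ("SV", "R+10", "TRAIN", "sitting"): (70.9, 9.0),
    ("CO", "BDC-7", "CTRL", "supine"): (6.1, 1.1),
    ("CO", "BDC-7", "CTRL", "sitting"): (5.5, 1.0),
    ("CO", "BDC-7", "TRAIN", "supine"): (6.5, 1.1),
    ("CO", "BDC-7", "TRAIN", "sitting"): (5.3, 0.8),
    ("CO", "R+10", "CTRL", "supine"): (6.2, 1.2),
    ("CO", "R+10", "CTRL", "sitting"): (5.2, 0.8),
    ("CO", "R+10", "TRAIN", "supine"): (5.8, 1.3),
    ("CO", "R+10", "TRAIN", "sitting"): (4.7, 0.6),
    ("SBP", "BDC-7", "CTRL", "supine"): (129.5, 10.0),
    ("SBP", "BDC-7", "CTRL", "sitting"): (125.4, 10.0),
    ("SBP", "BDC-7", "TRAIN", "supine"): (129.7, 8.6),
    ("SBP", "BDC-7", "TRAIN", "sitting"): (127.6, 9.6),
    ("SBP", "R+10", "CTRL", "supine"): (112.5, 7.8),
    ("SBP", "R+10", "CTRL", "sitting"): (122.4, 7.0),
    ("SBP", "R+10", "TRAIN", "supine"): (124.2, 9.3),
    ("SBP", "R+10", "TRAIN", "sitting"): (126.6, 8.1),
    ("DBP", "BDC-7", "CTRL", "supine"): (70.5, 7.5),
    ("DBP", "BDC-7", "CTRL", "sitting"): (76.6, 7.1),
    ("DBP", "BDC-7", "TRAIN", "supine"): (76.0, 8.6),
    ("DBP", "BDC-7", "TRAIN", "sitting"): (81.6, 9.6),
    ("DBP", "R+10", "CTRL", "supine"): (66.5, 4.8),
    ("DBP", "R+10", "CTRL", "sitting"): (77.6, 7.5),
    ("DBP", "R+10", "TRAIN", "supine"): (72.7, 10.0),
    ("DBP", "R+10", "TRAIN", "sitting"): (81.0, 5.4),
    ("TPR", "BDC-7", "CTRL", "supine"): (1148.0, 235.0),
    ("TPR", "BDC-7", "CTRL", "sitting"): (1318.0, 249.0),
    ("TPR", "BDC-7", "TRAIN", "supine"): (1154.0, 246.0),
    ("TPR", "BDC-7", "TRAIN", "sitting"): (1395.0, 209.0),
    ("TPR", "R+10", "CTRL", "supine"): (1026.0, 226.0),
    ("TPR", "R+10", "CTRL", "sitting"): (1379.0, 182.0),
    ("TPR", "R+10", "TRAIN", "supine"): (1223.0, 299.0),
    ("TPR", "R+10", "TRAIN", "sitting"): (1559.0, 188.0),
    ("EDR", "BDC-7", "CTRL", "supine"): (0.27, 0.03),
    ("EDR", "BDC-7", "CTRL", "sitting"): (0.29, 0.03),
    ("EDR", "BDC-7", "TRAIN", "supine"): (0.27, 0.04),
    ("EDR", "BDC-7", "TRAIN", "sitting"): (0.27, 0.03),
    ("EDR", "R+10", "CTRL", "supine"): (0.27, 0.02),
    ("EDR", "R+10", "CTRL", "sitting"): (0.27, 0.03),
    ("EDR", "R+10", "TRAIN", "supine"): (0.27, 0.03),
    ("EDR", "R+10", "TRAIN", "sitting"): (0.27, 0.02),
    ("HF", "BDC-7", "CTRL", "supine"): (2.85, 0.50),
    ("HF", "BDC-7", "CTRL", "sitting"): (2.38, 0.50),
    ("HF", "BDC-7", "TRAIN", "supine"): (2.58, 0.38),
    ("HF", "BDC-7", "TRAIN", "sitting"): (2.40, 0.25),
    ("HF", "R+10", "CTRL", "supine"): (2.81, 0.49),
    ("HF", "R+10", "CTRL", "sitting"): (2.69, 0.45),
    ("HF", "R+10", "TRAIN", "supine"): (2.75, 0.47),
    ("HF", "R+10", "TRAIN", "sitting"): (2.54, 0.34),
    ("LF", "BDC-7", "CTRL", "supine"): (3.10, 0.40),
    ("LF", "BDC-7", "CTRL", "sitting"): (3.02, 0.31),
    ("LF", "BDC-7", "TRAIN", "supine"): (3.03, 0.28),
    ("LF", "BDC-7", "TRAIN", "sitting"): (3.09, 0.34),
    ("LF", "R+10", "CTRL", "supine"): (3.15, 0.29),
    ("LF", "R+10", "CTRL", "sitting"): (3.08, 0.28),
    ("LF", "R+10", "TRAIN", "supine"): (3.14, 0.21),
    ("LF", "R+10", "TRAIN", "sitting"): (3.17, 0.25),
    ("VLF", "BDC-7", "CTRL", "supine"): (3.18, 0.39),
    ("VLF", "BDC-7", "CTRL", "sitting"): (3.22, 0.37),
    ("VLF", "BDC-7", "TRAIN", "supine"): (3.09, 0.35),
    ("VLF", "BDC-7", "TRAIN", "sitting"): (2.97, 0.21),
    ("VLF", "R+10", "CTRL", "supine"): (3.34, 0.40),
    ("VLF", "R+10", "CTRL", "sitting"): (3.30, 0.45),
    ("VLF", "R+10", "TRAIN", "supine"): (3.22, 0.40),
    ("VLF", "R+10", "TRAIN", "sitting"): (3.15, 0.31),
    ("LF/HF", "BDC-7", "CTRL", "supine"): (0.46, 0.07),
    ("LF/HF", "BDC-7", "CTRL", "sitting"): (0.65, 0.48),
    ("LF/HF", "BDC-7", "TRAIN", "supine"): (0.39, 0.05),
    ("LF/HF", "BDC-7", "TRAIN", "sitting"): (0.70, 0.29),
    ("LF/HF", "R+10", "CTRL", "supine"): (0.34, 0.36),
    ("LF/HF", "R+10", "CTRL", "sitting"): (0.39, 0.45),
    ("LF/HF", "R+10", "TRAIN", "supine"): (0.38, 0.32),
    ("LF/HF", "R+10", "TRAIN", "sitting"): (0.63, 0.30),
    ("DFA1", "BDC-7", "CTRL", "supine"): (0.81, 0.15),
    ("DFA1", "BDC-7", "CTRL", "sitting"): (1.09, 0.20),
    ("DFA1", "BDC-7", "TRAIN", "supine"): (0.87, 0.16),
    ("DFA1", "BDC-7", "TRAIN", "sitting"): (1.04, 0.11),
    ("DFA1", "R+10", "CTRL", "supine"): (0.90, 0.12),
    ("DFA1", "R+10", "CTRL", "sitting"): (0.96, 0.16),
    ("DFA1", "R+10", "TRAIN", "supine"): (0.89, 0.15),
    ("DFA1", "R+10", "TRAIN", "sitting"): (1.03, 0.11),
    ("DBP-LF", "BDC-7", "CTRL", "supine"): (1.28, 0.25),
    ("DBP-LF", "BDC-7", "CTRL", "sitting"): (1.20, 0.33),
    ("DBP-LF", "BDC-7", "TRAIN", "supine"): (1.32, 0.23),
    ("DBP-LF", "BDC-7", "TRAIN", "sitting"): (1.21, 0.14),
    ("DBP-LF", "R+10", "CTRL", "supine"): (1.43, 0.19),
    ("DBP-LF", "R+10", "CTRL", "sitting"): (1.26, 0.29),
    ("DBP-LF", "R+10", "TRAIN", "supine"): (1.28, 0.19),
    ("DBP-LF", "R+10", "TRAIN", "sitting"): (1.26, 0.15),
}

GROUP_SIZES = {"CTRL": 11, "TRAIN": 12}


def postural_test_means() -> pd.DataFrame:
    """Cohort mean (SD) table in long format.

    Columns: index, timepoint, group, posture, mean, sd.
    """
    rows = [
        {"index": k[0], "timepoint": k[1], "group": k[2], "posture": k[3],
         "mean": v[0], "sd": v[1]}
        for k, v in _CELLS.items()
    ]
    return pd.DataFrame(rows)


def cell_mean(index: str, timepoint: str, group: str, posture: str) -> float:
    return _CELLS[(index, timepoint, group, posture)][0]


def cell_sd(index: str, timepoint: str, group: str, posture: str) -> float:
    return _CELLS[(index, timepoint, group, posture)][1]
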