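"""Baseline-referenced time courses and postural-test delta scores.

Two derived outcome sets feed the inference layer:

* **Normalized time courses** — each supine session value is referenced to the
  subject's supine baseline (BDC-7): linear-scale indices (HR, SV, CO, TPR,
  SBP, DBP, DFA1, EDR) become percent of baseline (baseline = 100 %);
  frequency-domain indices (HF, LF, VLF, LF/HF, DBP-LF) become the log10
  difference from baseline (baseline = 0), since the band powers are
  log-transformed to attain normality.
* **Delta scores** — the after-minus-before bed-rest change
  (R+10 minus BDC-7) per subject, posture and index, so a negative delta is a
  decline from baseline.

Tables are long-format: columns subject, group, timepoint, posture, index,
value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError, MissingPairError

GROUPS = ("CTRL", "TRAIN")
TIMEPOINTS = ("BDC-7", "HDT2", "HDT28", "HDT56", "R+10")
POSTURES = ("supine", "sitting")
BASELINE_TIMEPOINT = "BDC-7"
FOLLOWUP_TIMEPOINT = "R+10"

#: indices expressed as percent of baseline in the time course
LINEAR_INDICES = ("HR", "SV", "CO", "TPR", "SBP", "DBP", "DFA1", "EDR")
#: frequency-domain indices expressed as log10 difference from baseline
LOG_INDICES = ("HF", "LF", "VLF", "LF/HF", "DBP-LF")

TABLE_COLUMNS = ["subject", "group", "timepoint", "posture", "index", "value"]


def percent_change(value: float, baseline: float) -> float:
    """Value as percent of its baseline (baseline -> 100)."""
    if baseline <= 0:
        raise DomainError(f"baseline must be > 0, got {baseline}")
    return 100.0 * (value / baseline)


def log_diff(value: float, baseline: float) -> float:
    """log10(value) - log10(baseline) (baseline -> 0)."""
    if value <= 0 or baseline <= 0:
        raise DomainError("log difference requires positive value and baseline")
    return float(np.log10(value) - np.log10(baseline))


def delta_score(after: float, before: float) -> float:
    """Bed-rest delta: value at R+10 minus value at BDC-7 (same posture).

    Negative deltas are declines from baseline, matching the convention in
    which a post-bed-rest fall in supine SBP appears as a negative score.
    """
    return after - before


def derive_hemodynamics(
    hr_bpm: float, sv_ml: float, sbp_mmhg: float, dbp_mmhg: float
) -> tuple[float, float, float]:
    """Standard hemodynamic derivations: CO (L/min), MAP (mmHg) and TPR
    (dyn.s.cm^-5) from heart rate, stroke volume and arterial pressures."""
    for name, v in (("HR", hr_bpm), ("SV", sv_ml), ("SBP", sbp_mmhg), ("DBP", dbp_mmhg)):
        if v <= 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    co = hr_bpm * sv_ml / 1000.0
    mean_ap = dbp_mmhg + (sbp_mmhg - dbp_mmhg) / 3.0
    tpr = 80.0 * mean_ap / co
    return co, mean_ap, tpr


def _check_table(df: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"session table missing columns {missing}")
    dup = df.duplicated(subset=["subject", "timepoint", "posture", "index"])
    if dup.any():
        raise DomainError("duplicate (subject, timepoint, posture, index) rows")


def normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    """Baseline-reference every session row against the subject's BDC-7
    supine value of the same index.

    Linear indices become percent of baseline, frequency-domain indices the
    log10 difference.  Baseline rows map to exactly 100 / 0 by construction.
    A subject/index without a baseline raises :class:`MissingPairError`; no
    rows are dropped silently.
    """
    _check_table(df)
    base = df[(df["timepoint"] == BASELINE_TIMEPOINT) & (df["posture"] == "supine")]
    base_map = base.set_index(["subject", "index"])["value"]
    out = df.copy()
    values = np.empty(len(df))
    records = df[["subject", "index", "value"]].to_numpy(dtype=object)
    for i, (subject, index, value) in enumerate(records):
        key = (subject, index)
        if key not in base_map.index:
            raise MissingPairError(
                f"subject {subject!r} has no BDC-7 supine baseline for "
                f"index {index!r}"
            )
        b = base_map.loc[key]
        if index in LOG_INDICES:
            values[i] = 0.0 if value == b else log_diff(value, b)
        else:
            values[i] = 100.0 if value == b else percent_change(value, b)
    out["value"] = values
    return out


def delta_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-subject postural-test delta scores (R+10 minus BDC-7, matched
    posture) for every index.

    Raises :class:`MissingPairError` naming the subject and posture when one
    member of a before/after pair is absent.
    """
    _check_table(df)
    sub = df[df["timepoint"].isin([BASELINE_TIMEPOINT, FOLLOWUP_TIMEPOINT])]
    rows = []
    for (subject, group, posture, index), g in sub.groupby(
        ["subject", "group", "posture", "index"], sort=False
    ):
        tp = g.set_index("timepoint")["value"]
        if BASELINE_TIMEPOINT not in tp.index or FOLLOWUP_TIMEPOINT not in tp.index:
            raise MissingPairError(
                f"subject {subject!r}, posture {posture!r}, index {index!r}: "
                "incomplete BDC-7/R+10 pair"
            )
        rows.append(
            {
                "subject": subject,
                "group": group,
                "posture": posture,
                "index": index,
                "delta": delta_score(tp[FOLLOWUP_TIMEPOINT], tp[BASELINE_TIMEPOINT]),
            }
        )
    return pd.DataFrame(rows)
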