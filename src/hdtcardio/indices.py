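"""One-session scalar summary: hemodynamic and autonomic indices.

Ties the signal-level modules together: from a cleaned :class:`BeatSeries`
compute mean HR/SV/SBP/DBP (with CO/MAP/TPR when stroke volume is present),
the R-R spectral band powers, the DBP LF power, the short-term fractal
exponent DFA1 and the EDR breathing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .beats import BeatSeries
from .fractal import dfa1
from .normalize import derive_hemodynamics
from .spectral import (
    LF_BAND,
    band_powers,
    edr_central_frequency,
    resample_series,
    smooth_psd,
    welch_psd,
)


@dataclass
class AutonomicIndices:
    """Scalar outputs of one 10-min session."""

    hr_bpm: float
    sbp_mmhg: float | None = None
    dbp_mmhg: float | None = None
    sv_ml: float | None = None
    co_l_min: float | None = None
    tpr_dyn_s_cm5: float | None = None
    vlf_ms2: float | None = None
    lf_ms2: float | None = None
    hf_ms2: float | None = None
    lf_hf: float | None = None
    dfa_alpha1: float | None = None
    dbp_lf_mmhg2: float | None = None
    edr_hz: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def compute_indices(
    beats: BeatSeries,
    analysis_start_s: float = 0.0,
    include_spectral: bool = True,
    include_dfa: bool = True,
) -> AutonomicIndices:
    """Compute the per-session index set from a cleaned beat series.

    ``analysis_start_s`` discards an initial transient (e.g. after a posture
    change) before analysis; default 0 uses the whole recording.
    """
    if analysis_start_s > 0:
        from dataclasses import replace

        k0 = int(np.searchsorted(beats.times, beats.times[0] + analysis_start_s))
        beats = replace(
            beats,
            times=beats.times[k0:],
            labels=beats.labels[k0:],
            sbp=None if beats.sbp is None else beats.sbp[k0:],
            dbp=None if beats.dbp is None else beats.dbp[k0:],
            sv=None if beats.sv is None else beats.sv[k0:],
            qrs_amplitude=None
            if beats.qrs_amplitude is None
            else beats.qrs_amplitude[k0:],
            excluded_intervals=beats.excluded_intervals[k0:],
        )
    _, nn = beats.nn_intervals()
    out = AutonomicIndices(hr_bpm=60000.0 / float(np.mean(nn)))
    if beats.sbp is not None:
        out.sbp_mmhg = float(np.nanmean(beats.sbp[beats.labels == "normal"]))
    if beats.dbp is not None:
        out.dbp_mmhg = float(np.nanmean(beats.dbp[beats.labels == "normal"]))
    if beats.sv is not None:
        out.sv_ml = float(np.nanmean(beats.sv[beats.labels == "normal"]))
        if out.sbp_mmhg and out.dbp_mmhg:
            out.co_l_min, _, out.tpr_dyn_s_cm5 = derive_hemodynamics(
                out.hr_bpm, out.sv_ml, out.sbp_mmhg, out.dbp_mmhg
            )
    if include_spectral:
        spec = smooth_psd(welch_psd(resample_series(beats, "nn")))
        bp = band_powers(spec)
        out.vlf_ms2, out.lf_ms2, out.hf_ms2 = bp.vlf, bp.lf, bp.hf
        out.lf_hf = bp.lf_hf
        if beats.dbp is not None:
            dbp_spec = smooth_psd(welch_psd(resample_series(beats, "dbp")))
            out.dbp_lf_mmhg2 = dbp_spec.band_power(*LF_BAND)
        if beats.qrs_amplitude is not None:
            out.edr_hz = edr_central_frequency(resample_series(beats, "qrs"))
    if include_dfa:
        out.dfa_alpha1 = dfa1(nn).alpha1
    return out
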