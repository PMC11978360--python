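"""Band-limited LFP power per time bin and the PS-vs-power screen.

Oscillation bands follow the hippocampal convention: theta 6-11 Hz, slow
gamma 30-50 Hz, mid gamma 55-90 Hz, fast gamma 95-140 Hz, ripples
150-250 Hz.  Each band is extracted with a zero-phase Hamming-window FIR
bandpass filter; instantaneous power is the squared Hilbert amplitude,
averaged per time bin of width ``L`` and reported in dB (re 1).

The screen regresses the z-scored per-bin prediction score on the five band
powers plus running speed and trial label by ordinary least squares, with
the overall F-test and per-coefficient t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = ["BANDS", "BandPower", "band_power", "ps_power_regression"]

BANDS = {
    "theta": (6.0, 11.0),
    "slow_gamma": (30.0, 50.0),
    "mid_gamma": (55.0, 90.0),
    "fast_gamma": (95.0, 140.0),
    "ripple": (150.0, 250.0),
}

_DB_FLOOR = -120.0


@dataclass
class BandPower:
    band: str
    band_edges: tuple
    power_db: np.ndarray        # per bin
    power_linear: np.ndarray
    bin_width: float
    floored: np.ndarray         # bins where the dB floor was applied


def _design_fir(fs: float, lo: float, hi: float) -> np.ndarray:
    # Hamming-window design with the -6 dB cutoffs pushed half a
    # transition width outside the nominal band, so the band itself stays
    # in the flat passband (<1 dB ripple) while 40 dB stopband attenuation
    # is reached by lo/1.5 below and 1.5*hi above
    tw = min(lo / 3.0, 1.9 * (fs / 2.0 - hi))
    if tw <= 0:
        raise ValueError("band too close to Nyquist for the filter design")
    numtaps = int(np.ceil(3.3 * fs / tw))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [lo - tw / 2.0, hi + tw / 2.0],
                         pass_zero=False, window="hamming", fs=fs)


def band_power(trace: np.ndarray, fs: float, band, bin_width: float) -> BandPower:
    """Mean squared Hilbert amplitude of one band per time bin, in dB.

    ``band`` is a name from :data:`BANDS` or an ``(lo, hi)`` pair in Hz.
    """
    if isinstance(band, str):
        name, (lo, hi) = band, BANDS[band]
    else:
        lo, hi = band
        name = f"{lo:g}-{hi:g}Hz"
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    trace = np.asarray(trace, dtype=float)
    taps = _design_fir(fs, lo, hi)
    if len(trace) <= 3 * len(taps):
        raise ValueError("trace too short for the FIR filter order")
    filtered = signal.filtfilt(taps, 1.0, trace)
    amp2 = np.abs(signal.hilbert(filtered)) ** 2
    samples_per_bin = int(round(bin_width * fs))
    n_bins = len(amp2) // samples_per_bin
    binned = amp2[: n_bins * samples_per_bin].reshape(n_bins, samples_per_bin)
    power = binned.mean(axis=1)
    floored = power <= 0
    if np.any(floored):
        logger.warning("%d bin(s) with zero power floored to %g dB",
                       int(floored.sum()), _DB_FLOOR)
    with np.errstate(divide="ignore"):
        db = np.where(floored, _DB_FLOOR, 10.0 * np.log10(np.maximum(power, 1e-300)))
        db = np.maximum(db, _DB_FLOOR)
    return BandPower(band=name, band_edges=(lo, hi), power_db=db,
                     power_linear=power, bin_width=bin_width, floored=floored)


def ps_power_regression(prediction_scores, band_powers: dict,
                        speed=None, labels=None):
    """OLS fit of z-scored prediction scores on band powers (+ speed, label).

    ``band_powers`` maps regressor names to per-bin dB values.  Returns the
    fitted statsmodels results object (F-statistic, per-coefficient
    t-tests).  Raises on rank-deficient designs.
    """
    ps = np.asarray(prediction_scores, dtype=float)
    cols, names = [], []
    for name, bp in band_powers.items():
        v = bp.power_db if isinstance(bp, BandPower) else np.asarray(bp, float)
        cols.append(v)
        names.append(name)
    if speed is not None:
        cols.append(np.asarray(speed, float))
        names.append("speed")
    if labels is not None:
        cols.append(np.asarray(labels, float))
        names.append("label")
    Xd = np.column_stack(cols)
    if any(len(c) != len(ps) for c in cols):
        raise ValueError("regressors and prediction scores are misaligned")
    ok = ~np.isnan(ps)
    ps, Xd = ps[ok], Xd[ok]
    sd = ps.std()
    if sd == 0:
        raise ValueError("prediction scores are constant; nothing to fit")
    z = (ps - ps.mean()) / sd
    X = sm.add_constant(Xd)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (duplicated or constant regressor)")
    model = sm.OLS(z, X)
    fit = model.fit()
    fit.model.exog_names[:] = ["const"] + names
    return fit
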