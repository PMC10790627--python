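"""Time-frequency phase extraction and inter-areal synchronization.

Phases come from complex Morlet wavelet convolution (the wavelet output
is already the analytic signal, so a separate Hilbert step is not
needed).  Phase convention: 0 at an oscillation peak, +-pi at a trough,
advancing in time.  The phase-locking value across N trials is

    PLV(f, t) = | (1/N) sum_n exp(j * dphi_n(f, t)) |

with dphi_n the per-trial phase difference between the two signals, and
the phase slope index is the imaginary part of the band-summed product
of neighboring-frequency coherencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .core import LFP_FS

#: default analysis band (Hz) and post-onset summary window (s)
DEFAULT_BAND = (4.0, 8.0)
DEFAULT_WINDOW = (0.0, 0.7)


@dataclass
class PhaseSeries:
    """Per-trial instantaneous phases phi(trial, frequency, time).

    ``valid`` masks out the first/last three wavelet standard deviations
    at each frequency, where convolution edge effects corrupt the phase.
    """

    phases: np.ndarray  # (n_trials, n_freqs, n_times), radians in (-pi, pi]
    freqs: np.ndarray   # Hz
    times: np.ndarray   # s, trial time
    valid: np.ndarray   # (n_freqs, n_times) bool

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]


@dataclass
class PLVResult:
    """Inter-areal phase locking over frequency x time."""

    plv: np.ndarray          # (n_freqs, n_times) in [0, 1]
    phase_diffs: np.ndarray  # (n_trials, n_freqs, n_times), wrapped
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    n_trials: int
    onset: float
    band_median: float       # median over band x window of valid PLV
    band_median_by_time: np.ndarray  # median over band per time point


def _wrap(phi):
    return np.angle(np.exp(1j * np.asarray(phi)))


def morlet_phase(
    lfp: np.ndarray,
    freqs,
    n_cycles: float = 5.0,
    fs: float = LFP_FS,
) -> PhaseSeries:
    """Instantaneous phase per trial and frequency via Morlet wavelets.

    Parameters
    ----------
    lfp : ndarray, (n_trials, n_samples)
    freqs : array of float
        Frequencies of interest, Hz (the analysis covers 2-90 Hz).
    n_cycles : float
        Wavelet cycles; 5 for phase locking, 3-4 for the phase slope index.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    n_samples = lfp.shape[-1]
    min_len = int(np.ceil(3.0 / freqs.min() * fs))
    if n_samples < min_len:
        raise ValueError(
            f"trace of {n_samples} samples too short: need >= {min_len} samples "
            f"(3 cycles at {freqs.min()} Hz)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tfr = tfr_array_morlet(
            lfp[:, None, :], fs, freqs=freqs, n_cycles=n_cycles,
            output="complex", verbose=False,
        )[:, 0]  # (n_trials, n_freqs, n_times)
    phases = np.angle(tfr)
    times = np.arange(n_samples) / fs
    valid = np.ones((freqs.size, n_samples), dtype=bool)
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * np.pi * f)
        edge = int(np.ceil(3.0 * sigma_t * fs))
        valid[i, :edge] = False
        if edge > 0:
            valid[i, n_samples - edge:] = False
    return PhaseSeries(phases, freqs, times, valid)


def _morlet_complex(lfp, freqs, n_cycles, fs):
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tfr_array_morlet(
            lfp[:, None, :], fs, freqs=np.asarray(freqs, dtype=float),
            n_cycles=n_cycles, output="complex", verbose=False,
        )[:, 0]


def plv(
    phases_a: PhaseSeries,
    phases_b: PhaseSeries,
    band: tuple = DEFAULT_BAND,
    window: tuple = DEFAULT_WINDOW,
    onset: float = 0.5,
) -> PLVResult:
    """Phase-locking value across trials between two phase series.

    The band summary is the median of PLV(f, t) over band frequencies and
    the post-onset window (time x frequency jointly), excluding
    edge-invalid points.
    """
    for attr in ("freqs", "times"):
        if not np.array_equal(getattr(phases_a, attr), getattr(phases_b, attr)):
            raise ValueError(f"phase series {attr} axes do not match")
    if phases_a.phases.shape != phases_b.phases.shape:
        raise ValueError("phase series trial counts do not match")
    n = phases_a.n_trials
    if n == 1:
        warnings.warn("PLV of a single trial is identically 1")
    dphi = _wrap(phases_a.phases - phases_b.phases)
    plv_ft = np.abs(np.mean(np.exp(1j * dphi), axis=0))
    valid = phases_a.valid & phases_b.valid
    freqs, times = phases_a.freqs, phases_a.times
    fsel = (freqs >= band[0]) & (freqs <= band[1])
    tsel = (times >= onset + window[0]) & (times <= onset + window[1])
    block = plv_ft[np.ix_(fsel, tsel)]
    vblock = valid[np.ix_(fsel, tsel)]
    band_median = float(np.median(block[vblock])) if vblock.any() else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        by_time = np.array([
            np.median(plv_ft[fsel, t][valid[fsel, t]]) if valid[fsel, t].any() else np.nan
            for t in np.flatnonzero(tsel)
        ])
    return PLVResult(plv_ft, dphi, freqs, times, valid, n, onset, band_median, by_time)


def phase_difference_samples(
    result: PLVResult,
    band: tuple = DEFAULT_BAND,
    window: tuple = DEFAULT_WINDOW,
) -> np.ndarray:
    """Pooled wrapped phase differences within a band and post-onset window.

    These are the samples used for circular density plots and two-sample
    Kuiper comparisons between conditions.
    """
    fsel = (result.freqs >= band[0]) & (result.freqs <= band[1])
    tsel = (result.times >= result.onset + window[0]) & (
        result.times <= result.onset + window[1]
    )
    block = result.phase_diffs[:, fsel][:, :, tsel]
    vmask = result.valid[np.ix_(fsel, tsel)]
    return block[:, vmask].ravel()


def phase_slope_index(
    lfp_a: np.ndarray,
    lfp_b: np.ndarray,
    band: tuple = DEFAULT_BAND,
    n_cycles: float = 3.5,
    freq_step: float = 1.0,
    fs: float = LFP_FS,
    window: tuple = None,
    onset: float = 0.5,
) -> float:
    """Signed phase slope index between two trial sets over a band.

    PSI = Im sum_f conj(C(f)) C(f + df) with C(f) the complex coherency
    estimated from trial- and time-averaged Morlet cross-spectra.
    Positive PSI means ``lfp_a`` temporally leads ``lfp_b``.  Exactly
    antisymmetric under argument swap.
    """
    freqs = np.arange(band[0], band[1] + 1e-9, freq_step)
    if freqs.size < 2:
        raise ValueError(f"band {band} too narrow: need >= 2 frequency bins")
    wa = _morlet_complex(lfp_a, freqs, n_cycles, fs)
    wb = _morlet_complex(lfp_b, freqs, n_cycles, fs)
    n_samples = wa.shape[-1]
    times = np.arange(n_samples) / fs
    tmask = np.ones(n_samples, dtype=bool)
    if window is not None:
        tmask &= (times >= onset + window[0]) & (times <= onset + window[1])
    # exclude edges at the band's lowest frequency (widest wavelet)
    edge = int(np.ceil(3.0 * n_cycles / (2.0 * np.pi * freqs.min()) * fs))
    tmask[:edge] = False
    if edge > 0:
        tmask[n_samples - edge:] = False
    wa, wb = wa[..., tmask], wb[..., tmask]
    s_ab = np.mean(wa * np.conj(wb), axis=(0, 2))
    s_aa = np.mean(np.abs(wa) ** 2, axis=(0, 2))
    s_bb = np.mean(np.abs(wb) ** 2, axis=(0, 2))
    coh = s_ab / np.sqrt(s_aa * s_bb)
    return float(np.imag(np.sum(np.conj(coh[:-1]) * coh[1:])))
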