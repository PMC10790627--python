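"""Laminar LFP selection, oscillation extrema metrics, and spectral
parameterization.

The spectral model is the knee-free aperiodic-plus-peaks decomposition

    log10 P(f) = offset - exponent * log10 f + sum_k G(f; c_k, h_k, s_k)

with Gaussian periodic peaks G parameterized by center (Hz), height
(log10 power above the aperiodic component, the "adjusted power"), and
standard deviation (Hz).  Peaks are extracted iteratively largest-first
and jointly refined; the aperiodic component is then refit on the
peak-subtracted spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .core import LFP_FS

#: minimum absolute amplitude for an oscillation extremum, in microvolts
EXTREMA_AMP_THRESHOLD_UV = 25.0
#: minimum separation between retained extrema, in seconds
EXTREMA_MIN_SEPARATION_S = 0.05


# ---------------------------------------------------------------------------
# laminar layer assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnLayers:
    """Superficial / middle / deep channel triple for one probe column."""

    middle_channel: int
    band: tuple  # (upper depth, lower depth) of the middle band, um
    superficial_channel: int
    deep_channel: int


@dataclass(frozen=True)
class LayerAssignment:
    """Per-column layer assignment; keys are column indices."""

    columns: dict

    def channels(self, layer: str) -> list:
        attr = {"superficial": "superficial_channel",
                "middle": "middle_channel",
                "deep": "deep_channel"}[layer]
        return [getattr(c, attr) for c in self.columns.values()]


class LayerAssignmentError(ValueError):
    pass


def _amplitude(trace: np.ndarray) -> float:
    # "largest amplitude" read as max |trial-averaged LFP| in the window:
    # robust to evoked-response polarity across depths
    return float(np.max(np.abs(trace)))


def assign_layers(
    trial_avg_lfp: np.ndarray,
    depths,
    columns,
    onset: float = 0.5,
    fs: float = LFP_FS,
    band_halfwidth_um: float = 100.0,
) -> LayerAssignment:
    """Assign superficial / middle / deep LFP channels per probe column.

    The middle-layer channel is the one with the largest trial-averaged
    amplitude 50-150 ms post-onset; the middle band spans +-100 um around
    its depth.  Superficial and deep channels maximize amplitude within
    50-1000 ms post-onset among channels strictly above / below the band.
    Exact amplitude ties go to the shallower channel.
    """
    trial_avg_lfp = np.asarray(trial_avg_lfp, dtype=float)
    depths = np.asarray(depths, dtype=float)
    columns = np.asarray(columns)
    i_early = slice(int((onset + 0.05) * fs), int((onset + 0.15) * fs))
    i_late = slice(int((onset + 0.05) * fs), int((onset + 1.0) * fs))
    out = {}
    for col in np.unique(columns):
        ch_idx = np.flatnonzero(columns == col)
        d = depths[ch_idx]
        if len(ch_idx) < 3 or (d.max() - d.min()) <= 200.0:
            raise LayerAssignmentError(
                f"column {col}: need >= 3 channels spanning > 200 um "
                f"(got {len(ch_idx)} channels over {d.max() - d.min():.0f} um)"
            )
        # shallower channel wins ties: iterate in depth order, strict >
        order = ch_idx[np.argsort(d, kind="stable")]

        def _argmax_amp(cands, window):
            best, best_amp = None, -np.inf
            for ch in cands:
                amp = _amplitude(trial_avg_lfp[ch, window])
                if amp > best_amp:
                    best, best_amp = ch, amp
            return best

        mid = _argmax_amp(order, i_early)
        mid_depth = depths[mid]
        band = (mid_depth - band_halfwidth_um, mid_depth + band_halfwidth_um)
        above = [ch for ch in order if depths[ch] < band[0]]
        below = [ch for ch in order if depths[ch] > band[1]]
        if not above or not below:
            raise LayerAssignmentError(
                f"column {col}: no channel {'above' if not above else 'below'} "
                f"the middle band {band}"
            )
        sup = _argmax_amp(above, i_late)
        deep = _argmax_amp(below, i_late)
        out[int(col) if np.issubdtype(columns.dtype, np.integer) else col] = ColumnLayers(
            int(mid), band, int(sup), int(deep)
        )
    return LayerAssignment(out)


# ---------------------------------------------------------------------------
# oscillation extrema
# ---------------------------------------------------------------------------

@dataclass
class ExtremaSet:
    """Alternating troughs and peaks of a post-onset LFP trace."""

    times: np.ndarray          # s, trial time, sorted
    amplitudes: np.ndarray     # uV, same order
    is_peak: np.ndarray        # bool, same order
    trough_to_peak: np.ndarray  # uV, adjacent trough->peak differences
    mean_t2p_early: float      # mean trough-to-peak within 0-0.7 s post onset

    @property
    def trough_times(self):
        return self.times[~self.is_peak]

    @property
    def peak_times(self):
        return self.times[self.is_peak]


def detect_extrema(lfp: np.ndarray, onset: float = 0.5, fs: float = LFP_FS) -> ExtremaSet:
    """Detect alternating oscillation troughs and peaks 0-1 s post-onset.

    Local extrema with |amplitude| > 25 uV are scanned in descending
    |amplitude| order and greedily retained if at least 50 ms from every
    already-retained extremum.  Alternation is then enforced by dropping
    the smaller of any two same-sign neighbors.  An empty set is a valid
    result.
    """
    lfp = np.asarray(lfp, dtype=float)
    i0, i1 = int(onset * fs), int((onset + 1.0) * fs)
    if lfp.size < i1:
        raise ValueError(f"trace must cover onset + 1.0 s ({i1} samples, got {lfp.size})")
    seg = lfp[i0:i1]
    pk, _ = signal.find_peaks(seg)
    tr, _ = signal.find_peaks(-seg)
    cand_idx = np.concatenate([pk, tr])
    cand_peak = np.concatenate([np.ones(pk.size, bool), np.zeros(tr.size, bool)])
    amp = seg[cand_idx]
    keep_mask = np.abs(amp) > EXTREMA_AMP_THRESHOLD_UV
    cand_idx, cand_peak, amp = cand_idx[keep_mask], cand_peak[keep_mask], amp[keep_mask]

    # greedy by descending |amplitude|; ties broken by earlier time
    order = np.lexsort((cand_idx, -np.abs(amp)))
    accepted = []
    min_sep = int(EXTREMA_MIN_SEPARATION_S * fs)
    for k in order:
        if all(abs(int(cand_idx[k]) - int(cand_idx[j])) >= min_sep for j in accepted):
            accepted.append(k)
    accepted.sort(key=lambda k: cand_idx[k])
    idx = [int(cand_idx[k]) for k in accepted]
    pks = [bool(cand_peak[k]) for k in accepted]
    amps = [float(amp[k]) for k in accepted]

    # enforce alternation: drop the smaller of same-sign neighbors
    changed = True
    while changed:
        changed = False
        for k in range(len(idx) - 1):
            if pks[k] == pks[k + 1]:
                drop = k if abs(amps[k]) < abs(amps[k + 1]) else k + 1
                del idx[drop], pks[drop], amps[drop]
                changed = True
                break

    times = onset + np.asarray(idx, dtype=float) / fs
    amps = np.asarray(amps, dtype=float)
    is_peak = np.asarray(pks, dtype=bool)
    # adjacent trough->peak amplitude differences
    t2p, t2p_times = [], []
    for k in range(len(times) - 1):
        lo, hi = (k, k + 1) if not is_peak[k] else (k + 1, k)
        t2p.append(amps[hi] - amps[lo])
        t2p_times.append(0.5 * (times[k] + times[k + 1]))
    t2p = np.asarray(t2p, dtype=float)
    t2p_times = np.asarray(t2p_times, dtype=float)
    early = t2p[(t2p_times - onset) <= 0.7] if t2p.size else t2p
    mean_early = float(np.mean(early)) if early.size else float("nan")
    return ExtremaSet(times, amps, is_peak, t2p, mean_early)


# ---------------------------------------------------------------------------
# Welch PSD
# ---------------------------------------------------------------------------

def welch_psd(
    lfp: np.ndarray,
    fs: float = LFP_FS,
    window_s: float = 0.7,
    overlap_s: float = 0.35,
):
    """One-sided Welch power spectrum with Hann windows.

    Defaults match 700 ms Hann windows with 350 ms overlap, fixing the
    frequency resolution at 1/0.7 ~ 1.43 Hz.  Returns (freqs Hz,
    power uV^2/Hz).
    """
    lfp = np.asarray(lfp, dtype=float)
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_s * fs))
    if lfp.shape[-1] < nperseg:
        raise ValueError(
            f"segment of {lfp.shape[-1]} samples shorter than the "
            f"{nperseg}-sample window"
        )
    freqs, pxx = signal.welch(
        lfp, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, detrend="constant"
    )
    return freqs, pxx


# ---------------------------------------------------------------------------
# spectral parameterization
# ---------------------------------------------------------------------------

@dataclass
class SpectralFit:
    """Knee-free aperiodic fit plus Gaussian periodic peaks.

    ``peaks`` rows are (center Hz, adjusted log10 power above the
    aperiodic component, bandwidth Hz = 2 * Gaussian sd).
    """

    offset: float
    exponent: float
    peaks: list = field(default_factory=list)
    fit_range: tuple = (1.0, 40.0)
    r_squared: float = float("nan")

    def aperiodic(self, freqs) -> np.ndarray:
        return self.offset - self.exponent * np.log10(np.asarray(freqs, dtype=float))

    def band_peak_power(self, lo: float = 4.0, hi: float = 8.0) -> float:
        """Largest adjusted peak power with center inside [lo, hi]; 0 if none."""
        in_band = [h for (c, h, _) in self.peaks if lo <= c <= hi]
        return max(in_band) if in_band else 0.0


def _gaussian(f, center, height, sd):
    return height * np.exp(-((f - center) ** 2) / (2.0 * sd**2))


def _fit_aperiodic(logf, logp):
    # OLS in log-log space, then a robust refit excluding the points most
    # elevated above the first fit (peak regions bias the slope upward)
    A = np.vstack([np.ones_like(logf), -logf]).T
    coef, *_ = np.linalg.lstsq(A, logp, rcond=None)
    resid = logp - A @ coef
    thresh = np.percentile(resid, 40.0)
    mask = resid <= max(thresh, np.min(resid) + 1e-12)
    if mask.sum() >= 3:
        coef, *_ = np.linalg.lstsq(A[mask], logp[mask], rcond=None)
    return float(coef[0]), float(coef[1])  # offset, exponent


def fit_spectral_model(
    freqs,
    power,
    fit_range: tuple = (1.0, 40.0),
    max_peaks: int = 6,
    min_peak_height: float = 0.05,
    bandwidth_limits: tuple = (1.0, 12.0),
) -> SpectralFit:
    """Parameterize a power spectrum into aperiodic + Gaussian peaks.

    The aperiodic component is log10 P = offset - exponent * log10 f
    (no knee).  Peaks are pulled out of the flattened spectrum iteratively
    (largest residual first, up to ``max_peaks``, minimum height
    ``min_peak_height`` log10 units), jointly refined with bounded least
    squares, and the aperiodic component is refit on the peak-subtracted
    spectrum.  Scale-equivariant: multiplying power by c shifts the offset
    by log10 c and changes nothing else.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    f, p = freqs[sel], power[sel]
    if f.size < 5:
        raise ValueError("fewer than 5 spectral points in fit range")
    if np.any(p <= 0):
        raise ValueError("power must be strictly positive over the fit range")
    logf, logp = np.log10(f), np.log10(p)
    sd_lo, sd_hi = bandwidth_limits[0] / 2.0, bandwidth_limits[1] / 2.0

    offset, exponent = _fit_aperiodic(logf, logp)
    flat = logp - (offset - exponent * logf)

    # iterative peak extraction from the flattened spectrum
    guesses = []
    resid = flat.copy()
    for _ in range(max_peaks):
        k = int(np.argmax(resid))
        h = resid[k]
        if h < min_peak_height:
            break
        # half-height extent -> sd guess
        half = h / 2.0
        left = k
        while left > 0 and resid[left] > half:
            left -= 1
        right = k
        while right < len(resid) - 1 and resid[right] > half:
            right += 1
        fwhm = max(f[right] - f[left], 2.0 * sd_lo * 2.355 / 2.0)
        sd = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
        guesses.append((float(f[k]), float(h), sd))
        resid = resid - _gaussian(f, f[k], h, sd)

    peaks = []
    if guesses:
        def multi_gauss(f_, *params):
            out = np.zeros_like(f_)
            for i in range(0, len(params), 3):
                out = out + _gaussian(f_, params[i], params[i + 1], params[i + 2])
            return out

        p0, lo, hi = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            lo += [fit_range[0], 0.0, sd_lo]
            hi += [fit_range[1], 10.0, sd_hi]
        try:
            popt, _ = curve_fit(
                multi_gauss, f, flat, p0=p0, bounds=(lo, hi), maxfev=5000
            )
            cand = [tuple(popt[i:i + 3]) for i in range(0, len(popt), 3)]
        except RuntimeError:
            cand = guesses
        peaks = [
            (float(c), float(h), float(2.0 * s))
            for c, h, s in cand
            if h >= min_peak_height
        ]
        # refit aperiodic on the peak-subtracted spectrum
        peak_model = np.zeros_like(f)
        for c, h, bw in peaks:
            peak_model = peak_model + _gaussian(f, c, h, bw / 2.0)
        A = np.vstack([np.ones_like(logf), -logf]).T
        coef, *_ = np.linalg.lstsq(A, logp - peak_model, rcond=None)
        offset, exponent = float(coef[0]), float(coef[1])

    model = offset - exponent * logf
    for c, h, bw in peaks:
        model = model + _gaussian(f, c, h, bw / 2.0)
    ss_res = float(np.sum((logp - model) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    peaks.sort(key=lambda t: -t[1])
    return SpectralFit(offset, exponent, peaks, tuple(fit_range), r2)
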