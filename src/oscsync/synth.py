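"""Synthetic two-area laminar sessions with known ground truth.

The generator emulates the recorded phenomenology: a 5 x 5 SF/TF
stimulus grid with 20 trials per stimulus, trials with a 500 ms
pre-stimulus baseline, an evoked transient at stimulus onset, a damped
4-8 Hz oscillation beginning at stimulus offset riding on 1/f
background noise, a laminar depth profile across channel columns, a
second area whose oscillation phase trails the first by a fixed lag
plus von Mises per-trial jitter, spikes phase-locked to the local
oscillation, and binary spike trains coupled through the same logistic
model the directed-information stage fits.  Every stochastic element is
seeded and the generating parameters are stored in the session's
``ground_truth`` so downstream stages have parameter-recovery tests
with analytic oracles (Bessel-ratio resultant lengths for PLV/PPC,
coupling-weight signs for directed information).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .core import LFP_FS, Session, StimulusGrid
from .spikes import bandpass_filter

TRIAL_DURATION_S = 2.2
ONSET_S = 0.5
STIM_DURATION_S = 0.2
#: the damped oscillation starts at stimulus offset (trial time, s)
OSC_START_S = ONSET_S + STIM_DURATION_S

DEFAULT_COLUMN_DEPTHS = (100.0, 250.0, 400.0, 550.0, 700.0, 850.0)


@dataclass
class LfpGenParams:
    """Ground-truth parameters of the laminar LFP generator.

    ``osc_amp`` is the peak oscillation amplitude in microvolts, either a
    scalar (same for every stimulus) or a 5 x 5 array per (SF, TF) cell.
    ``trial_jitter_kappa`` is the von Mises concentration of the
    per-trial phase offset added to area 2; ``inter_areal_lag`` is the
    fixed area-1-leads-area-2 phase lag in radians.
    """

    n_trials: int = 20
    osc_freq: float = 6.0
    osc_amp: object = 50.0
    osc_decay: float = 1.0          # s, amplitude time constant
    evoked_amp: float = 120.0       # uV, onset transient (middle layer)
    evoked_latency: float = 0.08    # s after onset
    aperiodic_exponent: float = 1.0
    noise_scale: float = 2.0        # uV rms broadband background
    inter_areal_lag: float = np.pi / 4
    trial_jitter_kappa: float = 1e6
    areas: tuple = ("V1", "LM")
    column_depths: tuple = DEFAULT_COLUMN_DEPTHS
    n_columns_per_area: int = 1
    stimuli: tuple = None           # flat stimulus ids; None = full grid
    condition: str = "pre"
    mouse_id: str = "m0"
    seed: int = 0

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if np.any(np.asarray(self.osc_amp) < 0):
            raise ValueError("osc_amp must be >= 0")
        if self.trial_jitter_kappa < 0:
            raise ValueError("trial_jitter_kappa must be >= 0")


@dataclass
class SpikeGenParams:
    """Parameters of the phase-locked inhomogeneous-Poisson spike generator.

    Spiking intensity is rate(t) * exp(kappa * cos(phi(t) - preferred)) /
    I0(kappa), where phi is the 4-8 Hz phase of the unit's best-channel
    LFP; the von Mises modulation gives the closed-form expectation
    PPC = (I1(kappa)/I0(kappa))^2 for spikes emitted while the oscillation
    sweeps phase uniformly.
    """

    base_rate: float = 2.0       # Hz, unmodulated background
    resp_rate: float = 8.0       # Hz, added during the response window
    resp_window: tuple = (OSC_START_S, OSC_START_S + 0.8)
    phase_kappa: float = 1.0
    preferred_phase: float = np.pi  # troughs
    n_units_per_area: int = 3
    band: tuple = (4.0, 8.0)
    seed: int = 0

    def __post_init__(self):
        if self.base_rate < 0 or self.resp_rate < 0 or self.base_rate + self.resp_rate <= 0:
            raise ValueError("rates must be non-negative and not all zero")
        if self.phase_kappa < 0:
            raise ValueError("phase_kappa must be >= 0")


@dataclass
class CouplingSpec:
    """Ground-truth logistic-GLM coupling for binary train generation.

    ``cross_weights[(i, j)]`` is the weight on unit i's summed 10-bin
    history in unit j's model.  ``refractory_weight`` acts on
    Y(t-1)+Y(t-2) and is strongly negative by default; ``self_weight``
    acts on Y(t-3)+...+Y(t-10).
    """

    n_units: int = 2
    intercepts: object = -3.5
    refractory_weight: float = -4.0
    self_weight: float = 0.2
    cross_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = [self.refractory_weight, self.self_weight, *np.atleast_1d(self.intercepts),
                *self.cross_weights.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all coupling weights must be finite")


# ---------------------------------------------------------------------------
# LFP sessions
# ---------------------------------------------------------------------------

def _pink_noise(rng, n_samples, exponent, scale, shape):
    """Gaussian noise spectrally shaped to 1/f^exponent, unit-calibrated rms."""
    n = int(np.prod(shape)) if shape else 1
    white = rng.standard_normal((n, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / LFP_FS)
    gain = np.ones_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    shaped = shaped / np.where(rms > 0, rms, 1.0) * scale
    return shaped.reshape(*shape, n_samples)


def _osc_gain(depth):
    # oscillation expressed most strongly superficially
    return 0.6 + 0.4 * np.exp(-((depth - 150.0) ** 2) / (2 * 200.0**2))


def _evoked_gain(depth):
    # evoked transient peaks in the middle (input) layer ~400 um
    return 0.3 + 0.7 * np.exp(-((depth - 400.0) ** 2) / (2 * 120.0**2))


def gen_lfp_session(params: LfpGenParams, grid: StimulusGrid = None) -> Session:
    """Generate a two-area laminar LFP session with known ground truth.

    Area-2 oscillation phase equals area-1 phase minus
    (inter_areal_lag + von Mises(0, trial_jitter_kappa) jitter) per
    trial, so area 1 leads and the circular mean of (phase_1 - phase_2)
    equals the lag.  Ground truth (lag, jitter draws, kappa, amplitudes)
    is stored in ``session.ground_truth``.
    """
    grid = grid or StimulusGrid()
    rng = np.random.default_rng(params.seed)
    fs = LFP_FS
    n_samples = int(round(TRIAL_DURATION_S * fs))
    t = np.arange(n_samples) / fs

    stimuli = tuple(params.stimuli) if params.stimuli is not None else tuple(
        range(grid.n_stimuli)
    )
    amp_map = np.asarray(params.osc_amp, dtype=float)
    if amp_map.ndim == 0:
        amp_map = np.full((5, 5), float(amp_map))

    depths, columns, areas = [], [], []
    col_idx = 0
    for area in params.areas:
        for _ in range(params.n_columns_per_area):
            depths.extend(params.column_depths)
            columns.extend([col_idx] * len(params.column_depths))
            areas.extend([area] * len(params.column_depths))
            col_idx += 1
    depths = np.asarray(depths, dtype=float)
    columns = np.asarray(columns, dtype=np.int64)
    areas = np.asarray(areas, dtype=object)
    n_ch = depths.size

    n_trials_total = len(stimuli) * params.n_trials
    lfp = np.zeros((n_trials_total, n_ch, n_samples))

    # deterministic per-trial jitter draws for area 2
    if params.trial_jitter_kappa >= 1e6:
        jitters = np.zeros(n_trials_total)
    else:
        jitters = rng.vonmises(0.0, params.trial_jitter_kappa, size=n_trials_total)

    osc_env = np.where(
        t >= OSC_START_S,
        np.exp(-(t - OSC_START_S) / params.osc_decay),
        0.0,
    )
    ev = np.exp(-((t - (ONSET_S + params.evoked_latency)) ** 2) / (2 * 0.02**2))
    ev[t < ONSET_S] = 0.0

    trial_rows = []
    tr = 0
    for sid in stimuli:
        i_sf, i_tf = grid.indices(sid)
        a = amp_map[i_sf, i_tf]
        for _ in range(params.n_trials):
            for ch in range(n_ch):
                is_area2 = areas[ch] != params.areas[0]
                phase_off = params.inter_areal_lag + jitters[tr] if is_area2 else 0.0
                osc = a * _osc_gain(depths[ch]) * osc_env * np.cos(
                    2 * np.pi * params.osc_freq * (t - OSC_START_S) - phase_off
                )
                evoked = -params.evoked_amp * _evoked_gain(depths[ch]) * ev
                lfp[tr, ch] = osc + evoked
            tr += 1
            trial_rows.append(
                dict(
                    stimulus_id=sid,
                    sf=grid.cell(sid)[0],
                    tf=grid.cell(sid)[1],
                    onset_s=ONSET_S,
                    condition=params.condition,
                )
            )
    if params.noise_scale > 0:
        lfp += _pink_noise(
            rng, n_samples, params.aperiodic_exponent, params.noise_scale,
            (n_trials_total, n_ch),
        )

    trials = pd.DataFrame(trial_rows)
    units = pd.DataFrame(columns=["area", "best_channel"]).astype(
        {"best_channel": np.int64}
    )
    gt = {
        "kind": "lfp",
        "osc_freq": params.osc_freq,
        "osc_amp": amp_map.tolist(),
        "osc_decay": params.osc_decay,
        "osc_start_s": OSC_START_S,
        "aperiodic_exponent": params.aperiodic_exponent,
        "inter_areal_lag": params.inter_areal_lag,
        "trial_jitter_kappa": params.trial_jitter_kappa,
        "trial_jitters": jitters.tolist(),
        "seed": params.seed,
    }
    return Session(
        lfp=lfp,
        channel_depths=depths,
        channel_columns=columns,
        channel_areas=areas,
        spike_trains={},
        units=units,
        trials=trials,
        mouse_id=params.mouse_id,
        grid=grid,
        ground_truth=gt,
    ).validate()


# ---------------------------------------------------------------------------
# phase-locked spikes
# ---------------------------------------------------------------------------

def gen_phase_locked_spikes(session: Session, params: SpikeGenParams) -> Session:
    """Add inhomogeneous-Poisson units phase-locked to the local 4-8 Hz LFP.

    Each unit's intensity is modulated by exp(kappa * cos(phi - mu)) /
    I0(kappa) of the band phase of its best-channel LFP (the same trace
    the spike-phase analysis later reads), restricted to the response
    window; a constant base rate runs throughout the trial.  Ground-truth
    kappa and preferred phase are stored in ``session.ground_truth``.
    """
    from scipy.special import i0

    rng = np.random.default_rng(params.seed)
    fs = session.fs
    n_samples = session.n_samples
    t = session.time()
    dt = 1.0 / fs

    units_rows = {}
    spike_trains = dict(session.spike_trains)
    for area in dict.fromkeys(session.channel_areas):
        ch_area = session.channels_of_area(area)
        # best channel: strongest superficial oscillation expression
        best = int(ch_area[np.argmax(_osc_gain(session.channel_depths[ch_area]))])
        filt = bandpass_filter(session.lfp[:, best, :], band=params.band, fs=fs)
        phi = np.angle(hilbert(filt, axis=-1))
        in_resp = (t >= params.resp_window[0]) & (t < params.resp_window[1])
        mod = np.exp(
            params.phase_kappa * np.cos(phi - params.preferred_phase)
        ) / i0(params.phase_kappa)
        rate = params.base_rate + params.resp_rate * in_resp[None, :] * mod
        p_bin = np.clip(rate * dt, 0.0, 1.0)
        for k in range(params.n_units_per_area):
            uid = f"{area}_u{k}"
            draws = rng.random((session.n_trials, n_samples))
            per_trial = []
            for tr in range(session.n_trials):
                idx = np.flatnonzero(draws[tr] < p_bin[tr])
                per_trial.append(idx / fs)
            spike_trains[uid] = per_trial
            units_rows[uid] = dict(area=area, best_channel=best)

    units = pd.concat(
        [session.units, pd.DataFrame.from_dict(units_rows, orient="index")]
    ) if units_rows else session.units
    gt = dict(session.ground_truth)
    gt["spikes"] = {
        "phase_kappa": params.phase_kappa,
        "preferred_phase": params.preferred_phase,
        "base_rate": params.base_rate,
        "resp_rate": params.resp_rate,
        "resp_window": list(params.resp_window),
        "seed": params.seed,
    }
    out = Session(
        lfp=session.lfp,
        channel_depths=session.channel_depths,
        channel_columns=session.channel_columns,
        channel_areas=session.channel_areas,
        spike_trains=spike_trains,
        units=units.astype({"best_channel": np.int64}),
        trials=session.trials,
        mouse_id=session.mouse_id,
        grid=session.grid,
        ground_truth=gt,
    )
    return out.validate()


# ---------------------------------------------------------------------------
# GLM-coupled binary trains
# ---------------------------------------------------------------------------

def gen_coupled_binary_trains(
    spec: CouplingSpec, n_trials: int, bins_per_trial: int, seed: int
) -> np.ndarray:
    """Sample binary spike trains sequentially from the logistic model.

    Each unit's spiking probability at bin t is the logistic function of
    intercept + refractory_weight * (Y(t-1)+Y(t-2)) + self_weight *
    (Y(t-3)+...+Y(t-10)) + sum_i cross_weights[(i, j)] *
    (X_i(t-1)+...+X_i(t-10)) — exactly the feature construction the
    directed-information stage regresses on (shared code path, see
    :func:`oscsync.di.summed_history`).  History resets at trial
    boundaries.  Returns (n_trials, n_units, bins_per_trial) uint8.
    """
    rng = np.random.default_rng(seed)
    n_u = spec.n_units
    intercepts = np.broadcast_to(
        np.asarray(spec.intercepts, dtype=float), (n_u,)
    ).copy()
    w_cross = np.zeros((n_u, n_u))
    for (i, j), w in spec.cross_weights.items():
        w_cross[i, j] = w
    trains = np.zeros((n_trials, n_u, bins_per_trial), dtype=np.uint8)
    draws = rng.random((n_trials, bins_per_trial, n_u))
    for tr in range(n_trials):
        y = trains[tr]
        for t in range(bins_per_trial):
            lo_r = max(0, t - 2)
            lo_s = max(0, t - 10)
            refr = y[:, lo_r:t].sum(axis=1)
            hist10 = y[:, lo_s:t].sum(axis=1)
            selfh = hist10 - refr
            logit = (
                intercepts
                + spec.refractory_weight * refr
                + spec.self_weight * selfh
                + w_cross.T @ hist10
            )
            p = 1.0 / (1.0 + np.exp(-logit))
            y[:, t] = draws[tr, t] < p
    return trains


# ---------------------------------------------------------------------------
# tuning surfaces
# ---------------------------------------------------------------------------

def gen_tuning_responses(
    grid: StimulusGrid, preferred: tuple, width: float
) -> np.ndarray:
    """Unimodal 5 x 5 mean-rate surface peaked at the preferred (SF, TF).

    ``width`` is the Gaussian sd in grid cells; 0 gives a one-hot map and
    width -> infinity a uniform map.
    """
    sfs = np.asarray(grid.sfs)
    tfs = np.asarray(grid.tfs)
    i0_ = int(np.argmin(np.abs(sfs - preferred[0])))
    j0 = int(np.argmin(np.abs(tfs - preferred[1])))
    if not (np.isclose(sfs[i0_], preferred[0]) and np.isclose(tfs[j0], preferred[1])):
        raise ValueError(f"preferred {preferred} not on the stimulus grid")
    ii, jj = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
    if width == 0:
        out = np.zeros((5, 5))
        out[i0_, j0] = 1.0
        return out
    d2 = (ii - i0_) ** 2 + (jj - j0) ** 2
    return np.exp(-d2 / (2.0 * float(width) ** 2))
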