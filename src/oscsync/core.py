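"""Session container, stimulus grid, validation, and HDF5 persistence.

A :class:`Session` bundles everything one multi-trial laminar recording
provides: trial-aligned LFP (1 kHz, microvolts), channel geometry (depth
below pia, shank column, cortical area), curated single-unit spike times,
and per-trial stimulus metadata (spatial frequency, temporal frequency,
onset, condition tag).  All trial-relative times are in seconds with the
stimulus onset fixed at 0.5 s.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LFP_FS = 1000.0
"""LFP sample rate in Hz; the container accepts no other rate."""

SCHEMA_VERSION = "1.0"

DEFAULT_SFS = (0.015, 0.03, 0.06, 0.12, 0.24)
DEFAULT_TFS = (0.75, 1.5, 3.0, 6.0, 12.0)

VALID_AREAS = ("V1", "LM", "AL")
VALID_CONDITIONS = ("pre", "postA", "postB")


class SessionValidationError(ValueError):
    """A session field violates a container invariant.

    The message always names the offending field.
    """


class SchemaError(KeyError):
    """A session file is missing a required dataset."""


@dataclass(frozen=True)
class StimulusGrid:
    """The 5 x 5 spatial-frequency x temporal-frequency stimulus grid.

    Parameters
    ----------
    sfs : tuple of float
        Spatial frequencies in cycles/degree, strictly ascending.
    tfs : tuple of float
        Temporal frequencies in Hz, strictly ascending.
    """

    sfs: tuple = DEFAULT_SFS
    tfs: tuple = DEFAULT_TFS

    def __post_init__(self):
        for name, vals in (("sfs", self.sfs), ("tfs", self.tfs)):
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1 or len(arr) != 5:
                raise SessionValidationError(f"{name}: expected 5 values, got {arr.shape}")
            if not np.all(np.diff(arr) > 0):
                raise SessionValidationError(f"{name}: values must be strictly ascending")

    @property
    def n_stimuli(self) -> int:
        return len(self.sfs) * len(self.tfs)

    def stimulus_id(self, i_sf: int, i_tf: int) -> int:
        """Flat stimulus id for grid cell (i_sf, i_tf), row-major in SF."""
        return i_sf * len(self.tfs) + i_tf

    def cell(self, stimulus_id: int) -> tuple:
        """(sf, tf) values for a flat stimulus id."""
        i_sf, i_tf = divmod(int(stimulus_id), len(self.tfs))
        return self.sfs[i_sf], self.tfs[i_tf]

    def indices(self, stimulus_id: int) -> tuple:
        return divmod(int(stimulus_id), len(self.tfs))


@dataclass
class Session:
    """One simultaneous two-area laminar recording session.

    Attributes
    ----------
    lfp : ndarray, shape (n_trials, n_channels, n_samples)
        Trial-aligned LFP in microvolts at 1000 samples/s.
    channel_depths : ndarray of float, (n_channels,)
        Depth below pia in micrometers, increasing downward.
    channel_columns : ndarray of int, (n_channels,)
        Shank/column index per channel.
    channel_areas : ndarray of str, (n_channels,)
        Cortical area per channel; one of V1, LM, AL.
    spike_trains : dict[str, list[ndarray]]
        Per unit id, one array of spike times (s, trial-relative) per trial.
    units : pandas.DataFrame
        Indexed by unit id with columns ``area`` and ``best_channel``
        (channel with the largest spike amplitude).
    trials : pandas.DataFrame
        Columns ``stimulus_id``, ``sf``, ``tf``, ``onset_s``, ``condition``.
    mouse_id : str
    grid : StimulusGrid
    ground_truth : dict
        Generator-recorded ground truth (JSON-serializable); empty for
        real recordings.
    """

    lfp: np.ndarray
    channel_depths: np.ndarray
    channel_columns: np.ndarray
    channel_areas: np.ndarray
    spike_trains: dict
    units: pd.DataFrame
    trials: pd.DataFrame
    mouse_id: str = "m0"
    grid: StimulusGrid = field(default_factory=StimulusGrid)
    fs: float = LFP_FS
    ground_truth: dict = field(default_factory=dict)

    # -- convenience -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def onset(self) -> float:
        return float(self.trials["onset_s"].iloc[0])

    def time(self) -> np.ndarray:
        """Trial time axis in seconds."""
        return np.arange(self.n_samples) / self.fs

    def channels_of_area(self, area: str) -> np.ndarray:
        return np.flatnonzero(self.channel_areas == area)

    def units_of_area(self, area: str) -> list:
        return list(self.units.index[self.units["area"] == area])

    def trials_of_stimulus(self, stimulus_id: int) -> np.ndarray:
        return np.flatnonzero(self.trials["stimulus_id"].to_numpy() == stimulus_id)

    # -- validation --------------------------------------------------

    def validate(self) -> "Session":
        """Check all container invariants; raise naming the bad field."""
        if self.fs != LFP_FS:
            raise SessionValidationError(f"fs: LFP sample rate must be exactly {LFP_FS} Hz")
        lfp = np.asarray(self.lfp)
        if lfp.ndim != 3:
            raise SessionValidationError("lfp: expected trials x channels x samples array")
        n_tr, n_ch, _ = lfp.shape
        for name, arr in (
            ("channel_depths", self.channel_depths),
            ("channel_columns", self.channel_columns),
            ("channel_areas", self.channel_areas),
        ):
            if len(np.asarray(arr)) != n_ch:
                raise SessionValidationError(f"{name}: length must equal n_channels={n_ch}")
        bad = set(np.asarray(self.channel_areas)) - set(VALID_AREAS)
        if bad:
            raise SessionValidationError(f"channel_areas: unknown areas {sorted(bad)}")

        if len(self.trials) != n_tr:
            raise SessionValidationError("trials: row count must equal n_trials")
        for col in ("stimulus_id", "sf", "tf", "onset_s", "condition"):
            if col not in self.trials.columns:
                raise SessionValidationError(f"trials: missing column {col!r}")
        onsets = self.trials["onset_s"].to_numpy(dtype=float)
        if not np.all(onsets == onsets[0]):
            raise SessionValidationError("trials.onset_s: onset must be identical across trials")
        bad = set(self.trials["condition"]) - set(VALID_CONDITIONS)
        if bad:
            raise SessionValidationError(f"trials.condition: unknown tags {sorted(bad)}")
        # each stimulus id must map to exactly one grid (SF, TF)
        for sid, grp in self.trials.groupby("stimulus_id"):
            sf, tf = self.grid.cell(sid)
            if not (np.allclose(grp["sf"], sf) and np.allclose(grp["tf"], tf)):
                raise SessionValidationError(
                    f"trials: stimulus_id {sid} maps to multiple or off-grid (sf, tf)"
                )

        dur = self.duration
        for uid, per_trial in self.spike_trains.items():
            if uid not in self.units.index:
                raise SessionValidationError(f"spike_trains: unit {uid!r} missing from units table")
            if len(per_trial) != n_tr:
                raise SessionValidationError(
                    f"spike_trains: unit {uid!r} has {len(per_trial)} trials, expected {n_tr}"
                )
            for tr, times in enumerate(per_trial):
                t = np.asarray(times, dtype=float)
                if t.size and (t.min() < 0 or t.max() > dur):
                    raise SessionValidationError(
                        f"spike_trains: unit {uid!r} trial {tr} has spike times outside "
                        f"[0, {dur}] s"
                    )
        for col in ("area", "best_channel"):
            if col not in self.units.columns:
                raise SessionValidationError(f"units: missing column {col!r}")
        best = self.units["best_channel"].to_numpy(dtype=int)
        if best.size and (best.min() < 0 or best.max() >= n_ch):
            raise SessionValidationError("units.best_channel: channel index out of range")
        return self


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_REQUIRED = (
    "lfp",
    "channels/depths",
    "channels/columns",
    "channels/areas",
    "trials/stimulus_id",
    "trials/sf",
    "trials/tf",
    "trials/onset_s",
    "trials/condition",
    "units/ids",
    "units/area",
    "units/best_channel",
)

_KNOWN_GROUPS = {"lfp", "channels", "trials", "units", "spikes"}


def save_session(session: Session, path) -> str:
    """Write a validated session to a single HDF5 file.

    The layout is self-describing: ``/lfp`` (trials x channels x samples,
    with ``fs`` attribute), ``/channels``, ``/trials``, ``/units`` column
    datasets, and per-unit spike tables under ``/spikes`` stored as a flat
    (unit_index, trial_index, time_s) triple.  ``schema_version`` is a root
    attribute.  Round trip is bit-exact for integers and exact for float64.
    """
    session.validate()
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["mouse_id"] = session.mouse_id
        f.attrs["grid_sfs"] = np.asarray(session.grid.sfs, dtype=float)
        f.attrs["grid_tfs"] = np.asarray(session.grid.tfs, dtype=float)
        if session.ground_truth:
            f.attrs["ground_truth"] = json.dumps(session.ground_truth)
        d = f.create_dataset("lfp", data=np.asarray(session.lfp, dtype=np.float64))
        d.attrs["fs"] = session.fs
        d.attrs["units"] = "uV"
        ch = f.create_group("channels")
        ch.create_dataset("depths", data=np.asarray(session.channel_depths, dtype=float))
        ch.create_dataset("columns", data=np.asarray(session.channel_columns, dtype=np.int64))
        ch.create_dataset(
            "areas", data=np.asarray(session.channel_areas, dtype=object), dtype=str_dt
        )
        tr = f.create_group("trials")
        tr.create_dataset("stimulus_id", data=session.trials["stimulus_id"].to_numpy(np.int64))
        tr.create_dataset("sf", data=session.trials["sf"].to_numpy(float))
        tr.create_dataset("tf", data=session.trials["tf"].to_numpy(float))
        tr.create_dataset("onset_s", data=session.trials["onset_s"].to_numpy(float))
        tr.create_dataset(
            "condition", data=session.trials["condition"].to_numpy(object), dtype=str_dt
        )
        un = f.create_group("units")
        uids = list(session.units.index)
        un.create_dataset("ids", data=np.asarray(uids, dtype=object), dtype=str_dt)
        un.create_dataset(
            "area", data=session.units["area"].to_numpy(object), dtype=str_dt
        )
        un.create_dataset(
            "best_channel", data=session.units["best_channel"].to_numpy(np.int64)
        )
        # flat spike table
        u_idx, t_idx, times = [], [], []
        for i, uid in enumerate(uids):
            for tr_i, tt in enumerate(session.spike_trains.get(uid, [])):
                tt = np.asarray(tt, dtype=float)
                u_idx.append(np.full(tt.size, i, dtype=np.int64))
                t_idx.append(np.full(tt.size, tr_i, dtype=np.int64))
                times.append(tt)
        sp = f.create_group("spikes")
        sp.create_dataset(
            "unit_index", data=np.concatenate(u_idx) if u_idx else np.empty(0, np.int64)
        )
        sp.create_dataset(
            "trial_index", data=np.concatenate(t_idx) if t_idx else np.empty(0, np.int64)
        )
        sp.create_dataset(
            "time_s", data=np.concatenate(times) if times else np.empty(0, float)
        )
    return str(path)


def load_session(path) -> Session:
    """Read and validate a session written by :func:`save_session`.

    Unknown extra datasets are ignored with a logged warning so files
    written by newer minor schema versions still load.
    """
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED if k not in f]
        if missing:
            raise SchemaError(f"session file missing required dataset(s): {missing}")
        extras = sorted(set(f.keys()) - _KNOWN_GROUPS)
        if extras:
            logger.warning("ignoring unknown datasets in session file: %s", extras)
        lfp = f["lfp"][()]
        fs = float(f["lfp"].attrs.get("fs", LFP_FS))
        depths = f["channels/depths"][()]
        columns = f["channels/columns"][()]
        areas = f["channels/areas"].asstr()[()]
        trials = pd.DataFrame(
            {
                "stimulus_id": f["trials/stimulus_id"][()],
                "sf": f["trials/sf"][()],
                "tf": f["trials/tf"][()],
                "onset_s": f["trials/onset_s"][()],
                "condition": f["trials/condition"].asstr()[()],
            }
        )
        uids = list(f["units/ids"].asstr()[()])
        units = pd.DataFrame(
            {
                "area": f["units/area"].asstr()[()],
                "best_channel": f["units/best_channel"][()],
            },
            index=uids,
        )
        n_trials = lfp.shape[0]
        spike_trains = {uid: [np.empty(0, float)] * n_trials for uid in uids}
        u_idx = f["spikes/unit_index"][()]
        t_idx = f["spikes/trial_index"][()]
        times = f["spikes/time_s"][()]
        for i, uid in enumerate(uids):
            for tr_i in range(n_trials):
                sel = (u_idx == i) & (t_idx == tr_i)
                spike_trains[uid][tr_i] = times[sel]
        grid = StimulusGrid(
            tuple(f.attrs["grid_sfs"].tolist()), tuple(f.attrs["grid_tfs"].tolist())
        )
        gt = json.loads(f.attrs["ground_truth"]) if "ground_truth" in f.attrs else {}
        mouse_id = str(f.attrs.get("mouse_id", "m0"))
    sess = Session(
        lfp=lfp,
        channel_depths=depths,
        channel_columns=columns,
        channel_areas=np.asarray(areas, dtype=object),
        spike_trains=spike_trains,
        units=units,
        trials=trials,
        mouse_id=mouse_id,
        grid=grid,
        fs=fs,
        ground_truth=gt,
    )
    return sess.validate()


def spikes_to_csv(session: Session, path) -> str:
    """Export the spike table to plain CSV (unit_id, trial, time_s)."""
    rows = []
    for uid, per_trial in session.spike_trains.items():
        for tr, tt in enumerate(per_trial):
            for t in np.asarray(tt, dtype=float):
                rows.append((uid, tr, t))
    pd.DataFrame(rows, columns=["unit_id", "trial", "time_s"]).to_csv(path, index=False)
    return str(path)
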