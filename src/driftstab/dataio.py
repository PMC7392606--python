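"""Loading, segmentation, and normalization of multi-day session data.

Implements the inclusion rules the analyses assume: inter-trial
intervals removed, (optionally) correct trials only, per-trial zero-mean
centering for decoding; cross-day unit tracking with a recording-gap
limit; and the log / band-pass / z-score normalization used by the
drift-alignment statistics.

On-disk formats
---------------
HDF5: one group per session, ``/session_<i>/{activity, time, position,
velocity, view_angle, trial_id, correct, cue, iti_flag, unit_ids}`` with
attributes ``day_index``, ``sample_rate_hz``, ``maze_len_m``.

CSV: a directory with per-session ``session_<i>_kinematics.csv`` and
``session_<i>_activity.csv`` (UTF-8, header row, '.' decimal) plus a
``sessions.csv`` manifest of per-session attributes.

``deposited_mat``: best-effort reader for the per-mouse MAT v7.3 session
files of the study's public deposition (see README for the field map).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.signal

from .data import (EmptyDataError, KinematicsSeries, MultiDayDataset,
                   SessionData)

__all__ = [
    "save_dataset", "load_dataset", "prepare_decoding_series",
    "track_units", "bandpass_zscore", "UnsupportedFormatError",
]

_KIN_FIELDS = ("time", "position", "velocity", "view_angle", "trial_id",
               "correct", "cue", "iti_flag")


class UnsupportedFormatError(ValueError):
    pass


# ---------------------------------------------------------------- HDF5

def _save_hdf5(dataset: MultiDayDataset, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_sessions"] = dataset.n_sessions
        f.attrs["max_gap_days"] = dataset.max_gap_days
        for i, s in enumerate(dataset.sessions):
            g = f.create_group(f"session_{i}")
            g.attrs["day_index"] = s.day_index
            g.attrs["sample_rate_hz"] = s.sample_rate_hz
            g.attrs["maze_len_m"] = s.kinematics.maze_len_m
            g.create_dataset("activity", data=s.activity,
                             track_times=False)
            ids = np.asarray(s.unit_ids)
            if ids.dtype.kind in "US":
                ids = ids.astype(h5py.string_dtype())
            g.create_dataset("unit_ids", data=ids, track_times=False)
            for name in _KIN_FIELDS:
                g.create_dataset(name, data=getattr(s.kinematics, name),
                                 track_times=False)


def _load_hdf5(path: Path) -> MultiDayDataset:
    sessions = []
    with h5py.File(path, "r") as f:
        max_gap = int(f.attrs.get("max_gap_days", 2))
        keys = sorted((k for k in f if k.startswith("session_")),
                      key=lambda k: int(k.split("_")[1]))
        for k in keys:
            g = f[k]
            fields = {n: np.asarray(g[n]) for n in _KIN_FIELDS}
            kin = KinematicsSeries(**fields,
                                   maze_len_m=float(g.attrs["maze_len_m"]))
            ids = np.asarray(g["unit_ids"])
            if ids.dtype.kind in "OS":
                ids = ids.astype(str)
            sessions.append(SessionData(
                day_index=int(g.attrs["day_index"]), unit_ids=ids,
                activity=np.asarray(g["activity"]), kinematics=kin,
                sample_rate_hz=float(g.attrs["sample_rate_hz"])))
    sessions.sort(key=lambda s: s.day_index)
    return MultiDayDataset(sessions, max_gap_days=max_gap)


# ----------------------------------------------------------------- CSV

def _save_csv(dataset: MultiDayDataset, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(dataset.sessions):
        kin = pd.DataFrame({n: getattr(s.kinematics, n) for n in _KIN_FIELDS})
        kin.to_csv(path / f"session_{i}_kinematics.csv", index=False,
                   float_format="%.17g")
        act = pd.DataFrame(s.activity,
                           columns=[str(u) for u in s.unit_ids.tolist()])
        act.to_csv(path / f"session_{i}_activity.csv", index=False,
                   float_format="%.17g")
        manifest.append({"session": i, "day_index": s.day_index,
                         "sample_rate_hz": s.sample_rate_hz,
                         "maze_len_m": s.kinematics.maze_len_m})
    pd.DataFrame(manifest).to_csv(path / "sessions.csv", index=False)


def _load_csv(path: Path) -> MultiDayDataset:
    manifest = pd.read_csv(path / "sessions.csv")
    sessions = []
    for row in manifest.itertuples():
        kin_df = pd.read_csv(path / f"session_{row.session}_kinematics.csv",
                             float_precision="round_trip")
        kin = KinematicsSeries(
            **{n: kin_df[n].to_numpy() for n in _KIN_FIELDS},
            maze_len_m=float(row.maze_len_m))
        act_df = pd.read_csv(path / f"session_{row.session}_activity.csv",
                             float_precision="round_trip")
        ids = np.array(act_df.columns.tolist())
        try:
            ids = ids.astype(int)
        except ValueError:
            pass
        sessions.append(SessionData(
            day_index=int(row.day_index), unit_ids=ids,
            activity=act_df.to_numpy(float), kinematics=kin,
            sample_rate_hz=float(row.sample_rate_hz)))
    sessions.sort(key=lambda s: s.day_index)
    return MultiDayDataset(sessions)


# -------------------------------------------------- deposited MAT v7.3

_MAT_FIELD_MAP = {
    # deposited name -> internal name
    "dFF": "activity", "position": "position", "velocity": "velocity",
    "viewAngle": "view_angle", "trial": "trial_id", "correct": "correct",
    "cue": "cue", "iti": "iti_flag", "time": "time",
}


def _load_deposited_mat(path: Path) -> MultiDayDataset:
    """Read per-mouse MAT v7.3 session files from a deposition directory.

    Each ``*.mat`` file is expected to carry one session's arrays under
    the names in ``_MAT_FIELD_MAP`` plus scalar attributes ``day_index``
    / ``sample_rate_hz`` / ``maze_len_m`` and a ``unit_ids`` vector.
    """
    files = sorted(Path(path).glob("*.mat"))
    if not files:
        raise EmptyDataError(f"no .mat session files under {path}")
    sessions = []
    for fp in files:
        with h5py.File(fp, "r") as f:
            arrays = {}
            for src, dst in _MAT_FIELD_MAP.items():
                if src in f:
                    a = np.asarray(f[src])
                    arrays[dst] = a.T if a.ndim == 2 and dst == "activity" \
                        and a.shape[0] < a.shape[1] else np.squeeze(a)
            act = arrays.pop("activity")
            T = act.shape[0]
            kin = KinematicsSeries(
                time=arrays.get("time", np.arange(T) / 5.3),
                position=arrays["position"], velocity=arrays["velocity"],
                view_angle=arrays["view_angle"],
                trial_id=arrays["trial_id"].astype(int),
                correct=arrays["correct"].astype(bool),
                cue=arrays["cue"].astype(int),
                iti_flag=arrays.get("iti_flag",
                                    np.zeros(T, bool)).astype(bool),
                maze_len_m=float(np.squeeze(f.get("maze_len_m", 4.5))))
            ids = np.squeeze(np.asarray(f["unit_ids"])) if "unit_ids" in f \
                else np.arange(act.shape[1])
            sessions.append(SessionData(
                day_index=int(np.squeeze(f.get("day_index", len(sessions)))),
                unit_ids=ids, activity=act, kinematics=kin,
                sample_rate_hz=float(np.squeeze(f.get("sample_rate_hz",
                                                      5.3)))))
    sessions.sort(key=lambda s: s.day_index)
    return track_units(sessions)


# ------------------------------------------------------------ dispatch

def save_dataset(dataset: MultiDayDataset, path, format: str = "hdf5") -> None:
    path = Path(path)
    if format == "hdf5":
        _save_hdf5(dataset, path)
    elif format == "csv":
        _save_csv(dataset, path)
    else:
        raise UnsupportedFormatError(f"cannot write format {format!r}")


def load_dataset(path, format: str = "hdf5") -> MultiDayDataset:
    """Load a multi-day dataset; sessions come back sorted by day."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "csv":
        return _load_csv(path)
    if format == "deposited_mat":
        return _load_deposited_mat(path)
    raise UnsupportedFormatError(
        f"unknown format {format!r}; expected 'hdf5', 'csv' or "
        "'deposited_mat'")


# -------------------------------------------------------- preprocessing

def prepare_decoding_series(session: SessionData, correct_only: bool = True,
                            center: bool = True) -> SessionData:
    """Apply the decoding inclusion rules to one session.

    Drops inter-trial-interval samples, optionally drops error trials,
    and centers every retained trial to zero mean in the activity and
    in each kinematic channel.  Idempotent.
    """
    keep = ~session.kinematics.iti_flag
    if correct_only:
        keep &= session.kinematics.correct
    if not np.any(keep):
        raise EmptyDataError("no samples retained after ITI/correctness "
                             "filtering")
    out = session.select_samples(keep)
    if not center:
        return out
    kin = out.kinematics
    act = out.activity.copy()
    pos, vel, ang = (kin.position.copy(), kin.velocity.copy(),
                     kin.view_angle.copy())
    for t in np.unique(kin.trial_id):
        m = kin.trial_id == t
        act[m] -= act[m].mean(axis=0)
        pos[m] -= pos[m].mean()
        vel[m] -= vel[m].mean()
        ang[m] -= ang[m].mean()
    kin2 = KinematicsSeries(kin.time, pos, vel, ang, kin.trial_id,
                            kin.correct, kin.cue, kin.iti_flag,
                            kin.maze_len_m)
    # centered positions leave [0, maze_len]; the container tolerates it
    return SessionData(out.day_index, out.unit_ids, act, kin2,
                       out.sample_rate_hz)


def track_units(sessions: list[SessionData],
                max_gap_days: int = 2) -> MultiDayDataset:
    """Restrict to the longest usable session run and its common units.

    Sessions are sorted by day; the longest contiguous run whose
    consecutive day gaps are all <= ``max_gap_days`` is retained
    (earliest run on ties), restricted to the intersection of unit ids
    present in every retained session, with unit order canonicalized by
    sorted identifier.
    """
    if not sessions:
        raise EmptyDataError("no sessions given")
    ss = sorted(sessions, key=lambda s: s.day_index)
    days = [s.day_index for s in ss]
    # longest run under the gap rule, earliest on ties
    best = (0, 1)  # (start, length)
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or days[i] - days[i - 1] > max_gap_days:
            if i - start > best[1]:
                best = (start, i - start)
            start = i
    run = ss[best[0]:best[0] + best[1]]
    common = set(run[0].unit_ids.tolist())
    for s in run[1:]:
        common &= set(s.unit_ids.tolist())
    if not common:
        raise EmptyDataError("no units tracked across all retained sessions")
    order = sorted(common)
    return MultiDayDataset([s.restrict_units(order) for s in run],
                           common_units=np.asarray(order),
                           max_gap_days=max_gap_days)


def bandpass_zscore(activity: np.ndarray, low_hz: float = 0.03,
                    high_hz: float = 0.3, sample_rate_hz: float = 5.3,
                    log_floor_frac: float = 1e-3,
                    filter_order: int = 4) -> np.ndarray:
    """Log-transform, band-pass and z-score activity for drift alignment.

    Each column is floored at ``log_floor_frac`` of its maximum before
    the log (fluorescence can touch zero), filtered with a zero-phase
    forward-backward Butterworth band-pass of the given order, and
    z-scored to exactly zero mean / unit variance.
    """
    act = np.atleast_2d(np.asarray(activity, float))
    nyq = sample_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy "
            f"0 < low < high < Nyquist ({nyq:g} Hz)")
    floor = log_floor_frac * np.maximum(act.max(axis=0, keepdims=True), 1e-12)
    logged = np.log(np.maximum(act, floor))
    sos = scipy.signal.butter(filter_order, [low_hz / nyq, high_hz / nyq],
                              btype="bandpass", output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, logged, axis=0)
    mu = filtered.mean(axis=0, keepdims=True)
    sd = filtered.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (filtered - mu) / sd
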