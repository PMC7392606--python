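"""Core in-memory containers for multi-day population recordings.

A recording session couples a T x n matrix of normalized fluorescence
traces with time-aligned kinematics (linearized maze position, forward
velocity, view angle) and a trial segmentation.  Multi-day spans are
represented as an ordered list of sessions restricted to a common set of
tracked units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KinematicsSeries",
    "SessionData",
    "MultiDayDataset",
    "DataIntegrityError",
    "EmptyDataError",
    "InvalidParameterError",
]


class DataIntegrityError(ValueError):
    """Raised when aligned arrays disagree in shape or content."""


class InvalidParameterError(ValueError):
    """Raised for parameter values outside an operation's domain."""


class EmptyDataError(ValueError):
    """Raised when a filtering step leaves no usable data."""


def _as1d(x, dtype=None) -> np.ndarray:
    a = np.asarray(x)
    if dtype is not None:
        a = a.astype(dtype, copy=False)
    return np.atleast_1d(a)


@dataclass
class KinematicsSeries:
    """Time-aligned behavioral variables for one session.

    Attributes
    ----------
    time : array, seconds, strictly increasing
    position : array, meters along the linearized maze
    velocity : array, m/s forward velocity
    view_angle : array, degrees of heading in the virtual environment
    trial_id : int array, non-decreasing trial labels
    correct : bool array, whether the trial ended in the rewarded arm
    cue : int array, binary cue identity of the trial
    iti_flag : bool array, True for inter-trial-interval samples
    maze_len_m : float, total linearized maze length in meters
    """

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    view_angle: np.ndarray
    trial_id: np.ndarray
    correct: np.ndarray
    cue: np.ndarray
    iti_flag: np.ndarray
    maze_len_m: float = 4.5

    def __post_init__(self):
        self.time = _as1d(self.time, float)
        self.position = _as1d(self.position, float)
        self.velocity = _as1d(self.velocity, float)
        self.view_angle = _as1d(self.view_angle, float)
        self.trial_id = _as1d(self.trial_id, int)
        self.correct = _as1d(self.correct, bool)
        self.cue = _as1d(self.cue, int)
        self.iti_flag = _as1d(self.iti_flag, bool)
        n = len(self.time)
        for name in ("position", "velocity", "view_angle", "trial_id",
                     "correct", "cue", "iti_flag"):
            if len(getattr(self, name)) != n:
                raise DataIntegrityError(
                    f"kinematics channel '{name}' has length "
                    f"{len(getattr(self, name))}, expected {n}")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise DataIntegrityError("time must be strictly increasing")
        if n > 1 and np.any(np.diff(self.trial_id) < 0):
            raise DataIntegrityError("trial_id must be non-decreasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def channels(self) -> dict[str, np.ndarray]:
        """Continuous kinematic channels keyed by target name."""
        return {"position": self.position, "velocity": self.velocity,
                "view_angle": self.view_angle}

    def select(self, mask: np.ndarray) -> "KinematicsSeries":
        """Return a copy restricted to the boolean mask (order preserved)."""
        return KinematicsSeries(
            self.time[mask], self.position[mask], self.velocity[mask],
            self.view_angle[mask], self.trial_id[mask], self.correct[mask],
            self.cue[mask], self.iti_flag[mask], self.maze_len_m)

    def trial_table(self) -> pd.DataFrame:
        """Per-trial summary (id, cue, correct, n_samples), ITI excluded."""
        keep = ~self.iti_flag
        if not np.any(keep):
            return pd.DataFrame(
                columns=["trial_id", "cue", "correct", "n_samples"]
            ).astype({"trial_id": int, "cue": int,
                      "correct": bool, "n_samples": int})
        df = pd.DataFrame({"trial_id": self.trial_id[keep],
                           "cue": self.cue[keep],
                           "correct": self.correct[keep]})
        out = (df.groupby("trial_id", sort=True)
               .agg(cue=("cue", "first"), correct=("correct", "first"),
                    n_samples=("cue", "size"))
               .reset_index())
        return out


@dataclass
class SessionData:
    """One day's activity matrix with aligned kinematics.

    ``activity`` is T x n (time by unit) normalized fluorescence; rows
    align one-to-one with ``kinematics`` samples.
    """

    day_index: int
    unit_ids: np.ndarray
    activity: np.ndarray
    kinematics: KinematicsSeries
    sample_rate_hz: float = 5.3

    def __post_init__(self):
        self.unit_ids = _as1d(self.unit_ids)
        self.activity = np.atleast_2d(np.asarray(self.activity, float))
        if self.activity.size == 0:
            self.activity = self.activity.reshape(len(self.kinematics),
                                                  len(self.unit_ids))
        if self.activity.shape[0] != len(self.kinematics):
            raise DataIntegrityError(
                f"activity has {self.activity.shape[0]} rows but kinematics "
                f"has {len(self.kinematics)} samples")
        if self.activity.shape[1] != len(self.unit_ids):
            raise DataIntegrityError(
                f"activity has {self.activity.shape[1]} columns but "
                f"{len(self.unit_ids)} unit ids were given")

    @property
    def n_units(self) -> int:
        return self.activity.shape[1]

    @property
    def n_samples(self) -> int:
        return self.activity.shape[0]

    def target(self, name: str) -> np.ndarray:
        """Kinematic channel by decoding-target name."""
        try:
            return self.kinematics.channels[name]
        except KeyError:
            raise ValueError(f"unknown target {name!r}; expected one of "
                             "'position', 'velocity', 'view_angle'") from None

    def restrict_units(self, unit_ids: Sequence) -> "SessionData":
        """Return a copy keeping only (and ordered as) ``unit_ids``."""
        index = {u: i for i, u in enumerate(self.unit_ids.tolist())}
        try:
            cols = [index[u] for u in list(unit_ids)]
        except KeyError as e:
            raise DataIntegrityError(f"unit {e.args[0]!r} absent") from None
        return replace(self, unit_ids=np.asarray(list(unit_ids)),
                       activity=self.activity[:, cols])

    def select_samples(self, mask: np.ndarray) -> "SessionData":
        return replace(self, activity=self.activity[mask],
                       kinematics=self.kinematics.select(mask))


@dataclass
class MultiDayDataset:
    """Ordered sessions restricted to a common tracked unit set."""

    sessions: list[SessionData]
    common_units: np.ndarray = field(default=None)
    max_gap_days: int = 2

    def __post_init__(self):
        if self.common_units is None and self.sessions:
            self.common_units = np.asarray(self.sessions[0].unit_ids)
        self.common_units = _as1d(self.common_units)
        for s in self.sessions:
            if len(s.unit_ids) != len(self.common_units) or \
                    not np.array_equal(s.unit_ids, self.common_units):
                raise DataIntegrityError(
                    "session unit order differs from common_units; use "
                    "track_units() to align sessions first")

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def n_units(self) -> int:
        return len(self.common_units)

    @property
    def day_indices(self) -> np.ndarray:
        return np.array([s.day_index for s in self.sessions])

    @property
    def day_gaps(self) -> np.ndarray:
        """Days elapsed between consecutive sessions."""
        return np.diff(self.day_indices)

    def __iter__(self):
        return iter(self.sessions)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return MultiDayDataset(self.sessions[i], self.common_units,
                                   self.max_gap_days)
        return self.sessions[i]

    def map_sessions(self, fn) -> "MultiDayDataset":
        """Apply a SessionData -> SessionData transform to every session."""
        return MultiDayDataset([fn(s) for s in self.sessions],
                               self.common_units, self.max_gap_days)
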