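"""Containers for multi-trial calcium-imaging recordings.

The backbone of the package is the :class:`TraceSet`: a dense
``(units, frames, stimuli)`` array of fluorescence (raw counts or ΔF/F)
together with per-unit metadata (animal of origin, unit id) and per-stimulus
metadata (odorant label, trial/repetition index).  All downstream analyses —
ΔF/F conversion, bleach correction, response categorization, pattern
correlation and decoding — consume and produce TraceSets.

Conventions
-----------
* Frames are 0-based; windows are half-open ``[start, stop)`` in frames.
* Stimulus time ``t = 0`` is the stimulus onset; ``times`` converts frames to
  seconds relative to onset.
* Units are kept in a fixed canonical order (animal id, then unit id) so that
  population pattern vectors are comparable across trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraceSet", "SIGNAL_KINDS"]

SIGNAL_KINDS = ("raw", "dff", "dff_corrected")


@dataclass
class TraceSet:
    """Multi-unit, multi-trial fluorescence recording.

    Parameters
    ----------
    data
        Array of shape ``(n_units, n_frames, n_stimuli)``.
    units
        DataFrame with columns ``animal`` and ``unit`` (one row per unit, in
        canonical order: sorted by animal then unit).
    stimuli
        DataFrame with columns ``odor`` and ``trial`` (one row per stimulus
        presentation).
    frame_rate
        Acquisition rate in Hz.
    stim_onset_frame
        Frame index of stimulus onset.
    stim_duration_s
        Stimulus duration in seconds.
    signal_kind
        One of ``"raw"`` (fluorescence counts), ``"dff"`` (ΔF/F) or
        ``"dff_corrected"`` (bleach-corrected ΔF/F).
    """

    data: np.ndarray
    units: pd.DataFrame
    stimuli: pd.DataFrame
    frame_rate: float
    stim_onset_frame: int
    stim_duration_s: float
    signal_kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (units, frames, stimuli)")
        if len(self.units) != self.data.shape[0]:
            raise ValueError("units table does not match data")
        if len(self.stimuli) != self.data.shape[2]:
            raise ValueError("stimuli table does not match data")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        self.units = self.units.reset_index(drop=True)
        self.stimuli = self.stimuli.reset_index(drop=True)

    # ------------------------------------------------------------------ shape
    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_stimuli(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds relative to stimulus onset."""
        return (np.arange(self.n_frames) - self.stim_onset_frame) / self.frame_rate

    @property
    def stim_offset_frame(self) -> int:
        return self.stim_onset_frame + int(round(self.stim_duration_s * self.frame_rate))

    @property
    def stim_window(self) -> tuple[int, int]:
        """Half-open frame window of the stimulus."""
        return (self.stim_onset_frame, self.stim_offset_frame)

    @property
    def odorants(self) -> list:
        return list(pd.unique(self.stimuli["odor"]))

    @property
    def animals(self) -> list:
        return list(pd.unique(self.units["animal"]))

    def frame_index(self, t_seconds: float) -> int:
        """Frame index of a time given in seconds relative to onset."""
        return self.stim_onset_frame + int(round(t_seconds * self.frame_rate))

    def window_frames(self, t_start: float, t_stop: float) -> tuple[int, int]:
        """Half-open frame window for a time window in seconds after onset."""
        return (self.frame_index(t_start), self.frame_index(t_stop))

    # -------------------------------------------------------------- selection
    def select_stimulus(self, odor, trial) -> "TraceSet":
        """Single-presentation view (``n_stimuli == 1``)."""
        mask = (self.stimuli["odor"] == odor) & (self.stimuli["trial"] == trial)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size != 1:
            raise KeyError(f"stimulus ({odor!r}, trial {trial}) not found exactly once")
        return self._take_stimuli(idx)

    def select_odor(self, odor) -> "TraceSet":
        idx = np.flatnonzero((self.stimuli["odor"] == odor).to_numpy())
        if idx.size == 0:
            raise KeyError(f"odor {odor!r} not found")
        return self._take_stimuli(idx)

    def select_animals(self, animals) -> "TraceSet":
        """Subset of units from the given animals; duplicates are repeated.

        Repetition matters for bootstrap resampling of animals with
        replacement: a twice-drawn animal contributes its units twice.
        """
        parts = []
        for a in animals:
            rows = np.flatnonzero((self.units["animal"] == a).to_numpy())
            if rows.size == 0:
                raise KeyError(f"animal {a!r} not found")
            parts.append(rows)
        idx = np.concatenate(parts)
        return dataclasses.replace(
            self,
            data=self.data[idx],
            units=self.units.iloc[idx].reset_index(drop=True),
        )

    def select_units(self, unit_index) -> "TraceSet":
        idx = np.asarray(unit_index, dtype=int)
        return dataclasses.replace(
            self,
            data=self.data[idx],
            units=self.units.iloc[idx].reset_index(drop=True),
        )

    def _take_stimuli(self, idx) -> "TraceSet":
        return dataclasses.replace(
            self,
            data=self.data[:, :, idx],
            stimuli=self.stimuli.iloc[idx].reset_index(drop=True),
        )

    def matrix(self) -> np.ndarray:
        """``(units, frames)`` matrix of a single-presentation TraceSet."""
        if self.n_stimuli != 1:
            raise ValueError("matrix() requires a single-stimulus TraceSet")
        return self.data[:, :, 0]

    # --------------------------------------------------------------------- IO
    def to_table(self) -> pd.DataFrame:
        """Long-form table: one row per unit × frame × stimulus."""
        u = self.units
        s = self.stimuli
        n_u, n_f, n_s = self.data.shape
        frame = np.tile(np.repeat(np.arange(n_f), n_s), n_u)
        return pd.DataFrame(
            {
                "animal": np.repeat(u["animal"].to_numpy(), n_f * n_s),
                "unit": np.repeat(u["unit"].to_numpy(), n_f * n_s),
                "odor": np.tile(s["odor"].to_numpy(), n_u * n_f),
                "trial": np.tile(s["trial"].to_numpy(), n_u * n_f),
                "frame": frame,
                "value": self.data.reshape(-1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path, index=False)

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        frame_rate: float,
        stim_onset_frame: int,
        stim_duration_s: float,
        signal_kind: str = "raw",
    ) -> "TraceSet":
        """Rebuild a TraceSet from the long-form tabular format."""
        required = {"animal", "unit", "odor", "trial", "frame", "value"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table is missing columns: {sorted(missing)}")
        units = (
            table[["animal", "unit"]]
            .drop_duplicates()
            .sort_values(["animal", "unit"], kind="stable")
            .reset_index(drop=True)
        )
        stimuli = (
            table[["odor", "trial"]]
            .drop_duplicates()
            .sort_values(["odor", "trial"], kind="stable")
            .reset_index(drop=True)
        )
        n_frames = int(table["frame"].max()) + 1
        u_key = {t: i for i, t in enumerate(map(tuple, units.to_numpy()))}
        s_key = {t: i for i, t in enumerate(map(tuple, stimuli.to_numpy()))}
        data = np.full((len(units), n_frames, len(stimuli)), np.nan)
        ui = np.fromiter(
            (u_key[t] for t in zip(table["animal"], table["unit"])), int, len(table)
        )
        si = np.fromiter(
            (s_key[t] for t in zip(table["odor"], table["trial"])), int, len(table)
        )
        data[ui, table["frame"].to_numpy(int), si] = table["value"].to_numpy()
        if np.isnan(data).any():
            raise ValueError("table does not cover the full units × frames × stimuli grid")
        return cls(data, units, stimuli, frame_rate, stim_onset_frame,
                   stim_duration_s, signal_kind)

    @classmethod
    def from_csv(cls, path, frame_rate, stim_onset_frame, stim_duration_s,
                 signal_kind="raw") -> "TraceSet":
        return cls.from_table(pd.read_csv(path), frame_rate, stim_onset_frame,
                              stim_duration_s, signal_kind)

    def to_hdf5(self, path) -> None:
        """Write to an HDF5 container with named arrays."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["stim_onset_frame"] = self.stim_onset_frame
            f.attrs["stim_duration_s"] = self.stim_duration_s
            f.attrs["signal_kind"] = self.signal_kind
            f.create_dataset("animal", data=self.units["animal"].astype(str).to_numpy(dtype="S"))
            f.create_dataset("unit", data=self.units["unit"].to_numpy(int))
            f.create_dataset("odor", data=self.stimuli["odor"].astype(str).to_numpy(dtype="S"))
            f.create_dataset("trial", data=self.stimuli["trial"].to_numpy(int))

    @classmethod
    def from_hdf5(cls, path) -> "TraceSet":
        import h5py

        with h5py.File(path, "r") as f:
            units = pd.DataFrame(
                {"animal": [a.decode() for a in f["animal"][()]], "unit": f["unit"][()]}
            )
            stimuli = pd.DataFrame(
                {"odor": [o.decode() for o in f["odor"][()]], "trial": f["trial"][()]}
            )
            return cls(
                f["data"][()], units, stimuli,
                float(f.attrs["frame_rate"]), int(f.attrs["stim_onset_frame"]),
                float(f.attrs["stim_duration_s"]), str(f.attrs["signal_kind"]),
            )
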