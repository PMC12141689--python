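"""Trial-level epoch container and the canonical long-format text file.

Epochs hold a dense (n_epochs, n_channels, n_times) microvolt array plus a
per-epoch metadata frame.  The canonical on-disk form is a long-format
delimited table with columns

    subject, group, handedness, condition, trial, channel, time_ms, amplitude_uV

time is milliseconds relative to stimulus onset on a uniform grid of
1000/sampling_rate ms; the sample at time t covers [t, t + dt).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INFO_COLUMNS = ["subject", "group", "handedness", "condition", "trial"]

LONG_COLUMNS = INFO_COLUMNS + ["channel", "time_ms", "amplitude_uV"]


@dataclass
class Epochs:
    """Dense trial-level epoch data.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_times)
        Amplitudes in microvolts.
    info : DataFrame
        One row per epoch with columns subject, group, handedness,
        condition, trial (plus optional bookkeeping columns such as the
        simulator's truth artifact flags).
    channels : list of str
    times : ndarray
        Sample times in ms relative to stimulus onset.
    sfreq : float
        Sampling rate in Hz.
    """

    data: np.ndarray
    info: pd.DataFrame
    channels: list[str]
    times: np.ndarray
    sfreq: float
    rejection_log: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        n_ep, n_ch, n_t = self.data.shape
        if len(self.info) != n_ep:
            raise ValueError("info rows must match n_epochs")
        if len(self.channels) != n_ch:
            raise ValueError("channels must match data axis 1")
        if len(self.times) != n_t:
            raise ValueError("times must match data axis 2")
        self.info = self.info.reset_index(drop=True)

    # ---------------------------------------------------------------- basics
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "Epochs":
        return Epochs(self.data.copy(), self.info.copy(), list(self.channels),
                      self.times.copy(), self.sfreq,
                      None if self.rejection_log is None
                      else self.rejection_log.copy())

    def channel_index(self, names: list[str] | str) -> np.ndarray:
        if isinstance(names, str):
            names = [names]
        missing = [c for c in names if c not in self.channels]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        pos = {c: i for i, c in enumerate(self.channels)}
        return np.array([pos[c] for c in names], dtype=int)

    def time_mask(self, t_start: float, t_end: float,
                  inclusive: bool = True) -> np.ndarray:
        if inclusive:
            return (self.times >= t_start) & (self.times <= t_end)
        return (self.times >= t_start) & (self.times < t_end)

    def select(self, mask: np.ndarray) -> "Epochs":
        mask = np.asarray(mask)
        return Epochs(self.data[mask], self.info.loc[mask].copy(),
                      list(self.channels), self.times.copy(), self.sfreq)

    # ------------------------------------------------------------- long form
    def to_long_frame(self) -> pd.DataFrame:
        n_ep, n_ch, n_t = self.data.shape
        rep = self.info.loc[self.info.index.repeat(n_ch * n_t),
                            INFO_COLUMNS].reset_index(drop=True)
        rep["channel"] = np.tile(np.repeat(self.channels, n_t), n_ep)
        rep["time_ms"] = np.tile(self.times, n_ep * n_ch)
        rep["amplitude_uV"] = self.data.ravel()
        return rep

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame,
                        sfreq: float | None = None) -> "Epochs":
        frame = frame.rename(columns={c: c.lower() for c in frame.columns})
        frame = frame.rename(columns={"time": "time_ms",
                                      "amplitude": "amplitude_uV",
                                      "amplitude_uv": "amplitude_uV"})
        required = {"subject", "condition", "trial", "channel", "time_ms",
                    "amplitude_uV"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"long-format table missing columns: {sorted(missing)}")
        for col in ("group", "handedness"):
            if col not in frame.columns:
                frame[col] = ""
        times = np.sort(frame["time_ms"].unique())
        channels = list(pd.unique(frame["channel"]))
        if sfreq is None:
            dt = np.diff(times)
            if len(dt) and not np.allclose(dt, dt[0]):
                raise ValueError("time grid is not uniform")
            sfreq = 1000.0 / dt[0] if len(dt) else 250.0
        key = frame[INFO_COLUMNS].drop_duplicates().reset_index(drop=True)
        n_ch, n_t = len(channels), len(times)
        ch_pos = {c: i for i, c in enumerate(channels)}
        t_pos = {t: i for i, t in enumerate(times)}
        ep_key = list(map(tuple, key[INFO_COLUMNS].to_numpy()))
        ep_pos = {k: i for i, k in enumerate(ep_key)}
        data = np.zeros((len(key), n_ch, n_t))
        ep_idx = frame[INFO_COLUMNS].apply(tuple, axis=1).map(ep_pos).to_numpy()
        ci = frame["channel"].map(ch_pos).to_numpy()
        ti = frame["time_ms"].map(t_pos).to_numpy()
        data[ep_idx, ci, ti] = frame["amplitude_uV"].to_numpy(dtype=float)
        return cls(data, key, channels, times, float(sfreq))


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_epochs(path: str, sfreq: float | None = None) -> Epochs:
    """Read a long-format epochs file (comma- or tab-delimited, '#' comments)."""
    frame = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    return Epochs.from_long_frame(frame, sfreq=sfreq)


def write_epochs(epochs: Epochs, path: str,
                 header_lines: list[str] | None = None) -> None:
    """Write epochs as the canonical long-format CSV with comment header."""
    buf = io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    buf.write(f"# sampling_rate_hz: {epochs.sfreq}\n")
    epochs.to_long_frame().to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
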