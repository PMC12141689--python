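"""ERP component measurement: mean amplitude and peak latency in fixed
windows over fixed electrode sets.

Windows (inclusive endpoints, on the sampling grid):

* P1 to motion / N1 to color change: 130-170 ms over the five midline
  occipital sites.
* N2 to motion direction: 155-195 ms over the left {P5, PO3, PO7} and
  right {P4, PO4, PO8} parieto-occipital sets.

Peak latency is taken on the electrode-set-averaged waveform and snaps to
the sampling grid (4 ms at 250 Hz) without interpolation; ties go to the
earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .layout import ChannelLayout
from .preprocess import SubjectAverages

COMPONENT_COLUMNS = ["subject", "group", "handedness", "window", "hemisphere",
                     "condition", "mean_amplitude_uV", "peak_latency_ms",
                     "n_trials", "degenerate_peak", "polarity_mismatch"]


@dataclass
class ComponentWindow:
    """A named measurement window over an electrode role."""

    name: str
    t_start: float
    t_end: float
    electrode_set: str   # attribute name on ChannelLayout
    polarity: str        # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


M_P1 = ComponentWindow("M_P1", 130.0, 170.0, "occipital_set", "positive")
P_N1 = ComponentWindow("P_N1", 130.0, 170.0, "occipital_set", "negative")
N2 = ComponentWindow("N2", 155.0, 195.0, "occipital_set", "negative")


def _set_mean_waveform(avg: SubjectAverages, waveform: np.ndarray,
                       channels: list[str]) -> np.ndarray:
    idx = avg.channel_index(channels)
    return waveform[idx, :].mean(axis=0)


def _window_mask(times: np.ndarray, window: ComponentWindow) -> np.ndarray:
    mask = (times >= window.t_start) & (times <= window.t_end)
    if not mask.any():
        raise ValueError(f"no samples in window {window.name}")
    return mask


def mean_amplitude(avg: SubjectAverages, waveform: np.ndarray,
                   window: ComponentWindow, layout: ChannelLayout,
                   channels: list[str] | None = None) -> float:
    """Mean over all window samples (inclusive endpoints) and all channels
    of the window's electrode set."""
    channels = channels or getattr(layout, window.electrode_set)
    wave = _set_mean_waveform(avg, waveform, channels)
    return float(wave[_window_mask(avg.times, window)].mean())


def peak_latency(avg: SubjectAverages, waveform: np.ndarray,
                 window: ComponentWindow, layout: ChannelLayout,
                 channels: list[str] | None = None
                 ) -> tuple[float, bool, bool]:
    """Latency of the polarity-matching extremum of the set-averaged
    waveform.

    Returns (latency_ms, degenerate, polarity_mismatch).  A flat waveform
    returns the window start flagged degenerate; an extremum whose sign
    contradicts the window polarity is returned as found but flagged.
    """
    channels = channels or getattr(layout, window.electrode_set)
    wave = _set_mean_waveform(avg, waveform, channels)
    mask = _window_mask(avg.times, window)
    seg = wave[mask]
    tseg = avg.times[mask]
    if np.allclose(seg, seg[0]):
        return float(window.t_start), True, False
    i = int(np.argmax(seg)) if window.polarity == "positive" \
        else int(np.argmin(seg))      # argmax/argmin: earliest tie wins
    value = seg[i]
    mismatch = (value < 0) if window.polarity == "positive" else (value > 0)
    return float(tseg[i]), False, bool(mismatch)


class ComponentExtractor(BaseEstimator, TransformerMixin):
    """Measure the study's visual components from subject averages.

    transform(SubjectAverages) returns the long component table with one
    row per subject x window x hemisphere-tag x condition:

    * M_P1: motion conditions pooled (weighted by retained trials) over the
      occipital set; P_N1: color-change condition over the occipital set —
      both tagged 'midline-pooled'.
    * N2: four rows per subject, hemisphere LH/RH x condition M_SL/M_SR,
      over the corresponding parieto-occipital set.
    """

    def __init__(self, layout: ChannelLayout | None = None,
                 pool_motion_for_p1: bool = True,
                 windows: dict | None = None):
        self.layout = layout
        self.pool_motion_for_p1 = pool_motion_for_p1
        self.windows = windows

    def fit(self, X, y=None):
        return self

    def transform(self, X: SubjectAverages) -> pd.DataFrame:
        rows = []
        rows += measure_visual_components(
            X, self.layout, pool_motion=self.pool_motion_for_p1,
            _as_rows=True)
        rows += measure_n2(X, self.layout, _as_rows=True)
        return pd.DataFrame(rows, columns=COMPONENT_COLUMNS)


def _measure_row(avg, waveform, window, layout, channels, meta, n_trials):
    amp = mean_amplitude(avg, waveform, window, layout, channels)
    lat, degen, mism = peak_latency(avg, waveform, window, layout, channels)
    return {**meta, "window": window.name,
            "mean_amplitude_uV": amp, "peak_latency_ms": lat,
            "n_trials": int(n_trials), "degenerate_peak": degen,
            "polarity_mismatch": mism}


def measure_visual_components(avgs: SubjectAverages,
                              layout: ChannelLayout | None = None,
                              pool_motion: bool = True,
                              _as_rows: bool = False):
    """P1 (motion) and N1 (color change) over the occipital set, 130-170 ms.

    Motion scroll directions are pooled into a single average weighted by
    retained trial counts (configurable off, in which case M_SL/M_SR are
    measured separately).
    """
    layout = layout or ChannelLayout()
    rows = []
    t = avgs.table
    for subject, sub in t.groupby("subject", sort=True):
        meta_base = {"subject": subject, "group": sub.group.iloc[0],
                     "handedness": sub.handedness.iloc[0],
                     "hemisphere": "midline-pooled"}
        motion = sub[sub.condition.isin(["M_SL", "M_SR"])]
        if motion.empty:
            raise ValueError(f"subject {subject}: no motion conditions")
        if pool_motion:
            w = motion.n_trials_used.to_numpy(dtype=float)
            wave = np.tensordot(w / w.sum(),
                                avgs.data[motion.index.to_numpy()], axes=1)
            rows.append(_measure_row(avgs, wave, M_P1, layout, None,
                                     {**meta_base, "condition": "M"},
                                     w.sum()))
        else:
            for _, r in motion.iterrows():
                rows.append(_measure_row(
                    avgs, avgs.data[r.name], M_P1, layout, None,
                    {**meta_base, "condition": r.condition},
                    r.n_trials_used))
        color = sub[sub.condition == "P_CHANGE"]
        if color.empty:
            raise ValueError(f"subject {subject}: missing P_CHANGE condition")
        r = color.iloc[0]
        rows.append(_measure_row(avgs, avgs.data[color.index[0]], P_N1,
                                 layout, None,
                                 {**meta_base, "condition": "P_CHANGE"},
                                 r.n_trials_used))
    if _as_rows:
        return rows
    return pd.DataFrame(rows, columns=COMPONENT_COLUMNS)


def measure_n2(avgs: SubjectAverages, layout: ChannelLayout | None = None,
               _as_rows: bool = False):
    """N2 mean amplitude / peak latency per hemisphere and scroll direction.

    Four measures per subject: A_LH(SL), A_LH(SR), A_RH(SL), A_RH(SR) —
    155-195 ms means over the left / right parieto-occipital sets.
    """
    layout = layout or ChannelLayout()
    rows = []
    t = avgs.table
    for subject, sub in t.groupby("subject", sort=True):
        meta_base = {"subject": subject, "group": sub.group.iloc[0],
                     "handedness": sub.handedness.iloc[0]}
        for cond in ("M_SL", "M_SR"):
            sel = sub[sub.condition == cond]
            if sel.empty:
                raise ValueError(f"subject {subject}: missing {cond}")
            r = sel.iloc[0]
            wave = avgs.data[sel.index[0]]
            for hemi, chans in (("LH", layout.lh_set), ("RH", layout.rh_set)):
                rows.append(_measure_row(
                    avgs, wave, N2, layout, chans,
                    {**meta_base, "hemisphere": hemi, "condition": cond},
                    r.n_trials_used))
    if _as_rows:
        return rows
    return pd.DataFrame(rows, columns=COMPONENT_COLUMNS)
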