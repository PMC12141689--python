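"""Epoch preprocessing: re-reference, filter, baseline, artifact rejection,
condition averaging.

Each stage is an sklearn-style transformer over the :class:`Epochs`
container (stateless ``fit``, the work in ``transform``), so chains can be
built with :class:`sklearn.pipeline.Pipeline`.  Module-level functions wrap
the transformers.

Default chain, in order: re-reference to the mastoid average -> baseline
correction (-100..0 ms) -> per-trial artifact rejection (absolute amplitude
on analysis channels, peak-to-peak on the ocular channels) -> per-condition
averaging -> zero-phase 30 Hz low-pass of the averages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, TransformerMixin

from .epochs import Epochs
from .layout import ChannelLayout

AVERAGE_COLUMNS = ["subject", "group", "condition"]


def lowpass_array(data: np.ndarray, sfreq: float, cutoff: float = 30.0,
                  order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis.

    Forward-backward application of an order-``order`` Butterworth filter:
    exactly zero phase (peaks do not shift), monotone magnitude with the
    squared single-pass response.
    """
    if cutoff >= sfreq / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {sfreq / 2.0} Hz")
    b, a = butter(order, cutoff, btype="low", fs=sfreq)
    return filtfilt(b, a, data, axis=-1)


class MastoidReferencer(BaseEstimator, TransformerMixin):
    """Re-reference scalp channels to the mean of the two mastoids.

    EOG channels are left untouched (they are bipolar ocular derivations,
    not scalp potentials referenced to the vertex).
    """

    def __init__(self, layout: ChannelLayout | None = None,
                 include_eog: bool = False):
        self.layout = layout
        self.include_eog = include_eog

    def fit(self, X: Epochs, y=None):
        return self

    def transform(self, X: Epochs) -> Epochs:
        layout = self.layout or ChannelLayout()
        out = X.copy()
        m_idx = out.channel_index(layout.mastoids)  # raises if missing
        ref = out.data[:, m_idx, :].mean(axis=1, keepdims=True)
        targets = (out.channels if self.include_eog
                   else [c for c in out.channels
                         if c not in layout.eog_channels])
        t_idx = out.channel_index(targets)
        out.data[:, t_idx, :] -= ref
        return out


class LowPassFilter(BaseEstimator, TransformerMixin):
    """Zero-phase low-pass (default 30 Hz, 4th-order Butterworth)."""

    def __init__(self, cutoff: float = 30.0, order: int = 4):
        self.cutoff = cutoff
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X: Epochs) -> Epochs:
        out = X.copy()
        out.data = lowpass_array(out.data, out.sfreq, self.cutoff, self.order)
        return out


class BaselineCorrector(BaseEstimator, TransformerMixin):
    """Subtract the per-trial, per-channel mean over the baseline window.

    The window is half-open [t0, t1) in the package's time convention
    (the sample at t covers [t, t+dt)), so (-100, 0) averages the 100 ms
    of pre-stimulus samples and excludes the stimulus-onset sample.
    """

    def __init__(self, window: tuple[float, float] = (-100.0, 0.0)):
        self.window = window

    def fit(self, X, y=None):
        return self

    def transform(self, X: Epochs) -> Epochs:
        t0, t1 = self.window
        mask = (X.times >= t0) & (X.times < t1)
        if not mask.any():
            raise ValueError(f"baseline window {self.window} contains no samples")
        out = X.copy()
        out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
        return out


class ArtifactRejector(BaseEstimator, TransformerMixin):
    """Per-trial rejection on amplitude and ocular criteria.

    A trial is removed iff any analysis channel exceeds ``amp_threshold``
    in absolute value (strictly greater: a trial peaking exactly at the
    threshold is retained), or the horizontal-EOG peak-to-peak exceeds
    ``heog_threshold``, or the vertical-EOG peak-to-peak exceeds
    ``veog_threshold``.  The first matching reason (amplitude, HEM, VEOG)
    is logged per trial.  Retained trials are unmodified; the log is
    attached to the returned epochs as ``rejection_log``.
    """

    def __init__(self, layout: ChannelLayout | None = None,
                 amp_threshold: float = 200.0, heog_threshold: float = 40.0,
                 veog_threshold: float = 100.0):
        self.layout = layout
        self.amp_threshold = amp_threshold
        self.heog_threshold = heog_threshold
        self.veog_threshold = veog_threshold

    def fit(self, X, y=None):
        return self

    def transform(self, X: Epochs) -> Epochs:
        for name in ("amp_threshold", "heog_threshold", "veog_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        layout = self.layout or ChannelLayout()
        a_idx = X.channel_index(layout.analysis_channels)
        h_idx = X.channel_index([layout.heog])
        v_idx = X.channel_index(layout.veog)
        amp_bad = (np.abs(X.data[:, a_idx, :]) > self.amp_threshold
                   ).any(axis=(1, 2))
        heog_p2p = (X.data[:, h_idx, :].max(axis=2)
                    - X.data[:, h_idx, :].min(axis=2)).max(axis=1)
        veog_p2p = (X.data[:, v_idx, :].max(axis=2)
                    - X.data[:, v_idx, :].min(axis=2)).max(axis=1)
        hem_bad = heog_p2p > self.heog_threshold
        veog_bad = veog_p2p > self.veog_threshold
        reason = np.full(X.n_epochs, "none", dtype=object)
        reason[veog_bad] = "VEOG"
        reason[hem_bad] = "HEM"
        reason[amp_bad] = "amplitude"   # precedence: amplitude > HEM > VEOG
        keep = reason == "none"

        log = X.info.copy()
        log["reason"] = reason.astype(str)
        log["retained"] = keep
        summary = (log.groupby(["subject", "condition"], sort=True)
                   .agg(n_total=("retained", "size"),
                        n_retained=("retained", "sum"))
                   .reset_index())
        summary["retained_fraction"] = (summary["n_retained"]
                                        / summary["n_total"])
        empty = summary[summary.n_retained == 0]
        for _, r in empty.iterrows():
            warnings.warn(
                f"subject {r.subject}: all trials of condition "
                f"{r.condition} rejected; subject should be excluded "
                "downstream", stacklevel=2)
        out = X.select(keep)
        out.rejection_log = log
        self.summary_ = summary
        return out


class ConditionAverager(BaseEstimator, TransformerMixin):
    """Arithmetic mean over retained trials per (subject, condition).

    Produces a frame with one row per subject x condition carrying the
    channel x time waveform, the retained-trial count and a low-trial
    flag (fewer than ``min_trials`` retained).
    """

    def __init__(self, min_trials: int = 40):
        self.min_trials = min_trials

    def fit(self, X, y=None):
        return self

    def transform(self, X: Epochs) -> "SubjectAverages":
        rows = []
        waves = []
        grouped = X.info.groupby(AVERAGE_COLUMNS, sort=True)
        for (subject, group, cond), idx in grouped.indices.items():
            if len(idx) == 0:
                raise ValueError(
                    f"zero retained trials for {subject}/{cond}")
            waves.append(X.data[idx].mean(axis=0))
            hand = X.info.loc[idx[0], "handedness"]
            rows.append({"subject": subject, "group": group,
                         "handedness": hand, "condition": cond,
                         "n_trials_used": len(idx),
                         "low_trials": len(idx) < self.min_trials})
        return SubjectAverages(pd.DataFrame(rows), np.array(waves),
                               list(X.channels), X.times.copy(), X.sfreq)


class SubjectAverages:
    """Per-subject, per-condition averaged waveforms.

    ``table`` has one row per average (subject, group, handedness,
    condition, n_trials_used, low_trials); ``data[i]`` is the matching
    channel x time waveform in microvolts.
    """

    def __init__(self, table: pd.DataFrame, data: np.ndarray,
                 channels: list[str], times: np.ndarray, sfreq: float):
        self.table = table.reset_index(drop=True)
        self.data = np.asarray(data, dtype=float)
        self.channels = channels
        self.times = np.asarray(times, dtype=float)
        self.sfreq = sfreq

    def copy(self) -> "SubjectAverages":
        return SubjectAverages(self.table.copy(), self.data.copy(),
                               list(self.channels), self.times.copy(),
                               self.sfreq)

    def channel_index(self, names: list[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.channels)}
        missing = [c for c in names if c not in pos]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return np.array([pos[c] for c in names], dtype=int)

    def get(self, subject: str, condition: str) -> np.ndarray:
        m = ((self.table.subject == subject)
             & (self.table.condition == condition))
        if not m.any():
            raise KeyError(f"no average for {subject}/{condition}")
        return self.data[m.to_numpy().nonzero()[0][0]]


class AverageLowPass(BaseEstimator, TransformerMixin):
    """Zero-phase low-pass applied to subject averages (the default place
    for the 30 Hz filter in this pipeline)."""

    def __init__(self, cutoff: float = 30.0, order: int = 4):
        self.cutoff = cutoff
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X: SubjectAverages) -> SubjectAverages:
        out = X.copy()
        out.data = lowpass_array(out.data, out.sfreq, self.cutoff, self.order)
        return out


# ------------------------------------------------------------ function API
def rereference_to_mastoids(epochs: Epochs,
                            layout: ChannelLayout | None = None) -> Epochs:
    return MastoidReferencer(layout).transform(epochs)


def lowpass_filter(epochs: Epochs, cutoff: float = 30.0,
                   order: int = 4) -> Epochs:
    return LowPassFilter(cutoff, order).transform(epochs)


def baseline_correct(epochs: Epochs,
                     window: tuple[float, float] = (-100.0, 0.0)) -> Epochs:
    return BaselineCorrector(window).transform(epochs)


def reject_artifacts(epochs: Epochs, layout: ChannelLayout | None = None,
                     amp_threshold: float = 200.0,
                     heog_threshold: float = 40.0,
                     veog_threshold: float = 100.0
                     ) -> tuple[Epochs, pd.DataFrame]:
    rej = ArtifactRejector(layout, amp_threshold, heog_threshold,
                           veog_threshold)
    out = rej.transform(epochs)
    return out, out.rejection_log


def average_conditions(epochs: Epochs, min_trials: int = 40) -> SubjectAverages:
    return ConditionAverager(min_trials).transform(epochs)


def preprocess_epochs(epochs: Epochs, layout: ChannelLayout | None = None,
                      config=None) -> SubjectAverages:
    """Run the configured preprocessing chain (default study recipe)."""
    from .config import PreprocessConfig
    cfg = config or PreprocessConfig()
    layout = layout or ChannelLayout()
    stages = {
        "rereference": MastoidReferencer(layout),
        "baseline": BaselineCorrector(cfg.baseline_window),
        "reject": ArtifactRejector(layout, cfg.amp_threshold_uV,
                                   cfg.heog_threshold_uV,
                                   cfg.veog_threshold_uV),
        "average": ConditionAverager(cfg.min_trials),
        "lowpass": None,  # placement depends on order
    }
    x = epochs
    log = None
    for name in cfg.order:
        if name == "lowpass":
            if isinstance(x, SubjectAverages):
                x = AverageLowPass(cfg.lowpass_hz, cfg.filter_order).transform(x)
            else:
                x = LowPassFilter(cfg.lowpass_hz, cfg.filter_order).transform(x)
        else:
            x = stages[name].transform(x)
            if name == "reject":
                log = x.rejection_log
    if not isinstance(x, SubjectAverages):
        raise ValueError("preprocessing order must include 'average'")
    x.rejection_log = log
    return x
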