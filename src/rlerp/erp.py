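"""Feedback-locked epoch handling and single-trial ERP scoring.

Epochs span 800 ms, from 200 ms before to 600 ms after feedback onset, and
are baseline-corrected to the mean of the 200 ms preceding feedback.
Artifact rejection applies four thresholds per scored channel: voltage step
above 50 uV/ms, absolute values above 100 uV, max-min range above 100 uV
within the epoch, and activity below 0.1 uV within any 100-ms interval.

FRN scoring is two-stage: the latency of the most negative strict local
minimum between 200 and 350 ms is localized on the participant's
condition-average waveform at the frontocentral (FCz-role) channel, then
each single trial is scored as the mean amplitude from 20 ms before to
20 ms after that latency (40-ms window).  Conditions without a detectable
peak propagate as outliers.  P3a (FCz-role) and P3b (Pz-role) are mean
amplitudes over 300-500 ms; note the FRN and P3a windows deliberately
overlap on 300-350 ms, as both are scored from the same epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

__all__ = [
    "EpochSet",
    "ArtifactThresholds",
    "segment_and_baseline",
    "reject_artifacts",
    "frn_peak_latency",
    "single_trial_frn",
    "p3_amplitude",
    "score_epochs",
    "preprocess_continuous",
]

FRN_WINDOW_MS = (200.0, 350.0)
FRN_HALF_WIDTH_MS = 20.0
P3_WINDOW_MS = (300.0, 500.0)
DEFAULT_CONDITIONS = ("session", "feedback_valence", "learnability")


@dataclass
class EpochSet:
    """Feedback-locked epochs: trial x channel x time, in microvolts."""

    data: np.ndarray
    sfreq: float
    tmin_s: float  # epoch start relative to feedback onset, seconds
    channel_names: list[str]
    channel_roles: dict[str, str]  # {"frn_p3a": "FCz", "p3b": "Pz"}
    trial_keys: pd.DataFrame  # join keys to the events table
    rejection_mask: np.ndarray | None = None  # True = rejected

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        for role, name in self.channel_roles.items():
            if name not in self.channel_names:
                raise ValueError(f"channel for role {role!r} ({name!r}) not present")
        if len(self.trial_keys) != self.data.shape[0]:
            raise ValueError("trial_keys must have one row per epoch")

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return (self.tmin_s + np.arange(n) / self.sfreq) * 1000.0

    def channel(self, role: str) -> int:
        return self.channel_names.index(self.channel_roles[role])

    def save(self, array_path, sidecar_path) -> None:
        np.save(array_path, self.data)
        meta = {
            "sampling_rate": self.sfreq,
            "tmin_s": self.tmin_s,
            "channel_names": self.channel_names,
            "channel_roles": self.channel_roles,
            "trial_keys": self.trial_keys.to_dict(orient="list"),
            "rejection_mask": (
                None if self.rejection_mask is None else self.rejection_mask.astype(int).tolist()
            ),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, array_path, sidecar_path) -> "EpochSet":
        data = np.load(array_path)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        mask = meta.get("rejection_mask")
        return cls(
            data=data,
            sfreq=meta["sampling_rate"],
            tmin_s=meta["tmin_s"],
            channel_names=list(meta["channel_names"]),
            channel_roles=dict(meta["channel_roles"]),
            trial_keys=pd.DataFrame(meta["trial_keys"]),
            rejection_mask=None if mask is None else np.asarray(mask, dtype=bool),
        )


@dataclass(frozen=True)
class ArtifactThresholds:
    """The four automatic rejection thresholds."""

    max_step_uv_per_ms: float = 50.0
    max_abs_uv: float = 100.0
    max_range_uv: float = 100.0
    min_activity_uv: float = 0.1
    activity_window_ms: float = 100.0


def segment_and_baseline(
    continuous: np.ndarray,
    onsets_ms: np.ndarray,
    sfreq: float,
    channel_names: list[str],
    channel_roles: dict[str, str],
    trial_keys: pd.DataFrame,
    tmin_s: float = -0.2,
    tmax_s: float = 0.6,
) -> tuple[EpochSet, list[int]]:
    """Cut feedback-locked epochs from a continuous signal and subtract the
    per-channel mean of the [-200, 0) ms baseline.

    ``continuous`` is (channels, samples); ``onsets_ms`` gives feedback
    onsets relative to the start of the recording.  Epochs cover
    [tmin_s, tmax_s) — 800 samples at 1000 Hz by default.  Onsets too close
    to the recording edge are dropped; their positions are returned so the
    caller can log them.  Returns (epochs, dropped_indices).
    """
    continuous = np.asarray(continuous, dtype=float)
    n_samp_epoch = int(round((tmax_s - tmin_s) * sfreq))
    n_baseline = int(round(-tmin_s * sfreq))
    onset_samples = np.round(np.asarray(onsets_ms) * sfreq / 1000.0).astype(int)
    starts = onset_samples + int(round(tmin_s * sfreq))
    keep, dropped = [], []
    for i, s in enumerate(starts):
        if s < 0 or s + n_samp_epoch > continuous.shape[1]:
            dropped.append(i)
        else:
            keep.append(i)
    if keep:
        data = np.stack(
            [continuous[:, starts[i] : starts[i] + n_samp_epoch] for i in keep]
        )
    else:
        data = np.empty((0, continuous.shape[0], n_samp_epoch))
    # baseline: mean over the samples strictly before feedback onset
    baseline = data[:, :, :n_baseline].mean(axis=2, keepdims=True)
    data = data - baseline
    epochs = EpochSet(
        data=data,
        sfreq=sfreq,
        tmin_s=tmin_s,
        channel_names=list(channel_names),
        channel_roles=dict(channel_roles),
        trial_keys=trial_keys.iloc[keep].reset_index(drop=True),
    )
    return epochs, dropped


def reject_artifacts(
    epochs: EpochSet,
    thresholds: ArtifactThresholds | None = None,
    channels: list[str] | None = None,
) -> np.ndarray:
    """Flag epochs violating any artifact threshold on any scored channel.

    By default only the channels carrying scoring roles are checked
    (configurable via ``channels``).  Returns a boolean mask (True =
    rejected) and stores it on the EpochSet.
    """
    thr = thresholds or ArtifactThresholds()
    if channels is None:
        channels = sorted({name for name in epochs.channel_roles.values()})
    idx = [epochs.channel_names.index(c) for c in channels]
    x = epochs.data[:, idx, :]  # (trials, scored channels, samples)

    ms_per_sample = 1000.0 / epochs.sfreq
    step = np.abs(np.diff(x, axis=2)) / ms_per_sample  # uV per ms
    bad_step = (step > thr.max_step_uv_per_ms).any(axis=(1, 2))
    bad_abs = (np.abs(x) > thr.max_abs_uv).any(axis=(1, 2))
    rng_epoch = x.max(axis=2) - x.min(axis=2)
    bad_range = (rng_epoch > thr.max_range_uv).any(axis=1)
    win = int(round(thr.activity_window_ms * epochs.sfreq / 1000.0)) + 1
    win = min(win, x.shape[2])
    local_range = maximum_filter1d(x, size=win, axis=2, mode="nearest") - minimum_filter1d(
        x, size=win, axis=2, mode="nearest"
    )
    # restrict to windows fully inside the epoch
    half = win // 2
    interior = local_range[:, :, half : x.shape[2] - (win - 1 - half)]
    bad_flat = (interior < thr.min_activity_uv).any(axis=(1, 2))

    mask = bad_step | bad_abs | bad_range | bad_flat
    epochs.rejection_mask = mask
    return mask


def frn_peak_latency(
    condition_average: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = FRN_WINDOW_MS,
) -> float | None:
    """Latency (ms) of the most negative strict local minimum strictly
    inside the search window, or None when no local minimum exists.

    A sample qualifies if it is lower than both neighbours (neighbours may
    lie on the window boundary).  Ties go to the earliest latency.
    """
    x = np.asarray(condition_average, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    inside = np.nonzero((t > window_ms[0]) & (t < window_ms[1]))[0]
    best_i = None
    for i in inside:
        if i == 0 or i == x.size - 1:
            continue
        if x[i] < x[i - 1] and x[i] < x[i + 1]:
            if best_i is None or x[i] < x[best_i]:
                best_i = i
    return None if best_i is None else float(t[best_i])


def single_trial_frn(
    epoch: np.ndarray,
    times_ms: np.ndarray,
    peak_latency_ms: float | None,
    half_width_ms: float = FRN_HALF_WIDTH_MS,
) -> float:
    """Mean amplitude from 20 ms before to 20 ms after the condition-average
    FRN peak; NaN when no peak latency is available."""
    if peak_latency_ms is None:
        return float("nan")
    t = np.asarray(times_ms, dtype=float)
    sel = (t >= peak_latency_ms - half_width_ms) & (t <= peak_latency_ms + half_width_ms)
    return float(np.asarray(epoch, dtype=float)[sel].mean())


def p3_amplitude(
    epoch: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = P3_WINDOW_MS,
) -> float:
    """Mean amplitude in the 300-500 ms post-feedback window."""
    t = np.asarray(times_ms, dtype=float)
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    return float(np.asarray(epoch, dtype=float)[sel].mean())


def score_epochs(
    epochs: EpochSet,
    condition_columns: tuple[str, ...] = DEFAULT_CONDITIONS,
    thresholds: ArtifactThresholds | None = None,
) -> pd.DataFrame:
    """Run the full single-trial scoring chain on one participant's epochs.

    Rejects artifacts, averages retained trials within each condition
    (feedback timing x valence x learnability by default), localizes the
    FRN peak per condition average, then scores every retained trial:
    ``frn_amplitude`` / ``frn_peak_latency_ms`` (NaN + outlier flag when the
    condition average has no detectable peak), ``p3a_amplitude``, and
    ``p3b_amplitude``.  Returns the trial-key table with scoring columns
    appended; rejected trials carry NaN amplitudes and ``rejected=True``.
    """
    mask = (
        epochs.rejection_mask
        if epochs.rejection_mask is not None
        else reject_artifacts(epochs, thresholds)
    )
    t = epochs.times_ms
    frn_ch = epochs.channel("frn_p3a")
    p3b_ch = epochs.channel("p3b")

    out = epochs.trial_keys.reset_index(drop=True).copy()
    out["rejected"] = mask
    out["frn_peak_latency_ms"] = np.nan
    out["frn_amplitude"] = np.nan
    out["p3a_amplitude"] = np.nan
    out["p3b_amplitude"] = np.nan
    out["outlier_flag"] = False

    missing = [c for c in condition_columns if c not in out.columns]
    if missing:
        raise ValueError(f"trial_keys lack condition columns: {missing}")
    cond_key = out[list(condition_columns)].astype(str).agg("|".join, axis=1)
    for _, idx in cond_key.groupby(cond_key).groups.items():
        retained = [i for i in idx if not mask[i]]
        if not retained:
            continue
        avg = epochs.data[retained, frn_ch, :].mean(axis=0)
        lat = frn_peak_latency(avg, t)
        for i in retained:
            out.at[i, "p3a_amplitude"] = p3_amplitude(epochs.data[i, frn_ch, :], t)
            out.at[i, "p3b_amplitude"] = p3_amplitude(epochs.data[i, p3b_ch, :], t)
            if lat is None:
                out.at[i, "outlier_flag"] = True
            else:
                out.at[i, "frn_peak_latency_ms"] = lat
                out.at[i, "frn_amplitude"] = single_trial_frn(
                    epochs.data[i, frn_ch, :], t, lat
                )
    return out


def preprocess_continuous(
    continuous: np.ndarray,
    sfreq: float,
    l_freq: float = 0.1,
    h_freq: float = 30.0,
    notch_hz: float | None = 50.0,
) -> np.ndarray:
    """Optional continuous-signal preprocessing: band-pass plus notch filter
    (mirrors a 0.1-30 Hz Butterworth band-pass with a 50 Hz notch)."""
    import mne

    x = np.asarray(continuous, dtype=float)
    x = mne.filter.filter_data(x, sfreq, l_freq=l_freq, h_freq=h_freq, verbose=False)
    if notch_hz is not None and notch_hz < sfreq / 2:
        x = mne.filter.notch_filter(x, sfreq, freqs=notch_hz, verbose=False)
    return x
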