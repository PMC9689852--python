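"""Band-pass filtering, resampling, epoching and raw feature concatenation.

The preprocessing chain mirrors the acquisition pipeline: a 1–15 Hz
zero-phase Butterworth band-pass, downsampling to 250 Hz, segmentation into
1-s stimulus-locked epochs (0–1 s inclusive, 251 samples at 250 Hz) and,
for the raw-feature decoder, channel-major flattening of each epoch into a
single vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import CLASSES, ContinuousRecording

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``epochs x channels x samples`` in µV."""

    data: np.ndarray
    labels: np.ndarray  # per-epoch class, one of CLASSES
    sampling_rate: float
    channel_labels: list
    window: tuple = (0.0, 1.0)
    provenance: pd.DataFrame | None = None  # run, trial, (subject)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = set(self.labels) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown epoch labels: {sorted(unknown)}")
        if self.data.ndim != 3 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be epochs x channels x samples, one label each")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, index) -> "EpochSet":
        index = np.asarray(index)
        if index.dtype != bool:
            index = index.astype(int)
        prov = None
        if self.provenance is not None:
            prov = self.provenance.iloc[index].reset_index(drop=True)
        return replace(self, data=self.data[index], labels=self.labels[index],
                       provenance=prov)

    def select_channels(self, channels) -> "EpochSet":
        idx = [self.channel_labels.index(ch) for ch in channels]
        return replace(self, data=self.data[:, idx, :], channel_labels=list(channels))

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return {str(lab): int(n) for lab, n in zip(labels, counts)}


@dataclass
class RawFeatureMatrix:
    """Epochs flattened channel-major into one feature vector each."""

    X: np.ndarray
    labels: np.ndarray


def bandpass(recording: ContinuousRecording, low: float = 1.0, high: float = 15.0,
             order: int = 4) -> ContinuousRecording:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    nyquist = recording.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyquist} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=filtered)


def resample(recording: ContinuousRecording, target_rate: float) -> ContinuousRecording:
    """Polyphase anti-aliased downsampling; event onsets are rescaled."""
    if target_rate >= recording.sampling_rate:
        raise ValueError("target rate must be below the current rate")
    frac = Fraction(target_rate / recording.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    ratio = target_rate / recording.sampling_rate
    events = [replace(e, onset=round(e.onset * ratio)) for e in recording.events]
    return ContinuousRecording(data=data, sampling_rate=target_rate,
                               channel_labels=recording.channel_labels, events=events)


def epoch(recording: ContinuousRecording, events=None,
          window: tuple = (0.0, 1.0)) -> EpochSet:
    """Cut one epoch per stimulus event, inclusive of both window endpoints.

    Targets are labeled by their run condition (``MC_target`` /
    ``MI_target``); events whose window would be truncated at the recording
    end are dropped with a warning.
    """
    events = recording.events if events is None else events
    rate = recording.sampling_rate
    n_samp = round((window[1] - window[0]) * rate) + 1
    start_off = round(window[0] * rate)
    data, labels, prov = [], [], []
    n_dropped = 0
    for e in events:
        start = e.onset + start_off
        if start < 0 or start + n_samp > recording.n_samples:
            n_dropped += 1
            continue
        data.append(recording.data[:, start : start + n_samp])
        labels.append(e.label)
        prov.append((e.run_index, e.trial_index, e.condition, e.side))
    if n_dropped:
        logger.warning("dropped %d events with truncated epochs", n_dropped)
    return EpochSet(
        data=np.asarray(data),
        labels=np.asarray(labels, dtype=object),
        sampling_rate=rate,
        channel_labels=list(recording.channel_labels),
        window=window,
        provenance=pd.DataFrame(prov, columns=["run", "trial", "condition", "side"]),
    )


def concatenate_raw(epochs: EpochSet) -> RawFeatureMatrix:
    """Stack each epoch's channels head-to-tail into one feature vector."""
    if epochs.n_epochs == 0:
        raise ValueError("empty EpochSet")
    X = epochs.data.reshape(epochs.n_epochs, epochs.n_channels * epochs.n_samples)
    return RawFeatureMatrix(X=X.copy(), labels=epochs.labels.copy())


def downsample_epochs(epochs: EpochSet, target_rate: float = 100.0) -> EpochSet:
    """Polyphase downsampling along the time axis (251 @ 250 Hz -> 101 @ 100 Hz)."""
    if target_rate >= epochs.sampling_rate:
        raise ValueError("target rate must be below the current rate")
    frac = Fraction(target_rate / epochs.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=2)
    return replace(epochs, data=data, sampling_rate=target_rate)


def preprocess_recording(recording: ContinuousRecording, low: float = 1.0,
                         high: float = 15.0, rate: float = 250.0) -> EpochSet:
    """The standard chain: band-pass, downsample, epoch."""
    return epoch(resample(bandpass(recording, low, high), rate))
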