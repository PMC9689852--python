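"""ERP averaging, component quantification and scalp topographies."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

#: Default measurement windows (ms); only the SP window is protocol-defined.
COMPONENT_WINDOWS = {
    "P2": (150.0, 250.0),
    "N2": (200.0, 350.0),
    "SP": (500.0, 800.0),
}


@dataclass
class ErpAverage:
    """Per-condition mean waveforms (channels x samples, µV)."""

    waveforms: dict          # condition -> channels x samples
    n_epochs: dict           # condition -> epoch count
    channel_labels: list
    sampling_rate: float
    window: tuple
    subject: str = "grand"

    def times_ms(self) -> np.ndarray:
        n = next(iter(self.waveforms.values())).shape[1]
        return (self.window[0] + np.arange(n) / self.sampling_rate) * 1000.0


@dataclass
class ComponentMeasure:
    """Amplitude/latency measures of one ERP component at one electrode."""

    name: str
    electrode: str
    window_ms: tuple
    mean_amplitude: float = np.nan
    peak_amplitude: float = np.nan
    peak_latency_ms: float = np.nan


def average_erp(epochs: EpochSet, by: str = "label",
                conditions=None, baseline: tuple | None = None) -> ErpAverage:
    """Arithmetic mean waveform per condition.

    ``by='label'`` splits by epoch class; ``by='condition'`` and
    ``by='targetness'`` split by the provenance columns.  Requested
    conditions without epochs are omitted with a warning.  No baseline
    correction is applied unless a (start_s, end_s) ``baseline`` is given.
    """
    if by == "label":
        groups = epochs.labels.astype(str)
    elif by == "condition":
        groups = epochs.provenance["condition"].to_numpy(dtype=object)
    elif by == "targetness":
        groups = np.where(epochs.labels == "nontarget", "nontarget", "target")
    else:
        raise ValueError(f"unknown split {by!r}")
    data = epochs.data
    if baseline is not None:
        i0 = round((baseline[0] - epochs.window[0]) * epochs.sampling_rate)
        i1 = round((baseline[1] - epochs.window[0]) * epochs.sampling_rate) + 1
        data = data - data[:, :, i0:i1].mean(axis=2, keepdims=True)
    wanted = list(dict.fromkeys(groups)) if conditions is None else list(conditions)
    waveforms, counts = {}, {}
    for cond in wanted:
        mask = groups == cond
        if not mask.any():
            warnings.warn(f"no epochs for condition {cond!r}; omitted")
            continue
        waveforms[cond] = data[mask].mean(axis=0)
        counts[cond] = int(mask.sum())
    return ErpAverage(waveforms=waveforms, n_epochs=counts,
                      channel_labels=list(epochs.channel_labels),
                      sampling_rate=epochs.sampling_rate, window=epochs.window)


def grand_average(averages) -> ErpAverage:
    """Mean over subject-level averages (epochs first, then subjects)."""
    first = averages[0]
    conds = first.waveforms.keys()
    waveforms = {c: np.mean([a.waveforms[c] for a in averages], axis=0) for c in conds}
    n = {c: int(np.sum([a.n_epochs[c] for a in averages])) for c in conds}
    return ErpAverage(waveforms=waveforms, n_epochs=n,
                      channel_labels=first.channel_labels,
                      sampling_rate=first.sampling_rate, window=first.window)


def measure_component(erp: ErpAverage, condition: str, name: str, electrode: str,
                      window_ms: tuple | None = None) -> ComponentMeasure:
    """Mean and peak amplitude (and peak latency) in the component window."""
    if electrode not in erp.channel_labels:
        raise ValueError(f"electrode {electrode!r} not in montage")
    window_ms = window_ms or COMPONENT_WINDOWS[name]
    times = erp.times_ms()
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    if not mask.any():
        raise ValueError("component window outside the epoch")
    trace = erp.waveforms[condition][erp.channel_labels.index(electrode)][mask]
    # peak = extremum of appropriate polarity (negative for N2)
    peak_i = int(np.argmin(trace)) if name == "N2" else int(np.argmax(trace))
    return ComponentMeasure(
        name=name, electrode=electrode, window_ms=tuple(window_ms),
        mean_amplitude=float(trace.mean()),
        peak_amplitude=float(trace[peak_i]),
        peak_latency_ms=float(times[mask][peak_i]),
    )


def topography(erp: ErpAverage, condition: str, window_ms: tuple) -> pd.Series:
    """Window-mean amplitude per channel, for topographic display/export."""
    times = erp.times_ms()
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    if not mask.any():
        raise ValueError("window outside the epoch")
    values = erp.waveforms[condition][:, mask].mean(axis=1)
    return pd.Series(values, index=erp.channel_labels, name=condition)


def export_waveforms(erp: ErpAverage, path) -> None:
    """Write all condition waveforms as a long-format TSV."""
    rows = []
    times = erp.times_ms()
    for cond, wf in erp.waveforms.items():
        for ci, ch in enumerate(erp.channel_labels):
            rows.append(pd.DataFrame({"condition": cond, "channel": ch,
                                      "time_ms": times, "amplitude_uv": wf[ci]}))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
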