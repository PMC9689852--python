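"""Reading and writing recordings: classic EDF for the signal, TSV for events.

The writer emits plain 16-bit EDF (one-second data records, per-channel
physical scaling); reading goes through :func:`mne.io.read_raw_edf`, so any
EDF produced elsewhere works as well.  Events travel in a tab-separated
sidecar whose comment header carries the exact sample count (EDF pads the
final record) and the sampling rate.
"""

from __future__ import annotations


from pathlib import Path

import numpy as np
import pandas as pd

EDF_NAME = "recording.edf"
EVENTS_NAME = "events.tsv"

_EVENT_COLUMNS = ["onset_sample", "side", "is_target", "condition", "run", "trial"]


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(data: np.ndarray, sampling_rate: int, channel_labels, path) -> None:
    """Write ``channels x samples`` data (µV) as a classic EDF file.

    The final data record is zero-padded; callers that need the exact length
    must record it separately (see :func:`write_recording`).
    """
    data = np.asarray(data, dtype=float)
    n_channels, n_samples = data.shape
    if n_channels != len(channel_labels):
        raise ValueError("channel label count does not match data rows")
    rate = int(sampling_rate)
    if rate != sampling_rate:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(n_samples / rate))

    # physical limits are serialized as 8-char ASCII; round-trip them through
    # the string form so the scaling we apply matches what a reader recovers
    pmins, pmaxs = [], []
    for ch in data:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            hi = lo + 1.0
        lo_s, hi_s = f"{lo:.6g}"[:8], f"{hi:.6g}"[:8]
        lo, hi = float(lo_s), float(hi_s)
        if hi <= lo:  # degenerate after truncation
            hi = lo + 1.0
        pmins.append(lo)
        pmaxs.append(hi)

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))
        fh.write(_ascii("Startdate X X X X", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(256 * (n_channels + 1), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(1, 8))
        fh.write(_ascii(n_channels, 4))
        for lab in channel_labels:
            fh.write(_ascii(f"EEG {lab}", 16))
        for _ in channel_labels:
            fh.write(_ascii("AgAgCl electrode", 80))
        for _ in channel_labels:
            fh.write(_ascii("uV", 8))
        for v in pmins:
            fh.write(_ascii(f"{v:.6g}", 8))
        for v in pmaxs:
            fh.write(_ascii(f"{v:.6g}", 8))
        for _ in channel_labels:
            fh.write(_ascii(-32768, 8))
        for _ in channel_labels:
            fh.write(_ascii(32767, 8))
        for _ in channel_labels:
            fh.write(_ascii("", 80))
        for _ in channel_labels:
            fh.write(_ascii(rate, 8))
        for _ in channel_labels:
            fh.write(_ascii("", 32))

        padded = np.zeros((n_channels, n_records * rate))
        padded[:, :n_samples] = data
        scale = np.array([(hi - lo) / 65535.0 for lo, hi in zip(pmins, pmaxs)])
        offset = np.array(pmins)
        digital = np.rint((padded - offset[:, None]) / scale[:, None]) - 32768
        digital = np.clip(digital, -32768, 32767).astype("<i2")
        for rec in range(n_records):
            chunk = digital[:, rec * rate : (rec + 1) * rate]
            fh.write(chunk.tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (data in µV, sampling rate, channel labels)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    labels = [lab.removeprefix("EEG ").strip() for lab in raw.ch_names]
    return data, float(raw.info["sfreq"]), labels


def write_events(events, path, sampling_rate: int, n_samples: int) -> None:
    rows = [
        (e.onset, e.side, int(e.is_target), e.condition, e.run_index, e.trial_index)
        for e in events
    ]
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={int(sampling_rate)}\n")
        fh.write(f"# n_samples={int(n_samples)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_events(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = int(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    onsets = df["onset_sample"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    return df, meta


def write_recording(recording, path) -> Path:
    """Serialize a ContinuousRecording to ``path/recording.edf`` + ``path/events.tsv``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_edf(recording.data, recording.sampling_rate, recording.channel_labels, path / EDF_NAME)
    write_events(
        recording.events, path / EVENTS_NAME, recording.sampling_rate, recording.data.shape[1]
    )
    return path


def read_recording(path):
    """Load a recording written by :func:`write_recording`."""
    from .simulate import ContinuousRecording, Event

    path = Path(path)
    data, rate, labels = read_edf(path / EDF_NAME)
    df, meta = read_events(path / EVENTS_NAME)
    if "n_samples" in meta:
        data = data[:, : meta["n_samples"]]
    if "sampling_rate" in meta and int(rate) != meta["sampling_rate"]:
        raise ValueError("sampling rate mismatch between EDF and event table")
    events = [
        Event(
            onset=int(r.onset_sample),
            side=str(r.side),
            is_target=bool(r.is_target),
            condition=str(r.condition),
            run_index=int(r.run),
            trial_index=int(r.trial),
        )
        for r in df.itertuples()
    ]
    return ContinuousRecording(
        data=data, sampling_rate=rate, channel_labels=list(labels), events=events
    )
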