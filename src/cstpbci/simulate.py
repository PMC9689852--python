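"""Synthetic sessions of the two-button cued-MI / mental-counting protocol.

A session consists of four runs — two under the mental-counting (MC)
instruction and two under cued motor imagery (MI), in random order.  Each
run has six trials; a trial starts with a 5-s side instruction ("left" or
"right") followed by 30 button flashes (200 ms stimulus, 800 ms
inter-stimulus interval), half of them on the instructed (target) side.

Stimulus-locked responses are built from three ERP components:

* **P2** — early visual positivity over occipital sites, peaking ≈200 ms,
  present for targets under both strategies and (attenuated) non-targets;
* **N2** — fronto-central negativity ≈280 ms, stronger under mental
  counting;
* **SP** — late central-midline positivity spanning 500–800 ms, strongest
  for motor-imagery targets (the sensorimotor potential of cued MI).

Each component is a unit-norm scalp topography times a Gaussian-windowed
half-sine temporal kernel.  Background activity is 1/f-shaped broadband
noise with an optional sinusoidal alpha component; target templates receive
trial-level multiplicative amplitude jitter.  Left/right sides exist only
in the event table: the decoder distinguishes mental strategy and
targetness, not side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import read_recording, write_recording  # noqa: F401  (re-exported API)

#: 22-electrode montage, in recording order.
MONTAGE_22 = (
    "Fp1", "Fp2", "Fz", "FC3", "FCz", "FC4", "C5", "C3", "Cz", "C4", "C6",
    "CP3", "CPz", "CP4", "P3", "Pz", "P4", "PO3", "POz", "PO4", "O1", "O2",
)

#: Epoch class labels used throughout the package.
MC_TARGET = "MC_target"
MI_TARGET = "MI_target"
NONTARGET = "nontarget"
CLASSES = (MC_TARGET, MI_TARGET, NONTARGET)

CONDITIONS = ("MC", "MI")


class ConfigurationError(ValueError):
    """Raised when a protocol configuration violates the design invariants."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Experimental-design constants; defaults reproduce the recorded protocol."""

    n_runs: int = 4
    runs_per_condition: int = 2
    trials_per_run: int = 6
    stimuli_per_trial: int = 30
    target_fraction: float = 0.5
    stimulus_duration_ms: float = 200.0
    inter_stimulus_interval_ms: float = 800.0
    instruction_duration_s: float = 5.0
    sampling_rate: float = 1000.0
    channel_labels: tuple = MONTAGE_22
    seed: int = 0

    def __post_init__(self):
        n_target = self.stimuli_per_trial * self.target_fraction
        if abs(n_target - round(n_target)) > 1e-9:
            raise ConfigurationError(
                "stimuli_per_trial x target_fraction must be an integer, got "
                f"{n_target}"
            )
        if self.runs_per_condition * len(CONDITIONS) != self.n_runs:
            raise ConfigurationError("runs_per_condition x conditions must equal n_runs")

    @property
    def n_targets_per_trial(self) -> int:
        return round(self.stimuli_per_trial * self.target_fraction)

    @property
    def soa_samples(self) -> int:
        """Stimulus-onset asynchrony (stimulus + ISI) in samples."""
        soa_ms = self.stimulus_duration_ms + self.inter_stimulus_interval_ms
        return round(soa_ms / 1000.0 * self.sampling_rate)


@dataclass(frozen=True)
class Event:
    """One button flash: onset sample, flashed side, targetness and context."""

    onset: int
    side: str
    is_target: bool
    condition: str
    run_index: int
    trial_index: int

    @property
    def label(self) -> str:
        return f"{self.condition}_target" if self.is_target else NONTARGET


@dataclass(frozen=True)
class ErpComponent:
    """One ERP component: scalp topography x temporal kernel."""

    name: str
    peak_ms: float
    half_width_ms: float
    amplitude_uv: float
    topography: np.ndarray  # unit-norm, one weight per channel

    def kernel(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        """Gaussian-windowed half-sine, peak value = amplitude (µV)."""
        t = np.arange(n_samples) / sampling_rate * 1000.0  # ms
        hw = self.half_width_ms
        u = (t - self.peak_ms + hw) / (2.0 * hw)
        halfsine = np.where((u >= 0) & (u <= 1), np.sin(np.pi * np.clip(u, 0, 1)), 0.0)
        window = np.exp(-0.5 * ((t - self.peak_ms) / hw) ** 2)
        return self.amplitude_uv * halfsine * window


@dataclass(frozen=True)
class ErpTemplateSet:
    """Per-class component lists over a fixed channel montage."""

    channel_labels: tuple
    components: dict  # class label -> list[ErpComponent]

    def __post_init__(self):
        for label, comps in self.components.items():
            for c in comps:
                if len(c.topography) != len(self.channel_labels):
                    raise ValueError(
                        f"{label}/{c.name}: topography length != channel count"
                    )
                if not 0.0 <= c.peak_ms <= 1000.0:
                    raise ValueError(f"{label}/{c.name}: peak latency outside [0, 1000] ms")

    def waveform(self, label: str, n_samples: int, sampling_rate: float) -> np.ndarray:
        """Render the class template as a channels x samples array (µV)."""
        out = np.zeros((len(self.channel_labels), n_samples))
        for comp in self.components.get(label, []):
            out += np.outer(comp.topography, comp.kernel(n_samples, sampling_rate))
        return out

    def validate_target_dominance(self) -> None:
        """Non-target component amplitudes must be strictly below target ones."""
        nt = {c.name: abs(c.amplitude_uv) for c in self.components.get(NONTARGET, [])}
        for label in (MC_TARGET, MI_TARGET):
            for c in self.components.get(label, []):
                if c.name in nt and nt[c.name] >= abs(c.amplitude_uv):
                    raise ValueError(
                        f"non-target {c.name} amplitude not smaller than {label}'s"
                    )


@dataclass
class NoiseParams:
    """Background-activity model.

    The broadband floor is 1/f-shaped noise split between a set of shared
    spatially coherent background sources (volume conduction smears ongoing
    activity across the scalp) and independent per-channel sensor noise;
    ``spatial_mixing`` is the variance fraction carried by the shared
    sources.  An occipitally weighted alpha sinusoid can be added on top.
    """

    broadband_sigma_uv: float = 8.0   # per-channel RMS before band-pass filtering
    spectral_exponent: float = 1.0    # power ~ 1/f**exponent
    spatial_mixing: float = 0.7       # fraction of shared (correlated) variance
    n_background_sources: int = 6
    alpha_amplitude_uv: float = 2.0
    alpha_freq_hz: float = 10.0
    trial_jitter_sd: float = 0.15     # log-normal sd of trial-level template gain


@dataclass
class ContinuousRecording:
    """Multichannel EEG (µV) with its sampling rate, montage and event table."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list
    events: list

    def __post_init__(self):
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data row count must equal channel-label count")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN")
        onsets = [e.onset for e in self.events]
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _topography(channel_labels, weights: dict) -> np.ndarray:
    v = np.zeros(len(channel_labels))
    for ch, w in weights.items():
        v[list(channel_labels).index(ch)] = w
    norm = np.linalg.norm(v)
    return v / norm if norm else v


def default_templates(channel_labels=MONTAGE_22) -> ErpTemplateSet:
    """Condition-dependent defaults: P2 occipital, N2 frontal (MC>MI), SP central (MI)."""
    occ = _topography(channel_labels, {"O1": 1.0, "O2": 1.0, "POz": 0.8, "PO3": 0.7,
                                       "PO4": 0.7, "Pz": 0.4})
    fro = _topography(channel_labels, {"Fz": 1.0, "FCz": 0.9, "Fp1": 0.6, "Fp2": 0.6,
                                       "FC3": 0.7, "FC4": 0.7})
    cen = _topography(channel_labels, {"Cz": 1.0, "FCz": 0.7, "CPz": 0.8, "C3": 0.5,
                                       "C4": 0.5, "CP3": 0.4, "CP4": 0.4})

    def comps(p2, n2, sp):
        out = [ErpComponent("P2", 200.0, 50.0, p2, occ),
               ErpComponent("N2", 280.0, 60.0, n2, fro)]
        if sp:
            out.append(ErpComponent("SP", 650.0, 150.0, sp, cen))
        return out

    templates = ErpTemplateSet(
        channel_labels=tuple(channel_labels),
        components={
            MC_TARGET: comps(5.0, -6.0, 1.5),
            MI_TARGET: comps(5.0, -3.0, 6.0),
            NONTARGET: comps(2.0, -1.2, 0.5),
        },
    )
    templates.validate_target_dominance()
    return templates


def null_templates(channel_labels=MONTAGE_22) -> ErpTemplateSet:
    """Identical templates for all classes: a null condition with no decodable signal."""
    base = default_templates(channel_labels).components[MC_TARGET]
    return ErpTemplateSet(
        channel_labels=tuple(channel_labels),
        components={label: list(base) for label in CLASSES},
    )


def build_protocol(config: ProtocolConfig) -> list:
    """Lay out the seeded event sequence of one session.

    Run conditions are a uniform random arrangement of two MC and two MI
    runs; each trial draws its instructed side at random and presents the
    two buttons in pseudorandom order with exactly half the flashes on the
    instructed side.
    """
    rng = np.random.default_rng(config.seed)
    conditions = list(CONDITIONS) * config.runs_per_condition
    conditions = [conditions[i] for i in rng.permutation(len(conditions))]

    instr = round(config.instruction_duration_s * config.sampling_rate)
    soa = config.soa_samples
    events = []
    cursor = 0
    for run_index, condition in enumerate(conditions):
        for trial_index in range(config.trials_per_run):
            cursor += instr
            instructed = rng.choice(["left", "right"])
            is_target = np.zeros(config.stimuli_per_trial, dtype=bool)
            is_target[: config.n_targets_per_trial] = True
            is_target = is_target[rng.permutation(config.stimuli_per_trial)]
            for tgt in is_target:
                side = instructed if tgt else ("left" if instructed == "right" else "right")
                events.append(
                    Event(onset=cursor, side=side, is_target=bool(tgt),
                          condition=condition, run_index=run_index,
                          trial_index=trial_index)
                )
                cursor += soa
    return events


def _pink(rng, n_rows, n_samples, sampling_rate, exponent):
    from scipy import fft as sfft

    x = rng.standard_normal((n_rows, n_samples))
    if exponent:
        spec = sfft.rfft(x, axis=1)
        freqs = sfft.rfftfreq(n_samples, d=1.0 / sampling_rate)
        freqs[0] = freqs[1] if len(freqs) > 1 else 1.0
        spec *= freqs ** (-exponent / 2.0)
        x = sfft.irfft(spec, n=n_samples, axis=1)
        x /= x.std(axis=1, keepdims=True)
    return x


def _shaped_noise(rng, n_channels, n_samples, sampling_rate, params: NoiseParams,
                  channel_labels=None):
    sensor = _pink(rng, n_channels, n_samples, sampling_rate,
                   params.spectral_exponent)
    m = params.spatial_mixing
    if m > 0 and params.n_background_sources > 0:
        sources = _pink(rng, params.n_background_sources, n_samples, sampling_rate,
                        params.spectral_exponent)
        topo = rng.standard_normal((n_channels, params.n_background_sources))
        topo /= np.linalg.norm(topo, axis=1, keepdims=True)  # unit shared variance
        mixed = np.sqrt(1.0 - m) * sensor + np.sqrt(m) * (topo @ sources)
    else:
        mixed = sensor
    noise = params.broadband_sigma_uv * mixed
    if params.alpha_amplitude_uv:
        t = np.arange(n_samples) / sampling_rate
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        gain = np.ones(n_channels)
        if channel_labels is not None:  # posterior-dominant alpha
            gain = np.array([1.0 if ch.startswith(("O", "PO", "P")) else 0.4
                             for ch in channel_labels])
        noise += params.alpha_amplitude_uv * gain[:, None] * np.sin(
            2 * np.pi * params.alpha_freq_hz * t[None, :] + phases[:, None]
        )
    return noise


def render_session(
    events,
    templates: ErpTemplateSet,
    noise: NoiseParams | None = None,
    seed: int = 0,
    sampling_rate: float = 1000.0,
    tail_s: float = 1.5,
) -> ContinuousRecording:
    """Superimpose class templates at event onsets on background noise."""
    noise = noise if noise is not None else NoiseParams()
    for label in CLASSES:
        if label not in templates.components:
            raise ValueError(f"templates missing class {label}")
    rng = np.random.default_rng(seed)
    n_channels = len(templates.channel_labels)
    template_len = round(sampling_rate) + 1  # 0-1 s inclusive
    n_samples = max(e.onset for e in events) + round(tail_s * sampling_rate)
    if max(e.onset for e in events) + template_len > n_samples:
        raise ValueError("template extends past recording end; increase tail_s")

    if noise.broadband_sigma_uv or noise.alpha_amplitude_uv:
        data = _shaped_noise(rng, n_channels, n_samples, sampling_rate, noise,
                             channel_labels=templates.channel_labels)
    else:
        data = np.zeros((n_channels, n_samples))

    waveforms = {
        label: templates.waveform(label, template_len, sampling_rate) for label in CLASSES
    }
    trial_gain: dict = {}
    for e in events:
        key = (e.run_index, e.trial_index)
        if key not in trial_gain:
            trial_gain[key] = (
                float(np.exp(rng.normal(0.0, noise.trial_jitter_sd)))
                if noise.trial_jitter_sd
                else 1.0
            )
        data[:, e.onset : e.onset + template_len] += trial_gain[key] * waveforms[e.label]

    return ContinuousRecording(
        data=data,
        sampling_rate=sampling_rate,
        channel_labels=list(templates.channel_labels),
        events=list(events),
    )


def simulate_session(
    config: ProtocolConfig | None = None,
    templates: ErpTemplateSet | None = None,
    noise: NoiseParams | None = None,
    seed: int | None = None,
) -> ContinuousRecording:
    """Convenience wrapper: protocol + rendering with a single session seed."""
    config = config or ProtocolConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    templates = templates or default_templates(config.channel_labels)
    events = build_protocol(config)
    return render_session(
        events, templates, noise=noise, seed=config.seed + 1,
        sampling_rate=config.sampling_rate,
    )
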