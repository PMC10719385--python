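"""Surrogate paired MMG/EMG session generator.

Emulates the cued finger-flexion protocol: three 30-trial sessions (all index
finger, all little finger, alternating), one auditory cue every 5 s, a 1 s
movement executed shortly after the cue, recorded at 2343.8 Hz on 4 bipolar
EMG channels and 8 OPM-MMG channels (4 biaxial sensors, Y and Z axes).

Each trial's movement appears as a burst of 25-100 Hz band-limited Gaussian
noise shaped by a smooth 1 s tapered-cosine (Tukey) envelope — raised-cosine
attack and release ramps (default 100 ms, matching the fast rise of real
flexion bursts) around a flat sustain — scaled per channel by a
class-dependent spatial gain matrix (ulnar-side channels stronger for the
little finger DV, radial-side for the index finger DII) and by the modality's
signal-to-noise ratio. Bursts ride on a 1/f background, a 50 Hz line
component, and white sensor noise. Ground-truth gains are retained so that
channel-importance recovery can be tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.signal import windows as _windows

from .containers import Channel, EventTable, MOVEMENT_LABELS, Recording
from .preprocess import bandpass
from .util import child_seed

#: class column order of the gain matrices
GAIN_CLASSES = MOVEMENT_LABELS  # ("DII", "DV")


def default_emg_channels() -> list[Channel]:
    sides = ["radial", "ulnar", "radial", "ulnar"]
    return [Channel(f"EMG-{i + 1}", "EMG", "none", sides[i]) for i in range(4)]


def default_mmg_channels() -> list[Channel]:
    sides = ["radial", "ulnar", "radial", "ulnar"]
    chans = []
    for sensor in range(4):
        for axis in ("Y", "Z"):
            chans.append(Channel(f"OPM-{sensor + 1}{axis}", "MMG", axis, sides[sensor]))
    return chans


def default_gain_emg() -> np.ndarray:
    """Per-channel x per-class (DII, DV) burst gains for the 4 EMG channels.

    Radial channels (1, 3) respond more to DII, ulnar channels (2, 4) to DV,
    mirroring the flexor digitorum anatomy.
    """
    return np.array(
        [
            [1.00, 0.30],  # EMG-1 radial
            [0.30, 1.00],  # EMG-2 ulnar
            [0.80, 0.25],  # EMG-3 radial
            [0.25, 0.80],  # EMG-4 ulnar
        ]
    )


def default_gain_mmg() -> np.ndarray:
    """Gains for the 8 OPM channels; the Z axis (skin-perpendicular) is
    weighted above Y within each sensor."""
    sensor = np.array(
        [
            [1.00, 0.30],  # sensor 1 radial
            [0.30, 1.00],  # sensor 2 ulnar
            [0.80, 0.25],  # sensor 3 radial
            [0.25, 0.80],  # sensor 4 ulnar
        ]
    )
    rows = []
    for s in range(4):
        rows.append(0.6 * sensor[s])  # Y axis
        rows.append(1.0 * sensor[s])  # Z axis
    return np.array(rows)


def default_session_plan(n_trials: int = 30) -> list[list[str]]:
    """Three sessions: all DII, all DV, alternating DII/DV."""
    return [
        ["DII"] * n_trials,
        ["DV"] * n_trials,
        [MOVEMENT_LABELS[i % 2] for i in range(n_trials)],
    ]


@dataclass
class GeneratorConfig:
    """Parameters of the surrogate experiment.

    SNR is the ratio of the burst RMS (over the movement window, after the
    taper, at per-channel gain 1) to the background RMS in the 25-100 Hz
    band of the same channel; only these ratios matter downstream because all
    windows are z-scored.
    """

    fs_raw: float = 2343.8
    trial_len: float = 5.0
    move_len: float = 1.0
    n_trials_per_session: int = 30
    session_plan: list[list[str]] = field(default_factory=default_session_plan)
    cue_offset: float = 0.3  # cue-to-movement-onset latency, s
    emg_channels: list[Channel] = field(default_factory=default_emg_channels)
    mmg_channels: list[Channel] = field(default_factory=default_mmg_channels)
    gain_emg: np.ndarray = field(default_factory=default_gain_emg)
    gain_mmg: np.ndarray = field(default_factory=default_gain_mmg)
    snr_emg: float = 1.5
    snr_mmg: float = 0.9
    burst_ramp: float = 0.1  # raised-cosine attack/release length, s
    band: tuple[float, float] = (25.0, 100.0)
    line_freq: float = 50.0
    line_amp: float = 0.5
    pink_exponent: float = 1.0
    pink_amp: float = 1.0
    white_amp: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.gain_emg = np.asarray(self.gain_emg, dtype=float)
        self.gain_mmg = np.asarray(self.gain_mmg, dtype=float)
        if self.fs_raw <= 2 * self.band[1]:
            raise ValueError("fs_raw must exceed twice the upper band edge")
        if not self.move_len < self.trial_len:
            raise ValueError("move_len must be shorter than trial_len")
        if self.n_trials_per_session < 1:
            raise ValueError("need at least one trial per session")
        if np.any(self.gain_emg < 0) or np.any(self.gain_mmg < 0):
            raise ValueError("gain matrices must be non-negative")
        if self.snr_emg <= 0 or self.snr_mmg <= 0:
            raise ValueError("SNR must be positive")
        if self.gain_emg.shape != (len(self.emg_channels), len(GAIN_CLASSES)):
            raise ValueError("gain_emg shape must be (n_emg_channels, n_classes)")
        if self.gain_mmg.shape != (len(self.mmg_channels), len(GAIN_CLASSES)):
            raise ValueError("gain_mmg shape must be (n_mmg_channels, n_classes)")
        if self.cue_offset < 0 or self.cue_offset + self.move_len > self.trial_len:
            raise ValueError("movement must fit inside the trial")
        if not 0.0 < self.burst_ramp <= self.move_len / 2:
            raise ValueError("burst_ramp must be in (0, move_len/2]")

    @property
    def session_len(self) -> float:
        return self.n_trials_per_session * self.trial_len


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent Gaussian noise with unit RMS, synthesized in the frequency
    domain (random phases, amplitude ∝ f^(-exponent/2))."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _band_rms(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    return float(np.sqrt(np.mean(bandpass(x, fs, *band) ** 2)))


def _generate_modality(
    rng: np.random.Generator,
    channels: list[Channel],
    gains: np.ndarray,
    snr: float,
    class_sequence: list[str],
    cfg: GeneratorConfig,
) -> np.ndarray:
    n_trials = len(class_sequence)
    n = int(round(n_trials * cfg.trial_len * cfg.fs_raw))
    n_move = int(round(cfg.move_len * cfg.fs_raw))
    t = np.arange(n) / cfg.fs_raw
    # smooth on/offset: cosine ramps of burst_ramp s, flat sustain in between
    # (burst_ramp = move_len/2 degenerates to a Hann window)
    taper = _windows.tukey(n_move, alpha=2.0 * cfg.burst_ramp / cfg.move_len)
    class_idx = {c: k for k, c in enumerate(GAIN_CLASSES)}

    data = np.empty((len(channels), n))
    for ch in range(len(channels)):
        bg = cfg.pink_amp * _pink_noise(rng, n, cfg.pink_exponent)
        bg += cfg.line_amp * np.sin(2 * np.pi * cfg.line_freq * t + rng.uniform(0, 2 * np.pi))
        bg += cfg.white_amp * rng.standard_normal(n)
        bg_band_rms = _band_rms(bg, cfg.fs_raw, cfg.band)
        sig = bg
        for trial, label in enumerate(class_sequence):
            amp = snr * gains[ch, class_idx[label]] * bg_band_rms
            if amp == 0.0:
                # draw anyway so the noise stream is independent of the gains
                rng.standard_normal(n_move)
                continue
            burst = bandpass(rng.standard_normal(n_move), cfg.fs_raw, *cfg.band)
            burst *= taper
            burst_rms = np.sqrt(np.mean(burst**2))
            if burst_rms > 0:
                burst *= amp / burst_rms
            start = int(round((trial * cfg.trial_len + cfg.cue_offset) * cfg.fs_raw))
            sig[start : start + n_move] += burst
        data[ch] = sig
    return data


def generate_session(
    cfg: GeneratorConfig, class_sequence: list[str], seed: int, session_id: str = "session"
) -> tuple[Recording, Recording, EventTable]:
    """Generate one time-aligned (EMG, MMG) recording pair and its event table.

    Identical seeds give bit-identical output; the event table depends only on
    the class sequence and timing parameters, never on the noise seed.
    """
    unknown = set(class_sequence) - set(GAIN_CLASSES)
    if unknown:
        raise ValueError(f"unknown labels in class_sequence: {sorted(unknown)}")
    if len(class_sequence) != cfg.n_trials_per_session:
        raise ValueError(
            f"class_sequence has {len(class_sequence)} entries, "
            f"expected n_trials_per_session={cfg.n_trials_per_session}"
        )
    rng = np.random.default_rng(seed)
    emg = _generate_modality(rng, cfg.emg_channels, cfg.gain_emg, cfg.snr_emg, class_sequence, cfg)
    mmg = _generate_modality(rng, cfg.mmg_channels, cfg.gain_mmg, cfg.snr_mmg, class_sequence, cfg)

    onsets = np.arange(len(class_sequence)) * cfg.trial_len + cfg.cue_offset
    events = EventTable(
        onsets=onsets,
        durations=np.full(len(class_sequence), cfg.move_len),
        labels=np.array(class_sequence, dtype=object),
    )
    rec_emg = Recording(emg, cfg.fs_raw, list(cfg.emg_channels), session_id=f"{session_id}-EMG")
    rec_mmg = Recording(mmg, cfg.fs_raw, list(cfg.mmg_channels), session_id=f"{session_id}-MMG")
    return rec_emg, rec_mmg, events


def generate_experiment(
    cfg: GeneratorConfig, seed: int | None = None
) -> list[tuple[Recording, Recording, EventTable]]:
    """Generate the full three-session experiment (all-DII / all-DV /
    alternating). Per-session seeds are derived deterministically from the
    master seed."""
    if seed is None:
        seed = cfg.seed
    if len(cfg.session_plan) != 3:
        raise ValueError("session_plan must have exactly 3 entries")
    sessions = []
    for s, plan in enumerate(cfg.session_plan):
        sessions.append(
            generate_session(cfg, list(plan), child_seed(seed, s), session_id=f"S{s + 1}")
        )
    return sessions
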