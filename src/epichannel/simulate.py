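"""Seeded synthetic referential EEG with group-dependent spectral structure.

Real interictal recordings from the clinic cannot be redistributed, so
this module generates stand-in populations with the one statistical
property the downstream pipeline relies on: elevated theta-band (4-8 Hz)
power on pathological channels.  Each electrode signal is a sum of

* five band-limited noise components (delta/theta/alpha/beta/gamma), each
  built by zero-phase band-pass filtering white noise and rescaling to a
  target RMS amplitude in microvolt;
* a 50 Hz mains sinusoid with an electrode-specific random phase (kept
  per-electrode rather than common-mode so it survives the bipolar
  subtraction and gives the wavelet denoiser genuine work);
* a 1/f "pink" background.

Three population archetypes are produced.  ``normal`` subjects use the
baseline amplitudes everywhere.  ``focal`` subjects have the theta
amplitude multiplied by ``theta_gain_focal`` (default 3.0) on the
electrodes of one temporal chain (left: Fp1, F7, T3, T5, O1; right: Fp2,
F8, T4, T6, O2; or both), mimicking lateralized temporal-lobe epilepsy.
``generalized`` subjects get a weaker ``theta_gain_generalized`` (default
1.5) on all 16 electrodes.  Filtered-noise band power scales with the
square of the requested amplitude, so a gain g raises theta power by
roughly g^2.

No epileptiform transients (spikes / sharp waves) and no ocular or
muscle artifacts are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import BANDS
from .montage import ELECTRODES, TEMPORAL_CHAINS
from .types import GROUPS, ReferentialRecording

#: Baseline RMS amplitude (uV) of each band-limited component in a
#: resting-state adult recording; amplitudes fall off with frequency.
DEFAULT_BAND_AMPLITUDES = {
    "delta": 20.0,
    "theta": 10.0,
    "alpha": 15.0,
    "beta": 5.0,
    "gamma": 2.0,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic EEG generator.

    ``affected_chain`` selects the pathological temporal chain for focal
    subjects: ``"left"``, ``"right"``, ``"both"``, or ``"random"`` to draw
    a laterality per subject.
    """

    fs: float = 500.0
    duration_s: float = 10.0
    band_amplitudes: dict = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    theta_gain_focal: float = 3.0
    theta_gain_generalized: float = 1.5
    line_amp: float = 10.0
    pink_noise_amp: float = 5.0
    affected_chain: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        for name, amp in self.band_amplitudes.items():
            if amp < 0:
                raise ValueError(f"negative amplitude for band {name!r}")
        if min(self.line_amp, self.pink_noise_amp) < 0:
            raise ValueError("amplitudes must be non-negative")
        if not self.theta_gain_focal > self.theta_gain_generalized >= 1.0:
            raise ValueError(
                "expected theta_gain_focal > theta_gain_generalized >= 1"
            )
        if self.affected_chain not in ("left", "right", "both", "random"):
            raise ValueError(
                f"unknown affected_chain {self.affected_chain!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def _bandlimited_noise(n, fs, f_lo, f_hi, rms, rng):
    """White noise band-passed to [f_lo, f_hi] and rescaled to `rms`."""
    white = rng.standard_normal(n)
    if rms == 0.0:
        return np.zeros(n)
    nyq = fs / 2.0
    f_hi = min(f_hi, 0.99 * nyq)
    sos = sps.butter(4, [f_lo / nyq, f_hi / nyq], btype="bandpass", output="sos")
    y = sps.sosfiltfilt(sos, white)
    scale = np.sqrt(np.mean(y**2))
    return y * (rms / scale) if scale > 0 else np.zeros(n)


def _pink_noise(n, rms, rng):
    """1/f-amplitude noise via spectral shaping, rescaled to `rms`."""
    white = rng.standard_normal(n)
    if rms == 0.0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    y = np.fft.irfft(spec * shape, n)
    scale = np.sqrt(np.mean(y**2))
    return y * (rms / scale) if scale > 0 else np.zeros(n)


def simulate_channel(
    band_amplitudes: dict,
    gains: dict | None,
    line_amp: float,
    pink_noise_amp: float,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one electrode trace (uV) from a seeded generator.

    ``gains`` maps band names to multiplicative amplitude factors applied
    on top of ``band_amplitudes`` (missing bands default to 1).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    gains = gains or {}
    x = np.zeros(n_samples)
    for name, (f_lo, f_hi) in BANDS.items():
        amp = band_amplitudes.get(name, 0.0) * gains.get(name, 1.0)
        x += _bandlimited_noise(n_samples, fs, f_lo, f_hi, amp, rng)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    if line_amp > 0.0:
        t = np.arange(n_samples) / fs
        x += line_amp * np.sin(2.0 * np.pi * 50.0 * t + phase)
    x += _pink_noise(n_samples, pink_noise_amp, rng)
    return x


def _resolve_chain(config: SimulationConfig, rng: np.random.Generator) -> str:
    if config.affected_chain == "random":
        return str(rng.choice(["left", "right", "both"]))
    return config.affected_chain


def simulate_subject(
    group: str,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "subj-000",
) -> ReferentialRecording:
    """Generate one subject's 16-electrode referential recording.

    ``group`` is ``"normal"``, ``"focal"`` or ``"generalized"``; see the
    module docstring for the corresponding spectral structure.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    affected: set[str] = set()
    if group == "focal":
        chain = _resolve_chain(config, rng)
        if chain in ("left", "both"):
            affected |= set(TEMPORAL_CHAINS["left"])
        if chain in ("right", "both"):
            affected |= set(TEMPORAL_CHAINS["right"])
    elif group == "generalized":
        affected = set(ELECTRODES)

    rows = []
    for electrode in ELECTRODES:
        gains = {}
        if electrode in affected:
            gains["theta"] = (
                config.theta_gain_focal
                if group == "focal"
                else config.theta_gain_generalized
            )
        rows.append(
            simulate_channel(
                config.band_amplitudes,
                gains,
                config.line_amp,
                config.pink_noise_amp,
                config.n_samples,
                config.fs,
                rng,
            )
        )
    return ReferentialRecording(
        subject_id=subject_id,
        group=group,
        electrodes=ELECTRODES,
        fs=config.fs,
        data=np.vstack(rows),
        affected_electrodes=frozenset(affected),
    )


def simulate_population(
    n_subjects: int,
    group: str,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> list[ReferentialRecording]:
    """Generate a reproducible population of one archetype.

    Per-subject generators are spawned deterministically from the master
    seed, so populations are identical across runs and subjects are
    statistically independent.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or SimulationConfig()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        simulate_subject(
            group,
            config,
            rng=np.random.default_rng(child),
            subject_id=f"{group}-{i:03d}",
        )
        for i, child in enumerate(children)
    ]
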