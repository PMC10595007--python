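"""Synthetic multichannel EEG with planted frontal alpha asymmetry.

Every pipeline stage is testable without human recordings: the
generator emulates the study shape — 10 subjects, 2,048 one-second
records each, balanced across the two condition labels — and plants the
class signal the frontal-asymmetry theory predicts. Each channel is the
sum of

* 1/f**gamma background noise (``noise_exponent``), and
* two band-limited oscillators — narrowband-filtered Gaussian noise in
  the alpha (8–14 Hz) and beta (14–30 Hz) bands — rather than pure
  tones, so band-power statistics have realistic window-to-window
  variance.

The class signal lives only in the frontal pair: for label 1 (positive
condition) the F8 alpha-oscillator power is multiplied by
``asymmetry_effect`` and the F7 alpha power divided by it; label 0
swaps the two channels. The planted F8:F7 alpha-oscillator power ratio
is therefore ``asymmetry_effect**2`` for label 1 and its inverse for
label 0, and ``asymmetry_effect = 1`` is an exact null. Beta stays
symmetric unless ``plant_beta_asymmetry`` is set. All non-frontal
channels carry identical background statistics and no class signal, so
univariate selection should prefer F7/F8-derived columns.

A per-subject log-normal gain (``subject_sd``) multiplies every channel
of a subject equally — a crude stand-in for anatomical differences in
overall signal power — which shifts raw band powers across subjects
while leaving asymmetry ratios untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .datamodel import DEFAULT_MONTAGE, EEGRecording
from .errors import ConfigurationError

#: Oscillator bands (name, low Hz, high Hz, share of oscillation power).
_OSCILLATORS = (("alpha", 8.0, 14.0, 0.5), ("beta", 14.0, 30.0, 0.5))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults emulate the study shape."""

    n_subjects: int = 10
    records_per_subject: int = 2048
    window_seconds: float = 1.0
    sampling_rate: float = 128.0
    asymmetry_effect: float = 2.0
    subject_sd: float = 0.2
    noise_exponent: float = 1.0
    snr: float = 1.0
    seed: int = 0
    plant_beta_asymmetry: bool = False
    amplitude_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")
        if self.records_per_subject < 2 or self.records_per_subject % 2:
            raise ConfigurationError(
                "records_per_subject must be even (balanced labels), got "
                f"{self.records_per_subject}"
            )
        if self.window_seconds <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("rates and durations must be positive")
        if self.asymmetry_effect < 0:
            raise ConfigurationError("asymmetry_effect must be >= 0")
        if self.subject_sd < 0 or self.snr < 0:
            raise ConfigurationError("subject_sd and snr must be >= 0")


def _powerlaw_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f**exponent spectrum."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.empty_like(f)
    shape[0] = 0.0  # no DC
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    sos = _signal.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _channel_asymmetry_gain(
    channel: str, band: str, label: int, cfg: SyntheticConfig
) -> float:
    """Amplitude gain planting the class-dependent frontal asymmetry."""
    planted = {"alpha"} | ({"beta"} if cfg.plant_beta_asymmetry else set())
    if band not in planted or channel not in ("F7", "F8"):
        return 1.0
    favored = "F8" if label == 1 else "F7"
    power_mult = cfg.asymmetry_effect if channel == favored else 1.0 / cfg.asymmetry_effect
    return float(np.sqrt(power_mult))


def simulate_recording(
    cfg: SyntheticConfig,
    subject_index: int,
    label: int,
    montage: tuple[str, ...] = DEFAULT_MONTAGE,
) -> EEGRecording:
    """One subject/condition recording, deterministic given the config seed.

    The recording is exactly long enough to yield
    ``records_per_subject / 2`` non-overlapping windows.
    """
    n_windows = cfg.records_per_subject // 2
    n = int(round(n_windows * cfg.window_seconds * cfg.sampling_rate))
    # independent streams per (seed, subject, label, channel); the gain
    # stream is shared by both labels of a subject
    gain_rng = np.random.default_rng([cfg.seed, subject_index, 10**6])
    subject_gain = float(np.exp(gain_rng.normal(0.0, cfg.subject_sd)))

    noise_power = 1.0
    osc_total = cfg.snr * noise_power
    data = np.empty((len(montage), n), dtype=float)
    for ci, ch in enumerate(montage):
        rng = np.random.default_rng([cfg.seed, subject_index, label, ci])
        x = np.sqrt(noise_power) * _powerlaw_noise(rng, n, cfg.noise_exponent)
        for band, low, high, share in _OSCILLATORS:
            amp = np.sqrt(osc_total * share) * _channel_asymmetry_gain(ch, band, label, cfg)
            x = x + amp * _narrowband_noise(rng, n, cfg.sampling_rate, low, high)
        data[ci] = cfg.amplitude_scale * np.sqrt(subject_gain) * x
    return EEGRecording(
        subject_id=f"S{subject_index:02d}",
        condition_label=label,
        channel_names=tuple(montage),
        samples=data,
        sampling_rate=cfg.sampling_rate,
    )


def simulate_dataset(cfg: SyntheticConfig) -> list[EEGRecording]:
    """All recordings of a synthetic study: one per subject per label."""
    return [
        simulate_recording(cfg, s, label)
        for s in range(cfg.n_subjects)
        for label in (0, 1)
    ]


def expected_fba_signs(cfg: SyntheticConfig, label: int) -> dict[str, int]:
    """Expected signs of the v2 and v4 metrics under the planted asymmetry.

    Used as a self-consistency oracle: for label 1 the generator makes
    alpha power at F8 exceed F7, so v4 = aR - aL must be positive in
    expectation and v2 = ln aL - ln aR negative; label 0 inverts both.
    """
    if cfg.asymmetry_effect == 1.0:
        raise ConfigurationError(
            "asymmetry_effect == 1 plants no asymmetry; expected signs are undefined"
        )
    if cfg.asymmetry_effect < 1.0:
        raise ConfigurationError("expected signs are defined for asymmetry_effect > 1")
    if label not in (0, 1):
        raise ConfigurationError("label must be 0 or 1")
    return {"v2": -1, "v4": 1} if label == 1 else {"v2": 1, "v4": -1}
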