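"""Band decomposition, PSD statistics and frontal-asymmetry metrics.

Each epoch is decomposed into five frequency bands (delta 0.5–4 Hz,
theta 4–8, alpha 8–14, beta 14–30, gamma 30–40) by zero-phase
Butterworth band-pass filtering. A one-sided rectangular-taper
periodogram of every decomposed signal gives a power spectral density
whose mean and population standard deviation form the per-channel
spectral features: 14 channels x 5 bands x 2 statistics = 140 values.

The remaining 8 features are valence/arousal metrics of frontal brain
asymmetry (FBA). With ``aL, aR`` the alpha and ``bL, bR`` the beta band
powers at F7 (left) and F8 (right):

    v1 = aR/bR - aL/bL           a1 = (aL + aR) / (bL + bR)
    v2 = ln aL - ln aR           a2 = -(ln aL + ln aR)
    v3 = bL/aL - bR/aR           a3 = log2((bL + bR) / (aL + aR))
    v4 = aR - aL                 a4 = (bL + bR) / (aL + aR)

Band power is the integral of the one-sided periodogram over the band
(density x bin width summed over ``low <= f < high``), floored at
``EPSILON_POWER`` so ratios and logarithms stay finite on degenerate
input. Relative alpha suppression over the left frontal cortex is the
classical marker of positively valenced affect, which is what v1–v4
quantify in four algebraic variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .datamodel import (
    VA_NAMES,
    Epoch,
    feature_names,
)
from .errors import BandError, ConfigurationError, MontageError
from .preprocessing import FilterSpec, _mirror_filtfilt, _pad_for

#: Floor applied to band powers before ratios/logarithms.
EPSILON_POWER = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[low_hz, high_hz)``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ConfigurationError(
                f"band {self.name}: need 0 <= low < high, got "
                f"[{self.low_hz}, {self.high_hz})"
            )


#: The five default bands.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)


@dataclass
class PSDEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray
    density: np.ndarray
    resolution_hz: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.frequencies.shape != self.density.shape:
            raise ConfigurationError("frequency and density vectors must align")


@dataclass(frozen=True)
class BandPowerQuad:
    """The four band powers feeding the valence/arousal metrics."""

    alpha_f7: float
    alpha_f8: float
    beta_f7: float
    beta_f8: float

    def __post_init__(self) -> None:
        for name in ("alpha_f7", "alpha_f8", "beta_f7", "beta_f8"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(
                    f"{name} must be strictly positive (apply the power floor upstream)"
                )


@dataclass
class FeatureVector:
    """148 named features plus the label and group of the source epoch."""

    values: pd.Series
    label: int
    group: str


def _band_sos(band: BandDefinition, sampling_rate: float, spec: FilterSpec) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if band.high_hz >= nyq:
        raise ConfigurationError(
            f"band {band.name} upper edge {band.high_hz} Hz >= Nyquist {nyq} Hz"
        )
    return _signal.butter(
        spec.order, (band.low_hz, band.high_hz), btype="bandpass",
        fs=sampling_rate, output="sos",
    )


def _decompose_array(
    x: np.ndarray,
    sampling_rate: float,
    bands: tuple[BandDefinition, ...],
    spec: FilterSpec,
) -> np.ndarray:
    """Filter ``x`` (..., time) into each band; returns (n_bands, ..., time)."""
    out = np.empty((len(bands),) + x.shape, dtype=float)
    for i, band in enumerate(bands):
        sos = _band_sos(band, sampling_rate, spec)
        if spec.zero_phase:
            out[i] = _mirror_filtfilt(sos, x, _pad_for(band.low_hz, sampling_rate))
        else:
            out[i] = _signal.sosfilt(sos, x, axis=-1)
    return out


def band_decompose(
    epoch: Epoch,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    spec: FilterSpec = FilterSpec(),
) -> dict[tuple[str, str], np.ndarray]:
    """Decompose an epoch into per-(channel, band) narrowband signals.

    Returns exactly ``n_channels x n_bands`` signals, each the length of
    the epoch, keyed ``(channel_name, band_name)``.
    """
    stack = _decompose_array(epoch.samples, epoch.sampling_rate, tuple(bands), spec)
    return {
        (ch, band.name): stack[bi, ci]
        for ci, ch in enumerate(epoch.channel_names)
        for bi, band in enumerate(bands)
    }


def periodogram_psd(x: np.ndarray, sampling_rate: float) -> PSDEstimate:
    """One-sided rectangular-taper periodogram of a signal.

    Satisfies the discrete Parseval identity:
    ``sum(density) * resolution_hz == mean(x**2)``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 8:
        raise ConfigurationError("need >= 8 samples for a periodogram")
    freqs, dens = _signal.periodogram(
        x, fs=sampling_rate, window="boxcar", detrend=False, axis=-1
    )
    return PSDEstimate(freqs, dens, resolution_hz=float(freqs[1] - freqs[0]))


def psd_stats(psd: PSDEstimate) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation of the density."""
    d = psd.density
    return float(d.mean()), float(d.std(ddof=0))


def band_power(psd: PSDEstimate, band: BandDefinition, floor: float = EPSILON_POWER) -> float:
    """Integrated PSD over ``low <= f < high``, floored at ``floor``."""
    mask = (psd.frequencies >= band.low_hz) & (psd.frequencies < band.high_hz)
    if not mask.any():
        raise BandError(
            f"band {band.name} [{band.low_hz}, {band.high_hz}) Hz contains no "
            f"bins at resolution {psd.resolution_hz} Hz"
        )
    return max(float(psd.density[..., mask].sum(axis=-1) * psd.resolution_hz), floor)


def valence_arousal(q: BandPowerQuad) -> dict[str, float]:
    """The eight FBA valence/arousal metrics from the alpha/beta quad."""
    aL, aR = q.alpha_f7, q.alpha_f8
    bL, bR = q.beta_f7, q.beta_f8
    return {
        "v1": aR / bR - aL / bL,
        "v2": np.log(aL) - np.log(aR),
        "v3": bL / aL - bR / aR,
        "v4": aR - aL,
        "a1": (aL + aR) / (bL + bR),
        "a2": -(np.log(aL) + np.log(aR)),
        "a3": np.log2((bL + bR) / (aL + aR)),
        "a4": (bL + bR) / (aL + aR),
    }


def _batch_features(
    samples: np.ndarray,
    sampling_rate: float,
    channel_names: tuple[str, ...],
    bands: tuple[BandDefinition, ...],
    spec: FilterSpec,
    floor: float,
) -> np.ndarray:
    """Feature rows for a stack of epochs ``(n_epochs, n_channels, time)``.

    Vectorized path shared by the single-epoch and matrix APIs: one
    filtering call per band over the whole stack.
    """
    n_ep, n_ch, _ = samples.shape
    bands = tuple(bands)
    try:
        i7 = channel_names.index("F7")
        i8 = channel_names.index("F8")
    except ValueError as exc:
        raise MontageError("feature extraction requires channels F7 and F8") from exc
    band_index = {b.name: k for k, b in enumerate(bands)}
    if "alpha" not in band_index or "beta" not in band_index:
        raise ConfigurationError("band set must include alpha and beta for FBA metrics")

    stack = _decompose_array(samples, sampling_rate, bands, spec)  # (B, E, C, T)
    freqs, dens = _signal.periodogram(
        stack, fs=sampling_rate, window="boxcar", detrend=False, axis=-1
    )
    df = float(freqs[1] - freqs[0])
    means = dens.mean(axis=-1)          # (B, E, C)
    stds = dens.std(axis=-1, ddof=0)    # (B, E, C)

    # 140 spectral statistics in channel-major, band-minor, stat-inner order
    spectral = np.empty((n_ep, n_ch * len(bands) * 2), dtype=float)
    col = 0
    for ci in range(n_ch):
        for bi in range(len(bands)):
            spectral[:, col] = means[bi, :, ci]
            spectral[:, col + 1] = stds[bi, :, ci]
            col += 2

    def _bp(bi: int, ci: int) -> np.ndarray:
        b = bands[bi]
        mask = (freqs >= b.low_hz) & (freqs < b.high_hz)
        if not mask.any():
            raise BandError(f"band {b.name} contains no periodogram bins")
        return np.maximum(dens[bi, :, ci][:, mask].sum(axis=-1) * df, floor)

    ai, bi_ = band_index["alpha"], band_index["beta"]
    aL, aR = _bp(ai, i7), _bp(ai, i8)
    bL, bR = _bp(bi_, i7), _bp(bi_, i8)
    va = np.column_stack([
        aR / bR - aL / bL,
        np.log(aL) - np.log(aR),
        bL / aL - bR / aR,
        aR - aL,
        (aL + aR) / (bL + bR),
        -(np.log(aL) + np.log(aR)),
        np.log2((bL + bR) / (aL + aR)),
        (bL + bR) / (aL + aR),
    ])
    return np.hstack([spectral, va])


def extract_features(
    epoch: Epoch,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    spec: FilterSpec = FilterSpec(),
    floor: float = EPSILON_POWER,
) -> FeatureVector:
    """Transform one epoch into its 148-dimensional feature vector."""
    row = _batch_features(
        epoch.samples[None, :, :], epoch.sampling_rate, epoch.channel_names,
        tuple(bands), spec, floor,
    )[0]
    names = feature_names(epoch.channel_names, tuple(b.name for b in bands))
    return FeatureVector(
        values=pd.Series(row, index=names),
        label=epoch.condition_label,
        group=epoch.subject_id,
    )


def extract_feature_matrix(
    epochs: list[Epoch],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    spec: FilterSpec = FilterSpec(),
    floor: float = EPSILON_POWER,
) -> pd.DataFrame:
    """Feature matrix for a list of epochs sharing montage and window length.

    Returns a DataFrame of feature columns plus ``label`` and ``group``,
    with identical column ordering for every input batch.
    """
    if not epochs:
        cols = feature_names() + ["label", "group"]
        return pd.DataFrame(columns=cols)
    first = epochs[0]
    for ep in epochs:
        if ep.channel_names != first.channel_names:
            raise MontageError("all epochs in a dataset must share the montage")
        if ep.samples.shape != first.samples.shape:
            raise ConfigurationError("all epochs must share the window length")
    stack = np.stack([ep.samples for ep in epochs])
    rows = _batch_features(
        stack, first.sampling_rate, first.channel_names, tuple(bands), spec, floor
    )
    names = feature_names(first.channel_names, tuple(b.name for b in bands))
    frame = pd.DataFrame(rows, columns=names)
    frame["label"] = [ep.condition_label for ep in epochs]
    frame["group"] = [ep.subject_id for ep in epochs]
    return frame
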