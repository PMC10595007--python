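"""Core data types and on-disk formats.

The pipeline's unit of raw data is one subject/condition recording:
a channel x time matrix on the 14-electrode consumer montage
(AF3, AF4, F3, F4, FC5, FC6, F7, F8, T7, T8, P7, P8, O1, O2) sampled at
128 Hz, carrying a binary condition label (0 = negative, 1 = positive)
and the subject identifier used as the cross-validation group.

All files are comma-delimited UTF-8 text with one header line. Feature
matrices are plain DataFrames: 148 named feature columns followed by
``label`` and ``group``. Lines starting with ``#`` are treated as
comments (used for provenance headers) by all readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, MontageError, ParseError

#: Electrode names of the 14-channel montage, in canonical order.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "AF3", "AF4", "F3", "F4", "FC5", "FC6", "F7", "F8",
    "T7", "T8", "P7", "P8", "O1", "O2",
)

#: Frontal pair used for the asymmetry metrics.
FRONTAL_PAIR: tuple[str, str] = ("F7", "F8")

#: The five band names in spectral order.
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Names of the eight valence/arousal features, in vector order.
VA_NAMES: tuple[str, ...] = ("v1", "v2", "v3", "v4", "a1", "a2", "a3", "a4")

LABEL_COLUMN = "label"
GROUP_COLUMN = "group"


def feature_names(
    montage: tuple[str, ...] = DEFAULT_MONTAGE,
    bands: tuple[str, ...] = BAND_NAMES,
) -> list[str]:
    """Canonical ordered feature-column names.

    Channel-major, band-minor, statistic-innermost:
    ``<channel>_<band>_psd_mean``, ``<channel>_<band>_psd_std`` for every
    (channel, band) pair, followed by the eight asymmetry metrics
    ``v1..v4, a1..a4``.  For the default montage this yields
    14 x 5 x 2 + 8 = 148 names.
    """
    names = [
        f"{ch}_{band}_{stat}"
        for ch in montage
        for band in bands
        for stat in ("psd_mean", "psd_std")
    ]
    names.extend(VA_NAMES)
    return names


@dataclass
class EEGRecording:
    """One subject/condition multichannel EEG signal.

    Parameters
    ----------
    subject_id
        Group identifier used for leave-one-subject-out splitting.
    condition_label
        Binary condition code, 0 (negative) or 1 (positive).
    channel_names
        Ordered electrode names, one per row of ``samples``.
    samples
        ``(n_channels, n_samples)`` array in microvolt-scale units. The
        pipeline never rescales: every downstream feature is either a
        ratio or min-max normalized.
    sampling_rate
        Sampling frequency in Hz (default 128).
    """

    subject_id: str
    condition_label: int
    channel_names: tuple[str, ...]
    samples: np.ndarray
    sampling_rate: float = 128.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise IntegrityError("samples must be a 2-D channel x time array")
        if self.samples.shape[0] != len(self.channel_names):
            raise IntegrityError(
                f"{self.samples.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise IntegrityError("sampling_rate must be positive")
        if self.samples.shape[1] < 1:
            raise IntegrityError("recording must contain at least one sample")
        if int(self.condition_label) not in (0, 1):
            raise IntegrityError("condition_label must be 0 or 1")
        self.condition_label = int(self.condition_label)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def require_frontal_pair(self) -> tuple[int, int]:
        """Indices of (F7, F8), raising :class:`MontageError` if absent."""
        try:
            return (self.channel_names.index("F7"), self.channel_names.index("F8"))
        except ValueError as exc:
            raise MontageError(
                "montage must contain F7 and F8 for frontal-asymmetry metrics; "
                f"got {list(self.channel_names)}"
            ) from exc


@dataclass
class Epoch:
    """A fixed-length window cut from a recording; one classification record."""

    subject_id: str
    condition_label: int
    window_index: int
    samples: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...] = field(default=DEFAULT_MONTAGE)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise IntegrityError("epoch samples must be 2-D")
        if self.samples.shape[1] < 8:
            raise IntegrityError("epoch needs >= 8 samples to estimate a spectrum")
        if self.window_index < 0:
            raise IntegrityError("window_index must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def _looks_like_channel_header(tokens: list[str], montage: tuple[str, ...]) -> bool:
    """True when the header row names channels (channel-per-column layout)."""
    known = set(montage)
    hits = sum(1 for t in tokens if t in known)
    return hits >= max(2, len(tokens) // 2)


def read_recording(
    path,
    subject_id: str,
    condition_label: int,
    sampling_rate: float = 128.0,
    montage: tuple[str, ...] | None = DEFAULT_MONTAGE,
    validate_montage: bool = True,
) -> EEGRecording:
    """Read a delimited recording file into an :class:`EEGRecording`.

    Two layouts are accepted and auto-detected from the header line:

    * channel-per-column: header = channel names, one row per time sample;
    * channel-per-row: first column holds channel names, remaining columns
      are time samples (header tokens are then sample indices).

    Raises
    ------
    MontageError
        F7 or F8 missing while ``validate_montage`` is true.
    ParseError
        A non-numeric cell, reported with its row/column position.
    """
    ref = montage if montage is not None else DEFAULT_MONTAGE
    header = ""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line
                break
    tokens = [t.strip() for t in header.strip().split(",")]

    if _looks_like_channel_header(tokens, ref):
        frame = pd.read_csv(path, comment="#")
        names = [str(c) for c in frame.columns]
        raw = frame.to_numpy()
        data = _coerce_numeric(raw, names, rows_are_channels=False)
        data = data.T  # -> channel x time
    else:
        frame = pd.read_csv(path, comment="#", header=0)
        names = [str(v) for v in frame.iloc[:, 0].tolist()]
        raw = frame.iloc[:, 1:].to_numpy()
        data = _coerce_numeric(raw, names, rows_are_channels=True)

    rec = EEGRecording(
        subject_id=subject_id,
        condition_label=condition_label,
        channel_names=tuple(names),
        samples=data,
        sampling_rate=sampling_rate,
    )
    if validate_montage:
        missing = [ch for ch in FRONTAL_PAIR if ch not in rec.channel_names]
        if missing:
            raise MontageError(
                f"recording {path} lacks required channel(s) {missing}"
            )
    return rec


def _coerce_numeric(raw: np.ndarray, names: list[str], rows_are_channels: bool) -> np.ndarray:
    try:
        return raw.astype(float)
    except (TypeError, ValueError):
        pass
    # locate the first offending cell for the error message
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            try:
                float(raw[i, j])
            except (TypeError, ValueError):
                where = (
                    f"channel {names[i]!r}, sample {j}"
                    if rows_are_channels
                    else f"row {i}, channel {names[j]!r}"
                )
                raise ParseError(
                    f"non-numeric value {raw[i, j]!r} at {where}"
                ) from None
    raise ParseError("table could not be parsed as numeric")  # pragma: no cover


def write_recording(rec: EEGRecording, path, header_comment: str | None = None) -> None:
    """Write a recording in the canonical channel-per-column layout."""
    frame = pd.DataFrame(rec.samples.T, columns=list(rec.channel_names))
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.8g", lineterminator="\n")


def validate_feature_matrix(frame: pd.DataFrame) -> None:
    """Check the feature-matrix contract; raise :class:`IntegrityError` if broken."""
    for col in (LABEL_COLUMN, GROUP_COLUMN):
        if col not in frame.columns:
            raise IntegrityError(f"feature matrix lacks required column {col!r}")
    labels = frame[LABEL_COLUMN]
    if len(frame) and not labels.isin((0, 1)).all():
        raise IntegrityError("labels must be 0 or 1")
    if len(frame) and (frame[GROUP_COLUMN].astype(str).str.len() == 0).any():
        raise IntegrityError("group identifiers must be non-empty")
    feats = frame[feature_columns(frame)]
    if len(frame) and not np.isfinite(feats.to_numpy(dtype=float)).all():
        raise IntegrityError("feature values must all be finite")


def feature_columns(frame: pd.DataFrame) -> list[str]:
    """The feature columns of a matrix (everything except label/group)."""
    return [c for c in frame.columns if c not in (LABEL_COLUMN, GROUP_COLUMN)]


def write_feature_matrix(frame: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a feature matrix as CSV, lossless to 12 significant digits."""
    validate_feature_matrix(frame)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise IntegrityError(f"malformed feature matrix {path}: {exc}") from exc
    if GROUP_COLUMN in frame.columns:
        frame[GROUP_COLUMN] = frame[GROUP_COLUMN].astype(str)
    validate_feature_matrix(frame)
    return frame
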