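"""Loading, validation and denoising of multichannel sEMG recordings.

A :class:`Recording` holds a ``T × n`` matrix of amplitudes in volts (one row
per electrode channel) together with its sampling rate. Recordings are read
from plain delimited text (comma or whitespace), denoised with a zero-phase
Butterworth band-pass filter, and optionally Z-score normalized (the raw-signal
baseline used for ablation comparisons).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import signal as sps

from .errors import LengthError, ParseError, SemgError, ShapeError

logger = logging.getLogger(__name__)

Layout = Literal["channels-in-rows", "channels-in-columns"]
Scope = Literal["per-channel", "global"]


@dataclass
class Recording:
    """A labeled multichannel raw signal.

    Parameters
    ----------
    samples
        ``T × n`` float array, channels as rows, amplitudes in volts.
    fs
        Sampling rate in Hz (positive).
    label
        Optional gesture identifier.
    subject
        Optional subject identifier.
    meta
        Free-form provenance (filter settings, generator seeds, ...).
    """

    samples: np.ndarray
    fs: float
    label: int | str | None = None
    subject: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ShapeError(
                f"samples must be 2-D (channels × time), got ndim={self.samples.ndim}"
            )
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ShapeError(f"empty recording with shape {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise SemgError("recording contains non-finite amplitudes")
        if not self.fs > 0:
            raise SemgError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _parse_matrix(text: str, path: str) -> np.ndarray:
    """Parse comma- or whitespace-delimited numeric text into a 2-D array."""
    rows: list[list[float]] = []
    width: int | None = None
    for lineno, line in enumerate(io.StringIO(text), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        tokens = stripped.replace(",", " ").split()
        row = []
        for colno, tok in enumerate(tokens, start=1):
            try:
                row.append(float(tok))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at row {lineno}, column {colno}"
                ) from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ShapeError(
                f"{path}: ragged row {lineno} has {len(row)} values, expected {width}"
            )
        rows.append(row)
    if not rows:
        raise ShapeError(f"{path}: no numeric rows found")
    return np.array(rows, dtype=float)


def read_recording(
    path: str | Path,
    layout: Layout = "channels-in-rows",
    fs: float = 2000.0,
    label: int | str | None = None,
    subject: str | None = None,
) -> Recording:
    """Read a delimited text matrix as a Recording in channels × samples form.

    ``layout`` names the orientation *on disk*; the returned Recording always
    has channels as rows.
    """
    path = Path(path)
    mat = _parse_matrix(path.read_text(), str(path))
    if layout == "channels-in-columns":
        mat = mat.T
    elif layout != "channels-in-rows":
        raise ValueError(f"unknown layout {layout!r}")
    return Recording(mat, fs=fs, label=label, subject=subject, meta={"path": str(path)})


def write_recording(
    rec: Recording, path: str | Path, layout: Layout = "channels-in-rows"
) -> None:
    """Write a Recording as delimited text, inverse of :func:`read_recording`."""
    mat = rec.samples if layout == "channels-in-rows" else rec.samples.T
    np.savetxt(path, mat, delimiter=",", fmt="%.17g")


def bandpass_filter(
    rec: Recording,
    low: float = 10.0,
    high: float = 500.0,
    order: int = 4,
    kind: Literal["bandpass", "lowpass"] = "bandpass",
) -> Recording:
    """Zero-phase Butterworth filter, applied independently per channel.

    Defaults follow standard sEMG practice: 4th-order band-pass with edges at
    10 and 500 Hz, covering the band where surface-EMG power concentrates.
    An upper edge at or above the Nyquist frequency is clamped to
    ``0.99 · fs/2`` with a logged warning, so 1000 Hz devices work with the
    default 500 Hz edge. Filtering is forward–backward (``sosfiltfilt``) so
    the temporal alignment of features is preserved.
    """
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    nyq = rec.fs / 2.0
    if high >= nyq:
        clamped = 0.99 * nyq
        logger.warning(
            "upper cutoff %.6g Hz >= Nyquist %.6g Hz; clamped to %.6g Hz",
            high, nyq, clamped,
        )
        high = clamped
    if kind == "lowpass":
        sos = sps.butter(order, high, btype="lowpass", fs=rec.fs, output="sos")
    else:
        sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    try:
        filtered = sps.sosfiltfilt(sos, rec.samples, axis=-1)
    except ValueError as exc:
        raise LengthError(
            f"recording of length {rec.n_samples} too short for stable "
            f"order-{order} zero-phase filtering: {exc}"
        ) from exc
    meta = dict(rec.meta)
    meta["filter"] = {"kind": kind, "low": low, "high": high, "order": order}
    return replace(rec, samples=filtered, meta=meta)


def zscore_normalize(rec: Recording, scope: Scope = "per-channel") -> Recording:
    """Z-score the recording to mean 0 / SD 1 per channel or globally.

    This is the raw-signal baseline of the ablation study (variant T1).
    A zero-variance scope yields zeros for that scope with a logged warning.
    """
    x = rec.samples
    if scope == "per-channel":
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
    elif scope == "global":
        mean = np.full((1, 1), x.mean())
        sd = np.full((1, 1), x.std())
    else:
        raise ValueError(f"unknown scope {scope!r}")
    degenerate = sd == 0
    if np.any(degenerate):
        logger.warning(
            "zscore_normalize: %d zero-variance scope(s) mapped to zeros",
            int(degenerate.sum()),
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (x - mean) / safe_sd
    z = np.where(np.broadcast_to(degenerate, z.shape), 0.0, z)
    meta = dict(rec.meta)
    meta["zscore_scope"] = scope
    return replace(rec, samples=z, meta=meta)
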