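"""Sliding-window segmentation of feature matrices into grayscale images.

Mapped feature matrices are cut into ``T × L`` windows (``L = k·f/1000`` for
a window of ``k`` ms at sampling rate ``f``) advanced by a stride of ``h``
ms, and each window is rescaled to 8-bit grayscale: channels are image rows,
time is the horizontal axis. Images are written as single-channel PNGs with a
CSV manifest so the dataset round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigError, LengthError
from .multimap import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class GrayscaleMap:
    """One ``T × L`` 8-bit feature image with label and provenance."""

    pixels: np.ndarray  # T × L uint8
    label: int | str | None = None
    subject: str | None = None
    recording: str | None = None
    start_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ConfigError(f"pixels must be 2-D, got ndim={px.ndim}")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)) or np.any(px != np.round(px)):
                raise ConfigError("pixel values must be integers in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def window_length(k_ms: float, f_hz: float) -> int:
    """Samples per image window: ``L = k × f / 1000`` (k in ms, f in Hz).

    200 ms at 2000 Hz gives the canonical 400-sample window (images of size
    ``400 × T``). A non-integer product is a configuration error.
    """
    if k_ms <= 0 or f_hz <= 0:
        raise ConfigError(f"need positive k and f, got k={k_ms} ms, f={f_hz} Hz")
    raw = k_ms * f_hz / 1000.0
    L = round(raw)
    if abs(raw - L) > 1e-9 or L < 1:
        raise ConfigError(
            f"window k={k_ms} ms at f={f_hz} Hz gives non-integer length {raw}"
        )
    return int(L)


def segment(
    fm: FeatureMatrix, k_ms: float = 200.0, h_ms: float = 50.0
) -> list[tuple[int, np.ndarray]]:
    """Cut a feature matrix into ``T × L`` windows at stride ``h`` ms.

    Returns ``(start_index, window)`` pairs at starts ``0, step, 2·step, …``;
    the count is ``floor((m − L)/step) + 1``. Channel order is preserved
    top-to-bottom.
    """
    L = window_length(k_ms, fm.fs)
    step = window_length(h_ms, fm.fs)  # same divisibility rule as L
    m = fm.length
    if m < L:
        raise LengthError(
            f"recording too short: feature length {m} < window L={L}"
        )
    starts = range(0, m - L + 1, step)
    return [(s, fm.values[:, s : s + L]) for s in starts]


def to_grayscale(
    window: np.ndarray,
    vmin: float | None = None,
    vmax: float | None = None,
    **map_fields,
) -> GrayscaleMap:
    """Rescale a feature window to 8-bit gray: ``y = 255·(x − vmin)/(vmax − vmin)``.

    Bounds default to the window's own min/max (per-window scope, maximal
    contrast); pass explicit bounds for a global scope. Rounding is half-up,
    clipped to [0, 255]; a constant window maps to all zeros with a warning.
    """
    window = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(window)):
        raise ConfigError("window contains non-finite values")
    if vmin is None:
        vmin = float(window.min())
    if vmax is None:
        vmax = float(window.max())
    if vmax == vmin:
        logger.warning("to_grayscale: constant window mapped to all-zero image")
        pixels = np.zeros(window.shape, dtype=np.uint8)
    else:
        y = 255.0 * (window - vmin) / (vmax - vmin)
        # 1e-9 nudge so values an ulp below a half-integer (float artifacts of
        # the affine map) still round half-up as the exact rational would
        pixels = np.clip(np.floor(y + 0.5 + 1e-9), 0, 255).astype(np.uint8)
    return GrayscaleMap(pixels, **map_fields)


def imagize(
    fm: FeatureMatrix,
    k_ms: float = 200.0,
    h_ms: float = 50.0,
    scope: str = "per-window",
) -> list[GrayscaleMap]:
    """Segment a feature matrix and grayscale every window.

    ``scope="global"`` shares one min/max across all windows of the matrix;
    the default rescales each window independently.
    """
    if scope == "global":
        vmin, vmax = float(fm.values.min()), float(fm.values.max())
    elif scope == "per-window":
        vmin = vmax = None
    else:
        raise ValueError(f"unknown scope {scope!r}")
    rec_id = fm.meta.get("recording") or fm.meta.get("path")
    return [
        to_grayscale(
            win, vmin=vmin, vmax=vmax,
            label=fm.label, subject=fm.subject, recording=rec_id,
            start_index=start, meta={"stage": fm.stage},
        )
        for start, win in segment(fm, k_ms, h_ms)
    ]


def _config_hash(meta: dict) -> str:
    return hashlib.sha1(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_dataset(maps: list[GrayscaleMap], out_dir: str | Path) -> pd.DataFrame:
    """Write one 8-bit PNG per map plus a CSV manifest; returns the manifest.

    Layout: ``<out>/<subject>/<gesture>/<index>.png``; manifest columns are
    filename, label, subject, recording, start_index and a config hash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, gm in enumerate(maps):
        sub = str(gm.subject) if gm.subject is not None else "unknown"
        lab = str(gm.label) if gm.label is not None else "unlabeled"
        rel = Path(sub) / lab / f"{i:06d}.png"
        dest = out_dir / rel
        dest.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(gm.pixels, mode="L").save(dest, format="PNG")
        rows.append(
            {
                "filename": str(rel), "label": gm.label, "subject": gm.subject,
                "recording": gm.recording, "start_index": gm.start_index,
                "config_hash": _config_hash(gm.meta),
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=["filename", "label", "subject", "recording",
                 "start_index", "config_hash"],
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_image(path: str | Path) -> np.ndarray:
    """Read a written PNG back as a ``T × L`` uint8 matrix (lossless)."""
    return np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
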