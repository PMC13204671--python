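"""The multiple-mapping feature transform and its ablation variants.

The transform turns a raw multichannel sEMG recording into a bounded feature
matrix through four successive stages:

1. **sliding average power** — mean of squared samples over a length-``w``
   window advanced one sample at a time; proxies contraction intensity and
   separates channel activity levels by orders of magnitude;
2. **lg mapping** — base-10 logarithm (absolute value by default), which
   corrects the approximately lognormal power distribution toward normality;
3. **linear compression** — affine rescaling of the log-power onto a symmetric
   interval ``[−a, +a]`` (default a = 4, derived from the ≈100-fold dynamic
   range of surface-EMG amplitudes);
4. **sigmoid normalization** — elementwise logistic squashing to (0, 1),
   compressing extremes while preserving central detail.

Ablation variants: T1 = Z-scored raw signal, T2 = power only, T3 = power + lg,
T4 = the full chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit

from .errors import LengthError, SemgError
from .preprocess import Recording, zscore_normalize

logger = logging.getLogger(__name__)

Variant = Literal["T1", "T2", "T3", "T4"]
Stage = Literal["power", "lg", "scaled", "sigmoid", "zscore"]
NormScope = Literal["global", "per-channel"]

#: Raw surface-EMG amplitudes mostly fall in this range (volts).
AMPLITUDE_RANGE: tuple[float, float] = (1e-6, 1e-4)


@dataclass
class MappingConfig:
    """Parameters of the multiple-mapping transform.

    Parameters
    ----------
    w
        Power-window length in samples (default 200 = 100 ms at 2000 Hz).
    epsilon
        Positive floor applied before the logarithm; default far below the
        physiological power scale (~1e-12–1e-8 V²).
    half_width
        Half-width ``a`` of the symmetric compression target ``[−a, +a]``.
        The default 4 comes from the amplitude dynamic range: a 100-fold
        amplitude ratio is a 10⁴-fold power ratio, i.e. 4 decades of
        log-power, and the logistic at ±4 is already ≈0.018 / ≈0.982.
    use_abs
        Take ``|log10|`` rather than signed log10 (default on). For
        physiological powers (< 1 V²) the log is negative, so the absolute
        value reverses ordering: larger power ⇒ smaller mapped value.
    norm_scope
        Whether the min/max of the compression stage are taken over the whole
        recording (default — preserves inter-channel activity differences,
        which are the discriminative signal) or per channel.
    variant
        Ablation variant T1–T4.
    """

    w: int = 200
    epsilon: float = 1e-20
    half_width: float = 4.0
    use_abs: bool = True
    norm_scope: NormScope = "global"
    variant: Variant = "T4"

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError(f"w must be >= 1, got {self.w}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not self.half_width > 0:
            raise ValueError(f"half_width must be positive, got {self.half_width}")


@dataclass
class FeatureMatrix:
    """Per-channel mapped values at a named pipeline stage."""

    values: np.ndarray  # T × m
    stage: Stage
    fs: float
    label: int | str | None = None
    subject: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SemgError(f"feature values must be 2-D, got ndim={self.values.ndim}")
        if self.stage == "power" and np.any(self.values < 0):
            raise SemgError("power-stage values must be non-negative")
        if self.stage == "sigmoid" and not np.all(
            (self.values > 0) & (self.values < 1)
        ):
            raise SemgError("sigmoid-stage values must lie strictly in (0, 1)")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


def sliding_average_power(x: np.ndarray, w: int) -> np.ndarray:
    """Mean of squared samples over each length-``w`` window, stride 1.

    Output element ``i`` is ``mean(x[i : i+w] ** 2)``; an ``n``-sample input
    yields ``n − w + 1`` values (tail windows that would run past the end are
    not emitted).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise SemgError(f"expected 1-D signal, got ndim={x.ndim}")
    if w < 1:
        raise ValueError(f"window length must be >= 1, got {w}")
    n = x.size
    if n < w:
        raise LengthError(f"signal length {n} shorter than power window w={w}")
    sq = np.lib.stride_tricks.sliding_window_view(x * x, w)
    return sq.mean(axis=-1)


def lg_map(p: np.ndarray, epsilon: float = 1e-20, use_abs: bool = True) -> np.ndarray:
    """Base-10 logarithm of power values, floored at ``epsilon``.

    With ``use_abs`` on (the default) the absolute value is taken so all
    outputs are positive; for sub-unit powers this reverses ordering.
    The number of floored (sub-epsilon) elements is logged.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise SemgError("lg_map input must be non-negative (a power sequence)")
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    floored = int(np.count_nonzero(p < epsilon))
    if floored:
        logger.info("lg_map: %d value(s) floored at epsilon=%g", floored, epsilon)
    out = np.log10(np.maximum(p, epsilon))
    return np.abs(out) if use_abs else out


def linear_compress(
    v: np.ndarray,
    half_width: float = 4.0,
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Affine map sending ``vmin → −a`` and ``vmax → +a`` (a = half_width).

    Bounds default to the min/max of ``v`` itself; callers with a wider scope
    (e.g. all channels of a recording) pass them explicitly. A degenerate
    ``vmax == vmin`` maps everything to the interval midpoint 0, with a
    logged warning.
    """
    v = np.asarray(v, dtype=float)
    if not half_width > 0:
        raise ValueError(f"half_width must be positive, got {half_width}")
    if vmin is None:
        vmin = float(np.min(v))
    if vmax is None:
        vmax = float(np.max(v))
    if vmax < vmin:
        raise ValueError(f"vmax={vmax} < vmin={vmin}")
    if vmax == vmin:
        logger.warning("linear_compress: constant input, mapping to midpoint 0")
        return np.zeros_like(v)
    return half_width * (2.0 * (v - vmin) / (vmax - vmin) - 1.0)


def sigmoid_normalize(v: np.ndarray) -> np.ndarray:
    """Elementwise logistic ``1 / (1 + e^{−v})``; strictly in (0, 1)."""
    return expit(np.asarray(v, dtype=float))


def dynamic_range_interval(
    zmax: float = AMPLITUDE_RANGE[1], zmin: float = AMPLITUDE_RANGE[0]
) -> tuple[float, float]:
    """Derive the compression interval width from the amplitude dynamic range.

    Returns ``(j, J)`` where ``j = zmax / zmin`` is the amplitude ratio and
    ``J = 2·lg j`` is the corresponding spread in log10 *power* (power scales
    with amplitude squared, hence the factor 2). For the typical surface-EMG
    range 1e−6–1e−4 V this gives j = 100 and J = 4, motivating the default
    compression target ``[−4, +4]`` whose sigmoid image is ≈[0.018, 0.982].
    """
    if not (zmin > 0 and zmax > 0 and zmax >= zmin):
        raise ValueError(f"need 0 < zmin <= zmax, got zmin={zmin}, zmax={zmax}")
    j = zmax / zmin
    return j, 2.0 * np.log10(j)


def multiple_mapping(rec: Recording, cfg: MappingConfig | None = None) -> FeatureMatrix:
    """Apply the configured ablation variant to every channel of a recording.

    T1: Z-score only (length ``n``). T2: sliding power. T3: power → lg.
    T4: power → lg → linear compression → sigmoid, with the compression
    min/max taken over ``cfg.norm_scope``. Mapped stages have length
    ``n − w + 1``.
    """
    if cfg is None:
        cfg = MappingConfig()
    common = dict(fs=rec.fs, label=rec.label, subject=rec.subject)
    meta = dict(rec.meta)
    meta["mapping"] = {
        "variant": cfg.variant, "w": cfg.w, "epsilon": cfg.epsilon,
        "half_width": cfg.half_width, "use_abs": cfg.use_abs,
        "norm_scope": cfg.norm_scope,
    }

    if cfg.variant == "T1":
        z = zscore_normalize(rec, scope="per-channel")
        return FeatureMatrix(z.samples, stage="zscore", meta=meta, **common)

    rows = []
    for c in range(rec.n_channels):
        try:
            rows.append(sliding_average_power(rec.samples[c], cfg.w))
        except SemgError as exc:
            raise type(exc)(f"channel {c}: {exc}") from exc
    power = np.vstack(rows)
    if cfg.variant == "T2":
        return FeatureMatrix(power, stage="power", meta=meta, **common)

    lg = lg_map(power, epsilon=cfg.epsilon, use_abs=cfg.use_abs)
    if cfg.variant == "T3":
        return FeatureMatrix(lg, stage="lg", meta=meta, **common)

    if cfg.variant != "T4":
        raise ValueError(f"unknown variant {cfg.variant!r}")
    if cfg.norm_scope == "global":
        scaled = linear_compress(lg, half_width=cfg.half_width)
    else:
        scaled = np.vstack(
            [linear_compress(lg[c], half_width=cfg.half_width)
             for c in range(lg.shape[0])]
        )
    sig = sigmoid_normalize(scaled)
    return FeatureMatrix(sig, stage="sigmoid", meta=meta, **common)
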