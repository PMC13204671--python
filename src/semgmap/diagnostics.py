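"""Distribution diagnostics for the mapping stages.

The lg stage of the pipeline exists to correct the right-skewed, heavy-tailed
distribution of windowed sEMG power toward normality. This module quantifies
that correction: bias-corrected sample skewness and kurtosis, the Jarque–Bera
normality statistic, per-channel before/after comparison tables, and
channel-by-window energy heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import StatisticsError
from .multimap import FeatureMatrix, MappingConfig, lg_map, multiple_mapping
from .preprocess import Recording


@dataclass
class DistributionReport:
    """Skewness/kurtosis/Jarque–Bera summary of one sample.

    ``K_excess`` is the bias-corrected excess kurtosis (normal → 0);
    ``K_raw = K_excess + 3`` is the conventional kurtosis (normal → 3).
    Both are reported because comparisons against the "benchmark of 3" use
    the raw convention while the correction formula is the excess one.
    """

    m: int
    SK: float
    K_excess: float
    JB: float
    context: tuple = ()

    @property
    def K_raw(self) -> float:
        return self.K_excess + 3.0


def skewness_kurtosis(sample: np.ndarray, context: tuple = ()) -> DistributionReport:
    """Bias-corrected sample skewness and excess kurtosis.

    SK = m/((m−1)(m−2)) · Σ((x−x̄)/s)³ and
    K = m(m+1)·Σ((x−x̄)/s)⁴ / ((m−1)(m−2)(m−3)) − 3(m−1)²/((m−2)(m−3)),
    with s the (m−1)-denominator sample standard deviation. Defined only for
    m ≥ 4 and non-degenerate samples.
    """
    x = np.asarray(sample, dtype=float).ravel()
    m = x.size
    if m < 4:
        raise StatisticsError(f"need at least 4 samples, got m={m}")
    s = x.std(ddof=1)
    # ptp guard: a constant sample can yield std > 0 in the last ulp through
    # mean rounding, which would turn the moments into rounding noise
    if s == 0 or np.ptp(x) == 0:
        raise StatisticsError("zero sample variance; skewness/kurtosis undefined")
    z = (x - x.mean()) / s
    sk = m / ((m - 1) * (m - 2)) * np.sum(z**3)
    k_excess = (
        m * (m + 1) * np.sum(z**4) / ((m - 1) * (m - 2) * (m - 3))
        - 3.0 * (m - 1) ** 2 / ((m - 2) * (m - 3))
    )
    jb = m / 6.0 * (sk**2 + k_excess**2 / 4.0)
    return DistributionReport(m=m, SK=float(sk), K_excess=float(k_excess),
                              JB=float(jb), context=context)


def jarque_bera(report: DistributionReport) -> tuple[float, float]:
    """Jarque–Bera statistic and its asymptotic chi-square(2) p-value.

    JB = m/6 · (SK² + K_excess²/4); under normality JB → χ²₂, so the p-value
    uses the asymptotic reference (appropriate at the sample sizes the
    pipeline produces).
    """
    jb = report.m / 6.0 * (report.SK**2 + report.K_excess**2 / 4.0)
    return float(jb), float(chi2.sf(jb, df=2))


def stage_comparison_report(
    rec: Recording, cfg: MappingConfig | None = None
) -> pd.DataFrame:
    """Per-channel distribution statistics at the power stage vs the lg stage.

    Returns a tidy table with one row per (channel, stage) pair; channels
    whose statistics are undefined (e.g. constant signal) are reported with
    NaN statistics and an ``error`` note instead of aborting the run.
    """
    if cfg is None:
        cfg = MappingConfig()
    power = multiple_mapping(
        rec, MappingConfig(**{**cfg.__dict__, "variant": "T2"})
    ).values
    lg = lg_map(power, epsilon=cfg.epsilon, use_abs=False)
    rows = []
    for c in range(power.shape[0]):
        for stage, vals in (("power", power[c]), ("lg", lg[c])):
            row = {"channel": c, "stage": stage, "gesture": rec.label,
                   "m": vals.size}
            try:
                rep = skewness_kurtosis(vals, context=(rec.label, c, stage))
                jb, p = jarque_bera(rep)
                row.update(SK=rep.SK, K_excess=rep.K_excess, K_raw=rep.K_raw,
                           JB=jb, p_value=p, error=None)
            except StatisticsError as exc:
                row.update(SK=np.nan, K_excess=np.nan, K_raw=np.nan,
                           JB=np.nan, p_value=np.nan, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def energy_heatmap(
    fm: FeatureMatrix, k_ms: float = 200.0, h_ms: float = 50.0
) -> np.ndarray:
    """Channel × window matrix of mean power over sliding image windows.

    Cell ``(c, j)`` is the mean of channel ``c``'s power values inside window
    ``j``; the row pattern visualizes which muscles a gesture activates.
    """
    from .imaging import segment

    if fm.stage != "power":
        raise StatisticsError(
            f"energy heatmap requires a power-stage matrix, got {fm.stage!r}"
        )
    windows = segment(fm, k_ms, h_ms)
    return np.column_stack([win.mean(axis=1) for _, win in windows])


def plot_energy_heatmap(heat: np.ndarray, path: str, log_scale: bool = True):
    """Render an energy heatmap to an image file (log10 color scale by default)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.log10(np.maximum(heat, np.finfo(float).tiny)) if log_scale else heat
    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(data, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("window")
    ax.set_ylabel("channel")
    fig.colorbar(im, ax=ax, label="lg mean power" if log_scale else "mean power")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
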