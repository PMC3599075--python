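"""Normalization chain for two-color arrays.

Order of operations (see :func:`run_preprocess`):

1. additive day-effect correction per group and channel;
2. normal+exponential background correction with a variance-stabilizing
   offset (default 50), both channels, per array;
3. within-array loess normalization of M = log2(AF3/AF5) against
   A = 0.5*log2(AF3*AF5);
4. between-array quantile normalization of the sample channel within each
   cell-count group, on the log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm
import statsmodels.api as sm

from .array_io import ExperimentSet

__all__ = [
    "NormalizedSet",
    "PreprocessConfig",
    "UnsupportedDesignError",
    "day_effect_correct",
    "estimate_day_shifts",
    "normexp_fit",
    "normexp_correct",
    "loess_normalize",
    "quantile_normalize",
    "run_preprocess",
]

_LOG_FLOOR = 1e-12


class UnsupportedDesignError(ValueError):
    """More than two experimental days within a group."""


@dataclass(frozen=True)
class PreprocessConfig:
    offset: float = 50.0
    span: float = 0.30
    loess_iterations: int = 4
    quantile_both_channels: bool = False
    day_correct_log_scale: bool = False


@dataclass
class NormalizedSet:
    """Normalized signals plus M/A matrices and a step-by-step provenance."""

    annotation: pd.DataFrame
    samples: pd.DataFrame
    af3: pd.DataFrame
    af5: pd.DataFrame
    m: pd.DataFrame
    a: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.annotation["probe_id"])

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"].astype(str)))

    def samples_in_group(self, group: str, include_excluded: bool = False) -> list[str]:
        sel = self.samples["group"].astype(str) == str(group)
        if not include_excluded:
            sel &= ~self.samples["qc_excluded"].astype(bool)
        return self.samples.loc[sel, "sample_id"].tolist()

    def noncontrol_probes(self) -> pd.Index:
        keep = ~self.annotation["is_control"].astype(bool)
        return pd.Index(self.annotation.loc[keep.to_numpy(), "probe_id"])


# ---------------------------------------------------------------------------
# day-effect correction


def _day_split(samples: pd.DataFrame, group: str) -> tuple[list[str], list[str]]:
    sel = samples["group"].astype(str) == str(group)
    days = sorted(samples.loc[sel, "day"].astype(str).unique())
    if len(days) > 2:
        raise UnsupportedDesignError(
            f"group {group!r} spans {len(days)} days; only 1 or 2 supported")
    ids_by_day = [
        samples.loc[sel & (samples["day"].astype(str) == d), "sample_id"].tolist()
        for d in days
    ]
    if len(days) == 1:
        return ids_by_day[0], []
    return ids_by_day[0], ids_by_day[1]


def estimate_day_shifts(es: ExperimentSet) -> dict[tuple[str, str], float]:
    """Estimated mean(day-2) - mean(day-1) per (group, channel)."""
    shifts: dict[tuple[str, str], float] = {}
    for group in es.groups():
        d1, d2 = _day_split(es.samples, group)
        if not d2:
            continue
        for channel, mat in (("af3", es.af3), ("af5", es.af5)):
            shifts[(str(group), channel)] = float(
                mat[d2].to_numpy().mean() - mat[d1].to_numpy().mean())
    return shifts


def day_effect_correct(es: ExperimentSet,
                       log_scale: bool = False) -> ExperimentSet:
    """Shift day-2 arrays so per-group, per-channel day means coincide.

    Day-1 arrays are untouched; single-day groups pass through unchanged.
    The shift is additive on the linear scale by default (``log_scale=True``
    applies it on log2 signal instead).  Results are clipped at zero, which
    is a no-op whenever signals sit well above the estimated shift.
    """
    af3 = es.af3.copy()
    af5 = es.af5.copy()
    for group in es.groups():
        d1, d2 = _day_split(es.samples, group)
        if not d2:
            continue
        for mat in (af3, af5):
            if log_scale:
                log1 = np.log2(mat[d1].to_numpy().clip(min=_LOG_FLOOR))
                log2_ = np.log2(mat[d2].to_numpy().clip(min=_LOG_FLOOR))
                delta = log2_.mean() - log1.mean()
                mat[d2] = 2.0 ** (np.log2(mat[d2].clip(lower=_LOG_FLOOR)) - delta)
            else:
                delta = mat[d2].to_numpy().mean() - mat[d1].to_numpy().mean()
                mat[d2] = (mat[d2] - delta).clip(lower=0.0)
    return ExperimentSet(es.annotation.copy(), es.samples.copy(), af3, af5,
                         truth=es.truth)


# ---------------------------------------------------------------------------
# normal + exponential background correction


def normexp_fit(x: np.ndarray) -> tuple[float, float, float]:
    """Moment-style fit of the normal(mu, sigma) + exponential(alpha) model.

    The background mean ``mu`` is the lower mode of the intensity density
    (kernel estimate over the sub-median values, where background dominates);
    ``sigma`` comes from the half-normal spread of values below the mode, and
    the exponential mean ``alpha`` from the mean excess of values above it.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    lower = x[x <= med]
    if lower.size < 10 or lower.max() == lower.min():
        mu = float(lower.mean()) if lower.size else float(x.min())
    else:
        kde = gaussian_kde(lower)
        grid = np.linspace(lower.min(), lower.max(), 512)
        mu = float(grid[np.argmax(kde(grid))])
        # refine on a window around the crude mode: the first pass
        # oversmooths when the upper tail dominates the sub-median spread
        spread = x[x < mu] - mu
        w = 3.0 * np.sqrt(np.mean(spread ** 2)) if spread.size else 0.0
        window = x[np.abs(x - mu) < w] if w > 0 else np.empty(0)
        if window.size >= 10 and window.max() > window.min():
            kde2 = gaussian_kde(window)
            grid2 = np.linspace(window.min(), window.max(), 512)
            mu = float(grid2[np.argmax(kde2(grid2))])
    below = x[x < mu]
    if below.size:
        sigma = float(np.sqrt(np.mean((below - mu) ** 2)))
    else:
        sigma = 0.0
    if sigma <= 0:
        sigma = max(1e-2, 0.01 * (np.std(x) or 1.0))
    above = x[x > mu]
    alpha = float(np.mean(above - mu)) if above.size else 0.0
    if alpha <= 0:
        alpha = max(1e-2, np.std(x))
    return float(mu), sigma, alpha


def _normexp_conditional_mean(x: np.ndarray, mu: float, sigma: float,
                              alpha: float) -> np.ndarray:
    """E[signal | observed] for the normal+exponential convolution.

    With mu_sf = x - mu - sigma^2/alpha, the posterior mean is
    mu_sf + sigma * phi(mu_sf/sigma) / Phi(mu_sf/sigma), computed in log
    space for stability far into either tail.
    """
    mu_sf = x - mu - sigma ** 2 / alpha
    z = mu_sf / sigma
    ratio = np.exp(norm.logpdf(z) - norm.logcdf(z))  # Mills-ratio inverse
    return mu_sf + sigma * ratio


def normexp_correct(intensities: np.ndarray, offset: float = 50.0,
                    params: Optional[tuple[float, float, float]] = None
                    ) -> np.ndarray:
    """Background-correct one array's intensities under the normexp model.

    Fits per array by method of moments (unless ``params`` = (mu, sigma,
    alpha) is supplied), then returns the posterior-mean true signal plus
    ``offset``.  Output is strictly positive and strictly monotone in the
    input.  Degenerate (constant) input returns ``x - min + offset`` with a
    warning.
    """
    x = np.asarray(intensities, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("intensities must be finite")
    if x.size and x.max() == x.min():
        warnings.warn("constant intensities; returning x - min + offset",
                      stacklevel=2)
        return x - x.min() + offset
    mu, sigma, alpha = params if params is not None else normexp_fit(x)
    return _normexp_conditional_mean(x, mu, sigma, alpha) + offset


# ---------------------------------------------------------------------------
# loess normalization of M on A


def loess_normalize(m: np.ndarray, a: np.ndarray, span: float = 0.30,
                    iterations: int = 4) -> np.ndarray:
    """Remove the intensity-dependent trend of M: returns M - loess(M ~ A).

    Locally linear fit with tricube weights and ``iterations`` robustness
    passes (statsmodels lowess); ``delta`` interpolation keeps the fit
    O(n) on dense arrays.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape:
        raise ValueError("M and A must have the same length")
    if m.size < 10:
        raise ValueError("need >= 10 points for loess normalization")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    delta = 0.01 * (a.max() - a.min())
    fitted = sm.nonparametric.lowess(m, a, frac=span, it=iterations,
                                     delta=delta, return_sorted=False)
    return m - fitted


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic between-array quantile normalization on the log2 scale.

    Each array's rank-r value is replaced by the across-array mean of the
    r-th order statistics; tied values receive the mean of their tied
    reference values.  Input and output are linear-scale; a single array is
    returned unchanged with a warning.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 arrays; identity",
                      stacklevel=2)
        return matrix.copy()
    logv = np.log2(matrix.to_numpy(dtype=float).clip(min=_LOG_FLOOR))
    ref = np.sort(logv, axis=0).mean(axis=1)
    out = np.empty_like(logv)
    n = logv.shape[0]
    for j in range(logv.shape[1]):
        col = logv[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # ties: average the reference values assigned within each tied run
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(2.0 ** out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# full chain


def _m_a(af3: pd.DataFrame, af5: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    l3 = np.log2(af3.to_numpy(dtype=float).clip(min=_LOG_FLOOR))
    l5 = np.log2(af5.to_numpy(dtype=float).clip(min=_LOG_FLOOR))
    m = pd.DataFrame(l3 - l5, index=af3.index, columns=af3.columns)
    a = pd.DataFrame(0.5 * (l3 + l5), index=af3.index, columns=af3.columns)
    return m, a


def run_preprocess(es: ExperimentSet,
                   config: PreprocessConfig = PreprocessConfig()
                   ) -> NormalizedSet:
    """Apply the full normalization chain and compute final M/A matrices.

    QC-excluded samples should be removed first (:meth:`ExperimentSet.drop_excluded`).
    """
    if es.samples["qc_excluded"].astype(bool).any():
        raise ValueError("remove QC-excluded samples before preprocessing")
    provenance: list[dict] = []

    shifts = estimate_day_shifts(es)
    es = day_effect_correct(es, log_scale=config.day_correct_log_scale)
    provenance.append({"step": "day_effect_correct",
                       "log_scale": config.day_correct_log_scale,
                       "estimated_shifts": {f"{g}/{c}": v
                                            for (g, c), v in shifts.items()}})

    af3 = es.af3.copy()
    af5 = es.af5.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-column fallback is fine here
        for s in es.sample_ids:
            af3[s] = normexp_correct(af3[s].to_numpy(), offset=config.offset)
            af5[s] = normexp_correct(af5[s].to_numpy(), offset=config.offset)
    provenance.append({"step": "normexp_correct", "offset": config.offset,
                       "channels": ["af3", "af5"]})

    m, a = _m_a(af3, af5)
    for s in es.sample_ids:
        m[s] = loess_normalize(m[s].to_numpy(), a[s].to_numpy(),
                               span=config.span,
                               iterations=config.loess_iterations)
    # rebuild channels from normalized M at unchanged A
    af3 = pd.DataFrame(2.0 ** (a.to_numpy() + 0.5 * m.to_numpy()),
                       index=af3.index, columns=af3.columns)
    af5 = pd.DataFrame(2.0 ** (a.to_numpy() - 0.5 * m.to_numpy()),
                       index=af5.index, columns=af5.columns)
    provenance.append({"step": "loess_normalize", "span": config.span,
                       "iterations": config.loess_iterations})

    for group in es.groups():
        ids = es.samples_in_group(group, include_excluded=True)
        if len(ids) >= 2:
            af3[ids] = quantile_normalize(af3[ids])
            if config.quantile_both_channels:
                af5[ids] = quantile_normalize(af5[ids])
    provenance.append({"step": "quantile_normalize",
                       "channels": (["af3", "af5"]
                                    if config.quantile_both_channels else ["af3"]),
                       "within": "group"})

    m, a = _m_a(af3, af5)
    return NormalizedSet(es.annotation.copy(), es.samples.copy(), af3, af5,
                         m, a, provenance)
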