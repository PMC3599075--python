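"""Sample quality control: Dixon's Q outlier test with Monte-Carlo critical
values, multi-criteria outlier scans, and electropherogram fragment sizing."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .synthetic_data import Electropherogram

__all__ = [
    "QResult",
    "QCReport",
    "dixon_q",
    "dixon_critical_value",
    "flag_outlier_samples",
    "array_distribution_metrics",
    "mean_fragment_size",
    "DixonRangeError",
    "ZeroRangeError",
]

Side = Literal["low", "high", "two_sided"]

N_NULL_DRAWS = 100_000


class DixonRangeError(ValueError):
    """Sample size outside the 3..30 range the r10 statistic supports."""


class ZeroRangeError(ValueError):
    """All observations equal; Q undefined."""


@dataclass(frozen=True)
class QResult:
    statistic: float
    suspect_index: int
    n: int
    critical_value: float
    p_value: float
    is_outlier: bool
    side: str = "two_sided"
    alpha: float = 0.05


# null samples of the Q statistic, keyed by (n, side, seed, n_draws)
_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _null_q_sample(n: int, side: Side, seed: int, n_draws: int) -> np.ndarray:
    key = (n, side, seed, n_draws)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        x = np.sort(rng.standard_normal((n_draws, n)), axis=1)
        rng_span = x[:, -1] - x[:, 0]
        q_low = (x[:, 1] - x[:, 0]) / rng_span
        q_high = (x[:, -1] - x[:, -2]) / rng_span
        if side == "low":
            q = q_low
        elif side == "high":
            q = q_high
        else:
            q = np.maximum(q_low, q_high)
        _NULL_CACHE[key] = np.sort(q)
    return _NULL_CACHE[key]


def dixon_critical_value(n: int, alpha: float, seed: int = 0,
                         side: Side = "two_sided",
                         n_draws: int = N_NULL_DRAWS) -> float:
    """(1 - alpha) quantile of the r10 Q statistic under an i.i.d. normal null.

    Estimated by Monte-Carlo (>= 1e5 draws) and cached per (n, side, seed),
    so any (n, alpha) pair is supported without hard-coded tables.
    """
    if not 3 <= n <= 30:
        raise DixonRangeError(f"n={n} outside supported range 3..30")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if alpha == 1.0:
        return 0.0
    null = _null_q_sample(n, side, seed, n_draws)
    return float(np.quantile(null, 1.0 - alpha))


def dixon_q(values: Sequence[float], side: Side = "two_sided",
            alpha: float = 0.05, seed: int = 0) -> QResult:
    """Dixon's Q (r10) outlier test.

    Q = gap between the suspect extreme and its nearest neighbour divided by
    the range.  ``two_sided`` tests whichever end is more extreme; the
    critical value comes from the matching Monte-Carlo null, so the test is
    calibrated (type-I error = alpha) by construction.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if not 3 <= n <= 30:
        raise DixonRangeError(f"n={n} outside supported range 3..30")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    span = xs[-1] - xs[0]
    if span == 0:
        raise ZeroRangeError("all values equal; Dixon Q undefined")
    q_low = (xs[1] - xs[0]) / span
    q_high = (xs[-1] - xs[-2]) / span
    if side == "low":
        stat, suspect = q_low, order[0]
    elif side == "high":
        stat, suspect = q_high, order[-1]
    elif side == "two_sided":
        if q_high >= q_low:
            stat, suspect = q_high, order[-1]
        else:
            stat, suspect = q_low, order[0]
    else:
        raise ValueError(f"unknown side {side!r}")
    crit = dixon_critical_value(n, alpha, seed=seed, side=side)
    null = _null_q_sample(n, side, seed, N_NULL_DRAWS)
    p = float(np.mean(null >= stat))
    return QResult(statistic=float(stat), suspect_index=int(suspect), n=n,
                   critical_value=crit, p_value=p,
                   is_outlier=bool(stat > crit), side=side, alpha=alpha)


# ---------------------------------------------------------------------------
# multi-criteria sample scan


@dataclass
class QCReport:
    """Per-(sample, criterion) Dixon results plus overall exclusion flags."""

    rows: pd.DataFrame          # sample_id, criterion, metric, value, q, crit, p, flagged
    exclusions: dict[str, str]  # sample_id -> reason (union over criteria)
    warnings: list[str] = field(default_factory=list)

    def excluded_samples(self) -> list[str]:
        return sorted(self.exclusions)

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        out["excluded"] = out["sample_id"].isin(self.exclusions)
        out["reason"] = out["sample_id"].map(self.exclusions).fillna("")
        out.to_csv(path, sep="\t", index=False)


#: acceptable Abs260/Abs280 purity window for amplified cDNA
PURITY_RANGE = (1.9, 2.0)


def purity_ok(ratio: float, low: float = PURITY_RANGE[0],
              high: float = PURITY_RANGE[1]) -> bool:
    """Pass/fail range check on an Abs260/Abs280 absorbance ratio."""
    return low <= ratio <= high


MetricTable = Union[pd.Series, pd.DataFrame]


def flag_outlier_samples(metrics: Mapping[str, MetricTable],
                         alpha: float = 0.05,
                         groups: Optional[Mapping[str, str]] = None,
                         side: Side = "two_sided",
                         seed: int = 0) -> QCReport:
    """Dixon scan of per-sample QC metrics; union of per-criterion exclusions.

    ``metrics`` maps a criterion name to a Series (one metric) or DataFrame
    (several summaries, e.g. the five log2-AF3 distribution summaries) indexed
    by sample_id.  When ``groups`` is given each criterion is scanned within
    group; groups with fewer than 3 samples are skipped with a warning.  A
    multi-summary criterion flags a sample if any single summary flags it.
    """
    rows = []
    exclusions: dict[str, str] = {}
    warnings: list[str] = []

    for criterion, table in metrics.items():
        df = table.to_frame(name=criterion) if isinstance(table, pd.Series) else table
        sample_ids = df.index.astype(str)
        grp = (pd.Series([groups[s] for s in sample_ids], index=df.index)
               if groups is not None
               else pd.Series("all", index=df.index))
        for gname, members in grp.groupby(grp).groups.items():
            sub = df.loc[members]
            if len(sub) < 3:
                warnings.append(
                    f"criterion {criterion!r}: group {gname!r} has "
                    f"{len(sub)} samples (<3); skipped")
                continue
            flagged_here: set[str] = set()
            for col in sub.columns:
                vals = sub[col].astype(float)
                if vals.max() == vals.min():
                    continue  # constant metric carries no outlier signal
                res = dixon_q(vals.to_numpy(), side=side, alpha=alpha, seed=seed)
                suspect = str(vals.index[res.suspect_index])
                for sid, v in vals.items():
                    is_suspect = str(sid) == suspect
                    rows.append({
                        "sample_id": str(sid), "criterion": criterion,
                        "metric": col, "group": str(gname), "value": float(v),
                        "q_statistic": res.statistic if is_suspect else np.nan,
                        "critical_value": res.critical_value,
                        "p_value": res.p_value if is_suspect else np.nan,
                        "flagged": bool(res.is_outlier and is_suspect),
                    })
                if res.is_outlier:
                    flagged_here.add(suspect)
            for sid in flagged_here:
                prev = exclusions.get(sid)
                exclusions[sid] = f"{prev},{criterion}" if prev else criterion

    cols = ["sample_id", "criterion", "metric", "group", "value",
            "q_statistic", "critical_value", "p_value", "flagged"]
    rows_df = pd.DataFrame(rows, columns=cols)
    return QCReport(rows=rows_df, exclusions=exclusions, warnings=warnings)


def array_distribution_metrics(af3: pd.DataFrame) -> pd.DataFrame:
    """Five per-array summaries of log2 sample-channel signal.

    25th/50th/75th percentiles, maximum, and median absolute deviation of
    log2(AF3), one row per array — the array-performance QC criterion.
    """
    logv = np.log2(af3.clip(lower=1e-12))
    out = pd.DataFrame({
        "p25": logv.quantile(0.25),
        "p50": logv.quantile(0.50),
        "p75": logv.quantile(0.75),
        "max": logv.max(),
        "mad": (logv - logv.median()).abs().median(),
    })
    out.index.name = "sample_id"
    return out


def mean_fragment_size(trace: Electropherogram) -> float:
    """Fragment size (nt) where cumulative trace area first reaches 50%.

    Cumulative area is trapezoidal; the crossing is linearly interpolated
    between grid points.  Invariant to uniform rescaling of fluorescence.
    """
    x = trace.size_nt
    y = trace.fluorescence
    cum = cumulative_trapezoid(y, x, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise ZeroRangeError("electropherogram has zero total area")
    half = 0.5 * total
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(x[0])
    # area over [x[i-1], x[i]] is quadratic in position; a linear interp of the
    # cumulative curve is exact enough on a dense grid and is the documented rule
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(x[i - 1] + frac * (x[i] - x[i - 1]))
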