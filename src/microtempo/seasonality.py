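"""Seasonal ASV detection on unevenly sampled monthly series.

Each ASV's relative-abundance series is scanned with the Lomb–Scargle
periodogram under the standard (variance) normalisation, so the peak
normalised power PN lies in [0, 1] and reads as the fraction of series
variance explained by the best-fitting sinusoid at that period.
Significance comes from permuting the series over the fixed sampling
times. An ASV is called seasonal when PN exceeds the power threshold,
the permutation p-value is below the significance threshold, and the
peak period falls in the annual window (~1 year, default 10–14 months).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleTable, ValidationError

logger = logging.getLogger("microtempo")

__all__ = [
    "occurrence_filter",
    "period_grid",
    "lomb_scargle",
    "peak_significance",
    "call_seasonal",
    "peak_month",
    "PeriodogramRecord",
    "seasonal_analysis",
]


def occurrence_filter(table: CountTable, min_frac: float = 0.10) -> list:
    """ASVs detected (> 0) in at least ceil(min_frac × n_samples)
    samples."""
    n = table.data.shape[0]
    need = math.ceil(min_frac * n)
    occ = (table.counts > 0).sum(axis=0)
    return [a for a, o in zip(table.asv_ids, occ) if o >= need]


def period_grid(times: np.ndarray, oversample: int = 4) -> np.ndarray:
    """Period grid from 2 months (Nyquist for monthly sampling) to half
    the observation span, with ``oversample``-fold frequency
    oversampling."""
    span = float(np.max(times) - np.min(times))
    if span <= 4:
        raise ValidationError("time span too short for a period grid")
    f_min = 2.0 / span
    f_max = 0.5
    n = int(oversample * span * (f_max - f_min)) + 1
    freqs = np.linspace(f_min, f_max, n)
    return 1.0 / freqs[::-1]


def _ls_power(
    values: np.ndarray, times: np.ndarray, periods: np.ndarray
) -> np.ndarray:
    """Standard-normalised Lomb–Scargle power; ``values`` may be a
    (n_series, n_times) batch. Power in [0, 1]."""
    freqs = 2.0 * np.pi / periods
    y = np.atleast_2d(values).astype(float)
    y = y - y.mean(axis=1, keepdims=True)
    ss = (y**2).sum(axis=1)
    if np.any(ss <= 0):
        raise ValidationError("constant series has no periodogram")
    # classical Lomb with per-frequency time offset tau; vectorised over
    # series via matmuls (times shared by all series)
    out = np.empty((y.shape[0], freqs.size))
    for i, w in enumerate(freqs):
        tau = np.arctan2(np.sum(np.sin(2 * w * times)), np.sum(np.cos(2 * w * times))) / (2 * w)
        c = np.cos(w * (times - tau))
        s = np.sin(w * (times - tau))
        out[:, i] = (y @ c) ** 2 / (c @ c) + (y @ s) ** 2 / (s @ s)
    return out / ss[:, None]


def lomb_scargle(
    series: np.ndarray, times_months: np.ndarray, periods: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Periodogram of one unevenly sampled series.

    Returns (periods, power, PN, period_at_peak): PN is the maximum
    normalised power, period_at_peak its period in months.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times_months, dtype=float)
    if series.size < 8:
        raise ValidationError("need at least 8 observations")
    if np.var(series) <= 0:
        raise ValidationError("constant series has no periodogram")
    if periods is None:
        periods = period_grid(times)
    power = _ls_power(series, times, periods)[0]
    k = int(np.argmax(power))
    return periods, power, float(power[k]), float(periods[k])


def peak_significance(
    series: np.ndarray,
    times: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    periods: np.ndarray | None = None,
) -> float:
    """Permutation p-value of the periodogram peak: values permuted over
    the fixed times, p = (#{PN* >= PN} + 1)/(n_perm + 1)."""
    if n_perm < 19:
        raise ValidationError("n_perm must be >= 19")
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if periods is None:
        periods = period_grid(times)
    pn_obs = _ls_power(series, times, periods).max()
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(series) for _ in range(n_perm)])
    pn_perm = _ls_power(perms, times, periods).max(axis=1)
    return float((np.sum(pn_perm >= pn_obs - 1e-12) + 1) / (n_perm + 1))


def call_seasonal(
    records: pd.DataFrame,
    pn_min: float = 0.2,
    p_max: float = 0.01,
    period_window: tuple[float, float] = (10.0, 14.0),
) -> pd.Series:
    """Conjunction of the three seasonal criteria on a records frame with
    columns pn, p, period."""
    lo, hi = period_window
    return (
        (records["pn"] > pn_min)
        & (records["p"] < p_max)
        & records["period"].between(lo, hi)
    )


def peak_month(series: np.ndarray, dates: pd.Series) -> int:
    """Calendar month (1-12) with the maximum mean abundance across
    years; ties broken by the earlier month."""
    months = pd.to_datetime(dates).dt.month.to_numpy()
    vals = np.asarray(series, dtype=float)
    means = np.full(12, -np.inf)
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            means[m - 1] = vals[sel].mean()
    return int(np.argmax(means)) + 1


@dataclass
class PeriodogramRecord:
    asv_id: str
    occupancy: float
    pn: float
    period: float
    p: float
    seasonal: bool
    peak_month: int


def seasonal_analysis(
    table: CountTable,
    meta: SampleTable,
    min_frac: float = 0.10,
    n_perm: int = 999,
    seed: int = 0,
    pn_min: float = 0.2,
    p_max: float = 0.01,
    period_window: tuple[float, float] = (10.0, 14.0),
) -> pd.DataFrame:
    """Per-ASV seasonality table for one site/fraction dataset.

    Series are relative abundances; the time axis is decimal months
    since the first sample, so missing months need no imputation.
    """
    rel = table.relative()
    times = meta.months_since_start().loc[table.sample_ids].to_numpy()
    dates = meta.data.loc[table.sample_ids, "date"]
    periods = period_grid(times)
    keep = occurrence_filter(table, min_frac=min_frac)
    n_samples = table.data.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for asv in keep:
        y = rel[asv].to_numpy()
        if np.var(y) <= 0:
            logger.warning("skipping constant series for %s", asv)
            continue
        _, _, pn, per = lomb_scargle(y, times, periods)
        p = peak_significance(
            y, times, n_perm=n_perm, seed=int(rng.integers(2**31)),
            periods=periods,
        )
        rows.append(
            {
                "asv_id": asv,
                "occupancy": float((y > 0).sum() / n_samples),
                "pn": pn,
                "period": per,
                "p": p,
                "peak_month": peak_month(y, dates),
            }
        )
    out = pd.DataFrame(
        rows, columns=["asv_id", "occupancy", "pn", "period", "p", "peak_month"]
    )
    if len(out):
        out["seasonal"] = call_seasonal(
            out, pn_min=pn_min, p_max=p_max, period_window=period_window
        )
    else:
        out["seasonal"] = pd.Series(dtype=bool)
    return out
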