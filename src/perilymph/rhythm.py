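"""Rhythmicity screening and circadian time-series utilities.

Cosinor fitting with the zero-amplitude F-test, the immunofluorescence
screen normalization (isotype subtraction, second-highest scaling, low
expression flag, fold-change matrix), min-max profile integration, 24-h
moving-average bioluminescence detrending, and one-way ANOVA across clock
times with Tukey post tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RhythmSeries",
    "CosinorFit",
    "ScreenRow",
    "LumiSeries",
    "AnovaResult",
    "cosinor_fit",
    "screen_normalize",
    "fold_change_matrix",
    "integrate_profiles",
    "detrend_lumi",
    "timepoint_anova",
    "significance_tier",
]

EXPRESSION_THRESHOLD = 0.015  # "no/low expression" cut: fraction of screen max MFI


@dataclass
class RhythmSeries:
    """Replicate measurements at clock times on a fixed 24-h wheel."""

    times: np.ndarray  # hours, reduced mod period
    values: np.ndarray
    replicate_ids: np.ndarray | None = None
    group_id: str = ""
    period: float = 24.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float) % self.period
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if self.period <= 0:
            raise ValidationError("period must be positive")

    @property
    def n(self) -> int:
        return self.times.size

    def n_distinct_times(self) -> int:
        return np.unique(self.times).size


@dataclass
class CosinorFit:
    """Least-squares cosine fit ŷ(t) = M + A·cos(2π(t − φ)/period)."""

    mesor: float
    amplitude: float
    acrophase_h: float
    p_zero_amplitude: float
    residual_variance: float
    n: int
    period: float = 24.0

    def predict(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi / self.period
        return self.mesor + self.amplitude * np.cos(w * (t - self.acrophase_h))

    def to_dict(self) -> dict:
        return {
            "mesor": self.mesor,
            "amplitude": self.amplitude,
            "acrophase_h": self.acrophase_h,
            "p_zero_amplitude": self.p_zero_amplitude,
            "residual_variance": self.residual_variance,
            "n": self.n,
            "period": self.period,
        }


def cosinor_fit(series: RhythmSeries) -> CosinorFit:
    """Fit y = M + βc·cos(ωt) + βs·sin(ωt) with ω = 2π/period.

    Amplitude A = √(βc² + βs²), acrophase φ = atan2(βs, βc)/ω mod period.
    ``p_zero_amplitude`` is the F-test of (βc, βs) jointly zero against the
    intercept-only model.

    Raises
    ------
    ValidationError
        With fewer than 3 distinct time points, fewer than 4 observations,
        or a collinear design.
    """
    if series.n_distinct_times() < 3:
        raise ValidationError("cosinor needs >=3 distinct time points")
    if series.n < 4:
        raise ValidationError("cosinor needs >=4 observations")
    t, y = series.times, series.values
    w = 2.0 * np.pi / series.period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValidationError("collinear cosinor design (times carry no phase info)")
    mesor, bc, bs = beta
    amplitude = float(np.hypot(bc, bs))
    acrophase = float((np.arctan2(bs, bc) / w) % series.period)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    df = series.n - 3
    scale = max(rss0, 1.0) * np.finfo(float).eps * series.n
    if rss0 - rss1 <= scale:  # no amplitude signal at all (incl. constant series)
        p = 1.0
    elif rss1 <= scale:  # perfect rhythmic fit
        p = 0.0
    else:
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / df)
        p = float(stats.f.sf(f_stat, 2, df))
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase_h=acrophase,
        p_zero_amplitude=p,
        residual_variance=rss1 / df if df > 0 else float("nan"),
        n=series.n,
        period=series.period,
    )


@dataclass
class ScreenRow:
    """One molecule x tissue entry of the immunofluorescence screen."""

    raw_mfi: np.ndarray
    subtracted_mfi: np.ndarray
    normalized: np.ndarray | None
    second_highest: float
    expressed: bool | None
    normalizable: bool
    time_labels: np.ndarray | None = None


def screen_normalize(
    raw_mfi: Sequence[float],
    isotype_mfi: float | Sequence[float],
    screen_max: float | None = None,
    time_labels: Sequence[float] | None = None,
) -> ScreenRow:
    """Isotype-subtract per-ZT MFIs and scale to the second-highest value.

    The mean isotype MFI is subtracted (clamped at 0) and every value is
    divided by the second order statistic of the subtracted values (with
    ties duplicated, so an all-equal row normalizes to 1.0). If
    ``screen_max`` (screen-wide maximum subtracted MFI) is given, the entry
    is flagged not-expressed when its maximum falls below 1.5% of it.
    """
    raw = np.asarray(raw_mfi, dtype=float)
    if raw.size < 2:
        raise ValidationError("screen normalization needs >=2 clock times")
    iso = float(np.mean(isotype_mfi))
    sub = np.maximum(raw - iso, 0.0)
    second = float(np.sort(sub)[-2])
    normalizable = second > 0
    normalized = sub / second if normalizable else None
    expressed = None
    if screen_max is not None:
        if screen_max <= 0:
            raise ValidationError("screen_max must be positive")
        expressed = bool(sub.max() >= EXPRESSION_THRESHOLD * screen_max)
    return ScreenRow(
        raw_mfi=raw,
        subtracted_mfi=sub,
        normalized=normalized,
        second_highest=second,
        expressed=expressed,
        normalizable=normalizable,
        time_labels=None if time_labels is None else np.asarray(time_labels, float),
    )


def fold_change_matrix(values: Sequence[float]) -> np.ndarray:
    """K×K matrix of pairwise ratios: entry (i, j) = value_i / value_j.

    Zero denominators yield NaN entries (flagged with a warning).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("need a 1D vector of >=2 values")
    with np.errstate(divide="ignore", invalid="ignore"):
        m = v[:, None] / v[None, :]
    if np.any(v == 0):
        warnings.warn("zero denominator in fold-change matrix; entries set to NaN")
        m[:, v == 0] = np.nan
    return m


def integrate_profiles(
    profiles: Sequence[Sequence[float]],
    strategy: Literal["minmax", "zscore", "peak"] = "minmax",
) -> dict:
    """Collapse per-entity clock-time profiles into one mean ± s.e.m. curve.

    Each profile is rescaled (default min–max to [0, 1]) and the per-time
    mean and s.e.m. are taken across profiles. Flat profiles (max == min)
    are excluded with a warning.
    """
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValidationError("need >=1 profiles on a shared time grid")
    flat = np.isclose(arr.max(axis=1), arr.min(axis=1))
    if flat.any():
        warnings.warn(f"excluded {int(flat.sum())} flat profile(s) from integration")
    arr = arr[~flat]
    if arr.shape[0] == 0:
        raise ValidationError("all profiles are flat; nothing to integrate")
    if strategy == "minmax":
        lo = arr.min(axis=1, keepdims=True)
        hi = arr.max(axis=1, keepdims=True)
        scaled = (arr - lo) / (hi - lo)
    elif strategy == "zscore":
        scaled = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(
            axis=1, ddof=1, keepdims=True
        )
    elif strategy == "peak":
        scaled = arr / arr.max(axis=1, keepdims=True)
    else:
        raise ValidationError(f"unknown integration strategy {strategy!r}")
    n = scaled.shape[0]
    sem = scaled.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
    return {
        "mean": scaled.mean(axis=0),
        "sem": sem,
        "n_profiles": n,
        "n_excluded": int(flat.sum()),
        "strategy": strategy,
    }


@dataclass
class LumiSeries:
    """Bioluminescence photon counts per minute with optional detrended values."""

    t_min: np.ndarray
    counts: np.ndarray
    detrended: np.ndarray | None = None
    detrended_t_min: np.ndarray | None = None
    window_h: float = 24.0

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t_min.shape != self.counts.shape:
            raise ValidationError("timestamps and counts must have equal length")
        if self.t_min.size >= 2 and np.any(np.diff(self.t_min) <= 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def dt_min(self) -> float:
        return float(np.median(np.diff(self.t_min)))


def detrend_lumi(
    series: LumiSeries,
    window_h: float = 24.0,
    mode: Literal["subtract", "divide"] = "subtract",
) -> LumiSeries:
    """Relative bioluminescence: counts minus a centered 24-h moving average.

    Only timestamps where the full centered window fits are retained, so the
    output is ``window − 1`` samples shorter than the input (half a window
    dropped at each end). The window is the nearest odd sample count
    spanning ``window_h``, so the moving average is exactly centered and a
    linear trend detrends to 0. ``mode="divide"`` returns counts/average.
    """
    if series.t_min.size < 3:
        raise ValidationError("series too short to detrend")
    diffs = np.diff(series.t_min)
    if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
        raise ValidationError("detrending requires a regular sampling interval")
    dt = float(diffs[0])
    duration = series.t_min[-1] - series.t_min[0]
    if duration <= window_h * 60.0:
        raise ValidationError(
            f"series duration {duration / 60:.1f} h must exceed the "
            f"{window_h}-h window"
        )
    w = int(round(window_h * 60.0 / dt))
    if w % 2 == 0:
        w += 1
    ma = np.convolve(series.counts, np.ones(w) / w, mode="valid")
    half = (w - 1) // 2
    core = slice(half, series.counts.size - half)
    if mode == "subtract":
        detrended = series.counts[core] - ma
    elif mode == "divide":
        with np.errstate(divide="ignore", invalid="ignore"):
            detrended = series.counts[core] / ma
    else:
        raise ValidationError(f"unknown detrend mode {mode!r}")
    return LumiSeries(
        t_min=series.t_min,
        counts=series.counts,
        detrended=detrended,
        detrended_t_min=series.t_min[core],
        window_h=window_h,
    )


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_labels: list[float]
    tukey: list[dict] = field(default_factory=list)


def timepoint_anova(series: RhythmSeries) -> AnovaResult:
    """One-way ANOVA across time labels with Tukey HSD pairwise comparisons."""
    labels = np.unique(series.times)
    groups = [series.values[series.times == lab] for lab in labels]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValidationError("ANOVA needs >=2 groups with >=2 replicates each")
    f_stat, p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairs.append(
                {
                    "group_a": float(labels[i]),
                    "group_b": float(labels[j]),
                    "statistic": float(tukey.statistic[i, j]),
                    "p_value": float(tukey.pvalue[i, j]),
                }
            )
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        group_labels=labels.tolist(),
        tukey=pairs,
    )


def significance_tier(p: float) -> str:
    """Asterisk annotation at the 0.05 / 0.01 / 0.001 / 0.0001 tiers."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"
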