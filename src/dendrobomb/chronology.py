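"""Detrending, chronology building and dating-quality statistics.

The standardisation chain is the classic one for ring-width data: each
series is detrended by a cubic smoothing spline whose stiffness is set so
the smoother passes 50% of the amplitude at a chosen wavelength (30 years
by default), the ring-width index is the ratio observed/fitted, and the
site chronology is the Tukey biweight robust mean of the indices year by
year.  Signal strength is summarised by the mean inter-series correlation
(rbar), the Expressed Population Signal (EPS) and the per-year Subsample
Signal Strength (SSS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.stats import t as t_dist

from .types import Chronology, RingWidthSeries

logger = logging.getLogger(__name__)

__all__ = [
    "DetrendResult",
    "CrossdateReport",
    "SegmentFlag",
    "detrend_spline",
    "spline_lambda",
    "biweight_mean",
    "build_chronology",
    "interseries_correlation",
    "mean_sensitivity",
    "eps_sss",
    "segment_lag_flags",
]


@dataclass(frozen=True)
class DetrendResult:
    """Smooth growth curve and ratio index (TRWi) for one series."""

    series_id: str
    first_year: int
    fitted: np.ndarray  # mm, strictly positive (floored)
    index: np.ndarray  # unitless ratio observed/fitted

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.index))


@dataclass(frozen=True)
class SegmentFlag:
    series_id: str
    segment: tuple[int, int]  # (first_year, last_year) of the segment
    suggested_lag: int
    lag_correlation: float
    zero_lag_correlation: float


@dataclass(frozen=True)
class CrossdateReport:
    per_series: dict[str, float]
    overall: float
    flags: list[SegmentFlag] = field(default_factory=list)


def spline_lambda(cutoff_years: float) -> float:
    """Smoothing penalty giving 50% amplitude response at the cutoff period.

    For unit-spaced data the cubic smoothing spline behaves as a low-pass
    filter with amplitude response ``1 / (1 + lam * omega**4)``; solving for
    response 0.5 at ``omega = 2*pi/cutoff`` gives ``lam = (cutoff/2pi)**4``.
    """
    return float((cutoff_years / (2.0 * np.pi)) ** 4)


def _fit_spline(years: np.ndarray, widths: np.ndarray, cutoff_years: float) -> np.ndarray:
    spl = make_smoothing_spline(
        years.astype(float), widths.astype(float), lam=spline_lambda(cutoff_years)
    )
    return np.asarray(spl(years.astype(float)), dtype=float)


def detrend_spline(series: RingWidthSeries, cutoff_years: int = 30) -> DetrendResult:
    """Detrend one series with the 50%-cutoff smoothing spline.

    The fitted curve is floored at ``0.05 * median width`` before the ratio
    is taken (guards against division blow-ups on near-zero tails); zero
    widths yield index 0.
    """
    n = len(series)
    if n < max(10, cutoff_years / 3):
        raise ValueError(
            f"series {series.series_id!r}: {n} rings is too short to detrend "
            f"with a {cutoff_years}-yr cutoff"
        )
    widths = series.values
    if np.all(widths == 0):
        raise ValueError(f"series {series.series_id!r}: all-zero series")
    fitted = _fit_spline(series.years, widths, cutoff_years)
    floor = 0.05 * float(np.median(widths[widths > 0]))
    fitted = np.maximum(fitted, floor)
    index = np.where(widths > 0, widths / fitted, 0.0)
    return DetrendResult(
        series_id=series.series_id,
        first_year=series.first_year,
        fitted=fitted,
        index=index,
    )


def biweight_mean(values, c: float = 9.0, max_iter: int = 50, tol: float = 1e-8) -> float:
    """Tukey's biweight robust location estimate.

    Iterates the biweight-weighted mean with scale = median absolute
    deviation and tuning constant ``c`` until convergence; falls back to
    the median when the MAD is zero (no spread to weight against).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("biweight_mean of empty input")
    if x.size == 1:
        return float(x[0])
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0.0:
        return m
    for _ in range(max_iter):
        u = np.clip((x - m) / (c * mad), -1.0, 1.0)
        w = (1.0 - u**2) ** 2
        if w.sum() == 0.0:
            return m
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def mean_sensitivity(series: RingWidthSeries) -> float:
    """Mean relative difference between consecutive ring widths (0..2)."""
    x = series.values
    pair_sum = x[1:] + x[:-1]
    if np.any(pair_sum == 0):
        raise ValueError(
            f"series {series.series_id!r}: consecutive zero widths make "
            "mean sensitivity undefined"
        )
    return float(np.mean(np.abs(2.0 * (x[1:] - x[:-1]) / pair_sum)))


def eps_sss(rbar: float, n_full: float, depth_per_year) -> tuple[float, np.ndarray]:
    """Expressed Population Signal and per-year Subsample Signal Strength.

    ``EPS = n*rbar / (1 + (n-1)*rbar)`` at the full sample depth ``n_full``;
    ``SSS(m) = m*(1 + (n-1)*rbar) / (n*(1 + (m-1)*rbar))`` so that
    ``SSS(n_full) == 1``.
    """
    if not 0.0 <= rbar <= 1.0:
        raise ValueError("rbar must be in [0, 1]")
    if n_full < 1:
        raise ValueError("n_full must be >= 1")
    depth = np.asarray(depth_per_year, dtype=float)
    if np.any(depth < 0):
        raise ValueError("sample depth must be >= 0")
    denom = 1.0 + (n_full - 1.0) * rbar
    eps = n_full * rbar / denom if denom > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        sss = depth * denom / (n_full * (1.0 + (depth - 1.0) * rbar))
    sss = np.where(depth > 0, sss, 0.0)
    return float(eps), sss


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0.0:
        return np.nan
    return float((x * y).sum() / denom)


def _index_matrix(
    detrended: list[DetrendResult],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack detrended indices on a common year axis (NaN where absent)."""
    y0 = min(d.first_year for d in detrended)
    y1 = max(d.first_year + len(d.index) - 1 for d in detrended)
    years = np.arange(y0, y1 + 1)
    mat = np.full((len(detrended), len(years)), np.nan)
    for i, d in enumerate(detrended):
        j = d.first_year - y0
        mat[i, j : j + len(d.index)] = d.index
    return years, mat


def _pairwise_rbar(mat: np.ndarray, min_overlap: int = 10) -> float:
    """Mean pairwise Pearson correlation weighted by overlap length."""
    n = mat.shape[0]
    num = den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(mat[i]) & np.isfinite(mat[j])
            m = int(ok.sum())
            if m < min_overlap:
                continue
            r = _pearson(mat[i, ok], mat[j, ok])
            if np.isfinite(r):
                num += m * r
                den += m
    return num / den if den > 0 else np.nan


def build_chronology(
    series: list[RingWidthSeries], cutoff_years: int = 30
) -> Chronology:
    """Detrend, average with the biweight mean, and attach signal statistics.

    The per-year index is the biweight mean of the available ring-width
    indices; rbar is the overlap-weighted mean pairwise correlation of the
    detrended series; EPS is evaluated at the mean sample depth and SSS per
    year at the per-year depth.  Years with no contributing series are
    dropped (the chronology keeps the longest contiguous covered block).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 series to build a chronology")
    detrended = [detrend_spline(s, cutoff_years) for s in series]
    years, mat = _index_matrix(detrended)
    depth = np.isfinite(mat).sum(axis=0)
    if not np.any(depth >= 2):
        raise ValueError("series have no overlap; cannot build a chronology")

    covered = depth >= 1
    if not covered.all():
        # keep the longest contiguous covered run
        runs = np.split(np.flatnonzero(covered), np.flatnonzero(np.diff(np.flatnonzero(covered)) > 1) + 1)
        keep = max(runs, key=len)
        sl = slice(keep[0], keep[-1] + 1)
    else:
        sl = slice(None)
    years, mat, depth = years[sl], mat[:, sl], depth[sl]

    index = np.array(
        [biweight_mean(col[np.isfinite(col)]) for col in mat.T]
    )
    # raw mean width on the same axis
    raw = np.full_like(mat, np.nan)
    y0 = years[0]
    for i, s in enumerate(series):
        j0 = s.first_year - y0
        for k, w in enumerate(s.widths):
            j = j0 + k
            if 0 <= j < raw.shape[1]:
                raw[i, j] = w
    raw_mean = np.nanmean(raw, axis=0)

    rbar = _pairwise_rbar(mat)
    rbar_c = float(np.clip(rbar, 0.0, 1.0)) if np.isfinite(rbar) else 0.0
    if np.isfinite(rbar) and rbar < 0:
        logger.warning("negative rbar (%.3f) clipped to 0 for EPS/SSS", rbar)
    n_full = float(depth.mean())
    eps, sss = eps_sss(rbar_c, max(n_full, 1.0), depth)
    return Chronology(
        years=years,
        index=index,
        raw_mean=raw_mean,
        sample_depth=depth,
        rbar=float(rbar) if np.isfinite(rbar) else 0.0,
        eps=eps,
        sss=sss,
    )


def _highpass(x: np.ndarray) -> np.ndarray:
    """First difference: the high-pass transform used before correlating."""
    return np.diff(x)


def _loo_master(mat: np.ndarray, leave_out: int) -> np.ndarray:
    """Biweight mean of all series except one, per year (NaN where empty)."""
    cols = []
    for j in range(mat.shape[1]):
        col = np.delete(mat[:, j], leave_out)
        col = col[np.isfinite(col)]
        cols.append(biweight_mean(col) if col.size else np.nan)
    return np.asarray(cols)


def interseries_correlation(
    series: list[RingWidthSeries],
    cutoff_years: int = 30,
    prewhiten: bool = True,
    min_overlap: int = 20,
) -> CrossdateReport:
    """Correlate each series against the leave-one-out master chronology.

    Each detrended index is compared with the biweight mean of all the
    *other* series; with ``prewhiten`` both sides are first-differenced
    before the Pearson correlation (a simple high-pass standing in for
    COFECHA's autoregressive prewhitening).  The overall value is the mean
    of the per-series correlations.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 series")
    detrended = [detrend_spline(s, cutoff_years) for s in series]
    _, mat = _index_matrix(detrended)
    per: dict[str, float] = {}
    short: list[str] = []
    for i, d in enumerate(detrended):
        master = _loo_master(mat, i)
        ok = np.isfinite(mat[i]) & np.isfinite(master)
        if ok.sum() < min_overlap:
            short.append(d.series_id)
            continue
        x, y = mat[i, ok], master[ok]
        if prewhiten:
            x, y = _highpass(x), _highpass(y)
        per[d.series_id] = _pearson(x, y)
    if short:
        raise ValueError(
            f"insufficient overlap (<{min_overlap} yr) with the master for: {short}"
        )
    return CrossdateReport(per_series=per, overall=float(np.mean(list(per.values()))))


def segment_lag_flags(
    series: RingWidthSeries,
    master: Chronology,
    cutoff_years: int = 30,
    seg_len: int = 50,
    overlap: int = 25,
    max_lag: int = 10,
    flag_margin: float = 0.10,
    alpha: float = 0.05,
) -> CrossdateReport:
    """Segment-wise lagged correlation against the master chronology.

    Splits the series into ``seg_len``-year segments lapped by ``overlap``,
    correlates the high-passed index against the master at lags
    ``-max_lag..+max_lag`` and flags segments whose best lag is non-zero,
    beats the lag-0 correlation by ``flag_margin`` and is significant at
    ``alpha`` — the signature of a misdated stretch (missing/false rings).
    Because the best lag is the maximum over a segments-by-lags search, the
    significance test is Bonferroni-corrected across the whole search so
    that an undated noise series is flagged with probability <= alpha.
    """
    d = detrend_spline(series, cutoff_years)
    x_years, x = d.years, d.index
    flags: list[SegmentFlag] = []
    per: dict[str, float] = {}

    common0 = max(x_years[0], int(master.years[0]))
    common1 = min(x_years[-1], int(master.years[-1]))
    span = common1 - common0 + 1
    if span < seg_len:
        logger.warning(
            "series %s overlaps master for only %d yr (< seg_len %d); "
            "testing the whole overlap as a single segment",
            series.series_id,
            span,
            seg_len,
        )
        starts = [common0]
        seg_len = span
    else:
        step = seg_len - overlap
        starts = list(range(common0, common1 - seg_len + 2, step))

    def _r_at_lag(y0: int, y1: int, lag: int) -> tuple[float, int]:
        """Correlate series years y0..y1 against master shifted by lag."""
        sy = np.arange(y0, y1 + 1)
        my = sy + lag
        ok = (
            (sy >= x_years[0])
            & (sy <= x_years[-1])
            & (my >= master.years[0])
            & (my <= master.years[-1])
        )
        if ok.sum() < 10:
            return np.nan, 0
        xs = x[sy[ok] - x_years[0]]
        ms = master.index[my[ok] - master.years[0]]
        return _pearson(_highpass(xs), _highpass(ms)), int(ok.sum())

    # multiplicity of the search: every non-zero lag in every segment
    alpha_adj = alpha / max(len(starts) * 2 * max_lag, 1)
    for y0 in starts:
        y1 = min(y0 + seg_len - 1, common1)
        r0, _ = _r_at_lag(y0, y1, 0)
        best_lag, best_r, best_n = 0, r0, 0
        for lag in range(-max_lag, max_lag + 1):
            r, n = _r_at_lag(y0, y1, lag)
            if np.isfinite(r) and (not np.isfinite(best_r) or r > best_r):
                best_lag, best_r, best_n = lag, r, n
        per[f"{y0}-{y1}"] = r0
        if best_lag != 0 and np.isfinite(best_r) and np.isfinite(r0):
            # first differences of near-white series are MA(1) with lag-1
            # autocorrelation ~ -0.5, inflating var(r) by ~1.5: shrink the
            # effective sample size accordingly before the t-test
            n_eff = max(int((best_n - 1) / 1.5), 3)
            if best_r - r0 >= flag_margin and _r_significant(best_r, n_eff, alpha_adj):
                flags.append(
                    SegmentFlag(
                        series_id=series.series_id,
                        segment=(y0, y1),
                        suggested_lag=best_lag,
                        lag_correlation=best_r,
                        zero_lag_correlation=r0,
                    )
                )
    vals = [v for v in per.values() if np.isfinite(v)]
    return CrossdateReport(
        per_series=per, overall=float(np.mean(vals)) if vals else np.nan, flags=flags
    )


def _r_significant(r: float, n: int, alpha: float) -> bool:
    """One-sided t-test that a correlation exceeds zero."""
    if n < 3 or not np.isfinite(r) or abs(r) >= 1.0:
        return abs(r) >= 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return bool(t_dist.sf(t, n - 2) < alpha)
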