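"""Segregation-dynamics statistics.

Growth-exponent estimation for cluster-size time series (the diffusive
regime of conserved demixing coarsens as L ~ t^{1/3}; coherent collective
motion gives L ~ t), envelopment quantification for three-phase lattice
states, and the small statistical toolkit used throughout: hourly
resampling of 10-minute data, Welch's unequal-variance t-test, and
five-number summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from segdyn.synthetic.lattice import LatticeState


@dataclass
class GrowthFit:
    """Power-law growth exponent z of L ~ t^z with its 95% CI."""

    z: float
    ci95: tuple[float, float]
    window: tuple[float, float]
    r2: float
    n_points: int


@dataclass
class EnvelopmentIndex:
    """Per-type share of the aggregate's medium-exposed surface."""

    fractions: dict[int, float]
    surface_sites: int


@dataclass
class SummaryStats:
    n: int
    mean: float
    sem: float
    five_number: tuple[float, float, float, float, float]


def _extract_series(series, channel):
    """Accept (times, values[, sem]) arrays or a ClusterSizeSeries."""
    from segdyn.correlation import ClusterSizeSeries

    if isinstance(series, ClusterSizeSeries):
        if channel is None:
            if len(series.R0) != 1:
                raise ValueError("channel required for multi-channel series")
            channel = next(iter(series.R0))
        t = series.times
        v = series.R0[channel]
        s = series.sem[channel] if series.sem else None
        return t, v, s
    t, v = np.asarray(series[0], float), np.asarray(series[1], float)
    s = np.asarray(series[2], float) if len(series) > 2 and series[2] is not None else None
    return t, v, s


def growth_exponent(
    series,
    channel: str | None = None,
    window: tuple[float, float] | None = None,
    sem: np.ndarray | None = None,
) -> GrowthFit:
    """OLS fit of log L against log t; z is the slope.

    Without an explicit window the first quartile of time points is
    excluded as mixing transient, and a terminal plateau — the longest
    final run whose successive size changes stay below one SEM (when SEM
    is available) — is excluded as well, since a bounded field caps the
    attainable cluster size.  The 95% CI comes from the slope's standard
    error; a series that is plateau throughout has no growth regime.
    """
    t, v, s = _extract_series(series, channel)
    if sem is not None:
        s = np.asarray(sem, float)
    ok = np.isfinite(t) & np.isfinite(v) & (v > 0)
    if np.any(t[ok] <= 0):
        raise ValueError("all times must be > 0 for a log-log fit")
    t, v = t[ok], v[ok]
    s = s[ok] if s is not None else None

    if window is None:
        n = len(t)
        start = n // 4  # drop the first quartile of points (transient)
        end = n
        if s is not None and np.all(np.isfinite(s)):
            # Terminal plateau: longest final run of sub-SEM size changes.
            dv = np.abs(np.diff(v))
            tol = s[1:]
            k = n - 1
            while k > 0 and dv[k - 1] < tol[k - 1]:
                k -= 1
            if k == 0:
                raise ValueError("no growth regime: plateau covers the series")
            end = min(n, k + 1)
        if end - start < 5 and n >= 5:
            start = max(0, end - 5)
        t_w, v_w = t[start:end], v[start:end]
        window = (float(t_w[0]), float(t_w[-1])) if len(t_w) else (np.nan, np.nan)
    else:
        sel = (t >= window[0]) & (t <= window[1])
        t_w, v_w = t[sel], v[sel]
    if len(t_w) < 5:
        raise ValueError("need >=5 valid points in the fit window")
    if np.ptp(np.log(v_w)) == 0:
        raise ValueError("no growth regime: size is constant over the window")
    res = spstats.linregress(np.log(t_w), np.log(v_w))
    df = len(t_w) - 2
    tcrit = spstats.t.ppf(0.975, df)
    half = tcrit * res.stderr
    return GrowthFit(
        z=float(res.slope),
        ci95=(float(res.slope - half), float(res.slope + half)),
        window=(float(window[0]), float(window[1])),
        r2=float(res.rvalue**2),
        n_points=len(t_w),
    )


def resample_hourly(
    times: np.ndarray,
    values: np.ndarray,
    points_per_hour: int = 6,
    spacing_tol: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-average 10-minute data into hourly means.

    Consecutive non-overlapping blocks of 6 points are averaged; a
    trailing partial block is dropped.  Input spacing must be 10 min
    (1/6 h) within the relative tolerance.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(times) < points_per_hour:
        raise ValueError(f"need at least {points_per_hour} points")
    dt = np.diff(times)
    expected = 1.0 / points_per_hour
    if np.any(np.abs(dt - expected) > spacing_tol * expected):
        raise ValueError("input spacing is not 10 minutes within tolerance")
    n_blocks = len(times) // points_per_hour
    k = n_blocks * points_per_hour
    tb = times[:k].reshape(n_blocks, points_per_hour).mean(axis=1)
    vb = values[:k].reshape(n_blocks, points_per_hour).mean(axis=1)
    return tb, vb


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Unpaired two-sample t-test assuming unequal variances.

    Returns (t, Welch–Satterthwaite df, two-tailed p).  Implemented from
    the defining formulas; cross-checked against scipy in the test suite.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate samples: both variances are zero")
    na, nb = len(a), len(b)
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2.0 * spstats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def five_number_summary(values) -> SummaryStats:
    """Min, lower quartile, median, upper quartile, max (+ mean, SEM).

    Quartiles use linear interpolation with inclusive endpoints (numpy's
    default percentile convention).  SEM is NaN for a single value.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty input")
    q = np.percentile(v, [0, 25, 50, 75, 100], method="linear")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else np.nan
    return SummaryStats(
        n=int(v.size),
        mean=float(v.mean()),
        sem=sem,
        five_number=tuple(float(x) for x in q),
    )


def envelopment_index(state: LatticeState) -> EnvelopmentIndex:
    """Per-type share of the aggregate surface exposed to the medium.

    A surface site is a cell-labelled site with at least one medium
    (label 0) nearest neighbour, using the lattice's own connectivity and
    boundary convention.  The cell type enveloping the aggregate owns most
    of the surface; fractions over the present types sum to one.
    """
    labels = state.labels
    if not (labels == 0).any():
        raise ValueError("no medium phase: aggregate surface undefined")
    is_medium = labels == 0
    has_medium_nbr = np.zeros_like(is_medium)
    for axis in range(labels.ndim):
        for shift in (1, -1):
            if state.periodic:
                nb = np.roll(is_medium, shift, axis=axis)
            else:
                nb = np.zeros_like(is_medium)
                src = [slice(None)] * labels.ndim
                dst = [slice(None)] * labels.ndim
                if shift == 1:
                    src[axis] = slice(0, -1)
                    dst[axis] = slice(1, None)
                else:
                    src[axis] = slice(1, None)
                    dst[axis] = slice(0, -1)
                nb[tuple(dst)] = is_medium[tuple(src)]
            has_medium_nbr |= nb
    surface = (labels > 0) & has_medium_nbr
    total = int(surface.sum())
    types = [int(t) for t in np.unique(labels) if t > 0]
    if total == 0:
        fractions = {t: np.nan for t in types}
    else:
        fractions = {t: float((labels[surface] == t).sum() / total) for t in types}
    return EnvelopmentIndex(fractions=fractions, surface_sites=total)
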