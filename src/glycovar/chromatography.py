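"""Glucose-unit calibration and peak integration for HILIC-UHPLC traces.

Retention times drift between runs and instruments; expressing peak
positions in glucose units (GU) — interpolated against an external dextran
ladder of 2-AB-labeled glucose oligomers — makes integration windows
transferable.  The calibration is a monotone piecewise-cubic (PCHIP)
interpolant through the ladder knots, linearly extrapolated beyond them; the
inverse map is obtained by root-finding on the forward map so the two are
exact inverses (to solver tolerance), not merely consistent at the knots.

Integration uses fixed, shared, half-open GU windows with a local linear
baseline per window, mirroring fixed integration intervals applied uniformly
to all samples of a study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq


@dataclass
class Chromatogram:
    """Fluorescence trace: uniform time grid (minutes) and signal (EU)."""

    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 2:
            raise ValueError("chromatogram needs at least 2 points")
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.signal))):
            raise ValueError("chromatogram contains non-finite values")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass(frozen=True)
class PeakWindow:
    """Half-open integration window [start, end) in glucose units."""

    peak_id: str
    start: float
    end: float
    structure: str | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"window {self.peak_id!r}: end must exceed start")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def validate_panel(windows: list[PeakWindow]) -> None:
    """Windows within one panel must not overlap."""
    ordered = sorted(windows, key=lambda w: w.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"windows {a.peak_id!r} and {b.peak_id!r} overlap")


class DextranLadder:
    """External calibration standard: (GU, retention time) knots."""

    def __init__(self, points: list[tuple[int, float]]):
        pts = sorted(points)
        if len(pts) < 4:
            raise ValueError("dextran ladder needs at least 4 points")
        gus = np.array([p[0] for p in pts], dtype=float)
        times = np.array([p[1] for p in pts], dtype=float)
        for i in range(len(pts) - 1):
            if not (gus[i + 1] > gus[i] and times[i + 1] > times[i]):
                raise ValueError(
                    "ladder must be strictly increasing in GU and time; "
                    f"offending pair: {pts[i]} -> {pts[i + 1]}"
                )
        self.gu = gus
        self.time = times

    def __len__(self) -> int:
        return len(self.gu)


class GUCalibration:
    """Monotone bijection between retention time (min) and glucose units."""

    def __init__(self, ladder: DextranLadder):
        self.ladder = ladder
        self._fwd = PchipInterpolator(ladder.time, ladder.gu, extrapolate=False)
        # secant slopes of the end intervals define the linear extensions
        # (PCHIP endpoint derivatives can be arbitrarily small, which would
        # make linear extrapolation and its inverse ill-conditioned)
        self._slope_lo = (ladder.gu[1] - ladder.gu[0]) / (ladder.time[1] - ladder.time[0])
        self._slope_hi = (ladder.gu[-1] - ladder.gu[-2]) / (
            ladder.time[-1] - ladder.time[-2])

    # -- forward: time -> GU ----------------------------------------------
    def time_to_gu(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        lo, hi = self.ladder.time[0], self.ladder.time[-1]
        out = np.empty_like(t)
        inside = (t >= lo) & (t <= hi)
        out[inside] = self._fwd(t[inside])
        below = t < lo
        out[below] = self.ladder.gu[0] + self._slope_lo * (t[below] - lo)
        above = t > hi
        out[above] = self.ladder.gu[-1] + self._slope_hi * (t[above] - hi)
        return float(out[0]) if scalar else out

    # -- inverse: GU -> time ----------------------------------------------
    def gu_to_time(self, g):
        g = np.asarray(g, dtype=float)
        scalar = g.ndim == 0
        g = np.atleast_1d(g)
        glo, ghi = self.ladder.gu[0], self.ladder.gu[-1]
        tlo, thi = self.ladder.time[0], self.ladder.time[-1]
        out = np.empty_like(g)
        for i, gi in enumerate(g):
            if gi < glo:
                out[i] = tlo + (gi - glo) / self._slope_lo
            elif gi > ghi:
                out[i] = thi + (gi - ghi) / self._slope_hi
            else:
                # strictly monotone forward map -> unique root
                out[i] = brentq(
                    lambda t, gi=gi: float(self._fwd(np.clip(t, tlo, thi))) - gi,
                    tlo, thi, xtol=1e-12, rtol=8.9e-16,
                )
        return float(out[0]) if scalar else out


def fit_gu_calibration(ladder: DextranLadder) -> GUCalibration:
    """Fit the time <-> GU calibration from a dextran ladder."""
    return GUCalibration(ladder)


def synthesize_chromatogram(
    percent_areas,
    windows: list[PeakWindow],
    cal: GUCalibration,
    peak_sigma: float = 0.05,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    total_area: float = 100.0,
    dt: float = 0.005,
    margin: float = 0.5,
    seed: int | None = None,
) -> Chromatogram:
    """Render a synthetic trace: one Gaussian per window at its GU midpoint.

    Component areas are proportional to ``percent_areas`` (which must sum to
    100) scaled so the total Gaussian area equals ``total_area`` EU*min.
    Optional flat baseline and white Gaussian noise; deterministic given
    ``seed``.
    """
    percent_areas = np.asarray(percent_areas, dtype=float)
    if percent_areas.shape != (len(windows),):
        raise ValueError("need one percent area per window")
    if not np.isclose(percent_areas.sum(), 100.0, atol=1e-6):
        raise ValueError("percent areas must sum to 100")
    if peak_sigma <= 0:
        raise ValueError("peak_sigma must be positive")
    centers = np.array([cal.gu_to_time(w.midpoint) for w in windows])
    t0 = min(cal.gu_to_time(w.start) for w in windows) - margin
    t1 = max(cal.gu_to_time(w.end) for w in windows) + margin
    time = np.arange(t0, t1 + dt, dt)
    signal = np.full_like(time, float(baseline))
    areas = percent_areas / 100.0 * total_area
    for area, c in zip(areas, centers):
        amp = area / (peak_sigma * np.sqrt(2 * np.pi))
        signal = signal + amp * np.exp(-0.5 * ((time - c) / peak_sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=time.shape)
    return Chromatogram(time=time, signal=signal)


def integrate_peaks(
    chrom: Chromatogram,
    windows: list[PeakWindow],
    cal: GUCalibration,
    subtract_baseline: bool = True,
) -> np.ndarray:
    """Integrate a trace into per-window raw areas (EU*min).

    Each window's baseline is the line joining the signal values at the
    window boundaries; the baseline-subtracted trapezoidal integral is
    clipped at zero.  Windows must lie within the trace's time range.
    """
    validate_panel(windows)
    t, y = chrom.time, chrom.signal
    bad = []
    bounds = []
    for w in windows:
        ta, tb = cal.gu_to_time(w.start), cal.gu_to_time(w.end)
        if ta < t[0] or tb > t[-1]:
            bad.append(w.peak_id)
        bounds.append((ta, tb))
    if bad:
        raise ValueError(f"windows outside chromatogram time range: {bad}")
    areas = np.empty(len(windows))
    for i, (ta, tb) in enumerate(bounds):
        inner = (t > ta) & (t < tb)
        tt = np.concatenate(([ta], t[inner], [tb]))
        yy = np.concatenate(([np.interp(ta, t, y)], y[inner], [np.interp(tb, t, y)]))
        if subtract_baseline:
            base = yy[0] + (yy[-1] - yy[0]) * (tt - ta) / (tb - ta)
            base = np.maximum(base, 0.0)
            yy = yy - base
        areas[i] = max(np.trapezoid(yy, tt), 0.0)
    return areas


def default_windows(panel: str, gu_start: float = 4.0, width: float = 0.28,
                    gap: float = 0.06) -> list[PeakWindow]:
    """Evenly spaced placeholder GU windows for the Tf (35) or IgG (24) panel.

    The true per-peak GU boundaries of the published panels are not public;
    these synthetic defaults provide a well-separated, valid panel for
    simulation and round-trip testing, and are overridable via CSV.
    """
    from .traits import default_annotation

    ann = default_annotation(panel)
    windows = []
    pos = gu_start
    for pid, row in ann.table.iterrows():
        windows.append(PeakWindow(peak_id=pid, start=pos, end=pos + width,
                                  structure=row["structure"]))
        pos += width + gap
    return windows


def identity_ladder(n: int = 15) -> DextranLadder:
    """Ladder with retention time numerically equal to GU (testing aid)."""
    return DextranLadder([(g, float(g)) for g in range(1, n + 1)])
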