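"""Destructive three-point-bending curve analysis.

A whole-bone bending record is reduced to three scalars:

* elastic stiffness — slope of the linear elastic range, found as the
  best-fitting (maximum R^2) contiguous window inside a force band of the
  ultimate load;
* ultimate load — maximum force sustained;
* yield load — force at the changing point between the elastic and plastic
  ranges, located where the measured force departs from the extrapolated
  elastic line.

Whole-bone tests have no gauge strain, so yield is defined by elastic-line
deviation rather than a 0.2 %-offset rule.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LoadDisplCurve",
    "MechSummary",
    "WindowRule",
    "elastic_stiffness",
    "ultimate_load",
    "yield_load",
    "analyze_curve",
    "read_curve",
    "write_curve",
    "batch_summarize",
]


@dataclass
class LoadDisplCurve:
    """Sampled displacement/force record of a destructive bending test."""

    displacement_mm: np.ndarray
    force_n: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=np.float64)
        self.force_n = np.asarray(self.force_n, dtype=np.float64)
        if self.displacement_mm.ndim != 1 or self.force_n.shape != self.displacement_mm.shape:
            raise ValueError("displacement and force must be 1D arrays of equal length")
        if len(self.displacement_mm) < 20:
            raise ValueError("curve needs at least 20 samples")
        if np.any(np.diff(self.displacement_mm) < 0):
            raise ValueError("displacement must be monotone non-decreasing")
        if abs(self.displacement_mm[0]) > 1e-12:
            raise ValueError("displacement must start at 0")

    def __len__(self) -> int:
        return len(self.displacement_mm)


@dataclass
class MechSummary:
    """Elastic stiffness, yield load and ultimate load of one test."""

    elastic_stiffness_n_per_mm: float
    yield_load_n: float
    ultimate_load_n: float
    fit_window: tuple[int, int]          # half-open index range of elastic fit
    fit_r2: float
    low_quality: bool = False            # no window reached the R^2 floor
    yield_is_ultimate: bool = False      # curve never left the elastic line
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.elastic_stiffness_n_per_mm > 0:
            raise ValueError("stiffness must be positive")
        if self.yield_load_n > self.ultimate_load_n * (1 + 1e-9):
            raise ValueError("yield load cannot exceed ultimate load")
        if not 0 <= self.fit_r2 <= 1 + 1e-12:
            raise ValueError("fit_r2 must be in [0, 1]")


@dataclass
class WindowRule:
    """Elastic-window search parameters.

    Candidate windows are contiguous index runs whose forces lie inside
    ``[band_lo, band_hi] * ultimate`` and that span at least
    ``min_fraction`` of all samples; the window maximizing R^2 wins, ties go
    to the longest and then the earliest.
    """

    band_lo: float = 0.10
    band_hi: float = 0.60
    min_fraction: float = 0.15
    r2_floor: float = 0.90

    def __post_init__(self) -> None:
        if not 0 <= self.band_lo < self.band_hi <= 1:
            raise ValueError("need 0 <= band_lo < band_hi <= 1")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")


def ultimate_load(curve: LoadDisplCurve) -> tuple[float, int]:
    """Maximum force and its sample index."""
    i = int(np.argmax(curve.force_n))
    return float(curve.force_n[i]), i


def _window_fits(d: np.ndarray, f: np.ndarray, i0: int, min_len: int):
    """Best least-squares window starting search from prefix sums.

    Yields (slope, intercept, r2, (a, b)) for every window [a, b) of length
    >= min_len inside [i0-based segment]; vectorized with cumulative sums.
    """
    n = len(d)
    # prefix sums for O(1) window statistics
    cd = np.concatenate(([0.0], np.cumsum(d)))
    cf = np.concatenate(([0.0], np.cumsum(f)))
    cdd = np.concatenate(([0.0], np.cumsum(d * d)))
    cff = np.concatenate(([0.0], np.cumsum(f * f)))
    cdf = np.concatenate(([0.0], np.cumsum(d * f)))
    best = None
    for a in range(0, n - min_len + 1):
        bs = np.arange(a + min_len, n + 1)
        m = bs - a
        sd = cd[bs] - cd[a]
        sf = cf[bs] - cf[a]
        sdd = cdd[bs] - cdd[a]
        sff = cff[bs] - cff[a]
        sdf = cdf[bs] - cdf[a]
        sxx = sdd - sd * sd / m
        syy = sff - sf * sf / m
        sxy = sdf - sd * sf / m
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy / sxx
            r2 = np.where(
                (sxx > 0) & (syy > 0), sxy * sxy / (sxx * syy), np.where(syy <= 0, 1.0, 0.0)
            )
        valid = (sxx > 0) & np.isfinite(slope) & (slope > 0)
        if not valid.any():
            continue
        r2v = np.where(valid, r2, -np.inf)
        # ties -> longest, then earliest: scan with strict improvement rules
        j = int(np.argmax(np.round(r2v, 12) + m * 1e-15))
        cand = (float(r2v[j]), int(m[j]), -a, float(slope[j]), (a, int(bs[j])))
        if best is None or (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
            best = cand
    return best


def elastic_stiffness(
    curve: LoadDisplCurve, rule: WindowRule | None = None
) -> tuple[float, tuple[int, int], float, bool]:
    """Slope of the detected linear elastic range.

    Returns ``(slope, (a, b), r2, low_quality)``; ``low_quality`` flags a fit
    whose R^2 never reached the rule's floor (the slope of the best window is
    still reported, never silently dropped).
    """
    rule = rule or WindowRule()
    f_u, i_u = ultimate_load(curve)
    if f_u <= 0:
        raise ValueError("curve has no positive force samples")
    band = (curve.force_n >= rule.band_lo * f_u) & (curve.force_n <= rule.band_hi * f_u)
    band[i_u:] = False  # pre-peak only
    min_len = max(int(np.ceil(rule.min_fraction * len(curve))), 3)

    # contiguous index runs inside the band
    idx = np.flatnonzero(band)
    if idx.size == 0:
        raise ValueError("no samples inside the elastic force band")
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)

    best = None
    for run in runs:
        if len(run) < min_len:
            continue
        a0 = int(run[0])
        res = _window_fits(
            curve.displacement_mm[run[0]: run[-1] + 1],
            curve.force_n[run[0]: run[-1] + 1],
            a0,
            min_len,
        )
        if res is None:
            continue
        r2, length, nega, slope, (wa, wb) = res
        cand = (r2, length, -(a0 + wa), slope, (a0 + wa, a0 + wb))
        if best is None or (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
            best = cand
    if best is None:
        # fall back: longest run even if shorter than the required fraction
        run = max(runs, key=len)
        if len(run) < 3:
            raise ValueError("elastic band too short for a line fit")
        a, b = int(run[0]), int(run[-1]) + 1
        slope, r2 = _plain_fit(curve, a, b)
        return slope, (a, b), r2, True

    r2, _, _, slope, window = best
    return slope, window, r2, bool(r2 < rule.r2_floor)


def _plain_fit(curve: LoadDisplCurve, a: int, b: int) -> tuple[float, float]:
    d = curve.displacement_mm[a:b]
    f = curve.force_n[a:b]
    slope, intercept = np.polyfit(d, f, 1)
    pred = slope * d + intercept
    ss = np.sum((f - f.mean()) ** 2)
    r2 = 1.0 if ss == 0 else 1.0 - float(np.sum((f - pred) ** 2) / ss)
    return float(slope), max(min(r2, 1.0), 0.0)


def yield_load(
    curve: LoadDisplCurve,
    stiffness: float,
    fit_window: tuple[int, int],
    deviation_fraction: float = 0.05,
) -> tuple[float, bool]:
    """Force at the elastic-to-plastic changing point.

    The elastic line (through the fit window, least-squares intercept) is
    extrapolated beyond the window; the first sample before the ultimate
    point where the measured force falls below the line by more than
    ``deviation_fraction`` (relative) marks departure, and yield is reported
    at the last preceding sample that still sat on or above the line. If the
    curve never departs, yield equals the ultimate load and is flagged.
    """
    a, b = fit_window
    d, f = curve.displacement_mm, curve.force_n
    intercept = float(np.mean(f[a:b]) - stiffness * np.mean(d[a:b]))
    pred = stiffness * d + intercept
    f_u, i_u = ultimate_load(curve)

    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(pred > 0, (pred - f) / pred, 0.0)
    beyond = np.arange(len(curve)) >= b
    beyond &= np.arange(len(curve)) <= i_u
    hits = np.flatnonzero(beyond & (dev > deviation_fraction))
    if hits.size == 0:
        return f_u, True
    i_star = int(hits[0])
    # walk back to the last sample on/above the elastic line (tiny epsilon so
    # exact noiseless samples count as on-line despite rounding)
    on_line = np.flatnonzero((np.arange(len(curve)) < i_star) & (dev <= 1e-9))
    i_y = int(on_line[-1]) if on_line.size else i_star
    return float(min(f[i_y], f_u)), False


def analyze_curve(
    curve: LoadDisplCurve,
    rule: WindowRule | None = None,
    deviation_fraction: float = 0.05,
) -> MechSummary:
    """Full reduction of one curve to a :class:`MechSummary`."""
    slope, window, r2, low_q = elastic_stiffness(curve, rule)
    f_u, _ = ultimate_load(curve)
    f_y, flagged = yield_load(curve, slope, window, deviation_fraction)
    return MechSummary(
        elastic_stiffness_n_per_mm=slope,
        yield_load_n=min(f_y, f_u),
        ultimate_load_n=f_u,
        fit_window=window,
        fit_r2=r2,
        low_quality=low_q,
        yield_is_ultimate=flagged,
        metadata=dict(curve.metadata),
    )


# ---------------------------------------------------------------------------
# I/O

_HEADER = ["displacement_mm", "force_n"]


def read_curve(path: str | os.PathLike, metadata: dict | None = None) -> LoadDisplCurve:
    """Read a two-column CSV with header ``displacement_mm,force_n``."""
    path = os.fspath(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if list(df.columns[:2]) != _HEADER:
        raise ValueError(
            f"{path}: expected header '{','.join(_HEADER)}', got "
            f"'{','.join(map(str, df.columns[:2]))}' (line 1)"
        )
    bad = df[_HEADER].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed value at line {int(bad.idxmax()) + 2}")
    meta = dict(metadata or {})
    meta.setdefault("specimen", Path(path).stem)
    return LoadDisplCurve(df[_HEADER[0]].to_numpy(), df[_HEADER[1]].to_numpy(), meta)


def write_curve(curve: LoadDisplCurve, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {_HEADER[0]: curve.displacement_mm, _HEADER[1]: curve.force_n}
    ).to_csv(path, index=False)


def batch_summarize(
    directory: str | os.PathLike,
    rule: WindowRule | None = None,
    deviation_fraction: float = 0.05,
) -> pd.DataFrame:
    """Summarize every ``*.csv`` curve in a directory, one row per file."""
    rows = []
    for p in sorted(Path(directory).glob("*.csv")):
        s = analyze_curve(read_curve(p), rule, deviation_fraction)
        rows.append(
            {
                "specimen": s.metadata.get("specimen", p.stem),
                "elastic_stiffness_n_per_mm": s.elastic_stiffness_n_per_mm,
                "yield_load_n": s.yield_load_n,
                "ultimate_load_n": s.ultimate_load_n,
                "fit_r2": s.fit_r2,
                "low_quality": s.low_quality,
                "yield_is_ultimate": s.yield_is_ultimate,
            }
        )
    if not rows:
        raise ValueError(f"no curve CSV files found in {directory}")
    return pd.DataFrame(rows)
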