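"""Radiocarbon calibration against a user-supplied calibration curve.

A conventional radiocarbon age (CRA) +/- sigma is converted to a posterior
density over calendar years on a 1-yr grid via the Gaussian measurement
model

    p(theta)  propto  exp( -(cra - mu(theta))^2 / (2 (sigma^2 + sigma_curve(theta)^2)) )

where mu and sigma_curve are linear interpolations of the curve knots.
Calibrated results are reported as 95.4% highest-posterior-density ranges.
The calibration curve itself (e.g. SHCal04 in the standard ``.14c`` column
layout) is supplied by the user; none is bundled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_LEVEL = 0.954


class OutOfCurveError(ValueError):
    """CRA falls outside the 14C range covered by the calibration curve."""


@dataclass
class CalibrationCurve:
    """Calendar-age grid with 14C ages and 1-sigma curve errors."""

    cal_bp: np.ndarray
    c14_bp: np.ndarray
    error: np.ndarray
    name: str = "curve"

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_bp = np.asarray(self.c14_bp, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if not (len(self.cal_bp) == len(self.c14_bp) == len(self.error)):
            raise ValueError("curve columns must have equal length")
        if len(self.cal_bp) < 2:
            raise ValueError("curve needs at least 2 knots")
        order = np.argsort(self.cal_bp)
        self.cal_bp = self.cal_bp[order]
        self.c14_bp = self.c14_bp[order]
        self.error = self.error[order]
        if (np.diff(self.cal_bp) == 0).any():
            raise ValueError("duplicate calendar knots in curve")
        if (self.error <= 0).any():
            raise ValueError("curve errors must be positive")

    def mu(self, theta: np.ndarray) -> np.ndarray:
        return np.interp(theta, self.cal_bp, self.c14_bp)

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        return np.interp(theta, self.cal_bp, self.error)

    @classmethod
    def identity(cls, lo: float = 0.0, hi: float = 10000.0,
                 error: float = 1e-9) -> "CalibrationCurve":
        """Degenerate curve mu(theta) = theta, used for property checks."""
        grid = np.array([lo, hi])
        return cls(grid, grid.copy(), np.full(2, max(error, 1e-9)), name="identity")


@dataclass
class CalibratedDate:
    """Posterior over calendar years plus 95.4% HPD ranges."""

    cra: float
    sigma: float
    grid: np.ndarray  # calendar years BP, ascending, 1-yr spacing
    density: np.ndarray  # sums to 1
    hpd: list[tuple[int, int]]  # (older, younger) cal BP, older >= younger
    level: float = DEFAULT_LEVEL
    curve_name: str = "curve"

    @property
    def mode(self) -> int:
        return int(self.grid[int(np.argmax(self.density))])

    @property
    def median(self) -> int:
        cdf = np.cumsum(self.density)
        return int(self.grid[int(np.searchsorted(cdf, 0.5))])

    def format_ranges(self) -> str:
        return "; ".join(f"{o}−{y}" for o, y in self.hpd)


def load_curve(path: str | Path, name: str | None = None) -> CalibrationCurve:
    """Parse a ``.14c`` file: cal BP, 14C BP, error; comma/whitespace split.

    Lines starting with ``#`` (and inline ``#`` comments) are ignored; extra
    columns (Delta-14C etc.) are tolerated.  Knots are sorted ascending.
    """
    path = Path(path)
    cal, c14, err = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in re.split(r"[,\s]+", line) if p]
            if len(parts) < 3:
                raise ValueError(f"curve line needs >= 3 columns: {line!r}")
            cal.append(float(parts[0]))
            c14.append(float(parts[1]))
            err.append(float(parts[2]))
    return CalibrationCurve(np.array(cal), np.array(c14), np.array(err),
                            name=name or path.stem)


def _hpd_ranges(grid: np.ndarray, density: np.ndarray, level: float) -> list[tuple[int, int]]:
    """Descending-density accumulation to >= level, merged into intervals."""
    order = np.argsort(density)[::-1]
    cum = np.cumsum(density[order])
    k = int(np.searchsorted(cum, level)) + 1
    chosen = np.sort(order[:k])
    intervals: list[tuple[int, int]] = []
    start = prev = chosen[0]
    for idx in chosen[1:]:
        if idx == prev + 1:
            prev = idx
        else:
            intervals.append((int(round(grid[prev])), int(round(grid[start]))))
            start = prev = idx
    intervals.append((int(round(grid[prev])), int(round(grid[start]))))
    # grid ascends young->old in cal BP terms?  grid is ascending cal BP, so
    # the end of a run is the OLDER year; report (older, younger)
    return sorted(intervals, reverse=True)


def calibrate(
    cra: float,
    sigma: float,
    curve: CalibrationCurve,
    level: float = DEFAULT_LEVEL,
) -> CalibratedDate:
    """Calibrate one measurement to a posterior and its HPD ranges."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    max_err = float(np.max(curve.error))
    lo_14c = float(np.min(curve.c14_bp)) - 10 * (sigma + max_err)
    hi_14c = float(np.max(curve.c14_bp)) + 10 * (sigma + max_err)
    if not lo_14c <= cra <= hi_14c:
        raise OutOfCurveError(
            f"CRA {cra} outside curve 14C support [{lo_14c:.0f}, {hi_14c:.0f}]"
        )
    grid = np.arange(np.floor(curve.cal_bp.min()), np.ceil(curve.cal_bp.max()) + 1.0)
    mu = curve.mu(grid)
    var = sigma**2 + curve.sigma(grid) ** 2
    log_density = -((cra - mu) ** 2) / (2.0 * var)
    log_density -= log_density.max()
    density = np.exp(log_density)
    total = density.sum()
    if total == 0:
        raise OutOfCurveError(f"CRA {cra} has no posterior mass on the curve grid")
    density /= total
    hpd = _hpd_ranges(grid, density, level)
    return CalibratedDate(cra=cra, sigma=sigma, grid=grid, density=density,
                          hpd=hpd, level=level, curve_name=curve.name)


def ranges_overlap(a: CalibratedDate, b: CalibratedDate) -> bool:
    """True iff any HPD interval of ``a`` intersects any of ``b`` (closed)."""
    for ao, ay in a.hpd:
        for bo, by in b.hpd:
            if max(ay, by) <= min(ao, bo):
                return True
    return False


def intersect_hpd(dates: list[CalibratedDate]) -> list[tuple[int, int]]:
    """Intersection of the HPD range-sets of several dates (may be empty)."""
    if not dates:
        return []
    current = list(dates[0].hpd)
    for d in dates[1:]:
        nxt = []
        for ao, ay in current:
            for bo, by in d.hpd:
                older, younger = min(ao, bo), max(ay, by)
                if younger <= older:
                    nxt.append((older, younger))
        current = sorted(set(nxt), reverse=True)
    return current


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cal BP, 14C age BP, error\n")
        for c, m, e in zip(curve.cal_bp, curve.c14_bp, curve.error):
            fh.write(f"{c:.0f},{m:.1f},{e:g}\n")


def write_calibrations(dates: dict[str, CalibratedDate], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "sample": name,
            "cra": d.cra,
            "error": d.sigma,
            "calibrated_95_4": d.format_ranges(),
            "mode_cal_bp": d.mode,
            "median_cal_bp": d.median,
        }
        for name, d in sorted(dates.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
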