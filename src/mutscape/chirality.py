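"""Chiral-HPLC peak integration and stereochemical ratios.

The Michael adduct of butanal and trans-β-nitrostyrene has two chiral
centres, giving four stereoisomers that a chiral stationary phase separates
into four peaks.  The syn enantiomers carry absolute labels (2R3S, 2S3R)
because reference material fixes their elution order; the anti enantiomers
cannot be assigned and keep elution-order labels anti-1 and anti-2.

From labelled peak areas:

* d.r. (diastereomeric ratio)  = 100 * syn : anti over the total area,
* e.r. (enantiomeric ratio)    = 100 * 2R3S : 2S3R over the syn pool,

both stored at full precision and reported Table-style as integers.  A
chromatogram whose total integrated area falls below ``min_total_area``
yields no ratios (insufficient ultraviolet signal).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

STEREO_LABELS = ("2R3S", "2S3R", "anti-1", "anti-2")

#: Retention-time windows (min) matching the synthetic generator's defaults.
DEFAULT_RT_WINDOWS: dict[str, tuple[float, float]] = {
    "2R3S": (4.0, 5.0),
    "2S3R": (5.0, 6.2),
    "anti-1": (6.4, 7.6),
    "anti-2": (8.0, 9.2),
}


@dataclasses.dataclass
class Peak:
    retention_time_min: float
    area: float
    start_index: int
    stop_index: int


@dataclasses.dataclass
class StereoResult:
    areas: dict[str, float]             # label -> integrated area
    dr: tuple[float, float] | None      # syn : anti, sums to 100
    er: tuple[float, float] | None      # 2R3S : 2S3R, sums to 100
    sufficient_signal: bool

    def rounded(self) -> dict[str, tuple[int, int] | None]:
        """Table-style integer ratios."""
        out = {}
        for name, pair in (("dr", self.dr), ("er", self.er)):
            if pair is None:
                out[name] = None
            else:
                a = int(round(pair[0]))
                out[name] = (a, 100 - a)
        return out


def estimate_baseline(signal_values: np.ndarray) -> float:
    """Constant baseline: 5th percentile of the signal."""
    return float(np.percentile(signal_values, 5.0))


def detect_and_integrate(chrom: pd.DataFrame, min_prominence: float = 1.0,
                         baseline: float | None = None) -> list[Peak]:
    """Find peaks above ``min_prominence`` and integrate them.

    ``chrom`` is a (time_min, signal) table.  After flat-baseline
    subtraction, each peak's region extends to the minima separating it from
    its neighbours (or the trace edges) and the area is the trapezoidal
    integral of the subtracted signal over that region.
    """
    t = chrom["time_min"].to_numpy(dtype=float)
    y = chrom["signal"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError("empty chromatogram")
    if baseline is None:
        baseline = estimate_baseline(y)
    ysub = y - baseline
    idx, _ = sps.find_peaks(ysub, prominence=min_prominence)
    if idx.size == 0:
        return []
    # region boundaries: minima between adjacent apexes, trace edges outside
    bounds = [0]
    for a, b in zip(idx[:-1], idx[1:]):
        bounds.append(int(a + np.argmin(ysub[a:b + 1])))
    bounds.append(t.size - 1)
    peaks = []
    for k, apex in enumerate(idx):
        lo, hi = bounds[k], bounds[k + 1]
        area = float(np.trapezoid(ysub[lo:hi + 1], t[lo:hi + 1]))
        peaks.append(Peak(retention_time_min=float(t[apex]), area=area,
                          start_index=lo, stop_index=hi))
    return peaks


def assign_stereoisomers(peaks: Sequence[Peak],
                         rt_windows: Mapping[str, tuple[float, float]] = DEFAULT_RT_WINDOWS,
                         ) -> tuple[dict[str, float], list[Peak]]:
    """Assign each peak to the retention-time window containing its apex.

    Windows must be disjoint.  Returns (label -> summed area, unassigned
    peaks).  Labels with no peak get area 0.
    """
    items = sorted(rt_windows.items(), key=lambda kv: kv[1][0])
    for (_, (lo1, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
        if hi1 > lo2:
            raise ValueError("retention-time windows overlap")
    areas = {label: 0.0 for label in rt_windows}
    unassigned = []
    for pk in peaks:
        for label, (lo, hi) in rt_windows.items():
            if lo <= pk.retention_time_min <= hi:
                areas[label] += pk.area
                break
        else:
            unassigned.append(pk)
    return areas, unassigned


def compute_dr_er(areas: Mapping[str, float],
                  min_total_area: float = 1.0) -> StereoResult:
    """Diastereomeric and enantiomeric ratios from labelled areas."""
    a = {label: float(areas.get(label, 0.0)) for label in STEREO_LABELS}
    if any(v < 0 for v in a.values()):
        raise ValueError("areas must be nonnegative")
    syn = a["2R3S"] + a["2S3R"]
    anti = a["anti-1"] + a["anti-2"]
    total = syn + anti
    if total < min_total_area:
        return StereoResult(areas=a, dr=None, er=None, sufficient_signal=False)
    dr = (100.0 * syn / total, 100.0 * anti / total)
    er = (100.0 * a["2R3S"] / syn, 100.0 * a["2S3R"] / syn) if syn > 0 else None
    return StereoResult(areas=a, dr=dr, er=er, sufficient_signal=True)


def analyze_chromatogram(chrom: pd.DataFrame,
                         rt_windows: Mapping[str, tuple[float, float]] = DEFAULT_RT_WINDOWS,
                         min_prominence: float = 1.0,
                         min_total_area: float = 1.0) -> StereoResult:
    """Integrate, assign and ratio a chromatogram in one call."""
    peaks = detect_and_integrate(chrom, min_prominence=min_prominence)
    areas, _ = assign_stereoisomers(peaks, rt_windows)
    return compute_dr_er(areas, min_total_area=min_total_area)


def er_to_ee(er: tuple[float, float]) -> float:
    """Enantiomeric ratio (summing to 100) -> enantiomeric excess in %."""
    a, b = er
    if abs(a + b - 100.0) > 1e-6:
        raise ValueError("e.r. components must sum to 100")
    return abs(a - b)


def ee_to_er(ee: float, major_first: bool = True) -> tuple[float, float]:
    """Enantiomeric excess in % -> e.r. pair, major component first by default."""
    if not 0 <= ee <= 100:
        raise ValueError("ee must be within 0..100")
    major, minor = 50.0 + ee / 2.0, 50.0 - ee / 2.0
    return (major, minor) if major_first else (minor, major)


def majority_label(result: StereoResult) -> str | None:
    """Which syn enantiomer dominates; None at exactly 50:50 or without e.r."""
    if result.er is None:
        return None
    r, s = result.er
    if r == s:
        return None
    return "2R3S" if r > s else "2S3R"
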