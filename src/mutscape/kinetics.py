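"""Initial-rate extraction and per-plate relative specific activities.

The screening readout is a substrate-depletion progress curve per well.  The
analysis chain is:

1. average duplicate traces pointwise into one curve per variant;
2. fit the initial linear section with a sliding least-squares window
   (highest R², earliest window on ties, confined to the region where at
   most ``max_fraction_depleted`` of the initial signal has been lost);
3. subtract the plate's empty-vector (EV) background rate;
4. convert to an activity U (μmol min^-1) and, with the gel-derived enzyme
   concentration, to a specific activity U mg^-1;
5. divide by the mean wild-type specific activity of that same plate to get
   the relative specific activity (U_mut/mg) / (U_wt/mg).

WT and EV controls are used exclusively within their own plate; negative
background-corrected rates are reported as an explicit ``zero_activity``
state, and wells whose enzyme concentration sits below the densitometric
detection limit as ``below_lod``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np


@dataclasses.dataclass
class KineticTrace:
    """Absorbance time series for one well."""

    times_s: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float
    well_id: str = ""
    role: str = "variant"  # variant | wt | ev
    variant_id: str | None = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times_s.size != self.absorbance.size:
            raise ValueError("times and absorbance must have equal length")
        if self.times_s.size and (np.diff(self.times_s) <= 0).any():
            raise ValueError("times must be strictly increasing")


@dataclasses.dataclass
class RateEstimate:
    rate_uM_min: float          # clipped at 0
    window: tuple[int, int]     # [start, stop) indices of the fitted span
    fit_r_squared: float
    slope_AU_s: float           # signed raw slope


@dataclasses.dataclass
class ActivityRecord:
    variant_id: str
    plate_id: str
    activity_U: float | None            # μmol min^-1 after background subtraction
    specific_activity: float | None     # U mg^-1
    state: str                          # value | zero_activity | below_lod
    relative: float | None = None
    window: tuple[int, int] | None = None
    fit_r_squared: float | None = None


def average_traces(traces: Sequence[KineticTrace]) -> KineticTrace:
    """Pointwise mean of replicate traces (shared time base required)."""
    if not traces:
        raise ValueError("no traces to average")
    base = traces[0]
    for tr in traces[1:]:
        if tr.times_s.size != base.times_s.size or not np.allclose(tr.times_s, base.times_s):
            raise ValueError("replicate traces must share one time base")
    mean = np.mean([tr.absorbance for tr in traces], axis=0)
    return KineticTrace(
        times_s=base.times_s.copy(), absorbance=mean,
        wavelength_nm=base.wavelength_nm, well_id=base.well_id,
        role=base.role, variant_id=base.variant_id,
    )


def _window_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R² for one window; flat windows get R² 0."""
    tc = t - t.mean()
    denom = float(tc @ tc)
    slope = float(tc @ (y - y.mean())) / denom
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0, 0.0
    resid = y - y.mean() - slope * tc
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return slope, r2


def initial_rate(trace: KineticTrace, spec, min_points: int = 8,
                 max_fraction_depleted: float = 0.20,
                 window_points: int | None = None) -> RateEstimate:
    """Fit the initial linear section of a depletion curve.

    ``spec`` supplies the absorbance-to-concentration conversion via its
    ``slope_to_rate`` method.  The linear section is delimited by the
    depletion cap: only the leading stretch where at most
    ``max_fraction_depleted`` of the initial signal has been lost is
    eligible.  By default the whole eligible stretch is fitted in one
    least-squares pass (for a curve that is linear until substrate
    exhaustion the cap itself excludes the plateau, and using every point
    minimises the variance of the slope).  Passing ``window_points`` instead
    slides a fixed-length window over the eligible stretch and keeps the one
    with the highest R² (earliest on ties), for curves with early
    nonlinearity.
    """
    t, y = trace.times_s, trace.absorbance
    if t.size < min_points:
        raise ValueError(f"trace has {t.size} points, need at least {min_points}")
    a0 = y[0]
    if a0 > 0:
        inside = (a0 - y) / a0 <= max_fraction_depleted
        # contiguous prefix of the allowed region
        limit = int(np.argmin(inside)) if not inside.all() else t.size
    else:
        limit = t.size
    limit = max(limit, min_points)          # degenerate traces: keep one window
    limit = min(limit, t.size)

    length = limit if window_points is None else min(max(window_points, 2), limit)
    best = None
    for start in range(0, limit - length + 1):
        stop = start + length
        slope, r2 = _window_fit(t[start:stop], y[start:stop])
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, start, stop, slope)
    r2, start, stop, slope = best
    rate = max(spec.slope_to_rate(-slope), 0.0)
    return RateEstimate(rate_uM_min=rate, window=(start, stop),
                        fit_r_squared=r2, slope_AU_s=slope)


def background_rate(ev_traces: Sequence[KineticTrace], spec,
                    min_points: int = 8,
                    max_fraction_depleted: float = 0.20) -> float:
    """Mean initial depletion rate (μM min^-1) of the plate's EV wells."""
    if not ev_traces:
        raise ValueError("no empty-vector wells on this plate")
    rates = [initial_rate(tr, spec, min_points, max_fraction_depleted).rate_uM_min
             for tr in ev_traces]
    return float(np.mean(rates))


LOD_MG_ML = 0.5   # densitometric detection limit, mg ml^-1 soluble protein in CFE


def specific_activity(rate_uM_min: float, background_uM_min: float, expr, spec,
                      variant_id: str = "", plate_id: str = "") -> ActivityRecord:
    """Background-corrected specific activity for one well.

    ``expr`` carries the CFE enzyme concentration (``conc_mg_ml``,
    ``below_lod``); ``spec`` the well geometry (``reaction_volume_ul``,
    ``cfe_fraction``).  Corrected rates at or below zero become the
    ``zero_activity`` state; sub-detection-limit enzyme concentrations the
    ``below_lod`` state regardless of the observed rate.
    """
    if expr is not None and getattr(expr, "below_lod", False):
        return ActivityRecord(variant_id, plate_id, None, None, "below_lod")
    corrected = rate_uM_min - background_uM_min
    volume_l = spec.reaction_volume_ul * 1e-6
    if corrected <= 0:
        return ActivityRecord(variant_id, plate_id, 0.0, 0.0, "zero_activity")
    activity_U = corrected * volume_l          # μM min^-1 * L = μmol min^-1
    mass_mg = expr.conc_mg_ml * spec.reaction_volume_ul / 1000.0 * spec.cfe_fraction
    return ActivityRecord(variant_id, plate_id, activity_U,
                          activity_U / mass_mg, "value")


def relative_activity(records: Iterable[ActivityRecord],
                      wt_specific_activities: Sequence[float],
                      method: str = "mean") -> list[ActivityRecord]:
    """Fill ``relative`` on each valued record using the plate's WT reference.

    The reference is the arithmetic mean (or, behind the config switch,
    median) of the wild-type specific activities measured on that same
    plate; cross-plate references are never used.
    """
    wt = [s for s in wt_specific_activities if s is not None and np.isfinite(s)]
    if not wt:
        raise ValueError("no valued wild-type record on this plate; "
                         "relative activities are undefined")
    reference = float(np.mean(wt)) if method == "mean" else float(np.median(wt))
    if reference <= 0:
        raise ValueError("wild-type reference specific activity is not positive")
    out = []
    for rec in records:
        rec = dataclasses.replace(rec)
        if rec.state == "value":
            rec.relative = rec.specific_activity / reference
        out.append(rec)
    return out


def analyze_plate(plate, expression: dict, wt_conc_mg_ml: float,
                  min_points: int = 8, max_fraction_depleted: float = 0.20,
                  wt_method: str = "mean") -> list[ActivityRecord]:
    """Run the whole per-plate chain: average duplicates, fit, subtract, normalize.

    ``plate`` is a :class:`~mutscape.synthdata.PlateDataset`-shaped object
    (``plate_id``, ``spec``, ``traces``); ``expression`` maps variant_id to
    an expression record.  ``wt_conc_mg_ml`` is the known concentration of
    the purified WT stock used for the control wells.
    """
    spec = plate.spec
    by_variant: dict[str, list[KineticTrace]] = {}
    wt_traces, ev_traces = [], []
    for tr in plate.traces:
        if tr.role == "wt":
            wt_traces.append(tr)
        elif tr.role == "ev":
            ev_traces.append(tr)
        else:
            by_variant.setdefault(tr.variant_id, []).append(tr)

    bg = background_rate(ev_traces, spec, min_points, max_fraction_depleted)

    class _WTExpr:
        conc_mg_ml = wt_conc_mg_ml
        below_lod = False

    wt_specifics = []
    for tr in wt_traces:
        est = initial_rate(tr, spec, min_points, max_fraction_depleted)
        rec = specific_activity(est.rate_uM_min, bg, _WTExpr, spec,
                                variant_id="WT", plate_id=plate.plate_id)
        if rec.state == "value":
            wt_specifics.append(rec.specific_activity)

    records = []
    for vid, traces in by_variant.items():
        mean_trace = average_traces(traces)
        est = initial_rate(mean_trace, spec, min_points, max_fraction_depleted)
        rec = specific_activity(est.rate_uM_min, bg, expression[vid], spec,
                                variant_id=vid, plate_id=plate.plate_id)
        rec.window = est.window
        rec.fit_r_squared = est.fit_r_squared
        records.append(rec)
    return relative_activity(records, wt_specifics, method=wt_method)
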