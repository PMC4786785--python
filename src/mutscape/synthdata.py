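"""Synthetic raw-data generators for the screening pipeline.

Every raw input the analysis stages consume — variant manifests, plate-reader
progress curves, gel band-intensity tables and chiral-HPLC chromatograms — can
be generated here with known ground truth, so the whole pipeline is testable
end to end without any instrument export.

The generators mirror the structure of a plate-based site-saturation screen:

* a collection of single mutants covering at least ``min_per_position`` of the
  19 possible substitutions at every position 2..62;
* duplicate wells per variant on each microtitre plate, plus wild-type (WT)
  and empty-vector (EV) control wells on that same plate;
* substrate-depletion progress curves that are linear until the substrate is
  exhausted, then flat (the analysis only consumes the initial linear
  section, and this piecewise model makes ground-truth slopes exact);
* SDS-PAGE gels carrying calibration lanes of 0.5/1/2.5/5 μg purified WT
  protein next to the sample lanes;
* four-Gaussian chromatograms whose areas follow a chosen stereoisomer
  fraction vector.

Noise is homoscedastic Gaussian on the raw signal (absorbance, band
intensity, detector units); magnitudes are configuration, not measurements.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AMINO_ACIDS,
    FIRST_POSITION,
    LAST_POSITION,
    N_POSITIONS,
    SUBSTITUTIONS_PER_POSITION,
    ReferenceSequence,
    Variant,
)
from .kinetics import KineticTrace

# ---------------------------------------------------------------------------
# assay specification

@dataclasses.dataclass(frozen=True)
class AssaySpec:
    """Plate-reader assay parameters.

    ``extinction`` (mM^-1 cm^-1) and ``path_length`` (cm) are instrument /
    chemistry constants that convert absorbance to concentration; they are
    configuration, and relative activities are invariant to them because the
    conversion cancels in the wild-type ratio.
    """

    substrate_id: str = "5a"
    wavelength_nm: float = 320.0
    substrate_conc_uM: float = 500.0
    duration_s: float = 2400.0
    interval_s: float = 60.0
    extinction_mM_cm: float = 10.0
    path_length_cm: float = 0.29
    buffer_pH: float = 7.3
    reaction_volume_ul: float = 100.0
    cfe_fraction: float = 0.40

    def __post_init__(self):
        if not self.duration_s > self.interval_s > 0:
            raise ValueError("require duration > interval > 0")
        if self.extinction_mM_cm <= 0 or self.path_length_cm <= 0:
            raise ValueError("extinction and path length must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 0.5 * self.interval_s, self.interval_s)

    @property
    def initial_absorbance(self) -> float:
        # A = eps [mM^-1 cm^-1] * l [cm] * c [mM]
        return self.extinction_mM_cm * self.path_length_cm * self.substrate_conc_uM / 1000.0

    def rate_to_slope(self, rate_uM_min: float) -> float:
        """Depletion rate (μM min^-1) -> absorbance slope magnitude (AU s^-1)."""
        return self.extinction_mM_cm * self.path_length_cm * rate_uM_min / 1000.0 / 60.0

    def slope_to_rate(self, slope_AU_s: float) -> float:
        """Absorbance slope magnitude (AU s^-1) -> depletion rate (μM min^-1)."""
        return slope_AU_s * 60.0 * 1000.0 / (self.extinction_mM_cm * self.path_length_cm)


#: Acetaldehyde + trans-β-nitrostyrene screen: 40 min at 320 nm, 60 s interval.
MICHAEL_ADDITION_ASSAY = AssaySpec()

#: Butanal + trans-β-nitrostyrene screen: 80 min at 320 nm, 60 s interval, pH 5.5.
BUTANAL_ADDITION_ASSAY = AssaySpec(
    substrate_conc_uM=650.0, duration_s=4800.0, buffer_pH=5.5, cfe_fraction=0.20
)

#: Tautomerase screen: 40 s at 283 nm with a 0.26 s interval.
TAUTOMERASE_ASSAY = AssaySpec(
    substrate_id="8",
    wavelength_nm=283.0,
    substrate_conc_uM=400.0,
    duration_s=40.0,
    interval_s=0.26,
    cfe_fraction=0.002,
)

# default screen-level ground truth (configuration, not measurements)
DEFAULT_WT_CONC_MG_ML = 5.0
DEFAULT_WT_RATE_UM_MIN = 3.0
DEFAULT_BACKGROUND_RATE_UM_MIN = 0.5
DEFAULT_TRACE_NOISE_AU = 0.005


# ---------------------------------------------------------------------------
# ground truth

@dataclasses.dataclass
class VariantTruth:
    true_conc_mg_ml: float
    true_rel_activity: float
    # stereoisomer fractions in the order (2R3S, 2S3R, anti-1, anti-2)
    true_stereo_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        f = np.asarray(self.true_stereo_fractions, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("stereo fractions must be nonnegative and sum to 1")
        if self.true_rel_activity < 0:
            raise ValueError("relative activity must be >= 0")


class TruthTable(dict):
    """Mapping variant_id -> :class:`VariantTruth` (ground truth for recovery tests)."""

    @classmethod
    def uniform(cls, variants: Sequence[Variant], conc: float = DEFAULT_WT_CONC_MG_ML,
                rel_activity: float = 1.0) -> "TruthTable":
        return cls(
            (v.variant_id, VariantTruth(conc, rel_activity)) for v in variants
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for vid, t in self.items():
            rows.append({
                "variant_id": vid,
                "true_conc_mg_ml": t.true_conc_mg_ml,
                "true_rel_activity": t.true_rel_activity,
                "frac_2R3S": t.true_stereo_fractions[0],
                "frac_2S3R": t.true_stereo_fractions[1],
                "frac_anti1": t.true_stereo_fractions[2],
                "frac_anti2": t.true_stereo_fractions[3],
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutant collection

def make_collection(reference: ReferenceSequence, min_per_position: int = 15,
                    total: int = 1040, seed: int = 0) -> list[Variant]:
    """Draw a single-mutant collection covering every position 2..62.

    Every position receives at least ``min_per_position`` of its 19 possible
    substitutions; the remaining ``total - 61*min_per_position`` variants are
    drawn uniformly at random from the leftovers.  Deterministic under
    ``seed``; raises ``ValueError`` when the request is infeasible.
    """
    if not 0 < min_per_position <= SUBSTITUTIONS_PER_POSITION:
        raise ValueError("min_per_position must be in 1..19")
    max_total = N_POSITIONS * SUBSTITUTIONS_PER_POSITION
    if total > max_total:
        raise ValueError(f"total {total} exceeds the {max_total} possible singles")
    if total < N_POSITIONS * min_per_position:
        raise ValueError(
            f"infeasible: total {total} < {N_POSITIONS} positions x "
            f"{min_per_position} minimum per position"
        )

    rng = np.random.default_rng(seed)
    chosen: list[Variant] = []
    leftovers: list[Variant] = []
    for position in range(FIRST_POSITION, LAST_POSITION + 1):
        wt = reference[position]
        muts = [aa for aa in AMINO_ACIDS if aa != wt]
        picked = rng.choice(len(muts), size=min_per_position, replace=False)
        picked_set = set(picked.tolist())
        for i, aa in enumerate(muts):
            v = Variant(position, wt, aa)
            (chosen if i in picked_set else leftovers).append(v)
    extra = total - len(chosen)
    if extra:
        idx = rng.choice(len(leftovers), size=extra, replace=False)
        chosen.extend(leftovers[i] for i in sorted(idx.tolist()))
    chosen.sort()
    return chosen


def manifest_frame(collection: Sequence[Variant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in collection],
            "position": [v.position for v in collection],
            "wt_aa": [v.wt_aa for v in collection],
            "mut_aa": [v.mut_aa for v in collection],
        }
    )


# ---------------------------------------------------------------------------
# kinetic traces and plates

def simulate_trace(spec: AssaySpec, true_rate: float, background_rate: float = 0.0,
                   noise_sd: float = 0.0, seed: int = 0, well_id: str = "A1",
                   role: str = "variant", variant_id: str | None = None) -> KineticTrace:
    """Two-phase (linear then flat) substrate-depletion progress curve.

    The absorbance starts at ``extinction * path * substrate_conc``, falls
    linearly at the combined depletion rate and clips at zero once the
    substrate is exhausted; Gaussian noise of ``noise_sd`` AU is then added.
    """
    if true_rate < 0 or background_rate < 0 or noise_sd < 0:
        raise ValueError("rates and noise_sd must be nonnegative")
    times = spec.times_s
    slope = spec.rate_to_slope(true_rate + background_rate)
    clean = np.maximum(spec.initial_absorbance - slope * times, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd, size=times.size)
    return KineticTrace(
        times_s=times,
        absorbance=clean,
        wavelength_nm=spec.wavelength_nm,
        well_id=well_id,
        role=role,
        variant_id=variant_id,
    )


def enzyme_mass_mg(conc_mg_ml: float, spec: AssaySpec) -> float:
    """Enzyme mass (mg) delivered to one well by the CFE aliquot."""
    return conc_mg_ml * spec.reaction_volume_ul / 1000.0 * spec.cfe_fraction


def well_rate_uM_min(conc_mg_ml: float, rel_activity: float,
                     wt_specific_activity: float, spec: AssaySpec) -> float:
    """True enzymatic depletion rate in a well (μM min^-1), background excluded."""
    mass = enzyme_mass_mg(conc_mg_ml, spec)
    volume_l = spec.reaction_volume_ul * 1e-6
    return rel_activity * wt_specific_activity * mass / volume_l


def wt_specific_activity_for_rate(rate_uM_min: float, conc_mg_ml: float,
                                  spec: AssaySpec) -> float:
    """Specific activity (U mg^-1) that yields ``rate_uM_min`` in a WT well."""
    mass = enzyme_mass_mg(conc_mg_ml, spec)
    volume_l = spec.reaction_volume_ul * 1e-6
    return rate_uM_min * volume_l / mass


@dataclasses.dataclass
class PlateDataset:
    """One simulated microtitre plate: labelled wells with progress curves."""

    plate_id: str
    spec: AssaySpec
    traces: list[KineticTrace]

    def to_frame(self) -> pd.DataFrame:
        """Long CSV dialect: well, role, variant_id, time_s, absorbance."""
        frames = []
        for tr in self.traces:
            frames.append(pd.DataFrame({
                "plate_id": self.plate_id,
                "well": tr.well_id,
                "role": tr.role,
                "variant_id": tr.variant_id if tr.variant_id is not None else "",
                "time_s": tr.times_s,
                "absorbance": tr.absorbance,
            }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, spec: AssaySpec,
                   plate_id: str | None = None) -> "PlateDataset":
        if plate_id is None:
            plate_id = str(frame["plate_id"].iloc[0]) if "plate_id" in frame else "plate"
        traces = []
        for (well, role, vid), grp in frame.groupby(["well", "role", "variant_id"],
                                                    sort=False):
            grp = grp.sort_values("time_s")
            traces.append(KineticTrace(
                times_s=grp["time_s"].to_numpy(dtype=float),
                absorbance=grp["absorbance"].to_numpy(dtype=float),
                wavelength_nm=spec.wavelength_nm,
                well_id=str(well),
                role=str(role),
                variant_id=str(vid) if vid else None,
            ))
        return cls(plate_id=plate_id, spec=spec, traces=traces)


_WELL_ROWS = "ABCDEFGH"


def _well_names(n: int, capacity: int = 96):
    if n > capacity:
        raise ValueError(f"plate overflow: need {n} wells, capacity {capacity}")
    return [f"{_WELL_ROWS[i // 12]}{i % 12 + 1}" for i in range(n)]


def simulate_plate(collection: Sequence[Variant], truth: Mapping[str, VariantTruth],
                   spec: AssaySpec = MICHAEL_ADDITION_ASSAY, n_wt_wells: int = 4,
                   n_ev_wells: int = 4, seed: int = 0, plate_id: str = "P1",
                   replicates: int = 2,
                   wt_conc_mg_ml: float = DEFAULT_WT_CONC_MG_ML,
                   wt_rate_uM_min: float = DEFAULT_WT_RATE_UM_MIN,
                   background_rate_uM_min: float = DEFAULT_BACKGROUND_RATE_UM_MIN,
                   noise_sd: float = DEFAULT_TRACE_NOISE_AU) -> PlateDataset:
    """Simulate one screening plate.

    Each variant occupies ``replicates`` wells; WT control wells share one
    true specific activity and EV (empty-vector) wells carry only the
    background depletion rate.  Raises on plate overflow.
    """
    if n_ev_wells < 0 or n_wt_wells < 0:
        raise ValueError("control well counts must be nonnegative")
    n_wells = len(collection) * replicates + n_wt_wells + n_ev_wells
    wells = iter(_well_names(n_wells))
    rng = np.random.default_rng(seed)
    s_wt = wt_specific_activity_for_rate(wt_rate_uM_min, wt_conc_mg_ml, spec)

    traces: list[KineticTrace] = []

    def add(rate, role, vid):
        traces.append(simulate_trace(
            spec, rate, background_rate_uM_min, noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            well_id=next(wells), role=role, variant_id=vid,
        ))

    for v in collection:
        t = truth[v.variant_id]
        rate = well_rate_uM_min(t.true_conc_mg_ml, t.true_rel_activity, s_wt, spec)
        for _ in range(replicates):
            add(rate, "variant", v.variant_id)
    wt_rate = well_rate_uM_min(wt_conc_mg_ml, 1.0, s_wt, spec)
    for _ in range(n_wt_wells):
        add(wt_rate, "wt", None)
    for _ in range(n_ev_wells):
        add(0.0, "ev", None)
    return PlateDataset(plate_id=plate_id, spec=spec, traces=traces)


# ---------------------------------------------------------------------------
# gels

CALIBRATION_LOADS_UG = (0.5, 1.0, 2.5, 5.0)


def simulate_gel(sample_loads: Mapping[str, float],
                 calibration_loads: Sequence[float] = CALIBRATION_LOADS_UG,
                 gain: float = 1000.0, intercept: float = 50.0,
                 noise_sd: float = 0.0, seed: int = 0,
                 gel_id: str = "G1") -> pd.DataFrame:
    """Band-intensity table for one gel: calibration lanes plus sample lanes.

    Intensity is linear in loaded protein: ``gain * load + intercept`` plus
    Gaussian noise.  Calibration lanes are flagged via ``role``.
    """
    loads = list(calibration_loads) + list(sample_loads.values())
    if any(l < 0 for l in loads):
        raise ValueError("loads must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    lane = 1
    for load in calibration_loads:
        rows.append((gel_id, lane, "calibration", "", load))
        lane += 1
    for vid, load in sample_loads.items():
        rows.append((gel_id, lane, "sample", vid, load))
        lane += 1
    frame = pd.DataFrame(rows, columns=["gel_id", "lane", "role", "variant_id", "load_ug"])
    noise = rng.normal(0.0, noise_sd, size=len(frame)) if noise_sd > 0 else 0.0
    frame["intensity"] = gain * frame["load_ug"].to_numpy() + intercept + noise
    return frame


def simulate_expression_gels(collection: Sequence[Variant],
                             truth: Mapping[str, VariantTruth],
                             loaded_cfe_volume_ul: float = 1.0,
                             samples_per_gel: int = 22, gain: float = 1000.0,
                             intercept: float = 50.0, noise_sd: float = 0.0,
                             seed: int = 0) -> pd.DataFrame:
    """Split a collection over 26-lane gels (4 calibration + up to 22 samples).

    The lane load (μg) of each sample is its CFE concentration (mg ml^-1 ==
    μg μl^-1) times the CFE volume equivalent loaded per lane.
    """
    rng = np.random.default_rng(seed)
    frames = []
    ids = [v.variant_id for v in collection]
    for g, start in enumerate(range(0, len(ids), samples_per_gel), start=1):
        chunk = ids[start:start + samples_per_gel]
        loads = {vid: truth[vid].true_conc_mg_ml * loaded_cfe_volume_ul for vid in chunk}
        frames.append(simulate_gel(
            loads, gain=gain, intercept=intercept, noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)), gel_id=f"G{g}",
        ))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# chromatograms

DEFAULT_RETENTION_TIMES_MIN = (4.5, 5.5, 7.0, 8.5)   # 2R3S, 2S3R, anti-1, anti-2
DEFAULT_PEAK_SIGMA_MIN = (0.08, 0.08, 0.08, 0.08)
STEREO_LABELS = ("2R3S", "2S3R", "anti-1", "anti-2")


def simulate_chromatogram(fractions: Sequence[float],
                          retention_times: Sequence[float] = DEFAULT_RETENTION_TIMES_MIN,
                          widths: Sequence[float] = DEFAULT_PEAK_SIGMA_MIN,
                          total_area: float = 1000.0, baseline: float = 5.0,
                          noise_sd: float = 0.0, seed: int = 0,
                          t_max: float = 11.0, dt: float = 0.002) -> pd.DataFrame:
    """Sum of four Gaussian peaks on a flat baseline.

    Peak ``i`` has analytic area ``total_area * fractions[i]``; the Gaussian
    ``widths`` are standard deviations in minutes.  Returns a (time_min,
    signal) table.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size != len(retention_times):
        raise ValueError("one fraction per retention time required")
    if (fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    rts = np.asarray(retention_times, dtype=float)
    if np.unique(rts).size != rts.size:
        raise ValueError("retention times must be distinct")
    sigmas = np.asarray(widths, dtype=float)
    t = np.arange(0.0, t_max + dt / 2, dt)
    signal = np.full_like(t, float(baseline))
    for frac, rt, sg in zip(fractions, rts, sigmas):
        area = total_area * frac
        signal += area / (sg * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sg) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"time_min": t, "signal": signal})


#: Wild-type-like product stereochemistry: d.r. 91:9 (syn:anti) and
#: e.r. 57:43 (2R3S:2S3R) on the syn pool.
WT_STEREO_FRACTIONS = (0.5187, 0.3913, 0.045, 0.045)


def make_truth(collection: Sequence[Variant], seed: int = 0,
               mean_conc_mg_ml: float = DEFAULT_WT_CONC_MG_ML,
               conc_sd: float = 1.0, rel_sigma: float = 0.4,
               hotspots: Mapping[int, float] | None = None,
               stereo_fractions=WT_STEREO_FRACTIONS) -> TruthTable:
    """Ground truth for a whole collection.

    Concentrations are Gaussian around ``mean_conc_mg_ml`` (clipped at 0.05);
    relative activities are log-normal around 1 with log-sd ``rel_sigma``.
    ``hotspots`` pins every variant at the given positions to an exact
    fold-improvement, for recovery tests with a known answer.
    """
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    hotspots = hotspots or {}
    for v in collection:
        conc = max(float(rng.normal(mean_conc_mg_ml, conc_sd)), 0.05)
        if v.position in hotspots:
            rel = float(hotspots[v.position])
        else:
            rel = float(np.exp(rng.normal(0.0, rel_sigma)))
        truth[v.variant_id] = VariantTruth(conc, rel, tuple(stereo_fractions))
    return truth


def fractions_from_dr_er(dr_syn: float, er_major: float,
                         major_label: str = "2R3S",
                         anti_split: float = 50.0) -> tuple[float, float, float, float]:
    """Stereoisomer fraction vector from a syn:anti d.r. and a syn e.r.

    ``dr_syn`` and ``er_major`` are the first components of ratios summing to
    100 (e.g. d.r. 96:4 -> ``dr_syn=96``); ``major_label`` says which syn
    enantiomer the e.r. refers to.  The anti pool is split ``anti_split``:
    ``100-anti_split`` between anti-1 and anti-2.
    """
    syn = dr_syn / 100.0
    anti = 1.0 - syn
    major = syn * er_major / 100.0
    minor = syn - major
    if major_label == "2R3S":
        f_r, f_s = major, minor
    elif major_label == "2S3R":
        f_r, f_s = minor, major
    else:
        raise ValueError("major_label must be 2R3S or 2S3R")
    return (f_r, f_s, anti * anti_split / 100.0, anti * (100.0 - anti_split) / 100.0)
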