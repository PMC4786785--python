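"""Mutability-landscape matrices: 20 amino acids x positions 2..62.

A landscape is a grid of one measured property (soluble expression,
relative specific activity, or enantiomeric ratio) for every single
substitution, with explicit per-cell states:

* ``wild_type``            the reference residue at that position (bold squares);
* ``absent``               substitution not in the collection, or no record;
* ``below_lod``            enzyme concentration under the detection limit;
* ``zero_activity``        background-corrected activity at or below zero;
* ``insufficient_signal``  not enough product for a ratio (e.r. metric);
* ``value``                a numeric measurement.

The matrix is the canonical artifact (long-form CSV round-trips exactly);
hotspot and enantio-inversion reports are views over it.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, FIRST_POSITION, LAST_POSITION, ReferenceSequence, Variant

STATES = ("wild_type", "absent", "below_lod", "zero_activity",
          "insufficient_signal", "value")
METRICS = ("expression", "relative_activity", "er")


@dataclasses.dataclass
class LandscapeMatrix:
    values: pd.DataFrame   # float, NaN unless state == value (or wild_type for relative)
    states: pd.DataFrame   # str, one of STATES
    metric: str
    reference: ReferenceSequence

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(self.values.columns)

    def state_counts(self) -> pd.Series:
        return self.states.stack().value_counts().reindex(STATES, fill_value=0)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions:
            wt = self.reference[pos]
            for aa in self.amino_acids:
                val = self.values.at[aa, pos]
                rows.append({
                    "position": pos, "wt_aa": wt, "mut_aa": aa,
                    "state": self.states.at[aa, pos],
                    "value": val if np.isfinite(val) else "",
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        frame = self.to_long()
        frame.insert(0, "metric", self.metric)
        frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, reference: ReferenceSequence) -> "LandscapeMatrix":
        frame = pd.read_csv(path, keep_default_na=False)
        metric = str(frame["metric"].iloc[0])
        positions = sorted(frame["position"].unique())
        aas = list(dict.fromkeys(frame["mut_aa"]))
        values = pd.DataFrame(np.nan, index=aas, columns=positions)
        states = pd.DataFrame("absent", index=aas, columns=positions)
        for _, row in frame.iterrows():
            states.at[row["mut_aa"], row["position"]] = row["state"]
            if row["value"] != "":
                values.at[row["mut_aa"], row["position"]] = float(row["value"])
        return cls(values=values, states=states, metric=metric, reference=reference)


def assemble(records: pd.DataFrame, metric: str, manifest: pd.DataFrame,
             reference: ReferenceSequence,
             amino_acid_order: Sequence[str] = AMINO_ACIDS) -> LandscapeMatrix:
    """Build a landscape from per-variant records and the collection manifest.

    ``records`` needs columns (variant_id, state, value); ``manifest``
    (variant_id, position, mut_aa) defines which cells are addressable.
    A record for a variant outside the manifest, or two records for one
    cell, is an error.  For the relative-activity metric the wild-type
    cells carry 1 by construction.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    positions = list(range(FIRST_POSITION, LAST_POSITION + 1))
    values = pd.DataFrame(np.nan, index=list(amino_acid_order), columns=positions)
    states = pd.DataFrame("absent", index=list(amino_acid_order), columns=positions)

    for pos in positions:
        states.at[reference[pos], pos] = "wild_type"
        if metric == "relative_activity":
            values.at[reference[pos], pos] = 1.0

    manifest_ids = set(manifest["variant_id"])
    if len(manifest_ids) != len(manifest):
        raise ValueError("duplicate variants in manifest")

    seen = set()
    for _, row in records.iterrows():
        vid = row["variant_id"]
        if vid not in manifest_ids:
            raise ValueError(f"record for variant {vid} not in manifest")
        if vid in seen:
            raise ValueError(f"duplicate record for variant {vid}")
        seen.add(vid)
        v = Variant.from_id(vid)
        v.validate_against(reference)
        state = row["state"]
        if state not in STATES:
            raise ValueError(f"unknown state {state!r} for {vid}")
        states.at[v.mut_aa, v.position] = state
        if state == "value":
            values.at[v.mut_aa, v.position] = float(row["value"])
    return LandscapeMatrix(values=values, states=states, metric=metric,
                           reference=reference)


@dataclasses.dataclass
class HotspotReport:
    threshold: float
    entries: pd.DataFrame    # position, mut_aa, value

    @property
    def positions(self) -> list[int]:
        return sorted(self.entries["position"].unique())


def find_hotspots(matrix: LandscapeMatrix, fold_threshold: float = 5.0) -> HotspotReport:
    """All valued cells whose relative activity exceeds ``fold_threshold``."""
    if matrix.metric != "relative_activity":
        raise ValueError("hotspot detection needs a relative-activity landscape")
    rows = []
    for pos in matrix.positions:
        for aa in matrix.amino_acids:
            if matrix.states.at[aa, pos] == "value":
                val = matrix.values.at[aa, pos]
                if val > fold_threshold:
                    rows.append({"position": pos, "mut_aa": aa, "value": val})
    entries = pd.DataFrame(rows, columns=["position", "mut_aa", "value"])
    return HotspotReport(threshold=fold_threshold, entries=entries)


def find_inversions(matrix: LandscapeMatrix,
                    wt_majority_label: str = "2R3S") -> pd.DataFrame:
    """Variants whose majority syn enantiomer differs from the wild type's.

    The e.r. landscape stores the 2R3S percentage of the syn pool per cell;
    a cell at exactly 50:50 has no majority and is not an inversion.
    """
    if matrix.metric != "er":
        raise ValueError("inversion detection needs an e.r. landscape")
    if wt_majority_label not in ("2R3S", "2S3R"):
        raise ValueError("wt majority label must be 2R3S or 2S3R")
    rows = []
    for pos in matrix.positions:
        for aa in matrix.amino_acids:
            if matrix.states.at[aa, pos] != "value":
                continue
            pct_2r3s = matrix.values.at[aa, pos]
            if pct_2r3s == 50.0:
                continue
            label = "2R3S" if pct_2r3s > 50.0 else "2S3R"
            if label != wt_majority_label:
                rows.append({"position": pos, "mut_aa": aa,
                             "er_2R3S": pct_2r3s, "majority": label})
    return pd.DataFrame(rows, columns=["position", "mut_aa", "er_2R3S", "majority"])


def position_summary(matrix: LandscapeMatrix, beneficial_above: float = 2.0,
                     detrimental_below: float = 0.5) -> pd.DataFrame:
    """Per-position tallies of neutral / beneficial / detrimental cells."""
    if matrix.metric != "relative_activity":
        raise ValueError("classification needs a relative-activity landscape")
    rows = []
    for pos in matrix.positions:
        tally = {"position": pos, "beneficial": 0, "neutral": 0, "detrimental": 0}
        for aa in matrix.amino_acids:
            if matrix.states.at[aa, pos] != "value":
                continue
            val = matrix.values.at[aa, pos]
            if val > beneficial_above:
                tally["beneficial"] += 1
            elif val < detrimental_below:
                tally["detrimental"] += 1
            else:
                tally["neutral"] += 1
        rows.append(tally)
    return pd.DataFrame(rows)


def render_heatmap(matrix: LandscapeMatrix, path) -> None:
    """Optional figure export; the CSV remains the canonical artifact."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(14, 5))
    data = matrix.values.to_numpy(dtype=float)
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(matrix.amino_acids)), matrix.amino_acids)
    ax.set_xticks(range(0, len(matrix.positions), 5),
                  [str(p) for p in matrix.positions][::5])
    ax.set_xlabel("position")
    ax.set_title(f"mutability landscape: {matrix.metric}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
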