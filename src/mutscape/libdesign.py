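"""Degenerate-codon expansion, combinatorial library sizes, coverage,
and an additivity heuristic for multi-mutants.

A focused library is specified per position either as an explicit
amino-acid set or as a degenerate codon over the IUPAC nucleotide alphabet
(e.g. NNK = all four bases at the first two positions, G/T at the third:
32 codons covering all 20 amino acids plus the amber stop).  Protein-level
library sizes exclude stop codons but the stop count is reported, since it
matters for screening effort.

The combination predictor is explicitly a heuristic: fold-changes of
single mutants multiply (additivity on log activity), and enantiomer
preferences add on the log-odds scale.  Its outputs carry a model tag and
are predictions, not measurements.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .core import FIRST_POSITION, LAST_POSITION, N_POSITIONS, SUBSTITUTIONS_PER_POSITION, Variant

IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate(codon: str) -> str:
    """Standard genetic code; '*' for stop."""
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclasses.dataclass
class CodonExpansion:
    amino_acids: frozenset[str]
    stop_codons: int
    n_codons: int


def expand_codon(codon: str) -> CodonExpansion:
    """Enumerate a degenerate IUPAC triplet into amino acids and stops."""
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"degenerate codon must be a triplet, got {codon!r}")
    try:
        choices = [IUPAC_NT[c] for c in codon]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC nucleotide code in {codon!r}") from exc
    aas, stops, n = set(), 0, 0
    for bases in itertools.product(*choices):
        n += 1
        aa = _translate("".join(bases))
        if aa == "*":
            stops += 1
        else:
            aas.add(aa)
    return CodonExpansion(amino_acids=frozenset(aas), stop_codons=stops, n_codons=n)


@dataclasses.dataclass
class LibraryDesign:
    """Per-position allowed amino-acid sets for a combinatorial library."""

    positions: dict[int, frozenset[str]]

    @classmethod
    def from_spec(cls, spec: Mapping[int, Sequence[str] | str]) -> "LibraryDesign":
        """Build from explicit sets (iterable of residues) or codon strings.

        A position maps either to an amino-acid collection (e.g.
        ``["H", "I", "L", "M", "V"]``, or a string of >3 residues) or to a
        degenerate codon.  A 3-character string of IUPAC codes is always
        read as a codon; pass a list/set for a 3-residue explicit set.
        """
        positions = {}
        for pos, allowed in spec.items():
            if isinstance(allowed, str) and len(allowed) == 3 and \
                    all(c.upper() in IUPAC_NT for c in allowed):
                positions[pos] = expand_codon(allowed).amino_acids
            else:
                positions[pos] = frozenset(str(a).upper() for a in allowed)
            if not positions[pos]:
                raise ValueError(f"empty amino-acid set at position {pos}")
        return cls(positions=positions)

    def size(self) -> int:
        return library_size(self)

    def enumerate_variants(self, reference) -> pd.DataFrame:
        """Manifest of all protein members (mutation lists vs the reference)."""
        rows = []
        pos_sorted = sorted(self.positions)
        for combo in itertools.product(*(sorted(self.positions[p]) for p in pos_sorted)):
            muts = [
                f"{reference[p]}{p}{aa}"
                for p, aa in zip(pos_sorted, combo) if aa != reference[p]
            ]
            rows.append({"member_id": "/".join(muts) if muts else "WT",
                         "n_mutations": len(muts)})
        return pd.DataFrame(rows)


def library_size(design: LibraryDesign) -> int:
    """Distinct protein variants: product of per-position set cardinalities."""
    if not design.positions:
        raise ValueError("library design has no positions")
    size = 1
    for allowed in design.positions.values():
        if not allowed:
            raise ValueError("empty amino-acid set in design")
        size *= len(allowed)
    return size


#: The focused four-position library combining activity hotspots: limited
#: degeneracy at His-6, Ala-33 and Phe-50, full NNK degeneracy at Met-45.
HOTSPOT_LIBRARY = LibraryDesign.from_spec({
    6: "HILMV",
    33: "ADEQ",
    45: "NNK",
    50: "FVLA",
})


def coverage(manifest: pd.DataFrame, n_positions: int = N_POSITIONS,
             alphabet_size: int = SUBSTITUTIONS_PER_POSITION) -> tuple[float, int]:
    """Fraction of all possible single mutants present in a collection.

    Returns ``(percent, rounded_percent)``; full precision is always kept
    alongside the integer report.
    """
    ids = manifest["variant_id"] if isinstance(manifest, pd.DataFrame) else list(manifest)
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("manifest variants must be unique")
    pct = 100.0 * len(ids) / (n_positions * alphabet_size)
    return pct, int(round(pct))


def predict_combined(single_effects: Mapping[str, float], combo: Sequence[str],
                     model: str = "log_additive",
                     metric: str = "relative_activity",
                     wt_er_2R3S: float = 50.0) -> dict:
    """Heuristic prediction for a combination of single mutants.

    ``log_additive`` multiplies single fold-changes for activity; for the
    e.r. metric the single effects are 2R3S percentages and the prediction
    adds log enantiomer odds relative to the wild-type baseline.  One
    mutation per position is required; the empty combination returns the
    wild-type value.  The result carries the model tag.
    """
    if model != "log_additive":
        raise ValueError(f"unknown model {model!r}")
    variants = [Variant.from_id(vid) for vid in combo]
    positions = [v.position for v in variants]
    if len(set(positions)) != len(positions):
        raise ValueError("combination has two mutations at one position")
    for v in variants:
        if v.variant_id not in single_effects:
            raise KeyError(f"no single-mutant effect for {v.variant_id}")

    if metric == "relative_activity":
        pred = 1.0
        for v in variants:
            pred *= float(single_effects[v.variant_id])
    elif metric == "er":
        wt_odds = _odds(wt_er_2R3S)
        log_odds = np.log(wt_odds)
        for v in variants:
            log_odds += np.log(_odds(float(single_effects[v.variant_id]))) - np.log(wt_odds)
        odds = np.exp(log_odds)
        pred = 100.0 * odds / (1.0 + odds)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return {"prediction": float(pred), "metric": metric, "model": model,
            "combo": "/".join(sorted(combo)) if combo else "WT"}


def _odds(pct: float) -> float:
    if not 0 < pct < 100:
        raise ValueError("e.r. percentage must be strictly inside (0, 100) "
                         "for log-odds additivity")
    return pct / (100.0 - pct)
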