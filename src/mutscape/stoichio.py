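"""Preparative-reaction arithmetic: mol%, fold-excess and molar yields.

The semi-preparative Michael-type additions run a limiting nitroalkene
acceptor (typically 2 mM) against a large excess of the aldehyde donor with
catalytic enzyme (μM, monomer basis).  This module holds the bookkeeping
around those reactions:

* catalyst loading in mol% of the limiting substrate;
* donor-over-acceptor fold-excess;
* molar yield from an isolated product mass, with an optional
  weight-fraction correction for a known contaminant in the isolate.

Molar masses come from molecular formulas and IUPAC standard atomic
weights; γ-nitroaldehyde product formulas are tabulated from their
systematic names.
"""

from __future__ import annotations

import dataclasses
import re

# IUPAC 2021 standard atomic weights (conventional values), g mol^-1
ATOMIC_WEIGHTS = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06,
    "Cl": 35.45, "K": 39.098, "Br": 79.904, "I": 126.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """'C10H11NO3' -> {'C': 10, 'H': 11, 'N': 1, 'O': 3}."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, digits = match.group(1), match.group(2)
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molar_mass(formula: str | dict[str, int]) -> float:
    """Molar mass (g mol^-1) of a molecular formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts:
        raise ValueError("empty formula")
    for element, n in counts.items():
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r}")
        if n <= 0 or int(n) != n:
            raise ValueError(f"element count must be a positive integer, got {n}")
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())


@dataclasses.dataclass(frozen=True)
class CompoundSpec:
    id: str
    formula: str
    name: str = ""

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula)


#: γ-nitroaldehyde products and the nitroalkene acceptor; formulas derived
#: from the systematic names (synthetic fixtures table, not instrument data).
COMPOUNDS = {
    c.id: c for c in [
        CompoundSpec("5a", "C8H7NO2", "trans-beta-nitrostyrene"),
        CompoundSpec("6a", "C10H11NO3", "4-nitro-3-phenylbutanal"),
        CompoundSpec("6b", "C10H10ClNO3", "3-(4-chlorophenyl)-4-nitrobutanal"),
        CompoundSpec("6c", "C10H10FNO3", "3-(4-fluorophenyl)-4-nitrobutanal"),
        CompoundSpec("6d", "C10H11NO4", "3-(4-hydroxyphenyl)-4-nitrobutanal"),
        CompoundSpec("6e", "C11H13NO5", "3-(3-hydroxy-4-methoxyphenyl)-4-nitrobutanal"),
        CompoundSpec("6f", "C16H21NO5",
                     "3-(3-(cyclopentyloxy)-4-methoxyphenyl)-4-nitrobutanal"),
        CompoundSpec("6g", "C8H15NO3", "5-methyl-3-(nitromethyl)hexanal"),
        CompoundSpec("7", "C12H15NO3", "2-ethyl-4-nitro-3-phenylbutanal"),
    ]
}


@dataclasses.dataclass(frozen=True)
class ReactionSpec:
    """Preparative reaction: limiting substrate, donor, catalyst, volume."""

    limiting_conc_mM: float
    total_volume_ml: float
    donor_conc_mM: float = 0.0
    catalyst_conc_uM: float = 0.0   # monomer basis

    def __post_init__(self):
        if self.limiting_conc_mM <= 0 or self.total_volume_ml <= 0:
            raise ValueError("limiting concentration and volume must be positive")

    @property
    def theoretical_mmol(self) -> float:
        return self.limiting_conc_mM * self.total_volume_ml / 1000.0


def catalyst_molpercent(catalyst_uM: float, substrate_mM: float) -> float:
    """Catalyst loading as mol% of the limiting substrate."""
    if substrate_mM <= 0:
        raise ValueError("substrate concentration must be positive")
    return 100.0 * catalyst_uM / (substrate_mM * 1000.0)


def fold_excess(donor_mM: float, acceptor_mM: float) -> float:
    """Donor-over-acceptor concentration ratio."""
    if acceptor_mM <= 0:
        raise ValueError("acceptor concentration must be positive")
    return donor_mM / acceptor_mM


def isolated_yield(mass_mg: float, product: CompoundSpec, rxn: ReactionSpec,
                   contaminant_w_fraction: float = 0.0) -> tuple[float, float]:
    """Molar amount and percent yield from an isolated mass.

    ``contaminant_w_fraction`` removes a known weight fraction of a
    co-isolated impurity before converting to moles (0 is the identity
    correction).  Returns ``(mmol, percent)``.
    """
    if mass_mg < 0:
        raise ValueError("isolated mass must be nonnegative")
    if not 0 <= contaminant_w_fraction < 1:
        raise ValueError("contaminant weight fraction must be in [0, 1)")
    theoretical = rxn.theoretical_mmol
    if theoretical <= 0:
        raise ValueError("theoretical product amount is zero")
    effective_mg = mass_mg * (1.0 - contaminant_w_fraction)
    mmol = effective_mg / product.molar_mass
    return mmol, 100.0 * mmol / theoretical
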