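"""Accurate-mass arithmetic for positive-mode LC-MS annotation.

Monoisotopic element masses (most abundant isotope, 6 dp), the proton and
electron masses, and the common positive-mode adduct set used for
accurate-mass compound lookup. All adduct mass offsets are *computed* from
these constants rather than hand-entered, so internal consistency checks
(e.g. protonation minus water-loss-protonation equals one water) hold
exactly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_SPACING",
    "AdductHypothesis",
    "DEFAULT_ADDUCTS",
    "formula_mass",
    "mz_for_adduct",
    "invert_adduct",
    "CompoundRecord",
    "load_compound_table",
    "packaged_compounds",
]

# Most-abundant-isotope masses, Da (IUPAC/CODATA, 6 dp).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Na": 22.989770,
    "K": 38.963707,
    "Cl": 34.968853,
    "Br": 78.918338,
}

PROTON_MASS = 1.007276  # Da
ELECTRON_MASS = 0.000549  # Da
C13_SPACING = 1.003355  # Da, m(13C) - m(12C)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Monoisotopic neutral mass (Da) of an elemental formula.

    Supported elements: C, H, N, O, P, S, Na, K, Cl, Br. The mass is the
    sum of most-abundant-isotope masses, so e.g. ``formula_mass("H2O")``
    is 18.010565.

    Raises
    ------
    ValueError
        If the formula contains an unknown element or is malformed.
    """
    if not formula or not isinstance(formula, str):
        raise ValueError(f"empty or non-string formula: {formula!r}")
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        elem, count = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
        total += MONOISOTOPIC_MASS[elem] * (int(count) if count else 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return total


@dataclass(frozen=True)
class AdductHypothesis:
    """A singly charged positive ion type: m/z = neutral mass + mass_delta."""

    label: str
    mass_delta: float
    charge: int = 1


def _build_default_adducts() -> tuple[AdductHypothesis, ...]:
    water = formula_mass("H2O")
    acn = formula_mass("C2H3N")  # acetonitrile
    na_ion = MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS
    k_ion = MONOISOTOPIC_MASS["K"] - ELECTRON_MASS
    return (
        AdductHypothesis("[M+H]+", PROTON_MASS),
        AdductHypothesis("[M+Na]+", na_ion),
        AdductHypothesis("[M+K]+", k_ion),
        AdductHypothesis("[M+H-H2O]+", PROTON_MASS - water),
        AdductHypothesis("[M+H-2H2O]+", PROTON_MASS - 2.0 * water),
        AdductHypothesis("[M+ACN+H]+", acn + PROTON_MASS),
        AdductHypothesis("[M+ACN+Na]+", acn + na_ion),
        AdductHypothesis(
            "[M+2Na-H]+",
            2.0 * MONOISOTOPIC_MASS["Na"] - MONOISOTOPIC_MASS["H"] - ELECTRON_MASS,
        ),
    )


#: The common positive-mode adduct set used for database search.
DEFAULT_ADDUCTS: tuple[AdductHypothesis, ...] = _build_default_adducts()


def mz_for_adduct(neutral_mass: float, hypothesis: AdductHypothesis) -> float:
    """Predicted m/z of ``neutral_mass`` under the given (singly charged) ion type."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + hypothesis.mass_delta


def invert_adduct(mz: float, hypothesis: AdductHypothesis) -> float:
    """Neutral mass implied by an observed m/z under an adduct hypothesis.

    Exact inverse of :func:`mz_for_adduct`.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return mz - hypothesis.mass_delta


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    formula: str
    monoisotopic_mass: float


def load_compound_table(path) -> list[CompoundRecord]:
    """Load a compound table CSV with columns ``name,formula[,mass]``.

    The monoisotopic mass is recomputed from the formula; if a ``mass``
    column is present, a mismatch above 1e-4 Da fails validation.
    """
    records: list[CompoundRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        if reader.fieldnames is None or "name" not in reader.fieldnames or "formula" not in reader.fieldnames:
            raise ValueError(f"compound table {path} must have 'name' and 'formula' columns")
        for row in reader:
            mass = formula_mass(row["formula"].strip())
            declared = row.get("mass")
            if declared not in (None, ""):
                if abs(float(declared) - mass) > 1e-4:
                    raise ValueError(
                        f"compound {row['name']!r}: declared mass {declared} "
                        f"inconsistent with formula ({mass:.6f})"
                    )
            records.append(CompoundRecord(row["name"].strip(), row["formula"].strip(), mass))
    if not records:
        raise ValueError(f"compound table {path} is empty")
    return records


def packaged_compounds() -> list[CompoundRecord]:
    """The small packaged compound table (~50 common plasma metabolites and
    the three Alzheimer's-medication compounds)."""
    ref = resources.files("hrmwas").joinpath("data/compounds.csv")
    with resources.as_file(ref) as path:
        return load_compound_table(path)
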