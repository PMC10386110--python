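"""Monoisotopic mass arithmetic for accurate-mass dereplication.

Covers the numerical substrate of high-resolution LC-MS identification:
Hill-notation formula parsing, monoisotopic mass summation from a bundled
element table, positive-mode ESI adduct m/z arithmetic, and the paired
Da/ppm mass-error metric that accurate-mass library matching is gated on.

All masses are in daltons.  Adduct shifts carry the electron-mass
correction (the +H shift is the proton mass, not the H-atom mass), which
matters at sub-mDa matching tolerances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "ELECTRON_MASS",
    "Adduct",
    "MassError",
    "FormulaError",
    "load_element_table",
    "load_default_adducts",
    "parse_formula",
    "formula_to_hill",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_from_mz",
    "mass_error",
]

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.00054857990907

#: A molecular formula is a mapping element symbol -> count >= 1.
#: The empty mapping is the explicit "unknown formula" sentinel.
Formula = Mapping[str, int]


class FormulaError(ValueError):
    """Raised for malformed or unparseable molecular formulas."""


def _read_resource(name: str) -> pd.DataFrame:
    with resources.files("oxymet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_element_table() -> dict[str, float]:
    """Return the bundled element -> monoisotopic mass table (Da per atom)."""
    df = _read_resource("elements.csv")
    table = dict(zip(df["symbol"], df["monoisotopic_mass"].astype(float)))
    if len(table) != len(df):
        raise ValueError("element table contains duplicate symbols")
    if any(m <= 0 for m in table.values()):
        raise ValueError("element table contains non-positive masses")
    return table


@dataclass(frozen=True)
class Adduct:
    """A positive-mode ESI adduct: m/z = (M + mass_shift) / charge."""

    label: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")


def load_default_adducts() -> list[Adduct]:
    """Return the bundled default adduct set ([M+H]+, [M+Na]+, [M+NH4]+, [M+K]+)."""
    df = _read_resource("adducts.csv")
    adducts = [
        Adduct(row.label, float(row.mass_shift), int(row.charge))
        for row in df.itertuples()
    ]
    if len({a.label for a in adducts}) != len(adducts):
        raise ValueError("adduct table contains duplicate labels")
    return adducts


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str, elements: Mapping[str, float] | None = None) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into an element-count map.

    Isotope labels, charges and parenthesised groups are not supported.
    Repeated element tokens accumulate (``"CHHHH"`` == ``"CH4"``).

    Raises
    ------
    FormulaError
        On empty input, unknown element symbols, or malformed counts
        (the message names the offending symbol / position).
    """
    if elements is None:
        elements = load_element_table()
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    composition: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        symbol, digits = match.groups()
        if symbol not in elements:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        if digits == "":
            count = 1
        else:
            count = int(digits)
            if count < 1:
                raise FormulaError(
                    f"count for {symbol!r} must be >= 1 at position {pos} in {text!r}"
                )
        composition[symbol] = composition.get(symbol, 0) + count
        pos = match.end()
    return composition


def formula_to_hill(composition: Formula) -> str:
    """Serialize a composition map in Hill order (C, H, then alphabetical)."""
    def key(sym: str) -> tuple[int, str]:
        return ({"C": 0, "H": 1}.get(sym, 2), sym)

    parts = []
    for sym in sorted(composition, key=key):
        n = composition[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(
    formula: Formula | str, elements: Mapping[str, float] | None = None
) -> float:
    """Monoisotopic mass (Da) of a formula: sum of count x per-atom mass.

    Accepts either a composition map or a Hill-notation string.  The empty
    composition (unknown formula) has mass 0.0.
    """
    if elements is None:
        elements = load_element_table()
    if isinstance(formula, str):
        formula = parse_formula(formula, elements)
    total = 0.0
    for symbol, count in formula.items():
        if symbol not in elements:
            raise FormulaError(f"unknown element symbol {symbol!r}")
        if count < 0:
            raise FormulaError(f"negative count for element {symbol!r}")
        total += count * elements[symbol]
    return total


@dataclass(frozen=True)
class MassError:
    """Signed mass difference between an observed and a reference mass.

    ``delta_da`` is observed - reference in Da; ``delta_ppm`` the same
    difference relative to the reference mass, in parts per million.  The
    two share a sign by construction.
    """

    delta_da: float
    delta_ppm: float


def adduct_mz(neutral_mass: float, adduct: Adduct) -> float:
    """m/z of a neutral molecule ionised as ``adduct``."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + adduct.mass_shift) / adduct.charge


def neutral_from_mz(mz: float, adduct: Adduct) -> float:
    """Neutral monoisotopic mass implied by an observed m/z and its adduct."""
    neutral = mz * adduct.charge - adduct.mass_shift
    if neutral <= 0:
        raise ValueError(
            f"m/z {mz} with adduct {adduct.label} implies non-positive neutral mass"
        )
    return neutral


def mass_error(observed: float, reference: float) -> MassError:
    """Da and ppm error of ``observed`` against a library ``reference`` mass.

    The ppm denominator is the reference (library) mass: the tolerance is a
    property of the library assignment, and the difference against using
    the observed mass instead is far below rounding at these masses.
    """
    if reference <= 0:
        raise ValueError(f"reference mass must be positive, got {reference}")
    delta_da = observed - reference
    return MassError(delta_da=delta_da, delta_ppm=delta_da / reference * 1e6)
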