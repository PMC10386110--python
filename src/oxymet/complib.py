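"""Compound-library model and I/O for dereplication.

A :class:`CompoundLibrary` is the in-memory stand-in for a natural-product
reference database: named records with a monoisotopic mass (stored, or
computed from a molecular formula at load time), a biological source genus,
and free-form activity annotations.  The bundled fixture library
(``data/compound_library_synthetic.csv``) is a small open synthetic
substitute for commercial databases, containing published actinobacterial
metabolites plus invented mass-decoys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .chemmass import FormulaError, monoisotopic_mass, parse_formula

__all__ = [
    "CompoundRecord",
    "CompoundLibrary",
    "load_library",
    "bundled_library",
]

#: Stored mass vs formula-computed mass agreement required at load (Da).
_FORMULA_MASS_ATOL = 1e-6


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry.

    ``formula`` is None for records whose structure is unknown or whose
    published mass is more trustworthy than a derived formula; in that case
    ``monoisotopic_mass`` is the stored value.
    """

    name: str
    monoisotopic_mass: float
    biological_source: str
    formula: dict[str, int] | None = None
    activities: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: monoisotopic mass must be positive")
        if not self.biological_source:
            raise ValueError(f"{self.name}: biological source must be non-empty")
        if self.formula is not None:
            computed = monoisotopic_mass(self.formula)
            if abs(computed - self.monoisotopic_mass) > _FORMULA_MASS_ATOL:
                raise ValueError(
                    f"{self.name}: stored mass {self.monoisotopic_mass} disagrees "
                    f"with formula mass {computed:.6f}"
                )


class CompoundLibrary:
    """An ordered compound collection with a sorted-mass index for range queries."""

    def __init__(self, records: list[CompoundRecord], provenance: str = ""):
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound names: {dupes}")
        self.records = list(records)
        self.provenance = provenance
        order = np.argsort([r.monoisotopic_mass for r in self.records], kind="stable")
        self._sorted = [self.records[i] for i in order]
        self._masses = np.array([r.monoisotopic_mass for r in self._sorted])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> CompoundRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def mass_range_query(self, center: float, window: float) -> list[CompoundRecord]:
        """All records with |mass - center| <= window, nearest-mass first.

        Equivalent to a brute-force scan; implemented with a binary search
        on the sorted-mass index.  Ties in |mass - center| keep index order.
        """
        if window < 0:
            raise ValueError(f"window must be >= 0, got {window}")
        lo = int(np.searchsorted(self._masses, center - window, side="left"))
        hi = int(np.searchsorted(self._masses, center + window, side="right"))
        hits = self._sorted[lo:hi]
        return sorted(hits, key=lambda r: abs(r.monoisotopic_mass - center))


def _record_from_row(
    name: str,
    formula_text,
    mass,
    source,
    activities_text,
    elements: dict[str, float],
    row_label,
) -> CompoundRecord:
    formula = None
    if formula_text is not None and str(formula_text).strip() not in ("", "nan"):
        try:
            formula = parse_formula(str(formula_text).strip(), elements)
        except FormulaError as exc:
            raise ValueError(f"row {row_label} ({name!r}): {exc}") from exc
    if formula is not None:
        computed = monoisotopic_mass(formula, elements)
        if mass is not None and not np.isnan(float(mass)):
            stored = float(mass)
            if abs(stored - computed) > _FORMULA_MASS_ATOL:
                raise ValueError(
                    f"row {row_label} ({name!r}): stored mass {stored} disagrees "
                    f"with formula mass {computed:.6f}"
                )
        final_mass = computed
    else:
        if mass is None or np.isnan(float(mass)):
            raise ValueError(f"row {row_label} ({name!r}): neither formula nor mass given")
        final_mass = float(mass)
    if isinstance(activities_text, str) and activities_text.strip():
        activities = frozenset(
            tok.strip() for tok in activities_text.split(";") if tok.strip()
        )
    else:
        activities = frozenset()
    return CompoundRecord(
        name=name,
        monoisotopic_mass=final_mass,
        biological_source=str(source),
        formula=formula,
        activities=activities,
    )


_REQUIRED_COLUMNS = {"name", "formula", "monoisotopic_mass", "biological_source", "activities"}


def _library_from_frame(df: pd.DataFrame, provenance: str) -> CompoundLibrary:
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"library table is missing columns: {sorted(missing)}")
    from .chemmass import load_element_table

    elements = load_element_table()
    records = [
        _record_from_row(
            row["name"],
            row["formula"],
            row["monoisotopic_mass"],
            row["biological_source"],
            row["activities"],
            elements,
            idx,
        )
        for idx, row in df.iterrows()
    ]
    return CompoundLibrary(records, provenance=provenance)


def load_library(path: str | Path) -> CompoundLibrary:
    """Load a compound library from CSV or JSON.

    CSV columns: name, formula, monoisotopic_mass, biological_source,
    activities (semicolon-separated).  JSON mirrors the same schema as a
    list of objects.  Masses are recomputed from formulas where given and
    cross-checked against any stored value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload)
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                df[col] = None
        if "activities" in df.columns:
            df["activities"] = df["activities"].map(
                lambda v: ";".join(v) if isinstance(v, (list, tuple, set)) else v
            )
    else:
        df = pd.read_csv(path, comment="#")
    return _library_from_frame(df, provenance=str(path))


def bundled_library() -> CompoundLibrary:
    """The synthetic fixture library shipped with the package."""
    with resources.files("oxymet.data").joinpath("compound_library_synthetic.csv").open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    return _library_from_frame(df, provenance="bundled synthetic fixture library")
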