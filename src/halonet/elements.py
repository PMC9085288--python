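"""Isotope masses and natural abundances.

The static table below carries NIST-style atomic masses (Da) and natural
abundance fractions for the elements occurring in algal terpenoids and
C15-acetogenins (C, H, N, O, S plus Na for sodiated adducts and the
halogens Cl and Br).  Every theoretical m/z and isotopologue pattern in
this package derives from these numbers, so they are spelled out in
source rather than pulled from a dependency: a reported "calcd" value is
auditable against this file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Isotope",
    "ElementMassTable",
    "DEFAULT_TABLE",
    "ELECTRON_MASS",
]

#: Electron rest mass in Da (CODATA).  Used only by the optional
#: electron-corrected adduct convention.
ELECTRON_MASS = 0.000548579909


@dataclass(frozen=True)
class Isotope:
    """One isotope line: exact mass in Da and natural abundance fraction."""

    mass: float
    abundance: float


# mass (Da), abundance fraction; isotopes listed lightest first.
_DEFAULT_ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017779, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548351, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "Na": [(22.9897692809, 1.0)],
    "S": [(31.97207069, 0.9499), (32.9714585, 0.0075), (33.96786683, 0.0425), (35.96708088, 0.0001)],
    "Cl": [(34.96885271, 0.7576), (36.9659026, 0.2424)],
    "Br": [(78.9183376, 0.5069), (80.916291, 0.4931)],
}


class ElementMassTable:
    """Mapping of element symbol to its isotope list.

    Invariants enforced at construction: per-element abundances sum to
    1 within 1e-6, and isotope masses are strictly increasing.
    """

    def __init__(self, isotopes: Mapping[str, Iterable[tuple[float, float]]]):
        self._table: dict[str, tuple[Isotope, ...]] = {}
        for symbol, rows in isotopes.items():
            iso = tuple(Isotope(float(m), float(a)) for m, a in rows)
            if not iso:
                raise ValueError(f"element {symbol!r} has no isotopes")
            total = sum(i.abundance for i in iso)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"abundances for {symbol!r} sum to {total:.8f}, expected 1"
                )
            masses = [i.mass for i in iso]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses for {symbol!r} not increasing")
            self._table[symbol] = iso

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._table

    def __getitem__(self, symbol: str) -> tuple[Isotope, ...]:
        return self._table[symbol]

    def __iter__(self):
        return iter(self._table)

    def elements(self) -> tuple[str, ...]:
        return tuple(self._table)

    def monoisotopic(self, symbol: str) -> float:
        """Mass of the lightest isotope of ``symbol`` in Da."""
        return self._table[symbol][0].mass

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ElementMassTable":
        """Load a table from a 3-column TSV: symbol, mass, abundance.

        Rows for the same symbol accumulate; order within a symbol must
        be lightest first.  This is the override hook for users who want
        different atomic-mass conventions.
        """
        acc: dict[str, list[tuple[float, float]]] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                symbol, mass, abundance = row[0], float(row[1]), float(row[2])
                acc.setdefault(symbol, []).append((mass, abundance))
        return cls(acc)


#: The package-wide default table.
DEFAULT_TABLE = ElementMassTable(_DEFAULT_ISOTOPES)
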