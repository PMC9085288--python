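"""Molecular formulas, adduct m/z arithmetic and accurate-mass formula search.

The formula is the unit of all mass arithmetic here: parsing, Hill-order
writing, monoisotopic mass, adduct ion m/z and the bounded search that
assigns an elemental composition to an accurate mass under a ppm
tolerance and per-element count constraints (e.g. "exactly two Br and
one Cl", the constraint an isotopologue pattern justifies).

Adduct convention: published "calcd" m/z values for protonated and
sodiated ions of marine terpenoids are conventionally computed by adding
the NEUTRAL atom mass (H 1.00783, Na 22.98977) without an electron-mass
correction, and that convention reproduces the literature values this
package is tested against.  The physically strict convention (subtract
one electron mass per charge) is available via ``electron_correction``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .elements import DEFAULT_TABLE, ELECTRON_MASS, ElementMassTable

__all__ = [
    "MolecularFormula",
    "parse_formula",
    "Adduct",
    "PROTON_ADDUCT",
    "SODIUM_ADDUCT",
    "KNOWN_ADDUCTS",
    "monoisotopic_mass",
    "adduct_mz",
    "rdbe",
    "FormulaCandidate",
    "formula_search",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula input."""


class MolecularFormula(Mapping):
    """Immutable element→count mapping with additive arithmetic.

    Counts are non-negative integers; zero counts are dropped.  The
    empty formula is permitted (it is the identity of ``+`` and the
    added/removed part of simple adducts) — parsers reject it, code may
    construct it.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for symbol, n in (counts or {}).items():
            if not isinstance(n, int):
                raise FormulaError(f"count for {symbol!r} must be int, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {symbol!r}: {n}")
            if n > 0:
                clean[symbol] = n
        self._counts = clean

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts.get(symbol, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, symbol) -> bool:
        return symbol in self._counts

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self._counts)
        for s, n in other.items():
            merged[s] = merged.get(s, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self._counts)
        for s, n in other.items():
            merged[s] = merged.get(s, 0) - n
            if merged[s] < 0:
                raise FormulaError(
                    f"{other.hill()} is not a subformula of {self.hill() or '(empty)'}"
                )
        return MolecularFormula(merged)

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def contains(self, other: "MolecularFormula") -> bool:
        return all(self[s] >= n for s, n in other.items())

    def atom_count(self) -> int:
        return sum(self._counts.values())

    def is_empty(self) -> bool:
        return not self._counts

    # -- rendering --------------------------------------------------------
    def hill(self) -> str:
        """Canonical Hill-order string: C first, then H, then alphabetical."""
        parts = []
        symbols = sorted(self._counts)
        for special in ("C", "H"):
            if special in self._counts:
                symbols.remove(special)
                parts.append((special, self._counts[special]))
        parts.extend((s, self._counts[s]) for s in symbols)
        return "".join(f"{s}{n if n > 1 else ''}" for s, n in parts)

    def __repr__(self) -> str:
        return f"MolecularFormula({self.hill()!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, MolecularFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))


EMPTY = MolecularFormula()


def parse_formula(text: str, table: ElementMassTable = DEFAULT_TABLE) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C15H23Br2ClO"``.

    Raises :class:`FormulaError` on unknown element symbols, malformed
    tokens, explicit zero counts or an empty string.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in table:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(
    formula: MolecularFormula, table: ElementMassTable = DEFAULT_TABLE
) -> float:
    """Monoisotopic (lightest-isotope) mass in Da."""
    return sum(n * table.monoisotopic(s) for s, n in formula.items())


@dataclass(frozen=True)
class Adduct:
    """An ionized species: M plus ``added`` minus ``removed``, at ``charge``.

    ``added``/``removed`` are neutral-atom compositions; see the module
    docstring for the mass convention.
    """

    name: str
    added: MolecularFormula = field(default_factory=MolecularFormula)
    removed: MolecularFormula = field(default_factory=MolecularFormula)
    charge: int = 1

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")


PROTON_ADDUCT = Adduct("[M+H]+", added=MolecularFormula({"H": 1}))
SODIUM_ADDUCT = Adduct("[M+Na]+", added=MolecularFormula({"Na": 1}))

KNOWN_ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in (
        PROTON_ADDUCT,
        SODIUM_ADDUCT,
        Adduct(
            "[M-H2O+H]+",
            added=MolecularFormula({"H": 1}),
            removed=MolecularFormula({"H": 2, "O": 1}),
        ),
    )
}


def adduct_mz(
    formula: MolecularFormula,
    adduct: Adduct = PROTON_ADDUCT,
    table: ElementMassTable = DEFAULT_TABLE,
    electron_correction: bool = False,
) -> float:
    """m/z of the adduct ion of ``formula``.

    ``(mass(M) + mass(added) - mass(removed)) / charge`` with neutral
    atom masses; with ``electron_correction`` the mass of ``charge``
    electrons is subtracted before dividing.
    """
    if not (formula + adduct.added).contains(adduct.removed):
        raise FormulaError(
            f"cannot remove {adduct.removed.hill()} from "
            f"{(formula + adduct.added).hill()}"
        )
    mass = (
        monoisotopic_mass(formula, table)
        + monoisotopic_mass(adduct.added, table)
        - monoisotopic_mass(adduct.removed, table)
    )
    if electron_correction:
        mass -= adduct.charge * ELECTRON_MASS
    return mass / adduct.charge


def rdbe(formula: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents.

    Halogens count as valence-1:  C - (H + Cl + Br)/2 + N/2 + 1.
    """
    return (
        formula["C"]
        - (formula["H"] + formula["Cl"] + formula["Br"]) / 2.0
        + formula["N"] / 2.0
        + 1.0
    )


@dataclass(frozen=True)
class FormulaCandidate:
    """One composition explaining an accurate mass."""

    formula: MolecularFormula
    adduct: Adduct
    mz: float
    ppm_error: float  # signed, candidate minus target
    rdbe: float


#: Default per-element search bounds; adjusted by halogen constraints.
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 40),
    "H": (0, 80),
    "N": (0, 4),
    "O": (0, 12),
    "Br": (0, 4),
    "Cl": (0, 3),
}


def formula_search(
    target_mz: float,
    adduct: Adduct = PROTON_ADDUCT,
    tol_ppm: float = 5.0,
    bounds: Mapping[str, tuple[int, int]] | None = None,
    table: ElementMassTable = DEFAULT_TABLE,
    min_rdbe: float = 0.0,
) -> list[FormulaCandidate]:
    """Exhaustive composition search around an accurate m/z.

    Enumerates element counts within ``bounds`` (nested loops, heavy
    elements outermost, with mass pruning), keeps compositions whose
    adduct m/z lies within ``tol_ppm`` of ``target_mz`` and whose RDBE
    is at least ``min_rdbe``, and orders them by |ppm error| ascending,
    ties broken by RDBE descending then Hill string.

    An empty list is a valid result.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bounds = dict(bounds if bounds is not None else DEFAULT_BOUNDS)
    # Work in neutral-mass space: target neutral monoisotopic mass of M.
    neutral_target = (
        target_mz * adduct.charge
        - monoisotopic_mass(adduct.added, table)
        + monoisotopic_mass(adduct.removed, table)
    )
    tol_da = target_mz * tol_ppm * 1e-6 * adduct.charge
    lo_mass, hi_mass = neutral_target - tol_da, neutral_target + tol_da

    symbols = sorted(bounds, key=lambda s: -table.monoisotopic(s))
    unit = [table.monoisotopic(s) for s in symbols]
    lo = [bounds[s][0] for s in symbols]
    hi = [bounds[s][1] for s in symbols]
    # max mass attainable from element i onward (for lower-bound pruning)
    tail_max = [0.0] * (len(symbols) + 1)
    for i in range(len(symbols) - 1, -1, -1):
        tail_max[i] = tail_max[i + 1] + unit[i] * hi[i]

    out: list[FormulaCandidate] = []
    counts = [0] * len(symbols)

    def recurse(i: int, mass: float) -> None:
        if mass > hi_mass:
            return
        if mass + tail_max[i] < lo_mass:
            return
        if i == len(symbols):
            if lo_mass <= mass <= hi_mass:
                f = MolecularFormula(dict(zip(symbols, counts)))
                if f.is_empty():
                    return
                r = rdbe(f)
                if r < min_rdbe:
                    return
                mz = adduct_mz(f, adduct, table)
                ppm = (mz - target_mz) / target_mz * 1e6
                out.append(FormulaCandidate(f, adduct, mz, ppm, r))
            return
        for n in range(lo[i], hi[i] + 1):
            m = mass + n * unit[i]
            if m > hi_mass:
                break
            counts[i] = n
            recurse(i + 1, m)
        counts[i] = lo[i]

    recurse(0, 0.0)
    out.sort(key=lambda c: (abs(c.ppm_error), -c.rdbe, c.formula.hill()))
    return out
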