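"""Isotopologue patterns and halogen-count inference.

Bromine (79/81, ~51:49) and chlorine (35/37, ~76:24) give multi-line
precursor clusters spaced ~2 Da whose intensity ratios encode the
halogen count: Br2 reads 1:2:1, Br2Cl reads 3:7:5:1.  This module
computes theoretical isotopologue patterns by exact convolution over the
element table, renders the small-integer ratios used in dereplication
arguments, scores observed clusters against a grid of (nBr, nCl)
hypotheses, and groups network nodes that are isotopologues of one
another (13C +1.0034 Da or 81Br-79Br +1.9980 Da spacing at equal
retention time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .elements import DEFAULT_TABLE, ElementMassTable
from .formula import MolecularFormula

__all__ = [
    "IsotopePattern",
    "isotope_pattern",
    "halogen_pattern",
    "integer_ratio",
    "HalogenHypothesis",
    "classify_halogens",
    "find_isotopologue_partners",
]

#: 13C - 12C spacing in Da.
C13_SPACING = 1.00336
#: 81Br - 79Br spacing in Da (also ~ 37Cl - 35Cl, 1.99705).
BR_SPACING = 1.99795

# isotopologues closer than this aggregate into one pattern line; wide
# enough to merge e.g. 81Br vs 13C2 (+1.998 vs +2.007), narrow enough to
# keep the +1 (13C) and +2 (81Br) lines apart.
_BIN_WIDTH = 0.3


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue lines as parallel (m/z, relative intensity) arrays.

    ``normalization`` is ``"base"`` (largest line = 1) or ``"min"``
    (smallest retained line = 1, the convention behind printed ratios
    like 3:7:5:1).
    """

    mz: tuple[float, ...]
    intensity: tuple[float, ...]
    normalization: str = "base"

    def __post_init__(self):
        if len(self.mz) != len(self.intensity) or not self.mz:
            raise ValueError("pattern needs equal-length, nonempty mz/intensity")
        if any(b <= a for a, b in zip(self.mz, self.mz[1:])):
            raise ValueError("pattern m/z must be strictly increasing")
        if any(i <= 0 for i in self.intensity):
            raise ValueError("pattern intensities must be positive")

    def __len__(self) -> int:
        return len(self.mz)

    def rebase(self, normalization: str) -> "IsotopePattern":
        inten = np.asarray(self.intensity, dtype=float)
        if normalization == "base":
            inten = inten / inten.max()
        elif normalization == "min":
            inten = inten / inten.min()
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        return IsotopePattern(self.mz, tuple(inten), normalization)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mz\tintensity\n")
            for m, i in zip(self.mz, self.intensity):
                fh.write(f"{m:.6f}\t{i:.6g}\n")


def _n_atom_distribution(
    isotopes, n: int, prune: float = 1e-12
) -> list[tuple[float, float]]:
    """(mass, probability) lines for ``n`` atoms of one element.

    Exact multinomial expansion over the element's isotopes; pruning at
    ``prune`` only drops vanishing terms.
    """
    dist = [(0.0, 1.0)]
    for _ in range(n):
        nxt: dict[float, float] = {}
        for mass, p in dist:
            for iso in isotopes:
                key = mass + iso.mass
                nxt[key] = nxt.get(key, 0.0) + p * iso.abundance
        dist = [(m, p) for m, p in nxt.items() if p > prune]
    return dist


def _bin_lines(lines: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Aggregate lines within _BIN_WIDTH into intensity-weighted bins."""
    out: list[list[float]] = []  # [sum(m*p), sum(p)]
    for mass, p in sorted(lines):
        if out and mass - out[-1][0] / out[-1][1] < _BIN_WIDTH:
            out[-1][0] += mass * p
            out[-1][1] += p
        else:
            out.append([mass * p, p])
    return [(mp / p, p) for mp, p in out]


def isotope_pattern(
    formula: MolecularFormula,
    prune_below: float = 0.0,
    table: ElementMassTable = DEFAULT_TABLE,
    normalization: str = "base",
) -> IsotopePattern:
    """Theoretical isotopologue pattern of a (neutral or ionic) composition.

    Exact convolution of per-element multinomial distributions, then
    0.3-Da aggregation into isotopologue lines, pruning of lines below
    ``prune_below`` (fraction of the base line) and renormalization.
    """
    if not (0 <= prune_below < 0.5):
        raise ValueError("prune_below must lie in [0, 0.5)")
    if formula.is_empty():
        raise ValueError("cannot compute a pattern for the empty formula")
    lines = [(0.0, 1.0)]
    for symbol, n in formula.items():
        elem = _n_atom_distribution(table[symbol], n)
        merged: dict[float, float] = {}
        for m1, p1 in lines:
            for m2, p2 in elem:
                key = round(m1 + m2, 9)
                merged[key] = merged.get(key, 0.0) + p1 * p2
        lines = [(m, p) for m, p in merged.items() if p > 1e-12]
    binned = _bin_lines(lines)
    base = max(p for _, p in binned)
    kept = [(m, p) for m, p in binned if p >= prune_below * base]
    mz, inten = zip(*kept)
    return IsotopePattern(mz, inten, "base").rebase(normalization)


def halogen_pattern(
    n_br: int, n_cl: int, table: ElementMassTable = DEFAULT_TABLE
) -> IsotopePattern:
    """Halogen-only A/A+2/... pattern for nBr bromines and nCl chlorines.

    This is the pattern behind printed ratio arguments (Br2 → 1:2:1,
    Br2Cl → 3:7:5:1): C/H/O isotopes are deliberately ignored.  For the
    halogen-free hypothesis a single unit line at offset 0 is returned.
    """
    if n_br < 0 or n_cl < 0:
        raise ValueError("halogen counts must be non-negative")
    f = MolecularFormula({"Br": n_br, "Cl": n_cl})
    if f.is_empty():
        return IsotopePattern((0.0,), (1.0,), "base")
    return isotope_pattern(f, table=table)


def integer_ratio(pattern: IsotopePattern, max_den: int = 20) -> list[int]:
    """Small-integer rendering of a pattern's intensities.

    Intensities are divided by the smallest retained line and rounded
    half-to-even, the convention that renders the Br2Cl halogen pattern
    (3.30 : 7.48 : 5.18 : 1) as 3:7:5:1.  Lines weaker than 1/``max_den``
    of the base line are dropped before normalizing.
    """
    inten = np.asarray(pattern.intensity, dtype=float)
    keep = inten >= inten.max() / max_den
    inten = inten[keep]
    ratio = inten / inten.min()
    ints = [max(1, int(v)) for v in np.rint(ratio)]
    return ints


@dataclass(frozen=True)
class HalogenHypothesis:
    """A candidate (nBr, nCl) with a [0, 1] fit score against a cluster."""

    n_br: int
    n_cl: int
    score: float


def _even_series(observed: IsotopePattern, spacing_tol: float = 0.1):
    """Read the A, A+2, A+4... series of an observed cluster.

    Peaks whose offset from the first (anchor) peak is not within
    ``spacing_tol`` of an even number of Da — e.g. 13C satellites at
    +1.0034 — are excluded from the series rather than invalidating the
    cluster.  Returns (intensity vector indexed by A+2k, flagged peaks).
    """
    anchor = observed.mz[0]
    series: dict[int, float] = {}
    flagged: list[float] = []
    for m, i in zip(observed.mz, observed.intensity):
        delta = m - anchor
        k = int(round(delta / 2.0))
        if abs(delta - 2.0 * k) <= spacing_tol:
            series[k] = series.get(k, 0.0) + i
        else:
            flagged.append(m)
    size = max(series) + 1
    vec = np.zeros(size)
    for k, i in series.items():
        vec[k] = i
    return vec, flagged


def classify_halogens(
    observed: IsotopePattern,
    max_br: int = 4,
    max_cl: int = 3,
    table: ElementMassTable = DEFAULT_TABLE,
    metric: str = "cosine",
    spacing_tol: float = 0.1,
) -> list[HalogenHypothesis]:
    """Rank (nBr, nCl) hypotheses against an observed isotope cluster.

    The observed cluster is collapsed to its A/A+2/... intensity series
    (see :func:`_even_series`); each hypothesis on the grid is scored by
    the cosine between that series and the theoretical halogen-only
    pattern, aligned by peak index and zero-padded to equal length
    (``metric="chi2"`` scores by 1/(1+X2) on min-normalized vectors
    instead).  Sorted by score descending, ties by total halogen count
    ascending then nBr ascending — so the simplest compatible hypothesis
    wins ties, and a single-line cluster classifies as halogen-free.
    """
    obs_vec, _ = _even_series(observed, spacing_tol)
    results: list[HalogenHypothesis] = []
    for n_br in range(max_br + 1):
        for n_cl in range(max_cl + 1):
            theo = halogen_pattern(n_br, n_cl, table)
            theo_vec, _ = _even_series(theo)
            size = max(len(obs_vec), len(theo_vec))
            a = np.zeros(size)
            b = np.zeros(size)
            a[: len(obs_vec)] = obs_vec
            b[: len(theo_vec)] = theo_vec
            if metric == "cosine":
                denom = np.linalg.norm(a) * np.linalg.norm(b)
                score = float(a @ b / denom) if denom > 0 else 0.0
            elif metric == "chi2":
                an = a / a.min() if a.min() > 0 else a / max(a.max(), 1e-12)
                bn = b / b[b > 0].min()
                chi2 = float(((an - bn) ** 2 / np.maximum(bn, 1e-12)).sum())
                score = 1.0 / (1.0 + chi2)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            results.append(HalogenHypothesis(n_br, n_cl, score))
    results.sort(key=lambda h: (-h.score, h.n_br + h.n_cl, h.n_br))
    return results


def find_isotopologue_partners(
    nodes: Sequence[tuple[float, float, float]],
    rt_tol: float = 0.2,
    mz_tol: float = 0.01,
) -> list[list[int]]:
    """Group co-eluting nodes that are isotopologues of each other.

    ``nodes`` is a sequence of (m/z, intensity, RT in min).  Two nodes
    join a group when their RT difference is within ``rt_tol`` and their
    m/z difference matches the 13C (+1.00336) or 81Br-79Br (+1.99795)
    spacing — or a small multiple of either, so A/A+2/A+4 chains merge —
    to within ``mz_tol``.  Returns index groups, each sorted by m/z
    ascending: the first (lowest-m/z) member is the representative.
    """
    n = len(nodes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    spacings = [k * C13_SPACING for k in (1, 2)] + [k * BR_SPACING for k in (1, 2, 3)]
    for i in range(n):
        for j in range(i + 1, n):
            if abs(nodes[i][2] - nodes[j][2]) > rt_tol:
                continue
            dmz = abs(nodes[i][0] - nodes[j][0])
            if any(abs(dmz - s) <= mz_tol for s in spacings):
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = [sorted(g, key=lambda i: nodes[i][0]) for g in groups.values()]
    out.sort(key=lambda g: nodes[g[0]][0])
    return out
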