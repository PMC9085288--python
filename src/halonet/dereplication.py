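"""Halogen-aware dereplication of network nodes.

The annotation pipeline renders, per node, the reasoning a natural-
product chemist applies when reading a halogenated metabolite spectrum:

1. classify the precursor isotope cluster into a (nBr, nCl) hypothesis;
2. search elemental compositions at the precursor m/z under that
   halogen constraint (5 ppm default);
3. read a neutral-loss chain (H2O, HBr, HCl, ketene, NaOH on sodiated
   ions, ...) down from the precursor in the fragment peaks;
4. look the composition up in the packaged reference table of algal
   terpenoids and C15-acetogenins.

The confidence tier records which evidence lines agree: A = formula +
isotope pattern + loss chain, B = formula + pattern, C = formula only.
Equal-formula reference hits are all reported — MS alone cannot rank
isomers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import DEFAULT_TABLE, ElementMassTable
from .formula import (
    Adduct,
    FormulaCandidate,
    KNOWN_ADDUCTS,
    MolecularFormula,
    monoisotopic_mass,
    parse_formula,
)
from .isotopes import HalogenHypothesis, IsotopePattern, classify_halogens
from .networking import MolecularNetwork
from .spectra import Spectrum

__all__ = [
    "NeutralLoss",
    "LossStep",
    "LossChain",
    "load_neutral_losses",
    "CompoundRecord",
    "load_compounds",
    "annotate_losses",
    "AnnotationConfig",
    "AnnotationResult",
    "annotate_node",
    "find_acetylation_pairs",
    "report",
]

#: Precursor-mass difference marking a putative acetylated derivative
#: (replacement of H by acetyl = +C2H2O = +42.0106 Da).
ACETYL_DELTA = 42.0106

COMPOUND_CLASSES = frozenset(
    {
        "xeniane diterpene",
        "guaiane prenylated diterpene",
        "chamigrane sesquiterpene",
        "bisabolane-related",
        "C15-acetogenin",
    }
)


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral-loss species with its exact mass."""

    name: str
    formula: MolecularFormula
    mass: float
    context: str = ""

    def __post_init__(self):
        expected = monoisotopic_mass(self.formula)
        if abs(self.mass - expected) > 1e-4:
            raise ValueError(
                f"loss {self.name}: mass {self.mass} != formula mass {expected:.4f}"
            )


def load_neutral_losses(
    path: str | Path | None = None, table: ElementMassTable = DEFAULT_TABLE
) -> list[NeutralLoss]:
    """Load the neutral-loss table (packaged default or a user TSV)."""
    if path is None:
        src = resources.files("halonet.data").joinpath("neutral_losses.tsv")
    else:
        src = Path(path)
    losses = []
    with src.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            f = parse_formula(row["formula"], table)
            losses.append(
                NeutralLoss(
                    row["name"], f, monoisotopic_mass(f, table),
                    (row.get("context") or "").strip(),
                )
            )
    return losses


@dataclass(frozen=True)
class LossStep:
    loss: NeutralLoss
    expected_mz: float
    observed_mz: float
    error: float  # observed - expected, Da


@dataclass(frozen=True)
class LossChain:
    """An ordered, fully peak-confirmed sequence of neutral losses."""

    steps: tuple[LossStep, ...] = ()

    def __len__(self) -> int:
        return len(self.steps)

    def total_error(self) -> float:
        return float(sum(abs(s.error) for s in self.steps))

    def names(self) -> list[str]:
        return [s.loss.name for s in self.steps]

    def describe(self) -> str:
        return " -> ".join(f"-{n}" for n in self.names()) if self.steps else ""


@dataclass(frozen=True)
class CompoundRecord:
    """One reference compound of the dereplication table."""

    number: int
    name: str
    formula: MolecularFormula
    compound_class: str
    adduct: str
    loss_chain: tuple[str, ...]
    source_species: str
    note: str

    def __post_init__(self):
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")


def load_compounds(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load the reference compound table (packaged default or user TSV)."""
    if path is None:
        src = resources.files("halonet.data").joinpath("compounds.tsv")
    else:
        src = Path(path)
    records = []
    with src.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                CompoundRecord(
                    number=int(row["number"]),
                    name=row["name"],
                    formula=parse_formula(row["formula"]),
                    compound_class=row["compound_class"],
                    adduct=row["adduct"],
                    loss_chain=tuple(row["loss_chain"].split(";")),
                    source_species=row["source_species"],
                    note=row["note"],
                )
            )
    return records


def annotate_losses(
    spectrum: Spectrum,
    precursor_formula: MolecularFormula | None = None,
    adduct: Adduct | None = None,
    losses: list[NeutralLoss] | None = None,
    frag_tol: float = 0.02,
    max_depth: int = 4,
) -> LossChain:
    """Find the best peak-confirmed neutral-loss chain below the precursor.

    Breadth-first search over loss sequences (depth ≤ ``max_depth``)
    starting at the precursor m/z: a step survives only if an observed
    fragment peak lies within ``frag_tol`` of the expected m/z, so
    expected m/z is strictly decreasing along any chain.  When a
    precursor composition is supplied, each loss must remain a
    subformula of what is left of the ion (and NaOH is only considered
    when the ion carries sodium).  Returns the chain with the most
    confirmed steps, ties broken by the smaller summed |error|; the
    empty chain is a valid result.
    """
    if losses is None:
        losses = load_neutral_losses()
    ion_formula = None
    if precursor_formula is not None:
        ion_formula = precursor_formula + (adduct.added if adduct else MolecularFormula())
        if adduct is not None and not adduct.removed.is_empty():
            ion_formula = ion_formula - adduct.removed
    usable = []
    for loss in losses:
        if "sodiated" in loss.context and (
            ion_formula is None or ion_formula["Na"] == 0
        ):
            continue
        usable.append(loss)

    best = LossChain()
    # state: (chain tuple, current mz, remaining formula)
    frontier = [((), spectrum.precursor_mz, ion_formula)]
    seen: dict[tuple, float] = {}
    for _ in range(max_depth):
        nxt = []
        for chain, mz, remaining in frontier:
            for loss in usable:
                if remaining is not None and not remaining.contains(loss.formula):
                    continue
                expected = mz - loss.mass
                if expected <= 0:
                    continue
                idx = np.searchsorted(spectrum.mz, expected)
                cands = [
                    j
                    for j in (idx - 1, idx)
                    if 0 <= j < len(spectrum.mz)
                    and abs(spectrum.mz[j] - expected) <= frag_tol
                ]
                if not cands:
                    continue
                j = min(cands, key=lambda j: abs(spectrum.mz[j] - expected))
                step = LossStep(
                    loss, expected, float(spectrum.mz[j]),
                    float(spectrum.mz[j] - expected),
                )
                new_chain = chain + (step,)
                key = tuple(sorted(s.loss.name for s in new_chain))
                err = sum(abs(s.error) for s in new_chain)
                if key in seen and seen[key] <= err:
                    continue
                seen[key] = err
                new_remaining = (
                    remaining - loss.formula if remaining is not None else None
                )
                nxt.append((new_chain, expected, new_remaining))
                cand = LossChain(new_chain)
                if len(cand) > len(best) or (
                    len(cand) == len(best) and cand.total_error() < best.total_error()
                ):
                    best = cand
        frontier = nxt
        if not frontier:
            break
    return best


def cluster_from_spectrum(
    spectrum: Spectrum, frag_tol: float = 0.02, window: float = 8.0
) -> IsotopePattern | None:
    """Extract the precursor isotope cluster from the spectrum itself.

    QTof acquisitions with a wide isolation window co-transmit the
    precursor isotopologues, so MS/MS spectra of halogenated ions show
    the A/A+2/... cluster directly.  Returns the peaks from the one
    matching the precursor m/z (within ``frag_tol``) up to ``window`` Da
    above it, or None when the precursor peak itself is absent.
    """
    mask = np.abs(spectrum.mz - spectrum.precursor_mz) <= frag_tol
    if not mask.any():
        return None
    anchor = int(np.flatnonzero(mask)[np.argmax(spectrum.intensity[mask])])
    upper = spectrum.precursor_mz + window
    sel = slice(anchor, int(np.searchsorted(spectrum.mz, upper)))
    mz, inten = spectrum.mz[sel], spectrum.intensity[sel]
    if len(mz) == 0:
        return None
    return IsotopePattern(tuple(float(m) for m in mz), tuple(float(i) for i in inten))


@dataclass(frozen=True)
class AnnotationConfig:
    """Tolerances and search settings of the annotation pipeline."""

    ppm: float = 5.0
    frag_tol: float = 0.02
    max_depth: int = 4
    adducts: tuple[str, ...] = ("[M+H]+", "[M+Na]+")
    halogen_score_min: float = 0.95
    max_br: int = 4
    max_cl: int = 3
    bounds: dict = field(
        default_factory=lambda: {"C": (0, 30), "H": (0, 60), "N": (0, 0), "O": (0, 12)}
    )


@dataclass
class AnnotationResult:
    """Ranked evidence for one network node."""

    node_id: str
    halogens: HalogenHypothesis | None = None
    candidates: list[FormulaCandidate] = field(default_factory=list)
    chain: LossChain = field(default_factory=LossChain)
    matches: list[CompoundRecord] = field(default_factory=list)
    tier: str = ""

    @property
    def top_formula(self) -> MolecularFormula | None:
        return self.candidates[0].formula if self.candidates else None


def annotate_node(
    spectrum: Spectrum,
    cluster: IsotopePattern | None = None,
    reference: list[CompoundRecord] | None = None,
    config: AnnotationConfig = AnnotationConfig(),
    losses: list[NeutralLoss] | None = None,
) -> AnnotationResult:
    """Run the full halogen-aware annotation pipeline on one node.

    ``cluster`` is the node's precursor isotope cluster (from MS1 or
    from grouped isotopologue nodes); without it the halogen hypothesis
    is skipped and the search runs over the full Br/Cl grid, capping the
    confidence tier at C.
    """
    from .formula import formula_search  # local import to keep module load light

    result = AnnotationResult(node_id=spectrum.id)
    pattern_ok = False
    if cluster is None:
        cluster = cluster_from_spectrum(spectrum, config.frag_tol)
    if cluster is not None:
        hypotheses = classify_halogens(cluster, config.max_br, config.max_cl)
        result.halogens = hypotheses[0]
        pattern_ok = result.halogens.score >= config.halogen_score_min

    bounds = dict(config.bounds)
    if pattern_ok:
        bounds["Br"] = (result.halogens.n_br, result.halogens.n_br)
        bounds["Cl"] = (result.halogens.n_cl, result.halogens.n_cl)
    else:
        bounds["Br"] = (0, config.max_br)
        bounds["Cl"] = (0, config.max_cl)

    candidates: list[FormulaCandidate] = []
    for name in config.adducts:
        adduct = KNOWN_ADDUCTS[name]
        candidates.extend(
            formula_search(spectrum.precursor_mz, adduct, config.ppm, bounds)
        )
    candidates.sort(key=lambda c: (abs(c.ppm_error), -c.rdbe, c.formula.hill()))
    result.candidates = candidates

    if candidates:
        top = candidates[0]
        result.chain = annotate_losses(
            spectrum, top.formula, top.adduct, losses, config.frag_tol,
            config.max_depth,
        )
        if reference is None:
            reference = load_compounds()
        result.matches = [r for r in reference if r.formula == top.formula]
        if pattern_ok and len(result.chain) > 0:
            result.tier = "A"
        elif pattern_ok:
            result.tier = "B"
        else:
            result.tier = "C"
    return result


def find_acetylation_pairs(
    precursors: dict[str, float], tol: float = 0.01
) -> list[tuple[str, str]]:
    """Node pairs whose precursor m/z differ by the acetyl increment.

    A +42.0106 Da difference between two nodes suggests the heavier is
    an acetylated derivative of the lighter.  Returns (lighter id,
    heavier id) pairs.
    """
    items = sorted(precursors.items(), key=lambda kv: kv[1])
    out = []
    for i, (id_a, mz_a) in enumerate(items):
        for id_b, mz_b in items[i + 1 :]:
            delta = mz_b - mz_a
            if delta > ACETYL_DELTA + tol:
                break
            if abs(delta - ACETYL_DELTA) <= tol:
                out.append((id_a, id_b))
    return out


def report(
    network: MolecularNetwork,
    annotations: dict[str, AnnotationResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render node and family summary tables.

    One row per node (m/z, RT, extracts, family, tier, top formula,
    matched compound numbers joined by ";"); one row per family with
    node counts and pooled annotations.
    """
    acetyl = dict(
        (heavy, light)
        for light, heavy in find_acetylation_pairs(
            {n: network.graph.nodes[n]["mz"] for n in network.graph.nodes}
        )
    )
    rows = []
    for n in sorted(network.graph.nodes, key=lambda n: network.graph.nodes[n]["mz"]):
        data = network.graph.nodes[n]
        ann = annotations.get(n)
        rows.append(
            {
                "node": n,
                "mz": data["mz"],
                "rt": data["rt"],
                "extracts": data.get("extracts", ""),
                "family": data.get("family", ""),
                "tier": ann.tier if ann else "",
                "halogens": (
                    f"Br{ann.halogens.n_br}Cl{ann.halogens.n_cl}"
                    if ann and ann.halogens
                    else ""
                ),
                "formula": ann.top_formula.hill() if ann and ann.top_formula else "",
                "loss_chain": ann.chain.describe() if ann else "",
                "compounds": (
                    ";".join(str(r.number) for r in ann.matches) if ann else ""
                ),
                "acetylated_derivative_of": acetyl.get(n, ""),
            }
        )
    columns = [
        "node", "mz", "rt", "extracts", "family", "tier", "halogens",
        "formula", "loss_chain", "compounds", "acetylated_derivative_of",
    ]
    node_df = pd.DataFrame(rows, columns=columns)

    fam_rows = []
    for fam, members in network.families.items():
        tiers = [annotations[m].tier for m in members if m in annotations]
        compounds = sorted(
            {
                r.number
                for m in members
                if m in annotations
                for r in annotations[m].matches
            }
        )
        fam_rows.append(
            {
                "family": fam,
                "n_nodes": len(members),
                "min_mz": min(network.graph.nodes[m]["mz"] for m in members),
                "annotated": sum(1 for t in tiers if t),
                "compounds": ";".join(str(c) for c in compounds),
            }
        )
    family_df = pd.DataFrame(
        fam_rows, columns=["family", "n_nodes", "min_mz", "annotated", "compounds"]
    )
    return node_df, family_df
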