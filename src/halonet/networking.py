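"""Molecular network construction from MS/MS spectra.

Spectra are merged into consensus nodes by precursor m/z, scored
pairwise with the modified cosine (fragment matches either direct or
shifted by the precursor mass difference), and the thresholded edge set
is reduced to a network whose connected components of two or more nodes
are the molecular families F1, F2, ... (labelled by descending size).

Defaults mirror standard molecular-networking practice: square-root
intensity transform, cosine threshold 0.7, mutual top-10 edges per
node, components capped at 100 nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "CosineResult",
    "modified_cosine",
    "merge_precursors",
    "NetworkParams",
    "MolecularNetwork",
    "build_network",
    "export_graphml",
]


@dataclass(frozen=True)
class CosineResult:
    """Modified-cosine score in [0, 1] and matched peak-pair count."""

    score: float
    matches: int


def _normalized(spectrum: Spectrum) -> np.ndarray:
    """Square-root transformed, unit-norm intensity vector."""
    v = np.sqrt(spectrum.intensity)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _candidate_pairs(a: Spectrum, b: Spectrum, frag_tol: float):
    """(i, j, product, |Δ| ) candidate matches, direct and precursor-shifted."""
    va, vb = _normalized(a), _normalized(b)
    shift = b.precursor_mz - a.precursor_mz
    pairs = []
    seen = set()
    for offset in (0.0, shift):
        # two-pointer sweep over sorted arrays
        j0 = 0
        for i, ma in enumerate(a.mz):
            target = ma + offset
            while j0 < len(b.mz) and b.mz[j0] < target - frag_tol:
                j0 += 1
            j = j0
            while j < len(b.mz) and b.mz[j] <= target + frag_tol:
                if (i, j) not in seen:
                    seen.add((i, j))
                    pairs.append((i, j, va[i] * vb[j], abs(b.mz[j] - target)))
                j += 1
        if abs(shift) <= frag_tol:
            break  # identical precursors: shifted pass adds nothing
    return pairs


def modified_cosine(
    a: Spectrum, b: Spectrum, frag_tol: float = 0.02, exact: bool = False
) -> CosineResult:
    """Modified cosine similarity between two spectra.

    Candidate peak pairs match either directly (|Δm/z| ≤ ``frag_tol``)
    or shifted by the precursor m/z difference; a one-to-one matching is
    selected and the score is the sum of matched intensity products on
    square-root-normalized spectra.  The default matching is greedy by
    descending product (ties to the smaller m/z deviation); ``exact``
    switches to an optimal assignment (Hungarian), which tests compare
    against a brute-force enumeration.  Symmetric to 1e-12 and 1 only
    for identical normalized peak sets.
    """
    if len(a) == 0 or len(b) == 0:
        return CosineResult(0.0, 0)
    pairs = _candidate_pairs(a, b, frag_tol)
    if not pairs:
        return CosineResult(0.0, 0)
    if exact:
        cost = np.zeros((len(a), len(b)))
        for i, j, w, _ in pairs:
            cost[i, j] = max(cost[i, j], w)
        rows, cols = linear_sum_assignment(cost, maximize=True)
        allowed = {(i, j) for i, j, _, _ in pairs}
        score = 0.0
        matches = 0
        for i, j in zip(rows, cols):
            if (i, j) in allowed and cost[i, j] > 0:
                score += cost[i, j]
                matches += 1
    else:
        pairs.sort(key=lambda p: (-p[2], p[3]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        score = 0.0
        matches = 0
        for i, j, w, _ in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            score += w
            matches += 1
    return CosineResult(float(min(score, 1.0)), matches)


def merge_precursors(spectra: SpectrumSet, precursor_tol: float = 0.002) -> SpectrumSet:
    """Merge spectra whose precursor m/z agree within ``precursor_tol``.

    Single-linkage over the sorted precursor list; each group becomes a
    consensus spectrum with the intensity-weighted mean precursor m/z,
    mean RT, the peak union (peaks within 0.02 Da pooled into
    intensity-weighted m/z bins with summed intensity) and the union of
    extract memberships joined by "+" in the id.
    """
    if precursor_tol <= 0:
        raise ValueError("precursor_tol must be positive")
    items = sorted(spectra, key=lambda s: s.precursor_mz)
    if not items:
        return SpectrumSet([], dict(spectra.metadata))
    groups: list[list[Spectrum]] = [[items[0]]]
    for s in items[1:]:
        if s.precursor_mz - groups[-1][-1].precursor_mz <= precursor_tol:
            groups[-1].append(s)
        else:
            groups.append([s])
    merged: list[Spectrum] = []
    for group in groups:
        if len(group) == 1:
            merged.append(group[0])
            continue
        weights = np.array([max(s.base_peak_intensity(), 1.0) for s in group])
        precursor = float(
            np.average([s.precursor_mz for s in group], weights=weights)
        )
        rt = float(np.mean([s.rt for s in group]))
        mz = np.concatenate([s.mz for s in group])
        inten = np.concatenate([s.intensity for s in group])
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        out_mz: list[float] = []
        out_in: list[float] = []
        for m, i in zip(mz, inten):
            if out_mz and m - out_mz[-1] <= 0.02:
                w = out_in[-1] + i
                out_mz[-1] = (out_mz[-1] * out_in[-1] + m * i) / w
                out_in[-1] = w
            else:
                out_mz.append(float(m))
                out_in.append(float(i))
        extracts = sorted({s.extract for s in group if s.extract})
        merged.append(
            Spectrum(
                id="|".join(s.id for s in group),
                precursor_mz=precursor,
                rt=rt,
                mz=np.array(out_mz),
                intensity=np.array(out_in),
                charge=group[0].charge,
                extract="+".join(extracts),
            )
        )
    merged.sort(key=lambda s: s.precursor_mz)
    return SpectrumSet(merged, dict(spectra.metadata))


@dataclass(frozen=True)
class NetworkParams:
    """Edge-construction parameters (molecular-networking defaults).

    ``precursor_window``: before scoring, peaks within this window (Da)
    of a spectrum's own precursor m/z are removed — the standard
    precursor-window filter that keeps residual precursor/isotope lines
    from inflating similarity between unrelated ions.
    """

    frag_tol: float = 0.02
    score_threshold: float = 0.7
    min_matched: int = 4
    topk: int = 10
    max_component: int = 100
    precursor_window: float = 17.0

    def __post_init__(self):
        if min(self.frag_tol, self.score_threshold) <= 0 or min(
            self.min_matched, self.topk, self.max_component
        ) <= 0:
            raise ValueError("network parameters must be positive")


@dataclass
class MolecularNetwork:
    """Nodes, scored edges and family labels of one networking run."""

    graph: nx.Graph
    families: dict[str, list[str]] = field(default_factory=dict)

    @property
    def individual_nodes(self) -> list[str]:
        labelled = {n for members in self.families.values() for n in members}
        return [n for n in self.graph.nodes if n not in labelled]

    def node_count(self) -> int:
        return self.graph.number_of_nodes()


def _label_families(graph: nx.Graph) -> dict[str, list[str]]:
    components = [c for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort(
        key=lambda c: (-len(c), min(graph.nodes[n]["mz"] for n in c))
    )
    families: dict[str, list[str]] = {}
    for rank, comp in enumerate(components, start=1):
        members = sorted(comp, key=lambda n: graph.nodes[n]["mz"])
        families[f"F{rank}"] = members
    return families


def build_network(
    spectra: SpectrumSet, params: NetworkParams = NetworkParams()
) -> MolecularNetwork:
    """Score all spectrum pairs and assemble the molecular network.

    Edges require score ≥ threshold and matched pairs ≥ ``min_matched``;
    an edge survives only if it ranks within the top-``topk`` edges of
    both endpoints; components above ``max_component`` nodes are pruned
    by discarding their weakest edges.  Families (components of ≥2
    nodes) are labelled F1, F2, ... by descending size, ties by the
    smaller minimum precursor m/z.
    """
    nodes = [s for s in spectra if len(s) > 0]
    graph = nx.Graph()
    for s in nodes:
        graph.add_node(
            s.id, mz=round(float(s.precursor_mz), 6), rt=round(float(s.rt), 4),
            extracts=s.extract,
        )
    scored = []
    for s in nodes:
        keep = np.abs(s.mz - s.precursor_mz) > params.precursor_window
        scored.append(replace(s, mz=s.mz[keep], intensity=s.intensity[keep]))
    edges = []
    for a, b in itertools.combinations(scored, 2):
        res = modified_cosine(a, b, params.frag_tol)
        if res.score >= params.score_threshold and res.matches >= params.min_matched:
            edges.append((a.id, b.id, res))
    # mutual top-k filter
    by_node: dict[str, list[tuple[float, str, str]]] = {}
    for u, v, res in edges:
        by_node.setdefault(u, []).append((res.score, u, v))
        by_node.setdefault(v, []).append((res.score, u, v))
    keep: dict[tuple[str, str], int] = {}
    for node, incident in by_node.items():
        incident.sort(key=lambda t: -t[0])
        for _, u, v in incident[: params.topk]:
            keep[(u, v)] = keep.get((u, v), 0) + 1
    for u, v, res in edges:
        if keep.get((u, v), 0) == 2:
            graph.add_edge(u, v, score=round(res.score, 6), matches=res.matches)
    # cap component size by removing weakest edges
    while True:
        oversized = [
            c for c in nx.connected_components(graph) if len(c) > params.max_component
        ]
        if not oversized:
            break
        comp = oversized[0]
        u, v, _ = min(
            graph.subgraph(comp).edges(data="score"), key=lambda e: e[2]
        )
        graph.remove_edge(u, v)
    families = _label_families(graph)
    for fam, members in families.items():
        for n in members:
            graph.nodes[n]["family"] = fam
    for n in graph.nodes:
        graph.nodes[n].setdefault("family", "")
    return MolecularNetwork(graph, families)


def export_graphml(network: MolecularNetwork, path) -> None:
    """Write the network as GraphML (Cytoscape-compatible)."""
    out = network.graph.copy()
    for n in out.nodes:
        out.nodes[n].setdefault("annotation", "")
    nx.write_graphml(out, path)
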