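"""Modified cosine, precursor merging and network assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import networkx as nx

from halonet.networking import (
    NetworkParams,
    build_network,
    export_graphml,
    merge_precursors,
    modified_cosine,
)
from halonet.spectra import Spectrum, SpectrumSet

from conftest import random_spectrum


def brute_force_modified_cosine(a, b, frag_tol=0.02):
    """Oracle: best score over ALL one-to-one candidate matchings.

    Candidate pairs are found by a plain double loop (direct or
    precursor-shifted); the optimum is an explicit recursion over
    include/exclude decisions — independent of both the greedy and the
    assignment-solver paths.
    """
    va = np.sqrt(a.intensity)
    va /= np.linalg.norm(va)
    vb = np.sqrt(b.intensity)
    vb /= np.linalg.norm(vb)
    shift = b.precursor_mz - a.precursor_mz
    pairs = []
    for i, j in itertools.product(range(len(a)), range(len(b))):
        d = b.mz[j] - a.mz[i]
        if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
            pairs.append((i, j, va[i] * vb[j]))

    best = [0.0, 0]

    def go(k, used_a, used_b, score, count):
        if score > best[0] + 1e-15:
            best[0], best[1] = score, count
        if k == len(pairs):
            return
        i, j, w = pairs[k]
        if i not in used_a and j not in used_b:
            go(k + 1, used_a | {i}, used_b | {j}, score + w, count + 1)
        go(k + 1, used_a, used_b, score, count)

    go(0, frozenset(), frozenset(), 0.0, 0)
    return best[0]


def test_self_similarity_is_one(rng):
    s = random_spectrum(rng, 10, 450.0)
    res = modified_cosine(s, s)
    assert res.score == pytest.approx(1.0, abs=1e-9)
    assert res.matches == len(s)


def test_disjoint_spectra_score_zero():
    a = Spectrum("a", 400.0, 1.0, np.array([100.0, 150.0]), np.array([1.0, 1.0]))
    b = Spectrum("b", 400.0, 1.0, np.array([200.0, 250.0]), np.array([1.0, 1.0]))
    res = modified_cosine(a, b)
    assert res.score == 0.0 and res.matches == 0


def test_empty_spectrum_scores_zero():
    a = Spectrum("a", 400.0, 1.0, np.array([]), np.array([]))
    b = Spectrum("b", 400.0, 1.0, np.array([100.0]), np.array([1.0]))
    assert modified_cosine(a, b).score == 0.0


def test_exact_matching_equals_brute_force_small(rng):
    for _ in range(40):
        a = random_spectrum(rng, int(rng.integers(2, 8)), 450.0, "a")
        b = random_spectrum(rng, int(rng.integers(2, 8)), 462.0, "b")
        res = modified_cosine(a, b, exact=True)
        assert res.score == pytest.approx(
            brute_force_modified_cosine(a, b), abs=1e-9
        )


def test_greedy_never_beats_exact(rng):
    for _ in range(30):
        a = random_spectrum(rng, 8, 450.0, "a")
        b = random_spectrum(rng, 8, 465.0, "b")
        greedy = modified_cosine(a, b).score
        exact = modified_cosine(a, b, exact=True).score
        assert greedy <= exact + 1e-12


@given(st.integers(0, 2**31 - 1))
def test_symmetry(seed):
    rng = np.random.default_rng(seed)
    a = random_spectrum(rng, 6, 450.0, "a")
    b = random_spectrum(rng, 7, 470.0, "b")
    assert modified_cosine(a, b).score == pytest.approx(
        modified_cosine(b, a).score, abs=1e-12
    )


def test_score_bounds_and_match_count(rng):
    a = random_spectrum(rng, 9, 450.0, "a")
    b = random_spectrum(rng, 5, 455.0, "b")
    res = modified_cosine(a, b)
    assert 0.0 <= res.score <= 1.0
    assert res.matches <= min(len(a), len(b))


def test_matchms_cross_check(rng):
    """Independent implementation agreement on random spectra."""
    matchms = pytest.importorskip("matchms")
    from matchms import Spectrum as MSpec
    from matchms.similarity import ModifiedCosine

    sim = ModifiedCosine(tolerance=0.02)
    for _ in range(20):
        a = random_spectrum(rng, int(rng.integers(3, 10)), 450.0, "a")
        b = random_spectrum(rng, int(rng.integers(3, 10)), 468.0, "b")
        # feed sqrt intensities so both sides apply the same transform
        ma = MSpec(mz=a.mz, intensities=np.sqrt(a.intensity),
                   metadata={"precursor_mz": a.precursor_mz},
                   metadata_harmonization=False)
        mb = MSpec(mz=b.mz, intensities=np.sqrt(b.intensity),
                   metadata={"precursor_mz": b.precursor_mz},
                   metadata_harmonization=False)
        ref = sim.pair(ma, mb)
        mine = modified_cosine(a, b, 0.02)
        assert mine.score == pytest.approx(float(ref["score"]), abs=1e-9)
        assert mine.matches == int(ref["matches"])


def test_merge_precursors_below_tolerance():
    peaks = (np.array([150.0, 200.0]), np.array([100.0, 100.0]))
    a = Spectrum("a", 319.2274, 5.0, *peaks, extract="CC1")
    b = Spectrum("b", 319.2281, 5.1, *peaks, extract="DM1")
    c = Spectrum("c", 321.2441, 5.0, *peaks, extract="CC1")
    merged = merge_precursors(SpectrumSet([a, b, c]), 0.002)
    assert len(merged) == 2
    consensus = merged.spectra[0]
    assert consensus.extract == "CC1+DM1"
    assert 319.2274 <= consensus.precursor_mz <= 319.2281


def test_merge_precursors_empty_set():
    assert len(merge_precursors(SpectrumSet([]), 0.002)) == 0


def test_merge_identical_clique_collapses():
    peaks = (np.array([150.0, 200.0, 250.0]), np.array([10.0, 20.0, 30.0]))
    spectra = [Spectrum(f"s{k}", 400.0001 * 1.0, 5.0, *peaks) for k in range(5)]
    merged = merge_precursors(SpectrumSet(spectra), 0.002)
    assert len(merged) == 1


def test_threshold_monotonicity(rng):
    from halonet.synthetic import NoiseModel, generate_extracts
    from halonet.spectra import filter_peaks

    sset, _ = generate_extracts(3, 4, 2, NoiseModel(seed=3), seed=3)
    merged = merge_precursors(
        SpectrumSet([s for s in (filter_peaks(x, 50) for x in sset)]), 0.002
    )
    edge_counts = []
    for thr in (0.3, 0.5, 0.7, 0.9):
        net = build_network(merged, NetworkParams(score_threshold=thr))
        edge_counts.append(net.graph.number_of_edges())
    assert edge_counts == sorted(edge_counts, reverse=True)


def test_no_passing_edges_gives_all_individual(rng):
    spectra = []
    for k in range(4):
        spectra.append(random_spectrum(rng, 6, 300.0 + 40 * k, f"s{k}"))
    net = build_network(SpectrumSet(spectra), NetworkParams(score_threshold=0.99))
    assert net.families == {}
    assert sorted(net.individual_nodes) == [f"s{k}" for k in range(4)]


def test_family_labels_by_descending_size(tmp_path):
    from halonet.synthetic import NoiseModel, generate_extracts

    sset, _ = generate_extracts(2, 4, 1, NoiseModel(seed=1), seed=1)
    spectra = list(sset)
    # drop one member of family 1 so sizes differ (4 vs 3)
    spectra = [s for s in spectra if s.id != "syn_f1_m3"]
    net = build_network(SpectrumSet(spectra))
    sizes = [len(m) for m in net.families.values()]
    assert list(net.families) == [f"F{k}" for k in range(1, len(sizes) + 1)]
    assert sizes == sorted(sizes, reverse=True)


def test_max_component_pruning():
    from halonet.synthetic import NoiseModel, generate_extracts

    sset, _ = generate_extracts(1, 6, 1, NoiseModel(seed=2), seed=2)
    net = build_network(SpectrumSet(list(sset)), NetworkParams(max_component=3))
    assert all(
        len(c) <= 3 for c in nx.connected_components(net.graph)
    )


def test_graphml_round_trip(tmp_path):
    a = Spectrum("a", 400.0, 5.0, np.array([150.0, 200.0, 250.0, 300.0]),
                 np.array([10.0, 20.0, 30.0, 15.0]))
    b = Spectrum("b", 418.0, 5.2, np.array([150.0, 200.0, 250.0, 318.0]),
                 np.array([10.0, 20.0, 30.0, 15.0]))
    net = build_network(SpectrumSet([a, b]), NetworkParams(min_matched=3))
    path = tmp_path / "net.graphml"
    export_graphml(net, path)
    back = nx.read_graphml(path)
    assert set(back.nodes) == {"a", "b"}
    for n in back.nodes:
        assert back.nodes[n]["mz"] == net.graph.nodes[n]["mz"]
        assert back.nodes[n]["family"] == net.graph.nodes[n]["family"]
    for u, v in net.graph.edges:
        assert back.edges[u, v]["score"] == net.graph.edges[u, v]["score"]


def test_graphml_empty_network(tmp_path):
    net = build_network(SpectrumSet([]))
    path = tmp_path / "empty.graphml"
    export_graphml(net, path)
    assert nx.read_graphml(path).number_of_nodes() == 0
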