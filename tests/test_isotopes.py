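"""Isotopologue patterns, integer ratios and halogen classification."""

import itertools
import math

import numpy as np
import pytest

from halonet.elements import DEFAULT_TABLE
from halonet.formula import MolecularFormula, parse_formula
from halonet.isotopes import (
    IsotopePattern,
    classify_halogens,
    find_isotopologue_partners,
    halogen_pattern,
    integer_ratio,
    isotope_pattern,
)


def pattern_by_enumeration(formula, prune_below=0.0):
    """Independent oracle: exhaustive multinomial enumeration.

    For every element, enumerate all isotope count splits with the
    closed-form multinomial probability, take the cross product over
    elements, then bin within 0.3 Da and base-normalize — no
    convolution involved.
    """
    per_element = []
    for symbol, n in formula.items():
        isotopes = DEFAULT_TABLE[symbol]
        terms = []
        for split in itertools.product(range(n + 1), repeat=len(isotopes)):
            if sum(split) != n:
                continue
            coeff = math.factorial(n)
            prob = 1.0
            mass = 0.0
            for k, iso in zip(split, isotopes):
                coeff //= math.factorial(k)
                prob *= iso.abundance**k
                mass += k * iso.mass
            terms.append((mass, coeff * prob))
        per_element.append(terms)
    lines = {}
    for combo in itertools.product(*per_element):
        mass = sum(m for m, _ in combo)
        prob = math.prod(p for _, p in combo)
        key = round(mass, 9)
        lines[key] = lines.get(key, 0.0) + prob
    # bin within 0.3 Da (intensity-weighted mean m/z)
    binned = []
    for mass, p in sorted(lines.items()):
        if binned and mass - binned[-1][0] / binned[-1][1] < 0.3:
            binned[-1][0] += mass * p
            binned[-1][1] += p
        else:
            binned.append([mass * p, p])
    binned = [(mp / p, p) for mp, p in binned]
    base = max(p for _, p in binned)
    kept = [(m, p / base) for m, p in binned if p >= prune_below * base]
    return kept


@pytest.mark.parametrize(
    "formula", ["CH4", "Cl2", "Br2", "C2H5BrO", "C3BrCl", "SO2", "C5H5NOS"]
)
def test_pattern_matches_exhaustive_enumeration(formula):
    f = parse_formula(formula)
    assert f.atom_count() <= 30
    # identical relative prune on both routes so vanishing (<1e-7 of
    # base) lines do not enter the comparison
    expected = pattern_by_enumeration(f, prune_below=1e-7)
    got = isotope_pattern(f, prune_below=1e-7)
    assert len(got) == len(expected)
    for (em, ei), gm, gi in zip(expected, got.mz, got.intensity):
        # weighted bin m/z to 1e-6 Da; relative intensities to 1e-9
        assert gm == pytest.approx(em, abs=1e-6)
        assert gi == pytest.approx(ei, abs=1e-9)


def test_probability_conservation_before_normalization():
    from halonet.isotopes import _n_atom_distribution

    for symbol in ("C", "Br", "Cl", "O"):
        dist = _n_atom_distribution(DEFAULT_TABLE[symbol], 8, prune=0.0)
        assert sum(p for _, p in dist) == pytest.approx(1.0, abs=1e-9)


def test_ch4_carbon13_satellite():
    p = isotope_pattern(parse_formula("CH4"), prune_below=0.001)
    assert len(p) == 2
    # one 13C among one carbon: ratio ~ 0.0107/0.9893 plus 4 H contributions
    assert p.intensity[1] == pytest.approx(0.0113, abs=5e-4)


def test_chlorine_two_line_pattern():
    p = halogen_pattern(0, 1)
    assert len(p) == 2
    assert p.intensity[1] == pytest.approx(0.2424 / 0.7576, abs=1e-6)
    assert integer_ratio(p) == [3, 1]


@pytest.mark.parametrize(
    "n_br,n_cl,expected",
    [(2, 0, [1, 2, 1]), (2, 1, [3, 7, 5, 1]), (1, 0, [1, 1]), (0, 0, [1])],
)
def test_halogen_integer_ratios(n_br, n_cl, expected):
    assert integer_ratio(halogen_pattern(n_br, n_cl)) == expected


def test_integer_ratio_single_peak():
    assert integer_ratio(IsotopePattern((100.0,), (0.7,))) == [1]


def test_classify_recovers_generator_over_full_grid():
    """Self-consistency: noise-free theoretical patterns classify back."""
    for n_br in range(5):
        for n_cl in range(4):
            top = classify_halogens(halogen_pattern(n_br, n_cl))[0]
            assert (top.n_br, top.n_cl) == (n_br, n_cl)


@pytest.mark.parametrize("n_c", [5, 15, 25])
def test_classification_robust_to_carbon_isotopes(n_c):
    """13C satellites on a Br2Cl compound do not change the top call."""
    ion = MolecularFormula({"C": n_c, "H": 2 * n_c, "Br": 2, "Cl": 1, "O": 1})
    cluster = isotope_pattern(ion, prune_below=0.01)
    top = classify_halogens(cluster)[0]
    assert (top.n_br, top.n_cl) == (2, 1)


def test_classify_observed_clusters_from_printed_ratios():
    obs = IsotopePattern((424.9951, 426.9961, 428.9933), (1, 2, 1))
    assert (classify_halogens(obs)[0].n_br, classify_halogens(obs)[0].n_cl) == (2, 0)
    obs = IsotopePattern((412.9883, 414.9859, 416.9840, 418.9828), (3, 7, 5, 1))
    top = classify_halogens(obs)[0]
    assert (top.n_br, top.n_cl) == (2, 1)
    single = IsotopePattern((319.2274,), (1.0,))
    top = classify_halogens(single)[0]
    assert (top.n_br, top.n_cl) == (0, 0)


def test_partner_grouping_on_coeluting_satellites():
    nodes = [
        (269.2265, 100.0, 11.84),
        (270.2309, 22.0, 11.84),  # 13C satellite
        (271.2439, 80.0, 13.09),
        (272.2452, 18.0, 13.09),  # 13C satellite
        (319.2274, 50.0, 8.96),
        (361.2383, 40.0, 10.48),  # +42 Da: not isotopic
    ]
    groups = find_isotopologue_partners(nodes)
    as_mz = [[nodes[i][0] for i in g] for g in groups]
    assert [269.2265, 270.2309] in as_mz
    assert [271.2439, 272.2452] in as_mz
    assert [319.2274] in as_mz and [361.2383] in as_mz


def test_partner_grouping_respects_retention_time():
    nodes = [(400.0, 1.0, 5.0), (401.00336, 1.0, 9.0)]  # right Δm/z, wrong RT
    assert find_isotopologue_partners(nodes) == [[0], [1]]


def test_bromine_spacing_groups():
    nodes = [(390.9898, 10.0, 4.96), (392.9894, 20.0, 4.96), (394.9876, 9.0, 4.96)]
    groups = find_isotopologue_partners(nodes)
    assert groups == [[0, 1, 2]]
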