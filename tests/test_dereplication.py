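"""Neutral-loss chains, node annotation and report rendering."""

import numpy as np
import pytest

from halonet.dereplication import (
    AnnotationConfig,
    annotate_losses,
    annotate_node,
    cluster_from_spectrum,
    find_acetylation_pairs,
    load_compounds,
    load_neutral_losses,
    report,
)
from halonet.formula import KNOWN_ADDUCTS, monoisotopic_mass, parse_formula
from halonet.isotopes import isotope_pattern
from halonet.networking import build_network
from halonet.spectra import Spectrum, SpectrumSet
from halonet.synthetic import ZERO_NOISE, scaffold_for_compound, spectrum_from_scaffold


def test_loss_table_masses_agree_with_formulas(neutral_losses):
    for loss in neutral_losses:
        assert loss.mass == pytest.approx(
            monoisotopic_mass(loss.formula), abs=1e-4
        )
    by_name = {l.name: l for l in neutral_losses}
    # nominal-mass sanity of the classic losses
    assert by_name["H2O"].mass == pytest.approx(18.0106, abs=1e-4)
    assert by_name["HBr"].mass == pytest.approx(79.9262, abs=1e-4)
    assert by_name["HCl"].mass == pytest.approx(35.9767, abs=1e-4)
    assert by_name["NaOH"].mass == pytest.approx(39.9925, abs=1e-4)
    assert by_name["ketene"].mass == pytest.approx(42.0106, abs=1e-4)
    assert by_name["Br"].mass == pytest.approx(78.9183, abs=1e-4)


def test_compound_table_well_formed(compounds):
    assert [r.number for r in compounds] == list(range(1, 28))
    assert all(r.formula.atom_count() > 0 for r in compounds)


def test_double_water_loss_chain_confirmed():
    """Protonated diterpene with observed fragments at both water losses."""
    s = Spectrum(
        "f1", 319.2273, 8.96,
        np.array([283.2065, 301.2172]), np.array([500.0, 800.0]),
    )
    chain = annotate_losses(s, parse_formula("C20H30O3"), KNOWN_ADDUCTS["[M+H]+"])
    assert chain.names() == ["H2O", "H2O"]
    assert all(abs(step.error) <= 0.02 for step in chain.steps)


def test_sodiated_precursor_naoh_loss():
    s = Spectrum(
        "f1na", 385.2359, 7.3, np.array([345.2441]), np.array([900.0])
    )
    chain = annotate_losses(s, parse_formula("C22H34O4"), KNOWN_ADDUCTS["[M+Na]+"])
    assert chain.names() == ["NaOH"]


def test_naoh_not_considered_for_protonated_ion():
    # a peak 39.99 below the precursor must NOT be read as NaOH without Na
    s = Spectrum("p", 385.2359, 7.3, np.array([345.2434]), np.array([900.0]))
    chain = annotate_losses(s, parse_formula("C23H28O5"), KNOWN_ADDUCTS["[M+H]+"])
    assert "NaOH" not in chain.names()


def test_peaks_above_precursor_give_empty_chain():
    s = Spectrum("x", 300.0, 1.0, np.array([310.0, 350.0]), np.array([1.0, 1.0]))
    chain = annotate_losses(s, parse_formula("C20H28O2"), KNOWN_ADDUCTS["[M+H]+"])
    assert len(chain) == 0


def test_chain_expected_mz_strictly_decreasing():
    rec = {r.number: r for r in load_compounds()}[10]
    s, _ = spectrum_from_scaffold(scaffold_for_compound(rec), ZERO_NOISE)
    chain = annotate_losses(s, rec.formula, KNOWN_ADDUCTS["[M+H]+"])
    expected = [step.expected_mz for step in chain.steps]
    assert expected == sorted(expected, reverse=True)
    assert len(expected) == len(set(expected))


def test_annotation_self_recovery_all_reference_compounds(compounds):
    """Noise-free synthetic spectra recover their generating compound."""
    for rec in compounds:
        s, _ = spectrum_from_scaffold(
            scaffold_for_compound(rec), ZERO_NOISE, spectrum_id=f"c{rec.number}"
        )
        cluster = isotope_pattern(
            rec.formula + KNOWN_ADDUCTS[rec.adduct].added, prune_below=0.01
        )
        ann = annotate_node(s, cluster, compounds)
        assert rec.number in [r.number for r in ann.matches], rec.name


def test_annotation_tiers_monotone_under_peak_removal(compounds):
    """Dropping fragment peaks can lower the tier but never raise it."""
    rec = {r.number: r for r in compounds}[10]
    s, _ = spectrum_from_scaffold(scaffold_for_compound(rec), ZERO_NOISE)
    full = annotate_node(s, None, compounds)
    assert full.tier == "A"
    # remove everything below the precursor cluster: no chain evidence
    keep = s.mz >= s.precursor_mz - 0.5
    stripped = Spectrum("s", s.precursor_mz, s.rt, s.mz[keep], s.intensity[keep])
    partial = annotate_node(stripped, None, compounds)
    assert partial.tier == "B"
    assert partial.top_formula == full.top_formula


def test_annotation_without_cluster_caps_at_tier_c(compounds):
    rec = {r.number: r for r in compounds}[10]
    s, _ = spectrum_from_scaffold(scaffold_for_compound(rec), ZERO_NOISE)
    # drop the precursor cluster entirely: formula search unconstrained
    keep = s.mz < s.precursor_mz - 0.5
    bare = Spectrum("s", s.precursor_mz, s.rt, s.mz[keep], s.intensity[keep])
    ann = annotate_node(bare, None, compounds)
    assert ann.tier in ("", "C")


def test_node_with_no_evidence_annotates_empty():
    s = Spectrum("junk", 1200.003, 3.0, np.array([157.3, 311.9]), np.array([5.0, 7.0]))
    ann = annotate_node(
        s, None, [], AnnotationConfig(bounds={"C": (0, 10), "H": (0, 20), "N": (0, 0), "O": (0, 2)})
    )
    assert ann.matches == [] and ann.tier in ("", "C")


def test_cluster_extraction_from_wide_isolation_spectrum(compounds):
    rec = {r.number: r for r in compounds}[18]
    s, _ = spectrum_from_scaffold(scaffold_for_compound(rec), ZERO_NOISE)
    cluster = cluster_from_spectrum(s)
    assert cluster is not None
    assert cluster.mz[0] == pytest.approx(s.precursor_mz, abs=0.02)
    assert len(cluster) >= 3  # Br2: A, A+2, A+4


def test_acetylation_pairs_flagged():
    pairs = find_acetylation_pairs(
        {"n319": 319.2274, "n361": 361.2383, "n412": 412.9883}
    )
    assert pairs == [("n319", "n361")]


def test_report_tables_empty_network():
    net = build_network(SpectrumSet([]))
    node_df, fam_df = report(net, {})
    assert len(node_df) == 0 and len(fam_df) == 0
    assert "compounds" in node_df.columns and "n_nodes" in fam_df.columns


def test_report_three_family_run(compounds):
    from halonet.synthetic import NoiseModel, generate_extracts

    sset, _ = generate_extracts(3, 4, 2, NoiseModel(seed=11), seed=11)
    net = build_network(sset)
    annotations = {
        s.id: annotate_node(s, None, compounds) for s in sset
    }
    node_df, fam_df = report(net, annotations)
    assert len(fam_df) == 3
    assert len(node_df) == 12
    # matched compound numbers render ";"-joined
    joined = node_df.loc[node_df["compounds"] != "", "compounds"]
    assert any(";" in v for v in joined)
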