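"""Assign an elemental composition to an accurate mass.

A dibromo-chloro sesquiterpene of Laurencia gives a protonated ion at
m/z 412.9882.  With the halogen count fixed from its isotope pattern
(two Br, one Cl), a bounded search over C/H/O counts at 5 ppm recovers
the composition.
"""

from halonet import KNOWN_ADDUCTS, adduct_mz, formula_search, parse_formula

proton = KNOWN_ADDUCTS["[M+H]+"]

# forward direction: calcd m/z of a known composition
for text, adduct_name in [("C20H30O3", "[M+H]+"), ("C22H34O4", "[M+Na]+")]:
    mz = adduct_mz(parse_formula(text), KNOWN_ADDUCTS[adduct_name])
    print(f"calcd {adduct_name} of {text}: m/z {mz:.4f}")

# inverse direction: composition from an observed accurate mass
hits = formula_search(
    412.9882,
    proton,
    tol_ppm=5.0,
    bounds={"C": (0, 30), "H": (0, 60), "O": (0, 12), "Br": (2, 2), "Cl": (1, 1)},
)
print(f"\ncandidates for m/z 412.9882 ([M+H]+, 5 ppm, Br2Cl fixed):")
for cand in hits:
    print(
        f"  {cand.formula.hill():16s} {cand.ppm_error:+.2f} ppm  RDBE {cand.rdbe:.1f}"
    )
# The top (here: only) candidate is the published halogenated
# sesquiterpene composition; RDBE 3 fits a bicyclic chamigrane with one
# double bond.
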