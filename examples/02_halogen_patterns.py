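"""Read halogen counts from isotopologue clusters.

Br and Cl have heavy isotopes ~2 Da up at comparable abundance, so a
halogenated ion shows an A/A+2/A+4... cluster whose intensity ratio
encodes the halogen count: Br2 reads 1:2:1, Br2Cl reads 3:7:5:1.
"""

from halonet import (
    IsotopePattern,
    classify_halogens,
    halogen_pattern,
    integer_ratio,
    isotope_pattern,
    parse_formula,
)

for n_br, n_cl in [(1, 0), (2, 0), (2, 1), (0, 1)]:
    ratio = integer_ratio(halogen_pattern(n_br, n_cl))
    print(f"Br{n_br}Cl{n_cl}: {' : '.join(map(str, ratio))}")

# classify an observed cluster (values as printed from a QTof spectrum
# of a dibrominated C15-acetogenin)
observed = IsotopePattern((424.9951, 426.9961, 428.9933), (1.0, 2.0, 1.0))
top = classify_halogens(observed)[0]
print(f"\nobserved 1:2:1 cluster -> Br{top.n_br}Cl{top.n_cl} (score {top.score:.4f})")

# carbon isotopes do not confuse the call: the full theoretical cluster
# of protonated C15H23Br2ClO includes 13C satellites at odd offsets
full = isotope_pattern(parse_formula("C15H24Br2ClO"), prune_below=0.01)
top = classify_halogens(full)[0]
print(f"full C15H23Br2ClO [M+H]+ cluster -> Br{top.n_br}Cl{top.n_cl} (score {top.score:.4f})")
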