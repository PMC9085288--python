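"""Annotate a halogenated node end to end.

A noise-free synthetic spectrum of a dibromo-chloro chamigrane is read
the way the dereplication pipeline reads a real node: halogen count
from the isotope cluster, composition from the accurate mass under that
constraint, neutral-loss chain from the fragments, and candidate
structures from the reference table.
"""

from halonet import ZERO_NOISE, annotate_node, load_compounds
from halonet.synthetic import scaffold_for_compound, spectrum_from_scaffold

compounds = load_compounds()
record = next(r for r in compounds if r.number == 10)
spectrum, truth = spectrum_from_scaffold(
    scaffold_for_compound(record), ZERO_NOISE, spectrum_id="demo"
)
print(f"simulated {record.name}: precursor m/z {spectrum.precursor_mz:.4f}, "
      f"{len(spectrum)} peaks")

result = annotate_node(spectrum, reference=compounds)
print(f"halogen call : Br{result.halogens.n_br}Cl{result.halogens.n_cl} "
      f"(score {result.halogens.score:.4f})")
print(f"composition  : {result.top_formula.hill()} "
      f"({result.candidates[0].ppm_error:+.2f} ppm)")
print(f"loss chain   : {result.chain.describe()}")
print(f"tier         : {result.tier}")
print("candidates   :")
for rec in result.matches:
    print(f"  ({rec.number}) {rec.name} [{rec.compound_class}]")
# Tier A = composition, isotope pattern and loss chain all agree.  Three
# reference compounds share this composition — MS cannot rank isomers,
# so all are reported.
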