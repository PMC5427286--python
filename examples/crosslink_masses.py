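"""Peptide and cross-link mass arithmetic with 14N/15N labelling.

Digests the Hsp21-like demo sequence with trypsin rules, computes the
monoisotopic [M+H]+ of the ACD reporter peptide in both label states,
and predicts the four-peak isotope signature that distinguishes an
intrasubunit from an intersubunit (hybrid) BS3 cross-link.
"""

import numpy as np

from oligoxl import synthetic, xlms

sequence = synthetic.hsp21_synthetic_sequence()
peptides = xlms.digest(sequence, max_missed=2)
print(f"tryptic peptides (<=2 missed cleavages): {len(peptides)}")

reporter = "APWDIKEEEHEIK"
light = xlms.peptide_mz(reporter)
heavy = xlms.peptide_mz(xlms.Peptide(reporter, label="15N"))
print(f"{reporter}: [M+H]+ = {light:.1f} (14N), {heavy:.1f} (15N), "
      f"{xlms.nitrogen_count(reporter)} nitrogens")
# The 18.0 Da spacing is the isotope-dilution mass shift used to
# quantify limited proteolysis of this peptide.

species = xlms.CrossLinkSpecies(
    xlms.Peptide("ISVEDNVLVIKGEQK", (111, 125)),
    xlms.Peptide("KEDSDDSWSGR", (126, 136)), 121, 126, "BS3_internal")
quartet = xlms.predict_quartet(species)
print("cross-link K121-K126 label-state [M+H]+ quartet:")
for name, mz in zip(("14N-14N", "mixed", "mixed", "15N-15N"),
                    quartet.mz(1)):
    print(f"  {name:8s} {mz:.3f}")

# an MS1 peak list with all four peaks carries the hybrid signature --
# the evidence that the two peptides can come from different subunits
peaks = xlms.PeakList(np.array(quartet.mz(1)), np.full(4, 1e4))
print("signature:", xlms.classify_hybrid(peaks, quartet))
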