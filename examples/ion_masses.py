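"""Exact-mass arithmetic for glycosylated natural products.

Computes the diagnostic glycan oxocarbenium ions, the aglycone ions of the
glycosylated polyacetylenes, and classifies a precursor mass difference
against the modification-delta table.
"""

from glyconet import chem_masses as cm

print("Glycan B-type (oxocarbenium) ions, [sugar chain + H]+ :")
for name, chain in [
    ("HexNAc", [cm.HEXNAC]),
    ("hexose", [cm.HEXOSE]),
    ("pentose", [cm.PENTOSE]),
    ("HexNAc-pentose-hexose (B1-C-D, C=pentose)", [cm.HEXNAC, cm.PENTOSE, cm.HEXOSE]),
]:
    mz = cm.glycan_oxocarbenium_mz(chain)
    print(f"  {name:45s} m/z {mz:9.4f}  (nominal {cm.nominal_mass(mz)})")

print("\nAglycone ions of the C30 glycosylated polyacetylenes:")
for formula in ("C30H45O+", "C30H47O2+"):
    mz = cm.monoisotopic_mass(cm.parse_formula(formula))
    print(f"  {formula:10s} m/z {mz:9.4f}  (printed as {cm.format_mz(mz)})")

print("\nClassifying an observed precursor mass difference of +27.995 Da:")
entry, direction = cm.classify_delta(27.995, tolerance=0.01)
print(f"  -> {'+' if direction > 0 else '-'}{entry.name} "
      f"(theoretical {entry.delta_mass:+.4f} Da)")
# The 27.99 Da step is a methoxylation combined with a dehydrogenation (net
# +CO), the tailing difference that separates the two pentaglycoside families.
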