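"""Substructure motifs, glycosylation levels and delta-mass edge labels.

Detects the declarative motifs on simulated spectra, classifies the
glycosylation level by walking residue neutral losses, and labels network
edges with characteristic modification deltas.
"""

from glyconet import motif_annotation as ma
from glyconet import spectral_networking as sn
from glyconet import synthetic_data as sd

library = sd.make_congener_library(1, seed=1)
profile = sd.noiseless_profile("demo", {c.congener_id: 1.0 for c in library})
motifs = ma.default_motifs()

print("congener                  level  motifs")
for c in library[:9]:
    s = sd.simulate_spectrum(c, profile, seed=0)
    level = ma.classify_glycosylation(s)
    found = sorted(ma.detect_motifs(s, motifs))
    print(f"  {c.congener_id:22s}  {level}     {', '.join(found) or '-'}")
# motif_505 (HexNAc ion, m/z 204.09) marks every sarasinoside-like spectrum;
# motif_451 only the type-1 (C=hexose) pentaglycosides, motif_668 the type-2.

net = sn.MolecularNetwork()
specs = {}
for c in library[:3]:
    s = sd.simulate_spectrum(c, profile, seed=0)
    net.add_node(c.congener_id, s)
    specs[c.congener_id] = s
ids = [c.congener_id for c in library[:3]]
for u, v in zip(ids, ids[1:]):
    net.add_edge(sn.SpectralEdge(u, v, 0.9, 8,
                                 specs[v].precursor_mz - specs[u].precursor_mz))
labels = ma.annotate_delta_edges(net)
print("\nedge delta labels (successive glycosylation levels differ by one residue,")
print("so these edges stay unlabeled; tailing modifications would label them):")
for pair, label in labels.items():
    print(f"  {pair}: {label}")
print(f"  ({len(net.edges) - len(labels)} edge(s) without a matching delta)")
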