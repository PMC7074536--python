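"""Classical molecular networking on simulated congener spectra.

Simulates MS2 scans for one sarasinoside-like family, filters and clusters
them into consensus spectra, and builds the molecular network under the
standard thresholds (cosine > 0.7, >= 5 matched peaks, mutual top-10).
"""

from glyconet import spectral_networking as sn
from glyconet import synthetic_data as sd

library = sd.make_congener_library(1, seed=1)
profile = sd.SampleProfile("demo", {c.congener_id: 1.0 for c in library})
spectra = [sd.simulate_spectrum(c, profile, seed=k) for k, c in enumerate(library)]

filtered = [sn.filter_peaks(s, 500.0) for s in spectra]
consensus = sn.cluster_spectra(filtered, precursor_tol=0.01)
print(f"{len(spectra)} scans -> {len(consensus)} consensus spectra "
      "(the 4 planted RT isomers share one precursor and collapse here)")

net = sn.build_network([(c.consensus_id, c.spectrum) for c in consensus])
print(f"network: {len(net.nodes)} nodes, {len(net.edges)} edges")
for e in sorted(net.edges, key=lambda e: -e.cosine)[:5]:
    print(f"  {e.node_a} -- {e.node_b}  cosine {e.cosine:.3f}  "
          f"matched {e.matched_peaks}  delta {e.precursor_delta:+.4f} Da")
# Edges connect congeners sharing glycosidic fragments; the signed precursor
# delta on each edge is what the modification-delta annotation interprets.
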