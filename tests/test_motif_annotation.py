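"""Motif detection, glycosylation classification, propagation, delta edges,
alkyl-ladder diagnostics and dereplication."""

import numpy as np
import pandas as pd
import pytest

from glyconet import chem_masses as cm
from glyconet import motif_annotation as ma
from glyconet import spectral_networking as sn
from glyconet import synthetic_data as sd
from tests.conftest import spectrum

MOTIFS = ma.default_motifs()


class TestDetectMotifs:
    def test_hexnac_ion_triggers_motif_505(self):
        s = spectrum({204.087: 10.0}, precursor_mz=1200.0)
        assert ma.detect_motifs(s, MOTIFS) == {"motif_505"}

    def test_b1cd_ion_adds_motif_668(self):
        s = spectrum({204.087: 10.0, 498.182: 5.0}, precursor_mz=1200.0)
        assert ma.detect_motifs(s, MOTIFS) == {"motif_505", "motif_668"}

    def test_empty_spectrum_has_no_motifs(self):
        s = sn.filter_peaks(spectrum({100.0: 1.0}), 10.0)
        assert ma.detect_motifs(s, MOTIFS) == set()

    def test_neutral_loss_motifs_match_precursor_differences(self):
        hexose = cm.HEXOSE.residue_mass
        motif = ma.Motif("hexose_loss", (), (hexose,), 0.01, "hexose loss")
        s = spectrum({600.0 - hexose: 5.0}, precursor_mz=600.0)
        assert ma.detect_motifs(s, [motif]) == {"hexose_loss"}
        s2 = spectrum({400.0: 5.0}, precursor_mz=600.0)
        assert ma.detect_motifs(s2, [motif]) == set()

    def test_monotone_under_peak_addition(self):
        rng = np.random.default_rng(2)
        base = {204.087: 10.0, 498.182: 5.0}
        before = ma.detect_motifs(spectrum(base, precursor_mz=1200.0), MOTIFS)
        extra = dict(base)
        for m in rng.uniform(100, 1100, 20):
            extra[float(m)] = float(rng.uniform(1, 50))
        after = ma.detect_motifs(spectrum(extra, precursor_mz=1200.0), MOTIFS)
        assert before <= after


class TestClassifyGlycosylation:
    def test_two_hexose_losses(self):
        # diglycoside walk: 763.46 -> 601.41 -> 439.35
        s = spectrum({601.410: 50.0, 439.357: 80.0, 421.346: 40.0},
                     precursor_mz=763.462)
        assert ma.classify_glycosylation(s) == 2

    def test_aglycone_only_is_zero(self):
        s = spectrum({421.35: 10.0, 439.36: 20.0}, precursor_mz=439.36)
        assert ma.classify_glycosylation(s) == 0

    def test_noiseless_pentaglycoside_round_trip(self, library):
        penta = [c for c in library if c.glyco_level == 5]
        assert penta
        prof = sd.noiseless_profile("s", {c.congener_id: 1.0 for c in penta})
        for c in penta:
            s = sd.simulate_spectrum(c, prof, seed=0)
            assert ma.classify_glycosylation(s) == 5

    def test_noiseless_recovery_all_levels(self, library, noiseless_profiles):
        prof = noiseless_profiles[0]
        for c in library:
            s = sd.simulate_spectrum(c, prof, seed=1)
            assert ma.classify_glycosylation(s) == c.glyco_level, c.congener_id


class TestPropagatePatterns:
    def _net_with(self, node_motifs):
        net = sn.MolecularNetwork()
        for node in node_motifs:
            net.add_node(node, spectrum({100.0: 1.0}, precursor_mz=500.0))
        return net

    def test_type1_node_gets_both_labels(self):
        net = self._net_with({"n1": {"motif_451", "motif_505"}})
        ann = ma.propagate_patterns(net, {"n1": {"motif_451", "motif_505"}})
        assert ann["n1"].pattern_labels == {"A-B2 HexNAc conserved", "type-1 (C=hexose)"}
        assert not ann["n1"].conflict

    def test_singleton_is_labeled_without_edges(self):
        net = self._net_with({"lone": {"motif_505"}})
        ann = ma.propagate_patterns(net, {"lone": {"motif_505"}})
        assert "A-B2 HexNAc conserved" in ann["lone"].pattern_labels

    def test_no_motifs_unlabeled(self):
        net = self._net_with({"n1": set()})
        ann = ma.propagate_patterns(net, {"n1": set()})
        assert ann["n1"].pattern_labels == set()

    def test_conflicting_family_motifs_flagged(self):
        net = self._net_with({"n1": {"motif_451", "motif_668"}})
        ann = ma.propagate_patterns(net, {"n1": {"motif_451", "motif_668"}})
        assert ann["n1"].conflict


class TestAnnotateDeltaEdges:
    def _network(self, mz_pairs):
        net = sn.MolecularNetwork()
        for i, mz in enumerate(mz_pairs):
            net.add_node(f"n{i}", spectrum({100.0: 1.0}, precursor_mz=mz))
        for i in range(len(mz_pairs) - 1):
            net.add_edge(
                sn.SpectralEdge(f"n{i}", f"n{i+1}", 0.9, 6,
                                mz_pairs[i + 1] - mz_pairs[i])
            )
        return net

    def test_co_and_hydroxylation_labels(self):
        net = self._network([1000.0, 1027.995, 1043.990])
        labels = ma.annotate_delta_edges(net)
        assert labels[("n0", "n1")] == "+methoxylation-dehydrogenation"
        assert labels[("n1", "n2")] == "+hydroxylation"

    def test_zero_delta_is_isomer_edge(self):
        net = self._network([1000.0, 1000.0])
        labels = ma.annotate_delta_edges(net)
        assert labels[("n0", "n1")] == "isomer"

    def test_unmatched_delta_left_unlabeled(self):
        net = self._network([1000.0, 1005.5])
        assert ma.annotate_delta_edges(net) == {}

    def test_labels_reproducible_from_precursors(self):
        net = self._network([1000.0, 1015.995, 1030.010])
        labels = ma.annotate_delta_edges(net)
        for (u, v), label in labels.items():
            delta = net.spectra[v].precursor_mz - net.spectra[u].precursor_mz
            if label == "isomer":
                assert abs(delta) <= 0.01
            else:
                hit = cm.classify_delta(delta, tolerance=0.01)
                assert hit is not None and label.endswith(hit[0].name)


class TestAlkylLadder:
    def test_constructed_ch2_chain_detected(self):
        s = spectrum({113.0: 5, 127.02: 5, 141.03: 5, 155.05: 5, 169.06: 5},
                     precursor_mz=600.0)
        assert ma.detect_alkyl_ladder(s)

    def test_three_random_peaks_rejected(self):
        s = spectrum({110.0: 5, 150.0: 5, 260.0: 5}, precursor_mz=600.0)
        assert not ma.detect_alkyl_ladder(s)

    def test_synthetic_polyacetylene_spectrum_positive(self, library):
        pa = [c for c in library if c.family == "polyacetylene-like"][0]
        prof = sd.noiseless_profile("s", {pa.congener_id: 1.0})
        s = sd.simulate_spectrum(pa, prof, seed=0)
        assert ma.detect_alkyl_ladder(s)

    def test_sarasinoside_spectrum_negative(self, library):
        c = [x for x in library if x.family == "sarasinoside-like"][0]
        prof = sd.noiseless_profile("s", {c.congener_id: 1.0})
        s = sd.simulate_spectrum(c, prof, seed=0)
        assert not ma.detect_alkyl_ladder(s)


class TestDereplicate:
    LIB = pd.DataFrame(
        {
            "id": ["cmpd1", "cmpd2", "cmpd3"],
            "mz": [563.0601, 700.5, 563.0601],
            "expected_motifs": ["motif_505", "", "motif_668"],
        }
    )

    def test_exact_hit(self):
        res = ma.dereplicate(563.0601, self.LIB, observed_motifs={"motif_505"})
        assert res.status == "hit" and res.entry_ids == ["cmpd1"]

    def test_unknown_when_nothing_in_tolerance(self):
        res = ma.dereplicate(650.0, self.LIB)
        assert res.status == "unknown" and str(res) == "unknown"

    def test_equidistant_entries_ambiguous(self):
        res = ma.dereplicate(563.0601, self.LIB, require_motifs=False)
        assert res.status == "ambiguous" and set(res.entry_ids) == {"cmpd1", "cmpd3"}

    def test_motif_requirement_disqualifies(self):
        res = ma.dereplicate(563.0601, self.LIB, observed_motifs={"motif_668"})
        assert res.entry_ids == ["cmpd3"]


def test_glyco_recovery_rate_with_default_noise():
    """>= 95% exact glycosylation-level recovery over ~200 noisy congeners."""
    library = sd.make_congener_library(28, seed=7)[:200]
    assert len(library) == 200
    prof = sd.SampleProfile("s", {c.congener_id: 1.0 for c in library})
    correct = 0
    for k, c in enumerate(library):
        s = sd.simulate_spectrum(c, prof, seed=1000 + k)
        if ma.classify_glycosylation(s) == c.glyco_level:
            correct += 1
    assert correct / len(library) >= 0.95


def test_motif_csv_round_trip(tmp_path):
    path = tmp_path / "motifs.csv"
    ma.save_motifs(MOTIFS, path)
    back = ma.load_motifs(path)
    assert [m.motif_id for m in back] == [m.motif_id for m in MOTIFS]
    orig = {m.motif_id: m for m in MOTIFS}
    for m in back:
        assert m.fragment_mzs == pytest.approx(orig[m.motif_id].fragment_mzs, abs=1e-6)
        assert m.literature == orig[m.motif_id].literature
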