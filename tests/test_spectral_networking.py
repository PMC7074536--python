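"""Consensus clustering, modified cosine (with brute-force oracle), topology."""

import itertools

import numpy as np
import pytest

from glyconet import spectral_networking as sn
from tests.conftest import spectrum


def brute_force_modified_cosine(a, b, frag_tol=0.05):
    """Independent oracle: exhaustive search over one-to-one peak matchings.

    Enumerates every injective assignment of a's peaks to b's peaks over
    candidate pairs (direct or precursor-shifted within tolerance) and
    returns the best achievable cosine of sqrt-scaled, L2-normalized vectors.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    sa, sb = np.sqrt(a.intensity), np.sqrt(b.intensity)
    norm = np.linalg.norm(sa) * np.linalg.norm(sb)
    shift = a.precursor_mz - b.precursor_mz
    candidates = []
    for i in range(len(a)):
        for j in range(len(b)):
            d = a.mz[i] - b.mz[j]
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                candidates.append((i, j))
    best_score, best_matched = 0.0, 0
    n = len(candidates)
    for r in range(0, n + 1):
        for combo in itertools.combinations(candidates, r):
            rows = [c[0] for c in combo]
            cols = [c[1] for c in combo]
            if len(set(rows)) < r or len(set(cols)) < r:
                continue
            score = sum(sa[i] * sb[j] for i, j in combo) / norm
            if score > best_score:
                best_score, best_matched = score, r
    return best_score, best_matched


class TestFilterPeaks:
    def test_threshold_removes_low_peaks(self):
        s = spectrum({100.0: 400.0, 200.0: 600.0})
        out = sn.filter_peaks(s, 500.0)
        assert out.mz.tolist() == [200.0]

    def test_zero_floor_is_identity(self):
        s = spectrum({100.0: 400.0, 200.0: 600.0})
        out = sn.filter_peaks(s, 0.0)
        assert np.array_equal(out.mz, s.mz)

    def test_all_below_floor_keeps_empty_spectrum(self):
        s = spectrum({100.0: 10.0})
        out = sn.filter_peaks(s, 500.0)
        assert len(out) == 0 and out.precursor_mz == s.precursor_mz


class TestClusterSpectra:
    def test_within_tolerance_merges(self):
        a = spectrum({100.0: 1.0}, precursor_mz=500.000, scan_id="a")
        b = spectrum({100.0: 1.0}, precursor_mz=500.005, scan_id="b")
        out = sn.cluster_spectra([a, b], 0.01)
        assert len(out) == 1 and set(out[0].member_ids) == {"a", "b"}

    def test_outside_tolerance_splits(self):
        a = spectrum({100.0: 1.0}, precursor_mz=500.000)
        b = spectrum({100.0: 1.0}, precursor_mz=500.020)
        assert len(sn.cluster_spectra([a, b], 0.01)) == 2

    def test_singleton_identity(self):
        a = spectrum({100.0: 1.0, 150.0: 2.0}, precursor_mz=500.0)
        out = sn.cluster_spectra([a], 0.01)
        assert len(out) == 1
        assert np.allclose(out[0].spectrum.mz, a.mz)
        assert np.allclose(out[0].spectrum.intensity, a.intensity)

    def test_scan_conservation(self):
        rng = np.random.default_rng(0)
        spectra = [
            spectrum({100.0: 1.0}, precursor_mz=float(rng.uniform(400, 401)),
                     scan_id=f"s{i}")
            for i in range(30)
        ]
        out = sn.cluster_spectra(spectra, 0.01)
        assert sum(len(c.member_ids) for c in out) == 30


class TestModifiedCosine:
    def test_self_similarity(self):
        s = spectrum({100.0: 3.0, 150.0: 1.0, 220.0: 5.0})
        score, matched = sn.modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 3

    def test_half_overlap(self):
        a = spectrum({100.0: 1.0, 200.0: 1.0}, precursor_mz=500.0)
        b = spectrum({100.0: 1.0, 250.0: 1.0}, precursor_mz=500.0)
        score, matched = sn.modified_cosine(a, b)
        assert score == pytest.approx(0.5, abs=1e-12)
        assert matched == 1

    def test_disjoint_is_zero(self):
        a = spectrum({100.0: 1.0}, precursor_mz=500.0)
        b = spectrum({300.0: 1.0}, precursor_mz=500.0)
        assert sn.modified_cosine(a, b) == (0.0, 0)

    def test_empty_spectrum_defined(self):
        a = spectrum({100.0: 1.0})
        empty = sn.filter_peaks(a, 10.0)
        assert sn.modified_cosine(a, empty) == (0.0, 0)

    def test_shifted_peaks_match(self):
        # fragment offset equal to the precursor delta counts as a match
        a = spectrum({100.0: 1.0, 210.0: 1.0}, precursor_mz=500.0)
        b = spectrum({110.0: 1.0, 220.0: 1.0}, precursor_mz=510.0)
        score, matched = sn.modified_cosine(a, b)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 2

    def test_symmetry_on_random_spectra(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = spectrum(
                {float(m): float(i) for m, i in zip(
                    rng.uniform(50, 500, 5), rng.uniform(1, 100, 5))},
                precursor_mz=float(rng.uniform(400, 600)),
            )
            b = spectrum(
                {float(m): float(i) for m, i in zip(
                    rng.uniform(50, 500, 5), rng.uniform(1, 100, 5))},
                precursor_mz=float(rng.uniform(400, 600)),
            )
            sab = sn.modified_cosine(a, b)
            sba = sn.modified_cosine(b, a)
            assert sab[0] == pytest.approx(sba[0], abs=1e-9)
            assert sab[1] == sba[1]

    def test_matches_brute_force_oracle(self):
        # peak matching equals exhaustive assignment search on small spectra
        # m/z drawn from a coarse grid so direct and shifted collisions are
        # frequent and the assignment problem is non-trivial
        rng = np.random.default_rng(42)
        grid = np.arange(50, 400, 25.0)
        for _ in range(200):
            na, nb = rng.integers(1, 7), rng.integers(1, 7)
            pa = float(rng.uniform(400, 500))
            pb = pa + float(rng.choice([0.0, 25.0, 50.0, 7.3]))
            a = spectrum(
                {float(m): float(i) for m, i in zip(
                    rng.choice(grid, na), rng.uniform(1, 100, na))},
                precursor_mz=pa,
            )
            b = spectrum(
                {float(m): float(i) for m, i in zip(
                    rng.choice(grid, nb), rng.uniform(1, 100, nb))},
                precursor_mz=pb,
            )
            got_score, _ = sn.modified_cosine(a, b, 0.05)
            exp_score, _ = brute_force_modified_cosine(a, b, 0.05)
            assert got_score == pytest.approx(exp_score, abs=1e-9)

    def test_agrees_with_matchms_on_unambiguous_spectra(self):
        # independent cross-check against a reference implementation, using
        # equal precursors and well-separated peaks so matching is unique
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(3)
        sim = ModifiedCosine(tolerance=0.05)
        for _ in range(20)            :
            mz_a = np.sort(rng.choice(np.arange(60, 600, 2.0), 8, replace=False))
            mz_b = np.sort(rng.choice(np.arange(60, 600, 2.0), 8, replace=False))
            ia, ib = rng.uniform(1, 100, 8), rng.uniform(1, 100, 8)
            a = spectrum(dict(zip(mz_a.tolist(), ia.tolist())), precursor_mz=650.0)
            b = spectrum(dict(zip(mz_b.tolist(), ib.tolist())), precursor_mz=650.0)
            # matchms scores raw intensities; pre-apply the sqrt scaling here
            ref = sim.pair(
                matchms.Spectrum(mz=mz_a, intensities=np.sqrt(ia),
                                 metadata={"precursor_mz": 650.0}),
                matchms.Spectrum(mz=mz_b, intensities=np.sqrt(ib),
                                 metadata={"precursor_mz": 650.0}),
            )
            got = sn.modified_cosine(a, b)
            assert got[0] == pytest.approx(float(ref["score"]), abs=1e-6)
            assert got[1] == int(ref["matches"])


class TestBuildNetwork:
    def _triangle_nodes(self):
        peaks = {float(m): 10.0 for m in (100, 120, 140, 160, 180, 200)}
        return [
            (f"n{i}", spectrum(peaks, precursor_mz=500.0 + i, scan_id=f"n{i}"))
            for i in range(3)
        ]

    def test_complete_triangle_when_k_large(self):
        net = sn.build_network(self._triangle_nodes())
        assert len(net.edges) == 3

    def test_cosine_threshold_is_strict(self):
        a = spectrum({100.0: 1.0, 200.0: 1.0, 300.0: 1.0, 400.0: 1.0}, 500.0)
        b = spectrum({100.0: 1.0, 200.0: 1.0, 310.0: 1.0, 410.0: 1.0}, 500.0)
        score, _ = sn.modified_cosine(a, b)
        assert score == pytest.approx(0.5)
        net = sn.build_network([("a", a), ("b", b)], min_cosine=0.5, min_matched=1)
        assert len(net.edges) == 0  # exactly at threshold -> excluded

    def test_matched_peak_threshold(self):
        peaks = {float(m): 10.0 for m in (100, 120, 140, 160)}
        a = spectrum(peaks, 500.0)
        b = spectrum(peaks, 500.0)
        net5 = sn.build_network([("a", a), ("b", b)], min_matched=5)
        net4 = sn.build_network([("a", a), ("b", b)], min_matched=4)
        assert len(net5.edges) == 0  # only 4 matched peaks
        assert len(net4.edges) == 1

    def test_mutual_top_k_idempotent(self):
        rng = np.random.default_rng(11)
        base = np.arange(100, 400, 20.0)
        nodes = []
        for i in range(12):
            keep = rng.random(len(base)) > 0.3
            peaks = {float(m): float(rng.uniform(5, 50)) for m in base[keep]}
            nodes.append((f"n{i}", spectrum(peaks, precursor_mz=500.0 + i,
                                            scan_id=f"n{i}")))
        precursor = {nid: s.precursor_mz for nid, s in nodes}
        candidates = {}
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                score, matched = sn.modified_cosine(nodes[i][1], nodes[j][1])
                if score > 0.5 and matched >= 3:
                    candidates[frozenset((nodes[i][0], nodes[j][0]))] = (score, matched)
        once = sn._mutual_top_k(candidates, precursor, top_k=3)
        twice = sn._mutual_top_k(
            {p: candidates[p] for p in once}, precursor, top_k=3
        )
        assert once == twice

    def test_no_self_edges(self):
        net = sn.build_network(self._triangle_nodes())
        for e in net.edges:
            assert e.node_a != e.node_b


def test_mgf_round_trip(tmp_path):
    s = spectrum({100.5: 10.0, 200.25: 20.0}, precursor_mz=512.125, rt=3.5,
                 scan_id="scan1")
    path = tmp_path / "t.mgf"
    sn.write_mgf([s], path)
    back = sn.read_mgf(path)
    assert len(back) == 1
    assert back[0].precursor_mz == pytest.approx(512.125)
    assert back[0].rt == pytest.approx(3.5)
    assert np.allclose(back[0].mz, s.mz)


def test_network_exports(tmp_path):
    peaks = {float(m): 10.0 for m in (100, 120, 140, 160, 180, 200)}
    nodes = [(f"n{i}", spectrum(peaks, precursor_mz=500.0 + i)) for i in range(3)]
    net = sn.build_network(nodes)
    sn.write_graphml(net, tmp_path / "net.graphml")
    sn.write_edge_list(net, tmp_path / "edges.tsv")
    sn.write_node_table(net, tmp_path / "nodes.tsv")
    import networkx as nx

    g = nx.read_graphml(tmp_path / "net.graphml")
    assert set(g.nodes) == {"n0", "n1", "n2"}
    assert len(g.edges) == 3
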