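"""Classical molecular networking over tandem-MS spectra.

Consensus clustering of MS2 scans by precursor mass, modified-cosine spectral
similarity with precursor-shifted peak matching, and network construction
under score / matched-peak / mutual-top-K topology rules.

Default thresholds follow common practice for sponge-metabolome networking:
precursor clustering at 0.01 Da, fragment matching at 0.05 Da, edges kept at
cosine strictly above 0.7 with at least 5 matched peaks, and an edge retained
only when each endpoint ranks the other within its top 10 most similar nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from scipy.optimize import linear_sum_assignment


@dataclass
class FragmentSpectrum:
    """One MS2 scan: precursor descriptors plus a centroided peak list."""

    scan_id: str
    precursor_mz: float
    rt: float = 0.0
    precursor_charge: int = 1
    sample_id: str = ""
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(~np.isfinite(self.mz)) or np.any(~np.isfinite(self.intensity)):
            raise ValueError("peaks must be finite")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be > 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class ConsensusSpectrum:
    """Merged representative of one or more scans with near-identical precursor."""

    consensus_id: str
    member_ids: list[str]
    spectrum: FragmentSpectrum

    @property
    def precursor_mz(self) -> float:
        return self.spectrum.precursor_mz


def filter_peaks(s: FragmentSpectrum, ms2_noise_floor: float) -> FragmentSpectrum:
    """Drop peaks with intensity below the MS2 noise floor (default workflow: 500)."""
    if ms2_noise_floor < 0:
        raise ValueError("noise floor must be >= 0")
    keep = s.intensity >= ms2_noise_floor
    out = replace(s)
    out.mz = s.mz[keep]
    out.intensity = s.intensity[keep]
    return out


def merge_peak_lists(
    spectra: Sequence[FragmentSpectrum], frag_tol: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Tolerance-binned union of peak lists.

    Peaks within ``frag_tol`` are merged to their intensity-weighted mean m/z
    with intensities summed.
    """
    mz = np.concatenate([s.mz for s in spectra]) if spectra else np.empty(0)
    inten = np.concatenate([s.intensity for s in spectra]) if spectra else np.empty(0)
    if len(mz) == 0:
        return mz, inten
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    out_mz: list[float] = []
    out_int: list[float] = []
    group_mz = [mz[0]]
    group_int = [inten[0]]
    for m, i in zip(mz[1:], inten[1:]):
        if m - group_mz[-1] <= frag_tol:
            group_mz.append(m)
            group_int.append(i)
        else:
            w = np.asarray(group_int)
            out_mz.append(float(np.average(group_mz, weights=w)))
            out_int.append(float(w.sum()))
            group_mz, group_int = [m], [i]
    w = np.asarray(group_int)
    out_mz.append(float(np.average(group_mz, weights=w)))
    out_int.append(float(w.sum()))
    return np.asarray(out_mz), np.asarray(out_int)


def cluster_spectra(
    spectra: Sequence[FragmentSpectrum],
    precursor_tol: float = 0.01,
    frag_tol: float = 0.05,
) -> list[ConsensusSpectrum]:
    """Single-linkage grouping of scans on precursor m/z within tolerance.

    Scans are processed in ascending precursor order; consecutive precursors
    within ``precursor_tol`` chain into one consensus. The merged peak list is
    the tolerance-binned intensity-weighted union; the representative
    precursor is the intensity-weighted (by total ion current) mean.
    """
    if precursor_tol <= 0:
        raise ValueError("precursor_tol must be > 0")
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.scan_id))
    groups: list[list[FragmentSpectrum]] = []
    for s in ordered:
        if groups and s.precursor_mz - groups[-1][-1].precursor_mz <= precursor_tol:
            groups[-1].append(s)
        else:
            groups.append([s])
    out = []
    for k, grp in enumerate(groups):
        weights = np.array([s.intensity.sum() if len(s) else 1.0 for s in grp])
        if weights.sum() == 0:
            weights = np.ones(len(grp))
        prec = float(np.average([s.precursor_mz for s in grp], weights=weights))
        mz, inten = merge_peak_lists(grp, frag_tol)
        rt = float(np.average([s.rt for s in grp], weights=weights))
        merged = FragmentSpectrum(
            scan_id=f"consensus_{k}",
            precursor_mz=prec,
            rt=rt,
            precursor_charge=grp[0].precursor_charge,
            mz=mz,
            intensity=inten,
        )
        out.append(ConsensusSpectrum(f"consensus_{k}", [s.scan_id for s in grp], merged))
    return out


def modified_cosine(
    a: FragmentSpectrum, b: FragmentSpectrum, frag_tol: float = 0.05
) -> tuple[float, int]:
    """Modified cosine similarity with precursor-delta shifted matching.

    Peaks may match directly (|dmz| <= tol) or shifted by the precursor mass
    difference (|dmz - (pA - pB)| <= tol). A one-to-one assignment maximizing
    the cosine of square-root-scaled, L2-normalized intensity vectors is found
    by maximum-weight bipartite matching. Returns (score, matched peak count).
    Empty spectra give (0.0, 0) by definition.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    sa = np.sqrt(a.intensity)
    sb = np.sqrt(b.intensity)
    norm = float(np.linalg.norm(sa) * np.linalg.norm(sb))
    if norm == 0:
        return 0.0, 0
    shift = a.precursor_mz - b.precursor_mz
    dmz = a.mz[:, None] - b.mz[None, :]
    candidate = (np.abs(dmz) <= frag_tol) | (np.abs(dmz - shift) <= frag_tol)
    if not candidate.any():
        return 0.0, 0
    weights = np.where(candidate, sa[:, None] * sb[None, :], 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    chosen = weights[rows, cols]
    matched = int(np.count_nonzero(chosen > 0))
    score = float(chosen.sum() / norm)
    return min(score, 1.0), matched


@dataclass
class SpectralEdge:
    node_a: str
    node_b: str
    cosine: float
    matched_peaks: int
    precursor_delta: float  # signed, mz(node_b) - mz(node_a)


class MolecularNetwork:
    """A molecular network: nodes with spectra, edges scored by modified cosine."""

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.spectra: dict[str, FragmentSpectrum] = {}

    def add_node(self, node_id: str, spectrum: FragmentSpectrum, **attrs) -> None:
        self.spectra[node_id] = spectrum
        self.graph.add_node(
            node_id, precursor_mz=spectrum.precursor_mz, rt=spectrum.rt, **attrs
        )

    def add_edge(self, edge: SpectralEdge) -> None:
        if edge.node_a == edge.node_b:
            raise ValueError("self-edges are forbidden")
        self.graph.add_edge(
            edge.node_a,
            edge.node_b,
            cosine=edge.cosine,
            matched_peaks=edge.matched_peaks,
            precursor_delta=edge.precursor_delta,
        )

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[SpectralEdge]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            out.append(
                SpectralEdge(u, v, d["cosine"], d["matched_peaks"], d["precursor_delta"])
            )
        return out


def _mutual_top_k(
    candidates: dict[frozenset, tuple[float, int]],
    precursor: dict[str, float],
    top_k: int,
) -> set[frozenset]:
    """Keep edges where both endpoints rank each other within top_k by cosine.

    Ranking ties are broken by lower precursor m/z of the partner, then by
    node id, making the result invariant to input order.
    """
    neighbors: dict[str, list[tuple[float, float, str]]] = {}
    for pair, (cos, _) in candidates.items():
        u, v = tuple(pair)
        neighbors.setdefault(u, []).append((-cos, precursor[v], v))
        neighbors.setdefault(v, []).append((-cos, precursor[u], u))
    top: dict[str, set[str]] = {}
    for node, lst in neighbors.items():
        lst.sort()
        top[node] = {partner for _, _, partner in lst[:top_k]}
    kept = set()
    for pair in candidates:
        u, v = tuple(pair)
        if v in top.get(u, set()) and u in top.get(v, set()):
            kept.add(pair)
    return kept


def build_network(
    nodes: Sequence[tuple[str, FragmentSpectrum]],
    min_cosine: float = 0.7,
    min_matched: int = 5,
    top_k: int = 10,
    frag_tol: float = 0.05,
) -> MolecularNetwork:
    """Score all node pairs and build the pruned molecular network.

    Candidate edges require cosine strictly above ``min_cosine`` and at least
    ``min_matched`` matched peaks; mutual-top-K pruning is then applied once
    over the candidate set.
    """
    net = MolecularNetwork()
    for node_id, spec in nodes:
        net.add_node(node_id, spec)
    precursor = {nid: s.precursor_mz for nid, s in nodes}
    candidates: dict[frozenset, tuple[float, int]] = {}
    node_list = list(nodes)
    for i in range(len(node_list)):
        for j in range(i + 1, len(node_list)):
            ida, sa = node_list[i]
            idb, sb = node_list[j]
            score, matched = modified_cosine(sa, sb, frag_tol)
            if score > min_cosine and matched >= min_matched:
                candidates[frozenset((ida, idb))] = (score, matched)
    kept = _mutual_top_k(candidates, precursor, top_k)
    for pair in kept:
        u, v = sorted(pair)
        score, matched = candidates[pair]
        net.add_edge(SpectralEdge(u, v, score, matched, precursor[v] - precursor[u]))
    return net


# ---------------------------------------------------------------------------
# IO


def read_mgf(path: str | Path) -> list[FragmentSpectrum]:
    """Read MS2 spectra from an MGF file."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 1
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            out.append(
                FragmentSpectrum(
                    scan_id=str(params.get("title", f"scan_{i}")),
                    precursor_mz=float(params["pepmass"][0]),
                    rt=rt,
                    precursor_charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return out


def write_mgf(spectra: Iterable[FragmentSpectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.scan_id,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.precursor_charge}+",
                    "rtinseconds": s.rt * 60.0,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def write_graphml(net: MolecularNetwork, path: str | Path) -> None:
    g = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(n, **{k: v for k, v in d.items() if np.isscalar(v) or isinstance(v, str)})
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, **{k: v2 for k, v2 in d.items() if np.isscalar(v2) or isinstance(v2, str)})
    nx.write_graphml(g, str(path))


def write_edge_list(net: MolecularNetwork, path: str | Path) -> None:
    rows = [
        {
            "node1": e.node_a,
            "node2": e.node_b,
            "cosine": e.cosine,
            "matched": e.matched_peaks,
            "delta_mz": e.precursor_delta,
        }
        for e in net.edges
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "cosine", "matched", "delta_mz"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_table(net: MolecularNetwork, path: str | Path) -> None:
    rows = []
    for n, d in net.graph.nodes(data=True):
        row = {"node": n}
        row.update({k: v for k, v in d.items() if np.isscalar(v) or isinstance(v, str)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
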