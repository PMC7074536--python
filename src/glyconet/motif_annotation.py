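"""Declarative substructure motifs, propagation, and congener annotation.

A motif is a named set of fragment m/z values and/or neutral losses with a
matching tolerance, interpreted as a molecular substructure (the analytic
counterpart of an MS2LDA motif). Motifs here are *declared*, not discovered:
latent-topic motif inference is out of scope, because downstream use is
presence testing and propagation over the molecular network.

Shipped sarasinoside motifs are computed from glycan chain arithmetic:

* ``motif_505`` — the HexNAc oxocarbenium at m/z 204.09, diagnostic of the
  conserved A-B2 glycosylation pattern across all sarasinosides.
* ``motif_668`` — the B1-C-D chain ion at m/z 498.18 when ring C is a
  pentose (type-2 congeners).
* ``motif_451`` — B1-C (366.14) and A-B1-C-D (660.23) chain ions when ring C
  is a hexose (type-1 congeners).

The melophlin motifs ``motif_437``/``motif_444``/``motif_660`` have no
literature-printed fragment values; their shipped m/z values are model
choices derived from tetramate heterocycle ion formulas and are marked as
such in the exported CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import chem_masses as cm
from .spectral_networking import FragmentSpectrum, MolecularNetwork


@dataclass(frozen=True)
class Motif:
    """A declarative substructure: diagnostic fragments and neutral losses."""

    motif_id: str
    fragment_mzs: tuple[float, ...] = ()
    neutral_losses: tuple[float, ...] = ()
    tolerance: float = 0.01
    label: str = ""
    literature: bool = True  # False: shipped values are model-defined

    def __post_init__(self) -> None:
        if not self.fragment_mzs and not self.neutral_losses:
            raise ValueError("motif needs at least one fragment or loss")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def _ion_mz(formula: str) -> float:
    return cm.monoisotopic_mass(cm.parse_formula(formula))


def _chain_mz(*names: str) -> float:
    return cm.glycan_oxocarbenium_mz([cm.DEFAULT_GLYCANS[n] for n in names])


# Tetramate heterocycle ions for the melophlin motifs (model-defined; the
# desmethyl and C5-methyl cores differ by CH2).
MELOPHLIN_ION_DESMETHYL = _ion_mz("C4H6NO2+")   # 100.0393
MELOPHLIN_ION_METHYL = _ion_mz("C5H8NO2+")      # 114.0550
MELOPHLIN_ION_ACYL = _ion_mz("C7H10NO3+")       # 156.0655, shared acyl-tetramate


def default_motifs() -> list[Motif]:
    return [
        Motif("motif_505", (_chain_mz("HexNAc"),), label="A-B2 HexNAc conserved"),
        Motif(
            "motif_668",
            (_chain_mz("HexNAc", "pentose", "hexose"),),
            label="type-2 (C=pentose)",
        ),
        Motif(
            "motif_451",
            (_chain_mz("HexNAc", "hexose"),
             _chain_mz("pentose", "HexNAc", "hexose", "hexose")),
            label="type-1 (C=hexose)",
        ),
        Motif("motif_437", (MELOPHLIN_ION_DESMETHYL,),
              label="melophlin C5-desmethyl heterocycle", literature=False),
        Motif("motif_444", (MELOPHLIN_ION_METHYL,),
              label="melophlin C5-methyl heterocycle", literature=False),
        Motif("motif_660", (MELOPHLIN_ION_DESMETHYL, MELOPHLIN_ION_METHYL),
              label="melophlin tetramate core", literature=False),
    ]


#: Default motif -> pattern-label propagation rules.
DEFAULT_PATTERN_RULES: dict[str, str] = {
    m.motif_id: m.label for m in default_motifs()
}

#: Motif families treated as mutually exclusive; joint presence is flagged.
DEFAULT_CONFLICT_GROUPS: tuple[frozenset, ...] = (
    frozenset({"motif_451", "motif_668"}),
)


def detect_motifs(
    s: FragmentSpectrum,
    motifs: Sequence[Motif],
    min_fraction: float = 1.0,
) -> set[str]:
    """Return ids of motifs present in a spectrum.

    A motif is present when at least ``min_fraction`` of its fragment ions
    match an observed peak within tolerance AND every one of its neutral
    losses appears as a precursor-minus-peak difference within tolerance.
    """
    found = set()
    losses = s.precursor_mz - s.mz if len(s) else np.empty(0)
    for m in motifs:
        if m.fragment_mzs:
            hits = sum(
                1 for f in m.fragment_mzs if len(s) and np.min(np.abs(s.mz - f)) <= m.tolerance
            )
            if hits < min_fraction * len(m.fragment_mzs):
                continue
        ok = True
        for nl in m.neutral_losses:
            if not (len(losses) and np.min(np.abs(losses - nl)) <= m.tolerance):
                ok = False
                break
        if ok:
            found.add(m.motif_id)
    return found


def classify_glycosylation(
    s: FragmentSpectrum,
    residues: Mapping[str, cm.GlycanResidue] = cm.DEFAULT_GLYCANS,
    tol: float = 0.01,
) -> int:
    """Count glycosyl residues by walking successive neutral losses.

    Starting at the precursor, a depth-first search steps down by any residue
    mass in the table whenever an observed peak lies within tolerance of the
    reduced mass; the returned glycosylation level is the longest walkable
    chain of losses. Residue identity is not distinguished (a pentose-for-
    hexose swap changes the family label, not the level).
    """
    masses = [r.residue_mass for r in residues.values()]
    peak_mz = s.mz

    def depth(current: float) -> int:
        best = 0
        for rm in masses:
            target = current - rm
            if target <= 0:
                continue
            if len(peak_mz) and np.min(np.abs(peak_mz - target)) <= tol:
                hit = peak_mz[np.argmin(np.abs(peak_mz - target))]
                best = max(best, 1 + depth(float(hit)))
        return best

    return depth(s.precursor_mz)


@dataclass
class CongenerAnnotation:
    """Per-node structural annotation accumulated by the motif layer."""

    node_id: str
    glyco_level: Optional[int] = None
    pattern_labels: set[str] = field(default_factory=set)
    conflict: bool = False
    motifs: set[str] = field(default_factory=set)
    dereplication: str = "unknown"


def propagate_patterns(
    net: MolecularNetwork,
    node_motifs: Mapping[str, set[str]],
    rules: Mapping[str, str] = DEFAULT_PATTERN_RULES,
    conflict_groups: Sequence[frozenset] = DEFAULT_CONFLICT_GROUPS,
) -> dict[str, CongenerAnnotation]:
    """Assign pattern labels from detected motifs; union labels per node.

    Labels attach wherever the defining motif is present — including
    singletons, since motif presence needs no edges. Nodes carrying motifs
    from a mutually exclusive family group (e.g. both the type-1 and type-2
    sarasinoside motifs) are flagged as conflicting rather than resolved.
    """
    out: dict[str, CongenerAnnotation] = {}
    for node in net.nodes:
        motifs = set(node_motifs.get(node, set()))
        ann = CongenerAnnotation(node, motifs=motifs)
        for mid in motifs:
            if mid in rules:
                ann.pattern_labels.add(rules[mid])
        for group in conflict_groups:
            if len(motifs & group) > 1:
                ann.conflict = True
        out[node] = ann
    return out


def annotate_delta_edges(
    net: MolecularNetwork,
    table: Sequence[cm.ModificationDelta] = cm.DEFAULT_DELTAS,
    tol: float = 0.01,
) -> dict[tuple[str, str], str]:
    """Label network edges by characteristic precursor mass differences.

    An edge whose |precursor delta| matches a modification within tolerance
    gets that name with a direction sign; a delta of ~0 is labeled "isomer";
    others are left unlabeled. Labels are written onto edge attributes and
    returned keyed by the (sorted) node pair.
    """
    labels: dict[tuple[str, str], str] = {}
    for u, v, d in net.graph.edges(data=True):
        delta = d["precursor_delta"]
        if abs(delta) <= tol:
            label = "isomer"
        else:
            hit = cm.classify_delta(delta, table, tol)
            if hit is None:
                continue
            entry, direction = hit
            label = f"{'+' if direction > 0 else '-'}{entry.name}"
        d["delta_label"] = label
        labels[tuple(sorted((u, v)))] = label
    return labels


def detect_alkyl_ladder(
    s: FragmentSpectrum,
    spacing: float = 14.0157,
    window: tuple[float, float] = (100.0, 300.0),
    min_rungs: int = 4,
    tol: float = 0.02,
) -> bool:
    """Detect the methylene (CH2) fragment ladder diagnostic of a linear alkyl chain.

    Looks for >= ``min_rungs`` peaks inside the m/z window forming an
    arithmetic chain at the given spacing, with per-step tolerance.
    """
    in_window = np.sort(s.mz[(s.mz >= window[0]) & (s.mz <= window[1])])
    if len(in_window) < min_rungs:
        return False
    best = {}
    for i, m in enumerate(in_window):
        best[i] = 1
        target = m - spacing
        prev = np.abs(in_window[:i] - target)
        if len(prev) and prev.min() <= tol:
            j = int(np.argmin(prev))
            best[i] = best[j] + 1
        if best[i] >= min_rungs:
            return True
    return False


@dataclass
class DereplicationResult:
    status: str  # "hit" | "ambiguous" | "unknown"
    entry_ids: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        return ";".join(self.entry_ids) if self.entry_ids else "unknown"


def dereplicate(
    query_mz: float,
    library: pd.DataFrame,
    mz_tol: float = 0.01,
    require_motifs: bool = True,
    observed_motifs: Optional[set[str]] = None,
) -> DereplicationResult:
    """Match a precursor against a congener reference library.

    ``library`` columns: ``id``, ``mz`` ([M+H]+), optional ``expected_motifs``
    (semicolon-joined motif ids). The nearest library mass within tolerance
    wins; when ``require_motifs`` is set, entries whose expected motifs are
    not all observed are disqualified. Equidistant candidates are all
    reported and flagged ambiguous.
    """
    observed = observed_motifs or set()
    candidates: list[tuple[float, str]] = []
    for _, row in library.iterrows():
        err = abs(float(row["mz"]) - query_mz)
        if err > mz_tol:
            continue
        if require_motifs and "expected_motifs" in row and isinstance(row["expected_motifs"], str):
            expected = {m for m in row["expected_motifs"].split(";") if m}
            if not expected <= observed:
                continue
        candidates.append((err, str(row["id"])))
    if not candidates:
        return DereplicationResult("unknown")
    candidates.sort()
    best_err = candidates[0][0]
    tied = [cid for err, cid in candidates if abs(err - best_err) <= 1e-9]
    if len(tied) > 1:
        return DereplicationResult("ambiguous", tied)
    return DereplicationResult("hit", [tied[0]])


# ---------------------------------------------------------------------------
# IO


def save_motifs(motifs: Sequence[Motif], path: str | Path) -> None:
    rows = []
    for m in motifs:
        for f in m.fragment_mzs:
            rows.append({"motif_id": m.motif_id, "type": "frag", "mz": f,
                         "tol": m.tolerance, "label": m.label,
                         "literature": m.literature})
        for nl in m.neutral_losses:
            rows.append({"motif_id": m.motif_id, "type": "loss", "mz": nl,
                         "tol": m.tolerance, "label": m.label,
                         "literature": m.literature})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def load_motifs(path: str | Path) -> list[Motif]:
    df = pd.read_csv(path)
    out = []
    for mid, grp in df.groupby("motif_id", sort=False):
        frags = tuple(grp.loc[grp["type"] == "frag", "mz"].astype(float))
        losses = tuple(grp.loc[grp["type"] == "loss", "mz"].astype(float))
        out.append(
            Motif(
                str(mid), frags, losses,
                float(grp["tol"].iloc[0]), str(grp["label"].iloc[0]),
                bool(grp["literature"].iloc[0]) if "literature" in grp else True,
            )
        )
    return out


def save_annotations(annotations: Mapping[str, CongenerAnnotation], path: str | Path) -> None:
    rows = []
    for node, ann in sorted(annotations.items()):
        rows.append(
            {
                "node": node,
                "glyco_level": ann.glyco_level if ann.glyco_level is not None else "",
                "motifs": ";".join(sorted(ann.motifs)),
                "pattern_labels": ";".join(sorted(ann.pattern_labels)),
                "conflict": ann.conflict,
                "dereplication": ann.dereplication,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
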