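"""LC/MS feature-level processing and feature-based molecular networking (FBMN).

Consumes centroided per-sample feature rows (id, m/z, RT, intensity) —
chromatogram building and deconvolution from raw profile signal are upstream
of this package — and applies the standard post-detection stages in order:

    MS1 noise filter -> deisotoping -> cross-sample alignment ->
    duplicate removal -> gap filling -> MS2 scan pairing -> FBMN

Default tolerances mirror a widely used MZmine-style parameter set:
15 ppm / 0.1 min for grouping and alignment, 5 ppm / 0.1 min for duplicate
removal, 0.025 Da / 0.2 min for MS2 pairing, MS1 noise threshold 10,000,
maximum charge 3. FBMN keeps co-eluting isomers at one m/z as distinct
network nodes because features carry retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_masses import ISOTOPE_SPACING
from .spectral_networking import (
    FragmentSpectrum,
    MolecularNetwork,
    build_network,
    merge_peak_lists,
)


@dataclass
class FeatureRow:
    """One detected ion in one sample (post-deconvolution, centroided)."""

    row_id: str
    sample_id: str
    mz: float
    rt: float
    intensity: float
    charge: int = 1


@dataclass
class Feature:
    """An aligned cross-sample feature: representative m/z/RT + per-sample areas."""

    feature_id: str
    mz: float
    rt: float
    charge: int
    areas: dict[str, float] = field(default_factory=dict)
    ms2_scan_ids: list[str] = field(default_factory=list)


@dataclass
class AlignedFeatureTable:
    features: list[Feature]
    samples: list[str]
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            row = {"id": f.feature_id, "mz": f.mz, "rt": f.rt, "charge": f.charge}
            for s in self.samples:
                row[f"area_{s}"] = f.areas.get(s, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _ppm_close(a: float, b: float, ppm: float) -> bool:
    return abs(a - b) <= ppm * 1e-6 * max(a, b)


def filter_ms1_noise(rows: Sequence[FeatureRow], threshold: float = 10_000.0) -> list[FeatureRow]:
    """Drop rows whose area falls below the MS1 noise detection threshold."""
    return [r for r in rows if r.intensity >= threshold]


def deisotope(
    rows: Sequence[FeatureRow],
    ppm_tol: float = 15.0,
    rt_tol: float = 0.1,
    max_charge: int = 3,
) -> list[FeatureRow]:
    """Collapse isotopologue rows onto their most intense member.

    Rows whose m/z fits ``M + k*1.00336/z`` (k = 1, 2; z = 1..max_charge) of a
    co-eluting, more intense row are absorbed. The surviving representative is
    the most intense isotopologue, annotated with the inferred charge.
    """
    order = sorted(range(len(rows)), key=lambda i: -rows[i].intensity)
    absorbed = [False] * len(rows)
    out: list[FeatureRow] = []
    for i in order:
        if absorbed[i]:
            continue
        seed = rows[i]
        charge = seed.charge
        for z in range(1, max_charge + 1):
            for k in (1, 2):
                target = seed.mz + k * ISOTOPE_SPACING / z
                for j in order:
                    if absorbed[j] or j == i:
                        continue
                    cand = rows[j]
                    if cand.sample_id != seed.sample_id:
                        continue
                    if abs(cand.rt - seed.rt) <= rt_tol and _ppm_close(cand.mz, target, ppm_tol):
                        absorbed[j] = True
                        charge = max(charge, z) if z > 1 else charge
        out.append(
            FeatureRow(seed.row_id, seed.sample_id, seed.mz, seed.rt, seed.intensity, charge)
        )
    out.sort(key=lambda r: (r.sample_id, r.mz, r.rt))
    return out


def align(
    rows_per_sample: Sequence[Sequence[FeatureRow]],
    ppm_tol: float = 15.0,
    rt_tol: float = 0.1,
) -> AlignedFeatureTable:
    """Merge rows across samples within both m/z (ppm) and RT tolerances.

    Cluster seeds are taken in descending intensity order so the output does
    not depend on sample ordering; merged m/z and RT are intensity-weighted
    means, per-sample areas are preserved per column (summed within sample).
    """
    if not rows_per_sample:
        raise ValueError("need at least one sample")
    pool: list[FeatureRow] = [r for rows in rows_per_sample for r in rows]
    samples = sorted({r.sample_id for r in pool})
    order = sorted(range(len(pool)), key=lambda i: (-pool[i].intensity, pool[i].mz))
    claimed = [False] * len(pool)
    features: list[Feature] = []
    for i in order:
        if claimed[i]:
            continue
        seed = pool[i]
        members = [seed]
        claimed[i] = True
        for j in order:
            if claimed[j]:
                continue
            cand = pool[j]
            if abs(cand.rt - seed.rt) <= rt_tol and _ppm_close(cand.mz, seed.mz, ppm_tol):
                members.append(cand)
                claimed[j] = True
        w = np.array([m.intensity for m in members])
        mz = float(np.average([m.mz for m in members], weights=w))
        rt = float(np.average([m.rt for m in members], weights=w))
        areas: dict[str, float] = {}
        for m in members:
            areas[m.sample_id] = areas.get(m.sample_id, 0.0) + m.intensity
        charge = max(m.charge for m in members)
        features.append(Feature(f"F{len(features)}", mz, rt, charge, areas))
    features.sort(key=lambda f: (f.mz, f.rt))
    for k, f in enumerate(features):
        f.feature_id = f"F{k:05d}"
    return AlignedFeatureTable(features, samples, {"ppm_tol": ppm_tol, "rt_tol": rt_tol})


def remove_duplicates(
    table: AlignedFeatureTable, ppm_tol: float = 5.0, rt_tol: float = 0.1
) -> AlignedFeatureTable:
    """Merge feature rows that fall within both duplicate-filter tolerances."""
    feats = sorted(table.features, key=lambda f: -sum(f.areas.values()))
    kept: list[Feature] = []
    for f in feats:
        merged = False
        for g in kept:
            if abs(f.rt - g.rt) <= rt_tol and _ppm_close(f.mz, g.mz, ppm_tol):
                for s, a in f.areas.items():
                    g.areas[s] = g.areas.get(s, 0.0) + a
                g.ms2_scan_ids.extend(f.ms2_scan_ids)
                merged = True
                break
        if not merged:
            kept.append(f)
    kept.sort(key=lambda f: (f.mz, f.rt))
    return AlignedFeatureTable(kept, table.samples, dict(table.parameters))


def gap_fill(
    table: AlignedFeatureTable,
    raw_rows: Sequence[FeatureRow],
    ppm_tol: float = 15.0,
    rt_tol: float = 0.1,
    intensity_tolerance: float = 0.1,
) -> AlignedFeatureTable:
    """Fill missing per-sample areas from raw rows within tolerances.

    Only zero/absent cells are filled; an existing nonzero area is never
    overwritten. Cells with no qualifying raw row stay 0.
    """
    by_sample: dict[str, list[FeatureRow]] = {}
    for r in raw_rows:
        by_sample.setdefault(r.sample_id, []).append(r)
    for f in table.features:
        for s in table.samples:
            if f.areas.get(s, 0.0) > 0:
                continue
            best: Optional[FeatureRow] = None
            for r in by_sample.get(s, []):
                if abs(r.rt - f.rt) <= rt_tol and _ppm_close(r.mz, f.mz, ppm_tol):
                    if best is None or r.intensity > best.intensity:
                        best = r
            if best is not None:
                f.areas[s] = best.intensity
    return table


def filter_mz_range(
    table: AlignedFeatureTable, mz_min: float, mz_max: float
) -> AlignedFeatureTable:
    """Optional feature-list m/z range filter (e.g. 1280-1350 for a saponin window)."""
    feats = [f for f in table.features if mz_min <= f.mz <= mz_max]
    return AlignedFeatureTable(feats, table.samples, dict(table.parameters))


def pair_ms2(
    table: AlignedFeatureTable,
    spectra: Sequence[FragmentSpectrum],
    mz_pair_tol: float = 0.025,
    rt_pair_tol: float = 0.2,
) -> tuple[AlignedFeatureTable, list[str]]:
    """Attach each MS2 scan to its single nearest qualifying feature.

    Qualification requires both |dmz| <= mz_pair_tol and |dRT| <= rt_pair_tol;
    among qualifiers the smallest m/z distance wins, RT distance breaks ties.
    Returns the table plus the scan ids left unattached.
    """
    unpaired: list[str] = []
    for f in table.features:
        f.ms2_scan_ids = []
    for s in spectra:
        best: Optional[Feature] = None
        best_key = (np.inf, np.inf)
        for f in table.features:
            dmz = abs(s.precursor_mz - f.mz)
            drt = abs(s.rt - f.rt)
            if dmz <= mz_pair_tol and drt <= rt_pair_tol:
                key = (dmz, drt)
                if key < best_key:
                    best, best_key = f, key
        if best is None:
            unpaired.append(s.scan_id)
        else:
            best.ms2_scan_ids.append(s.scan_id)
    return table, unpaired


def fbmn_network(
    table: AlignedFeatureTable,
    spectra: Sequence[FragmentSpectrum],
    min_cosine: float = 0.7,
    min_matched: int = 6,
    top_k: int = 10,
    frag_tol: float = 0.05,
) -> MolecularNetwork:
    """Feature-based molecular network: one node per MS2-bearing feature.

    Each feature's representative spectrum is the tolerance-binned merge of
    its attached scans; scoring and mutual-top-K topology are as in classical
    networking but with the FBMN matched-peak threshold (default 6).
    Features without attached MS2 are excluded from the network but remain in
    the table.
    """
    by_scan = {s.scan_id: s for s in spectra}
    nodes: list[tuple[str, FragmentSpectrum]] = []
    for f in table.features:
        scans = [by_scan[sid] for sid in f.ms2_scan_ids if sid in by_scan]
        if not scans:
            continue
        mz, inten = merge_peak_lists(scans, frag_tol)
        rep = FragmentSpectrum(
            scan_id=f.feature_id,
            precursor_mz=f.mz,
            rt=f.rt,
            precursor_charge=f.charge,
            mz=mz,
            intensity=inten,
        )
        nodes.append((f.feature_id, rep))
    return build_network(nodes, min_cosine, min_matched, top_k, frag_tol)


# ---------------------------------------------------------------------------
# IO


def read_feature_rows(path: str | Path) -> list[FeatureRow]:
    df = pd.read_csv(path)
    return [
        FeatureRow(
            str(r["id"]), str(r["sample"]), float(r["mz"]), float(r["rt"]),
            float(r["intensity"]), int(r.get("charge", 1)),
        )
        for _, r in df.iterrows()
    ]


def write_feature_rows(rows: Sequence[FeatureRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.row_id, "sample": r.sample_id, "mz": r.mz,
                "rt": r.rt, "intensity": r.intensity, "charge": r.charge,
            }
            for r in rows
        ]
    ).to_csv(path, index=False, float_format="%.6f")
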