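"""End-to-end orchestration: synthetic data -> networks -> annotation ->
quantification -> metagenome mining, from a single seeded configuration.

Every stage writes plain-text artifacts (CSV/TSV/MGF/GraphML/JSON) into the
output directory and the run manifest records the seed and parameter set, so
two runs with the same config are identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import (
    chem_masses,
    feature_pipeline as fp,
    metagenome_mining as mm,
    motif_annotation as ma,
    quantify_compare as qc,
    spectral_networking as sn,
    synthetic_data as sd,
)


@dataclass
class RunConfig:
    """All stage toggles, thresholds and tolerances for one pipeline run."""

    seed: int = 0
    out_dir: str = "glyconet_run"
    n_families: int = 3
    n_samples_per_group: int = 2
    # spectral networking
    ms2_noise_floor: float = 500.0
    precursor_tol: float = 0.01
    frag_tol: float = 0.05
    min_cosine: float = 0.7
    min_matched: int = 5
    top_k: int = 10
    # feature pipeline
    ms1_noise_threshold: float = 10_000.0
    group_ppm_tol: float = 15.0
    group_rt_tol: float = 0.1
    dedup_ppm_tol: float = 5.0
    dedup_rt_tol: float = 0.1
    mz_pair_tol: float = 0.025
    rt_pair_tol: float = 0.2
    fbmn_min_matched: int = 6
    # quantification
    fc_threshold: float = 3.0
    alpha: float = 0.05
    sentinel: float = 6.0
    # microbiome / metagenome
    asv_depth: int = 20_000
    asv_samples: int = 2
    n_bins: int = 10
    # stage toggles
    stages: tuple = ("simulate", "network", "features", "annotate", "quantify", "mine")

    def __post_init__(self) -> None:
        for name in ("precursor_tol", "frag_tol", "mz_pair_tol", "rt_pair_tol",
                     "group_ppm_tol", "group_rt_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _seed_for(config: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunResult:
    out_dir: Path
    feature_table: Optional[fp.AlignedFeatureTable] = None
    classical_network: Optional[sn.MolecularNetwork] = None
    fbmn: Optional[sn.MolecularNetwork] = None
    annotations: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)


def run(config: RunConfig) -> RunResult:
    """Execute the enabled stages in dependency order; fail fast on gaps."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = RunResult(out)
    library = profiles = rows = spectra = truth = None

    if "simulate" in config.stages:
        seed = _seed_for(config, "simulate")
        rng = np.random.default_rng(seed)
        library = sd.make_congener_library(config.n_families, seed)
        profiles = _make_profiles(library, config, rng)
        rows, spectra, truth = sd.simulate_feature_tables(
            library, profiles, _seed_for(config, "tables")
        )
        sn.write_mgf(spectra, out / "spectra.mgf")
        fp.write_feature_rows(rows, out / "feature_rows.csv")
        truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    elif any(s in config.stages for s in ("network", "features", "annotate", "quantify")):
        mgf = out / "spectra.mgf"
        rows_csv = out / "feature_rows.csv"
        if not mgf.exists() or not rows_csv.exists():
            raise FileNotFoundError("stage 'network'/'features' requires simulate outputs")
        spectra = sn.read_mgf(mgf)
        rows = fp.read_feature_rows(rows_csv)

    filtered = []
    if spectra is not None:
        filtered = [sn.filter_peaks(s, config.ms2_noise_floor) for s in spectra]
        filtered = [s for s in filtered if len(s)]

    if "network" in config.stages:
        consensus = sn.cluster_spectra(filtered, config.precursor_tol, config.frag_tol)
        nodes = [(c.consensus_id, c.spectrum) for c in consensus]
        net = sn.build_network(
            nodes, config.min_cosine, config.min_matched, config.top_k, config.frag_tol
        )
        result.classical_network = net
        sn.write_graphml(net, out / "classical_network.graphml")
        sn.write_edge_list(net, out / "classical_edges.tsv")

    if "features" in config.stages:
        by_sample: dict[str, list[fp.FeatureRow]] = {}
        for r in fp.filter_ms1_noise(rows, config.ms1_noise_threshold):
            by_sample.setdefault(r.sample_id, []).append(r)
        deiso = {s: fp.deisotope(v, config.group_ppm_tol, config.group_rt_tol)
                 for s, v in by_sample.items()}
        table = fp.align(list(deiso.values()), config.group_ppm_tol, config.group_rt_tol)
        table = fp.remove_duplicates(table, config.dedup_ppm_tol, config.dedup_rt_tol)
        table = fp.gap_fill(table, rows, config.group_ppm_tol, config.group_rt_tol)
        table, unpaired = fp.pair_ms2(
            table, filtered, config.mz_pair_tol, config.rt_pair_tol
        )
        result.feature_table = table
        table.write_csv(out / "feature_table.csv")
        fbmn = fp.fbmn_network(
            table, filtered, config.min_cosine, config.fbmn_min_matched,
            config.top_k, config.frag_tol,
        )
        result.fbmn = fbmn
        sn.write_graphml(fbmn, out / "fbmn_network.graphml")
        sn.write_edge_list(fbmn, out / "fbmn_edges.tsv")

    if "annotate" in config.stages:
        if result.fbmn is None:
            raise RuntimeError("stage 'annotate' requires stage 'features'")
        motifs = ma.default_motifs()
        ma.save_motifs(motifs, out / "motifs.csv")
        node_motifs = {}
        for node in result.fbmn.nodes:
            node_motifs[node] = ma.detect_motifs(result.fbmn.spectra[node], motifs)
        annotations = ma.propagate_patterns(result.fbmn, node_motifs)
        for node, ann in annotations.items():
            ann.glyco_level = ma.classify_glycosylation(result.fbmn.spectra[node])
        ma.annotate_delta_edges(result.fbmn)
        if truth is not None:
            lib_df = pd.DataFrame(
                {
                    "id": [c.congener_id for c in library],
                    "mz": [c.precursor_mz for c in library],
                }
            ).drop_duplicates("id")
            for node, ann in annotations.items():
                hit = ma.dereplicate(
                    result.fbmn.spectra[node].precursor_mz, lib_df, require_motifs=False
                )
                ann.dereplication = str(hit)
        result.annotations = annotations
        ma.save_annotations(annotations, out / "annotations.tsv")

    if "quantify" in config.stages:
        if result.feature_table is None:
            raise RuntimeError("stage 'quantify' requires stage 'features'")
        table = result.feature_table
        matrix = table.to_frame().set_index("id")
        area_cols = [c for c in matrix.columns if c.startswith("area_")]
        areas = matrix[area_cols]
        areas.columns = [c[len("area_"):] for c in area_cols]
        groups = _sample_groups(table.samples)
        overlap = qc.feature_overlap(table, groups)
        pd.DataFrame(
            [
                {"groups": "+".join(sorted(k)), "count": v,
                 "percent": overlap.percentages()[k]}
                for k, v in sorted(overlap.counts.items(), key=lambda kv: -kv[1])
            ]
        ).to_csv(out / "feature_overlap.tsv", sep="\t", index=False)
        if truth is not None:
            cong_areas = truth.pivot_table(
                index="congener_id", columns="sample", values="area", fill_value=0.0,
                aggfunc="sum",
            )
            family = dict(zip(truth["congener_id"], truth["family"]))
            heat = qc.congener_heatmap(cong_areas, family, config.sentinel)
            heat.to_csv(out / "congener_heatmap.csv", float_format="%.4f")
        asv_seed = _seed_for(config, "asv")
        hma = sd.simulate_asv_table(sd.HMA_ARCHETYPE, config.asv_samples,
                                    config.asv_depth, asv_seed)
        lma = sd.simulate_asv_table(sd.LMA_ARCHETYPE, config.asv_samples,
                                    config.asv_depth, asv_seed + 1)
        hma.to_csv(out / "asv_hma.tsv", sep="\t")
        lma.to_csv(out / "asv_lma.tsv", sep="\t")
        div = pd.concat([qc.shannon_per_sample(hma), qc.shannon_per_sample(lma)])
        div.rename("shannon_bits").to_csv(out / "shannon.tsv", sep="\t")
        qc.phylum_heatmap(hma).to_csv(out / "phylum_heatmap_hma.csv", float_format="%.4f")
        qc.phylum_heatmap(lma).to_csv(out / "phylum_heatmap_lma.csv", float_format="%.4f")

    if "mine" in config.stages:
        planted = sd.simulate_metagenome(config.n_bins, _seed_for(config, "metagenome"))
        mm.write_bins(planted.bins, out / "bin_genes.tsv", out / "bin_scaffolds.tsv")
        counts = mm.count_by_category(planted.bins)
        counts.to_csv(out / "category_counts.tsv", sep="\t")
        candidates = mm.screen_bins(planted.bins)
        result.candidates = candidates
        (out / "screen_candidates.txt").write_text("\n".join(candidates) + "\n")
        reports = [
            mm.locus_report(b).to_text()
            for b in planted.bins if b.bin_id in candidates
        ]
        (out / "locus_reports.txt").write_text("\n\n".join(reports) + "\n")
        mm.bin_scatter_table(planted.bins).to_csv(
            out / "bin_scatter.tsv", sep="\t", index=False, float_format="%.4f"
        )

    sd.write_manifest(out / "manifest.json", config.seed, asdict(config))
    return result


def _make_profiles(library, config: RunConfig, rng) -> list[sd.SampleProfile]:
    """Two sample groups: one enriched for glycosylated-sterol congeners, one
    for the tetramate family, mirroring a paired-specimen study design."""
    sarc = [c.congener_id for c in library if c.family == "sarasinoside-like"]
    mel = [c.congener_id for c in library if c.family == "melophlin-like"]
    other = [c.congener_id for c in library
             if c.family not in ("sarasinoside-like", "melophlin-like")]
    profiles = []
    for g, (hi, lo) in enumerate(((sarc, mel), (mel, sarc))):
        for s in range(config.n_samples_per_group):
            abund = {}
            for cid in hi:
                abund[cid] = float(rng.uniform(0.5, 1.0))
            for cid in lo:
                abund[cid] = float(rng.uniform(0.05, 0.25))
            for cid in other:
                abund[cid] = float(rng.uniform(0.2, 0.8))
            profiles.append(
                sd.SampleProfile(f"group{g}_s{s}", abund)
            )
    return profiles


def _sample_groups(samples) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for s in samples:
        key = s.split("_")[0] if "_" in s else s
        groups.setdefault(key, []).append(s)
    return groups
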