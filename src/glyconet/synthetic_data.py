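"""Synthetic holobiont data with known ground truth.

Generates every input the pipeline consumes:

* glycosylated-congener MS2 spectra with glycosidic B/Y fragmentation,
  tailing modifications, and family-diagnostic ions;
* multi-sample LC/MS feature rows (isotope envelopes, RT jitter, ppm error)
  with linked MS2 scans for FBMN pairing;
* ASV count tables for high-microbial-abundance (diverse) vs
  low-microbial-abundance (archaeon-dominated) community archetypes;
* metagenome bins with GC%/coverage structure and exactly one planted bin
  carrying co-occurring sterol-pathway and glycosyltransferase loci.

Three congener families are modeled: *sarasinoside-like* polyglycosylated
sterols (glycan chain ordered innermost-first/outermost-last, ring pattern
A-pentose, B2/B1-HexNAc, C/D hexose or pentose), *melophlin-like* tetramate
lipids (no glycans, C5-methylation dichotomy, optional bromination), and
*polyacetylene-like* C30 lipids carrying one or two hexoses and a methylene
fragment ladder. Fragment intensity tiers follow the empirical dominance of
glycosidic Y ions (Y > B > aglycone > low-mass ladder); absolute tiers are
model choices recorded in the run manifest.

Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import chem_masses as cm
from .chem_masses import DEFAULT_DELTAS, DEFAULT_GLYCANS, PROTON_MASS, ISOTOPE_SPACING
from .feature_pipeline import FeatureRow
from .metagenome_mining import BinRecord, Gene, Scaffold
from .motif_annotation import (
    MELOPHLIN_ION_ACYL,
    MELOPHLIN_ION_DESMETHYL,
    MELOPHLIN_ION_METHYL,
)
from .spectral_networking import FragmentSpectrum

WATER_MASS = 18.0105646


@dataclass(frozen=True)
class CongenerSpec:
    """Ground-truth description of one congener."""

    congener_id: str
    family: str  # sarasinoside-like | melophlin-like | polyacetylene-like
    aglycone_mass: float
    glycan_chain: tuple = ()  # GlycanResidue, outermost-last
    modifications: tuple = ()  # ModificationDelta applied to the aglycone
    c5_methylated: bool = False
    true_rt: float = 5.0

    @property
    def precursor_mz(self) -> float:
        return (
            self.aglycone_mass
            + sum(r.residue_mass for r in self.glycan_chain)
            + sum(d.delta_mass for d in self.modifications)
            + PROTON_MASS
        )

    @property
    def glyco_level(self) -> int:
        return len(self.glycan_chain)


@dataclass
class SampleProfile:
    """Per-sample abundances and noise model."""

    sample_id: str
    abundances: dict[str, float] = field(default_factory=dict)
    noise_peaks: float = 10.0  # Poisson mean of MS2 noise peak count
    intensity_scale: float = 1e5
    rt_jitter_sd: float = 0.02  # min
    # calibrated high-resolution TOF accuracy; consistent with the 0.01 Da
    # precursor tolerances the downstream workflow assumes at m/z ~1300
    mz_error_ppm: float = 2.0

    def __post_init__(self) -> None:
        vals = list(self.abundances.values())
        if vals and (not all(np.isfinite(vals)) or min(vals) < 0):
            raise ValueError("abundances must be finite and >= 0")


def noiseless_profile(sample_id: str, abundances: dict[str, float]) -> SampleProfile:
    return SampleProfile(sample_id, abundances, noise_peaks=0.0,
                         rt_jitter_sd=0.0, mz_error_ppm=0.0)


_DELTAS = {d.name: d for d in DEFAULT_DELTAS}
_PENT = DEFAULT_GLYCANS["pentose"]
_HEX = DEFAULT_GLYCANS["hexose"]
_HEXNAC = DEFAULT_GLYCANS["HexNAc"]

#: Ring pattern of a type-1 pentaglycoside (C ring = hexose), outermost-last.
TYPE1_CHAIN = (_PENT, _HEXNAC, _HEXNAC, _HEX, _HEX)
#: Type-2: C ring swapped to pentose.
TYPE2_CHAIN = (_PENT, _HEXNAC, _HEXNAC, _PENT, _HEX)

#: Aglycone of the reference polyacetylene congener (C30H46O2): its [M+H]+
#: mono- and diglycosides land at m/z 601.41 and 763.46 and its aglycone ions
#: at 439.35 / 421.34.
POLYACETYLENE_AGLYCONE = cm.monoisotopic_mass(cm.parse_formula("C30H46O2"))


def make_congener_library(n_families: int, seed: int) -> list[CongenerSpec]:
    """Build a congener library with known structure, deterministically.

    Families cycle sarasinoside-like -> melophlin-like -> polyacetylene-like.
    Each sarasinoside-like family spans glycosylation levels 5..2, carries
    modification variants drawn from the default delta table, and plants one
    4-member isomer group (identical composition, RT spacing 0.3 min).
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    library: list[CongenerSpec] = []
    for f in range(n_families):
        kind = ("sarasinoside-like", "melophlin-like", "polyacetylene-like")[f % 3]
        prefix = f"fam{f}"
        if kind == "sarasinoside-like":
            aglycone = float(rng.uniform(460.0, 500.0))
            base_rt = float(rng.uniform(3.0, 9.0))
            for level in (5, 4, 3, 2):
                library.append(
                    CongenerSpec(
                        f"{prefix}_t1_g{level}", kind, aglycone,
                        TYPE1_CHAIN[:level], (), False,
                        base_rt + 0.02 * level + float(rng.uniform(0, 0.5)),
                    )
                )
            # type-2 pentaglycoside: C ring pentose, plus net +CO tailing
            library.append(
                CongenerSpec(
                    f"{prefix}_t2_g5", kind, aglycone, TYPE2_CHAIN,
                    (_DELTAS["methoxylation-dehydrogenation"],), False,
                    base_rt + float(rng.uniform(0.5, 1.5)),
                )
            )
            # tailing variants of the type-1 pentaglycoside
            for mod in ("hydroxylation", "dehydrogenation", "methylation"):
                library.append(
                    CongenerSpec(
                        f"{prefix}_t1_g5_{mod}", kind, aglycone, TYPE1_CHAIN,
                        (_DELTAS[mod],), False, base_rt + float(rng.uniform(0.2, 2.0)),
                    )
                )
            # planted isomer group: identical composition, RT-separated
            iso_rt = base_rt + 1.0
            for k in range(4):
                library.append(
                    CongenerSpec(
                        f"{prefix}_iso{k + 1}", kind, aglycone, TYPE1_CHAIN,
                        (_DELTAS["reduction"],), False, iso_rt + 0.3 * k,
                    )
                )
        elif kind == "melophlin-like":
            aglycone = float(rng.uniform(300.0, 360.0))
            base_rt = float(rng.uniform(6.0, 11.0))
            library.append(
                CongenerSpec(f"{prefix}_mel_desme", kind, aglycone, (), (), False,
                             base_rt)
            )
            library.append(
                CongenerSpec(
                    f"{prefix}_mel_c5me", kind,
                    aglycone + _DELTAS["methylation"].delta_mass, (), (), True,
                    base_rt + float(rng.uniform(0.3, 1.0)),
                )
            )
            library.append(
                CongenerSpec(
                    f"{prefix}_mel_br", kind, aglycone, (),
                    (_DELTAS["bromination"],), False,
                    base_rt + float(rng.uniform(0.3, 1.5)),
                )
            )
            library.append(
                CongenerSpec(
                    f"{prefix}_mel_oh", kind, aglycone, (),
                    (_DELTAS["hydroxylation"],), True,
                    base_rt + float(rng.uniform(0.2, 1.2)),
                )
            )
        else:  # polyacetylene-like
            aglycone = POLYACETYLENE_AGLYCONE if f < 3 else float(rng.uniform(400.0, 460.0))
            base_rt = float(rng.uniform(8.0, 12.0))
            library.append(
                CongenerSpec(f"{prefix}_pa_agl", kind, aglycone, (), (), False, base_rt)
            )
            library.append(
                CongenerSpec(f"{prefix}_pa_hex1", kind, aglycone, (_HEX,), (), False,
                             base_rt - 1.0)
            )
            library.append(
                CongenerSpec(f"{prefix}_pa_hex2", kind, aglycone, (_HEX, _HEX), (),
                             False, base_rt - 2.0)
            )
            for mod in ("hydroxylation", "dehydrogenation", "reduction"):
                library.append(
                    CongenerSpec(
                        f"{prefix}_pa_{mod}", kind, aglycone, (),
                        (_DELTAS[mod],), False, base_rt + float(rng.uniform(0.1, 1.0)),
                    )
                )
    return library


# fragment intensity tiers (relative; Y ions dominate glycoside spectra)
_TIER_Y = 1.0
_TIER_B = 0.45
_TIER_AGLYCONE = 0.25
_TIER_LADDER = 0.08


def simulate_spectrum(
    c: CongenerSpec, profile: SampleProfile, seed: int
) -> FragmentSpectrum:
    """Simulate one MS2 scan of a congener under a sample's noise model.

    Plants (i) the Y-type ladder of successive outermost-residue losses down
    to the aglycone ion, (ii) B-type oxocarbenium ions for contiguous glycan
    subchains (plus the branch A-B1-C-D ion for doubly HexNAc-substituted
    sarasinoside-like congeners), (iii) two aglycone fragment ions (the
    protonated aglycone and its water loss), (iv) family-diagnostic ions
    (tetramate heterocycle ions for melophlins, a 14.0157-spaced alkyl ladder
    for polyacetylenes), plus Poisson-count uniform noise peaks. All m/z are
    perturbed by the profile's ppm error.
    """
    rng = np.random.default_rng(seed)
    scale = profile.intensity_scale
    mzs: list[float] = []
    intens: list[float] = []

    def add(mz: float, tier: float) -> None:
        if mz <= 0:
            return
        mzs.append(mz)
        intens.append(tier * scale * float(rng.lognormal(0.0, 0.25)))

    precursor = c.precursor_mz
    chain = list(c.glycan_chain)
    # (i) Y ladder
    cum = precursor
    for residue in reversed(chain):
        cum -= residue.residue_mass
        add(cum, _TIER_Y)
    # (ii) B ions: all contiguous subchains
    for i in range(len(chain)):
        total = 0.0
        for j in range(i, len(chain)):
            total += chain[j].residue_mass
            add(total + PROTON_MASS, _TIER_B)
    # branch (A-B1-C-D) ion: loss of the branching HexNAc from the full
    # pentasaccharide only — truncated chains lack the B2 branch
    if (
        c.family == "sarasinoside-like"
        and len(chain) >= 5
        and sum(1 for r in chain if r.name == "HexNAc") >= 2
    ):
        branch = sum(r.residue_mass for r in chain) - _HEXNAC.residue_mass + PROTON_MASS
        add(branch, _TIER_B)
    # (iii) aglycone ions
    aglycone_ion = c.aglycone_mass + sum(d.delta_mass for d in c.modifications) + PROTON_MASS
    add(aglycone_ion, _TIER_AGLYCONE)
    add(aglycone_ion - WATER_MASS, _TIER_AGLYCONE)
    # (iv) family diagnostics
    if c.family == "melophlin-like":
        add(MELOPHLIN_ION_DESMETHYL, _TIER_LADDER * (3.0 if not c.c5_methylated else 1.0))
        add(MELOPHLIN_ION_METHYL, _TIER_LADDER * (3.0 if c.c5_methylated else 1.0))
        add(MELOPHLIN_ION_ACYL, _TIER_LADDER)
    if c.family == "polyacetylene-like":
        start = 111.1168
        for k in range(8):
            add(start + k * 14.0157, _TIER_LADDER)
    # noise
    n_noise = int(rng.poisson(profile.noise_peaks)) if profile.noise_peaks > 0 else 0
    if n_noise and intens:
        base = max(intens)
        for _ in range(n_noise):
            mzs.append(float(rng.uniform(50.0, precursor + 10.0)))
            intens.append(float(rng.uniform(0.005, 0.1)) * base)
    mz_arr = np.asarray(mzs)
    if profile.mz_error_ppm > 0:
        mz_arr = mz_arr * (1.0 + rng.normal(0.0, profile.mz_error_ppm * 1e-6, len(mz_arr)))
        precursor = precursor * (1.0 + float(rng.normal(0.0, profile.mz_error_ppm * 1e-6)))
    return FragmentSpectrum(
        scan_id=f"{profile.sample_id}:{c.congener_id}",
        precursor_mz=float(precursor),
        rt=c.true_rt,
        precursor_charge=1,
        sample_id=profile.sample_id,
        mz=mz_arr,
        intensity=np.asarray(intens),
    )


def simulate_feature_tables(
    library: Sequence[CongenerSpec],
    profiles: Sequence[SampleProfile],
    seed: int,
    area_scale: float = 1e6,
) -> tuple[list[FeatureRow], list[FragmentSpectrum], pd.DataFrame]:
    """Emit per-sample feature rows, linked MS2 scans and a ground-truth table.

    Each detectable congener (abundance > 0) produces a 3-isotopologue
    envelope (spacing 1.00336/z, decreasing intensity) and one MS2 scan whose
    precursor m/z and RT match the monoisotopic row within the profile's
    error model.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ss = np.random.SeedSequence(seed)
    rows: list[FeatureRow] = []
    spectra: list[FragmentSpectrum] = []
    truth_rows = []
    for profile, child in zip(profiles, ss.spawn(len(profiles))):
        rng = np.random.default_rng(child)
        for c in library:
            abundance = profile.abundances.get(c.congener_id, 0.0)
            if abundance <= 0:
                continue
            area = abundance * area_scale * float(rng.lognormal(0.0, 0.1))
            rt = c.true_rt + (
                float(rng.normal(0.0, profile.rt_jitter_sd)) if profile.rt_jitter_sd else 0.0
            )
            mz = c.precursor_mz
            if profile.mz_error_ppm:
                mz *= 1.0 + float(rng.normal(0.0, profile.mz_error_ppm * 1e-6))
            for k, frac in enumerate((1.0, 0.35, 0.08)):
                rows.append(
                    FeatureRow(
                        f"{profile.sample_id}:{c.congener_id}:M{k}",
                        profile.sample_id,
                        mz + k * ISOTOPE_SPACING,
                        rt,
                        area * frac,
                        1,
                    )
                )
            spec = simulate_spectrum(
                c, profile, int(rng.integers(0, 2**31 - 1))
            )
            spec = FragmentSpectrum(
                scan_id=spec.scan_id, precursor_mz=spec.precursor_mz, rt=rt,
                precursor_charge=1, sample_id=profile.sample_id,
                mz=spec.mz, intensity=spec.intensity,
            )
            spectra.append(spec)
            truth_rows.append(
                {
                    "congener_id": c.congener_id, "sample": profile.sample_id,
                    "family": c.family, "mz": c.precursor_mz, "rt": c.true_rt,
                    "area": area, "glyco_level": c.glyco_level,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return rows, spectra, truth


# ---------------------------------------------------------------------------
# microbiome


@dataclass(frozen=True)
class CommunityArchetype:
    """Phylum-level community template (HMA-like diverse vs LMA-like dominated)."""

    name: str
    phylum_weights: Mapping[str, float]
    richness: Mapping[str, int]  # ASVs per phylum

    def __post_init__(self) -> None:
        total = sum(self.phylum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phylum weights must sum to 1")


HMA_ARCHETYPE = CommunityArchetype(
    "HMA",
    {
        "Chloroflexi": 0.26, "Proteobacteria": 0.20, "Acidobacteria": 0.16,
        "Actinobacteria": 0.14, "Poribacteria": 0.09, "Gemmatimonadetes": 0.07,
        "Thaumarchaeota": 0.05, "Bacteroidetes": 0.03,
    },
    {
        "Chloroflexi": 40, "Proteobacteria": 35, "Acidobacteria": 25,
        "Actinobacteria": 25, "Poribacteria": 15, "Gemmatimonadetes": 12,
        "Thaumarchaeota": 6, "Bacteroidetes": 8,
    },
)

LMA_ARCHETYPE = CommunityArchetype(
    "LMA",
    {
        "Thaumarchaeota": 0.75, "Proteobacteria": 0.14,
        "Bacteroidetes": 0.06, "Cyanobacteria": 0.05,
    },
    {"Thaumarchaeota": 4, "Proteobacteria": 6, "Bacteroidetes": 4, "Cyanobacteria": 3},
)

_ARCHAEAL_PHYLA = {"Thaumarchaeota", "Crenarchaeota", "Euryarchaeota"}


def _lineage(phylum: str, k: int) -> str:
    domain = "Archaea" if phylum in _ARCHAEAL_PHYLA else "Bacteria"
    return (
        f"d__{domain}; p__{phylum}; c__{phylum}_c{k % 3}; o__{phylum}_o{k % 5}; "
        f"f__{phylum}_f{k}; g__{phylum}_g{k}; s__"
    )


def simulate_asv_table(
    archetype: CommunityArchetype,
    n_samples: int,
    depth: int,
    seed: int,
    dirichlet_concentration: float = 500.0,
) -> pd.DataFrame:
    """Multinomial ASV counts from Dirichlet-perturbed archetype weights.

    Returns an ASV x sample DataFrame with a 7-rank ``taxonomy`` lineage
    column; every sample column sums exactly to ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    asv_ids, taxonomies, base_weights = [], [], []
    for phylum, weight in archetype.phylum_weights.items():
        n_asv = archetype.richness[phylum]
        raw = rng.lognormal(0.0, 0.8, n_asv)
        raw = raw / raw.sum() * weight
        for k, w in enumerate(raw):
            asv_ids.append(f"{archetype.name}_{phylum}_asv{k}")
            taxonomies.append(_lineage(phylum, k))
            base_weights.append(float(w))
    base = np.asarray(base_weights)
    data = {}
    for s in range(n_samples):
        alpha = base * dirichlet_concentration
        probs = rng.dirichlet(np.clip(alpha, 1e-6, None))
        data[f"{archetype.name}_s{s}"] = rng.multinomial(depth, probs)
    df = pd.DataFrame(data, index=asv_ids)
    df["taxonomy"] = taxonomies
    return df


# ---------------------------------------------------------------------------
# metagenome


@dataclass
class PlantedMetagenome:
    bins: list[BinRecord]
    positive_bin_id: str


def simulate_metagenome(n_bins: int, seed: int) -> PlantedMetagenome:
    """Metagenome bins with GC/coverage structure and one planted positive.

    The positive bin carries a sterol-biosynthesis locus (>= 2 distinct
    sterol categories clustered on one scaffold) and a glycosyltransferase
    locus (HexNAc- plus hexose/pentose-transferase genes) on a *different*
    scaffold. Decoy bins carry glycosyltransferase hits only, partial sterol
    hits only, or unannotated housekeeping genes, so exactly one bin passes
    the default co-occurrence screen.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    rng = np.random.default_rng(seed)
    gc_centroids = np.linspace(0.32, 0.68, n_bins)
    rng.shuffle(gc_centroids)
    cov_centroids = rng.lognormal(3.5, 0.7, n_bins) + 5.0
    positive_idx = int(rng.integers(0, n_bins))
    bins: list[BinRecord] = []
    for b in range(n_bins):
        bin_id = f"bin{b:03d}"
        n_scaf = int(rng.integers(4, 9))
        scaffolds = []
        for s in range(n_scaf):
            scaffolds.append(
                Scaffold(
                    f"{bin_id}_scaf{s}",
                    int(rng.integers(30_000, 150_000)),
                    float(np.clip(gc_centroids[b] + rng.normal(0.0, 0.008), 0.0, 1.0)),
                    float(cov_centroids[b] * rng.lognormal(0.0, 0.05)),
                )
            )
        genes: list[Gene] = []

        def place(scaffold: Scaffold, start: int, patterns: Sequence[str], tag: str) -> int:
            length = int(rng.integers(900, 2400))
            end = min(start + length, scaffold.length)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(f"{bin_id}_{tag}", scaffold.scaffold_id, start, end, strand,
                     frozenset(patterns))
            )
            return end + int(rng.integers(200, 2500))

        if b == positive_idx:
            taxon = "gamma-proteobacterium"
            # msb-like sterol locus on scaffold 0
            pos = int(rng.integers(1, 3000))
            for k, pat in enumerate(("PF00494", "PF08491", "PF13243", "SterolRed")):
                pos = place(scaffolds[0], pos, [pat], f"msb{k}")
            # mgb-like glycosyl locus on a different scaffold
            pos = int(rng.integers(1, 3000))
            for k, pat in enumerate(
                ("CAZy:GT_HexNAc", "CAZy:GT_HexNAc", "CAZy:GT_HexPen", "PF00535")
            ):
                pos = place(scaffolds[1], pos, [pat], f"mgb{k}")
        else:
            taxon = f"taxon_{b}"
            decoy_kind = b % 3
            pos = int(rng.integers(1, 5000))
            if decoy_kind == 0:
                # glycosyltransferase-rich, but at most one sterol category
                for k in range(int(rng.integers(2, 6))):
                    pat = ("CAZy:GT_HexNAc", "CAZy:GT_HexPen", "PF00535")[k % 3]
                    pos = place(scaffolds[0], pos, [pat], f"gt{k}")
                if rng.random() < 0.5:
                    place(scaffolds[-1], int(rng.integers(1, 5000)), ["PF00494"], "st0")
            elif decoy_kind == 1:
                # multiple sterol categories, but missing the HexNAc GT category
                pos = place(scaffolds[0], pos, ["PF00494"], "st0")
                pos = place(scaffolds[0], pos, ["PF08491"], "st1")
                if rng.random() < 0.5:
                    place(scaffolds[-1], int(rng.integers(1, 5000)),
                          ["CAZy:GT_HexPen"], "gt0")
            # decoy_kind == 2: housekeeping only
        for k in range(int(rng.integers(2, 6))):
            scaf = scaffolds[int(rng.integers(0, len(scaffolds)))]
            place(scaf, int(rng.integers(1, scaf.length // 2)), [], f"hk{k}")
        bins.append(BinRecord(bin_id, taxon, scaffolds, genes))
    return PlantedMetagenome(bins, f"bin{positive_idx:03d}")


def write_manifest(path: str | Path, seed: int, parameters: Mapping) -> None:
    """Record the seed and generator parameters of a synthetic dataset."""
    manifest = {
        "seed": int(seed),
        "parameters": dict(parameters),
        "notes": (
            "Fragment intensity tiers and melophlin heterocycle ion masses are "
            "generator model choices, not literature values."
        ),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
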