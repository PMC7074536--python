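"""Co-occurrence mining of metagenome bins for joint sterol-biosynthesis and
glycosyltransferase capacity.

Operates on pre-computed bin tables (scaffold stats plus gene -> domain
pattern hits; HMM searching itself is upstream). The screen asks whether a
single bin — i.e. a single microbial taxon — carries multiple distinct
sterol-pathway domain categories together with both required
glycosyltransferase categories, the genomic signature expected of a symbiont
producing glycosylated sterols. Candidate bins are then examined with a
locus report that groups qualifying genes into clusters per scaffold.

The default category map uses the PFAM patterns for the sterol pathway
(PF00494 squalene synthase, PF08491 squalene epoxidase, PF13243/PF13249
squalene cyclase) plus configurable placeholder ids for sterol reductase /
demethylase and the CAZy-style HexNAc and hexose/pentose transferase
categories, which have no canonical single pattern id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class Scaffold:
    scaffold_id: str
    length: int
    gc: float  # fraction in [0, 1]
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("GC must be a fraction in [0,1]")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    scaffold_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    patterns: frozenset = frozenset()


@dataclass
class BinRecord:
    bin_id: str
    taxon: str = ""
    scaffolds: list[Scaffold] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {s.scaffold_id: s.length for s in self.scaffolds}
        for g in self.genes:
            if g.scaffold_id in lengths and not (1 <= g.start <= g.end <= lengths[g.scaffold_id]):
                raise ValueError(f"gene {g.gene_id} outside scaffold {g.scaffold_id}")


#: Sterol-pathway category names recognized by the default criterion.
STEROL_CATEGORIES = (
    "squalene_synthase",
    "squalene_epoxidase",
    "squalene_cyclase",
    "sterol_reductase",
    "sterol_demethylase",
)

#: Default category -> pattern-id map. CAZy-style and the reductase/
#: demethylase ids are placeholders, user-configurable.
DEFAULT_CATEGORY_MAP: dict[str, frozenset] = {
    "squalene_synthase": frozenset({"PF00494"}),
    "squalene_epoxidase": frozenset({"PF08491"}),
    "squalene_cyclase": frozenset({"PF13243", "PF13249"}),
    "sterol_reductase": frozenset({"SterolRed"}),
    "sterol_demethylase": frozenset({"SterolDem"}),
    "glycosyltransferase": frozenset({"PF00535"}),
    "hexnac_transferase": frozenset({"CAZy:GT_HexNAc"}),
    "hexose_pentose_transferase": frozenset({"CAZy:GT_HexPen"}),
}


@dataclass(frozen=True)
class MiningCriterion:
    """Joint-capacity screen: >= N distinct sterol categories plus every
    required glycosyltransferase category present in one bin."""

    required_sterol_categories_min: int = 2
    required_gt_categories: frozenset = frozenset(
        {"hexnac_transferase", "hexose_pentose_transferase"}
    )

    def __post_init__(self) -> None:
        if self.required_sterol_categories_min < 1:
            raise ValueError("required_sterol_categories_min must be >= 1")


def count_by_category(
    bins: Sequence[BinRecord],
    category_map: Mapping[str, frozenset] = DEFAULT_CATEGORY_MAP,
) -> pd.DataFrame:
    """Category x bin gene-hit counts, plus a metagenome-wide 'total' column.

    A gene is counted once per category it matches (a gene carrying patterns
    from two categories contributes to both).
    """
    data = {}
    for b in bins:
        col = {}
        for cat, patterns in category_map.items():
            col[cat] = sum(1 for g in b.genes if g.patterns & patterns)
        data[b.bin_id] = col
    df = pd.DataFrame(data, index=list(category_map)).fillna(0).astype(int)
    df["total"] = df.sum(axis=1)
    return df


def screen_bins(
    bins: Sequence[BinRecord],
    category_map: Mapping[str, frozenset] = DEFAULT_CATEGORY_MAP,
    criterion: MiningCriterion = MiningCriterion(),
) -> list[str]:
    """Bins satisfying the joint sterol + glycosyltransferase criterion.

    Sorted by total qualifying hits, descending (ties by bin id).
    """
    counts = count_by_category(bins, category_map)
    sterol_cats = [c for c in STEROL_CATEGORIES if c in counts.index]
    passed = []
    for b in bins:
        col = counts[b.bin_id]
        n_sterol = sum(1 for c in sterol_cats if col[c] > 0)
        gt_ok = all(
            c in counts.index and col[c] > 0 for c in criterion.required_gt_categories
        )
        if n_sterol >= criterion.required_sterol_categories_min and gt_ok:
            qualifying = sum(col[c] for c in sterol_cats) + sum(
                col[c] for c in criterion.required_gt_categories if c in counts.index
            )
            passed.append((-qualifying, b.bin_id))
    passed.sort()
    return [bid for _, bid in passed]


@dataclass
class Locus:
    scaffold_id: str
    genes: list[Gene]
    categories: list[str]

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))


@dataclass
class LocusReport:
    bin_id: str
    loci: list[Locus]
    dispersed: list[tuple[Gene, list[str]]]

    def to_text(self) -> str:
        lines = [f"bin {self.bin_id}"]
        for k, loc in enumerate(self.loci):
            lo, hi = loc.span
            lines.append(f"  locus {k + 1} on {loc.scaffold_id} [{lo}-{hi}]")
            for g, cats in zip(loc.genes, loc.categories):
                lines.append(f"    {g.gene_id} ({g.strand}) {g.start}-{g.end}: {cats}")
        for g, cats in self.dispersed:
            lines.append(f"  dispersed {g.gene_id} on {g.scaffold_id}: {','.join(cats)}")
        return "\n".join(lines)


def _categories_of(gene: Gene, category_map: Mapping[str, frozenset]) -> list[str]:
    return sorted(c for c, pats in category_map.items() if gene.patterns & pats)


def locus_report(
    b: BinRecord,
    category_map: Mapping[str, frozenset] = DEFAULT_CATEGORY_MAP,
    window: int = 20_000,
) -> LocusReport:
    """Group a bin's qualifying genes into loci per scaffold.

    Genes matching any mapped category are sorted along each scaffold and
    chained into one locus while consecutive genes are <= ``window`` bp
    apart; runs of >= 2 genes are reported as loci, lone genes as dispersed.
    """
    qualifying = [
        (g, _categories_of(g, category_map)) for g in b.genes if _categories_of(g, category_map)
    ]
    by_scaffold: dict[str, list[tuple[Gene, list[str]]]] = {}
    for g, cats in qualifying:
        by_scaffold.setdefault(g.scaffold_id, []).append((g, cats))
    loci: list[Locus] = []
    dispersed: list[tuple[Gene, list[str]]] = []
    for scaffold_id in sorted(by_scaffold):
        entries = sorted(by_scaffold[scaffold_id], key=lambda e: e[0].start)
        run: list[tuple[Gene, list[str]]] = []
        for entry in entries:
            if run and entry[0].start - run[-1][0].end > window:
                _flush(run, scaffold_id, loci, dispersed)
                run = []
            run.append(entry)
        _flush(run, scaffold_id, loci, dispersed)
    return LocusReport(b.bin_id, loci, dispersed)


def _flush(run, scaffold_id, loci, dispersed) -> None:
    if not run:
        return
    if len(run) >= 2:
        loci.append(
            Locus(scaffold_id, [g for g, _ in run], [",".join(c) for _, c in run])
        )
    else:
        dispersed.append(run[0])


def bin_scatter_table(bins: Sequence[BinRecord]) -> pd.DataFrame:
    """Flat table (scaffold, GC%, coverage, bin) for a coverage vs %GC plot."""
    rows = [
        {
            "scaffold": s.scaffold_id,
            "gc_percent": 100.0 * s.gc,
            "coverage": s.coverage,
            "bin": b.bin_id,
        }
        for b in bins
        for s in b.scaffolds
    ]
    return pd.DataFrame(rows, columns=["scaffold", "gc_percent", "coverage", "bin"])


# ---------------------------------------------------------------------------
# IO: one gene per row TSV + scaffold TSV


def write_bins(bins: Sequence[BinRecord], gene_path: str | Path, scaffold_path: str | Path) -> None:
    gene_rows = [
        {
            "bin": b.bin_id, "scaffold": g.scaffold_id, "gene": g.gene_id,
            "start": g.start, "end": g.end, "strand": g.strand,
            "patterns": ";".join(sorted(g.patterns)),
        }
        for b in bins for g in b.genes
    ]
    pd.DataFrame(gene_rows).to_csv(gene_path, sep="\t", index=False)
    scaf_rows = [
        {
            "bin": b.bin_id, "taxon": b.taxon, "scaffold": s.scaffold_id,
            "length": s.length, "gc": s.gc, "coverage": s.coverage,
        }
        for b in bins for s in b.scaffolds
    ]
    pd.DataFrame(scaf_rows).to_csv(scaffold_path, sep="\t", index=False, float_format="%.6f")


def read_bins(gene_path: str | Path, scaffold_path: str | Path) -> list[BinRecord]:
    genes_df = pd.read_csv(gene_path, sep="\t")
    scafs_df = pd.read_csv(scaffold_path, sep="\t")
    bins: dict[str, BinRecord] = {}
    for _, r in scafs_df.iterrows():
        b = bins.setdefault(str(r["bin"]), BinRecord(str(r["bin"]), str(r.get("taxon", ""))))
        b.scaffolds.append(
            Scaffold(str(r["scaffold"]), int(r["length"]), float(r["gc"]), float(r["coverage"]))
        )
    for _, r in genes_df.iterrows():
        pats = frozenset(str(r["patterns"]).split(";")) if pd.notna(r["patterns"]) and str(r["patterns"]) else frozenset()
        b = bins.setdefault(str(r["bin"]), BinRecord(str(r["bin"])))
        b.genes.append(
            Gene(str(r["gene"]), str(r["scaffold"]), int(r["start"]), int(r["end"]),
                 str(r["strand"]), pats)
        )
    return [bins[k] for k in sorted(bins)]
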