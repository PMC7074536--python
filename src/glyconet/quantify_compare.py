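"""Quantitative comparison layers: congener heatmaps, feature overlap,
volcano statistics, and microbiome diversity summaries.

Conventions:

* Congener abundance heatmaps are on a negative log10 scale of family-
  normalized EIC areas (each natural-product family normalized to its own
  maximum), with absent congeners assigned a fixed sentinel of 6 — chosen
  above the dynamic range of detected congeners so that absence sorts beyond
  the least abundant detected value.
* Shannon diversity is reported in bits (log base 2).
* The two-group volcano applies inter-quartile-range filtering and pareto
  scaling before an unequal-variance t-test; fold changes are computed on
  unscaled group means. p-values are uncorrected by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .feature_pipeline import AlignedFeatureTable

ABSENT_SENTINEL = 6.0


def congener_heatmap(
    areas: pd.DataFrame,
    family: Mapping[str, str],
    sentinel: float = ABSENT_SENTINEL,
) -> pd.DataFrame:
    """Negative-log10 family-normalized abundance matrix (congener x sample).

    Within each family, areas are divided by the family's maximum over the
    whole matrix; -log10 is applied; zero/absent cells get the sentinel and
    all values are capped at the sentinel. The most abundant congener of each
    family therefore maps to 0.
    """
    if (areas.values < 0).any():
        raise ValueError("areas must be >= 0")
    out = pd.DataFrame(
        np.full(areas.shape, float(sentinel)), index=areas.index, columns=areas.columns
    )
    fam_series = pd.Series({c: family[c] for c in areas.index})
    for fam in fam_series.unique():
        rows = fam_series.index[fam_series == fam]
        block = areas.loc[rows]
        fam_max = block.values.max()
        if fam_max <= 0:
            warnings.warn(f"family {fam!r} has no nonzero areas; all cells set to sentinel")
            continue
        norm = block / fam_max
        with np.errstate(divide="ignore"):
            vals = -np.log10(norm.values)
        vals = np.where(np.isfinite(vals), np.minimum(vals, sentinel), sentinel)
        out.loc[rows] = vals
    return out


@dataclass
class OverlapSummary:
    """Partition of features by the set of groups they are present in."""

    counts: dict[frozenset, int]
    total: int

    def percentages(self, decimals: int = 1) -> dict[frozenset, float]:
        return {k: round(100.0 * v / self.total, decimals) for k, v in self.counts.items()}

    def shared_all(self) -> int:
        full = frozenset().union(*self.counts.keys()) if self.counts else frozenset()
        return self.counts.get(full, 0)


def feature_overlap(
    table: AlignedFeatureTable, groups: Mapping[str, Sequence[str]]
) -> OverlapSummary:
    """Count features by presence pattern across sample groups.

    A feature is present in a group when it has nonzero area in at least one
    of the group's samples. The returned counts partition the features over
    nonempty subsets of groups.
    """
    for g, samples in groups.items():
        if not samples:
            raise ValueError(f"group {g!r} is empty")
    counts: dict[frozenset, int] = {}
    total = 0
    for f in table.features:
        present = frozenset(
            g for g, samples in groups.items()
            if any(f.areas.get(s, 0.0) > 0 for s in samples)
        )
        if not present:
            continue
        total += 1
        counts[present] = counts.get(present, 0) + 1
    return OverlapSummary(counts, total)


def pareto_scale(x: np.ndarray) -> np.ndarray:
    """Mean-center a vector and divide by the square root of its SD."""
    sd = np.std(x, ddof=1)
    centered = x - np.mean(x)
    if sd == 0:
        return centered
    return centered / np.sqrt(sd)


def iqr_filter(matrix: pd.DataFrame, drop_fraction: float = 0.25) -> pd.DataFrame:
    """Drop the lowest-variability features (bottom quantile of IQR across samples)."""
    if drop_fraction <= 0 or matrix.empty:
        return matrix
    iqr = matrix.apply(lambda row: np.subtract(*np.percentile(row, [75, 25])), axis=1)
    cutoff = iqr.quantile(drop_fraction)
    return matrix.loc[iqr > cutoff]


@dataclass
class VolcanoResult:
    table: pd.DataFrame  # columns: feature, fold_change, p_value, klass

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["klass"] != "ns"]


def volcano(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 3.0,
    alpha: float = 0.05,
    iqr_drop_fraction: float = 0.25,
) -> VolcanoResult:
    """Two-group feature comparison (fold change vs p-value).

    ``matrix`` is feature x sample areas. After IQR filtering and per-feature
    pareto scaling, a two-sided Welch t-test compares the groups; fold change
    is the ratio of unscaled group means (group_a / group_b). Classes:
    ``up`` when FC >= threshold and p <= alpha, ``down`` when FC <=
    1/threshold and p <= alpha, otherwise ``ns``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >=2 replicates per group")
    cols = list(group_a) + list(group_b)
    sub = matrix[cols]
    sub = iqr_filter(sub, iqr_drop_fraction)
    rows = []
    for feat, row in sub.iterrows():
        a = row[list(group_a)].to_numpy(float)
        b = row[list(group_b)].to_numpy(float)
        scaled = pareto_scale(np.concatenate([a, b]))
        sa, sb = scaled[: len(a)], scaled[len(a):]
        if np.std(a) == 0 and np.std(b) == 0:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.ttest_ind(sa, sb, equal_var=False).pvalue)
            if not np.isfinite(p):
                p = 1.0
        mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
        if mean_b == 0:
            fc = np.inf if mean_a > 0 else 1.0
        else:
            fc = mean_a / mean_b
        if fc >= fc_threshold and p <= alpha:
            klass = "up"
        elif fc <= 1.0 / fc_threshold and p <= alpha:
            klass = "down"
        else:
            klass = "ns"
        rows.append({"feature": feat, "fold_change": fc, "p_value": p, "klass": klass})
    return VolcanoResult(
        pd.DataFrame(rows, columns=["feature", "fold_change", "p_value", "klass"])
    )


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i log2 p_i, in bits."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be >= 0")
    total = arr.sum()
    if total <= 0:
        raise ValueError("counts must sum to > 0")
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum())


def extract_phylum(lineage: str) -> str:
    """Pull the phylum rank out of a semicolon-joined 7-rank lineage string."""
    for tok in str(lineage).split(";"):
        tok = tok.strip()
        if tok.startswith("p__"):
            return tok[3:] or "unclassified"
    return "unclassified"


def phylum_table(asv: pd.DataFrame, taxonomy_col: str = "taxonomy") -> pd.DataFrame:
    """Aggregate an ASV count table (ASV x samples + taxonomy) to phylum level."""
    phyla = asv[taxonomy_col].map(extract_phylum)
    counts = asv.drop(columns=[taxonomy_col])
    return counts.groupby(phyla).sum()


def phylum_heatmap(asv: pd.DataFrame, taxonomy_col: str = "taxonomy") -> pd.DataFrame:
    """Phylum x sample matrix of -log10 within-sample relative abundances.

    Phyla with zero counts in a sample get a sentinel of (max finite value
    + 1) so they sort beyond every observed abundance. A sample with zero
    total reads is an error.
    """
    mat = phylum_table(asv, taxonomy_col)
    sums = mat.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"zero-read sample(s): {bad}")
    rel = mat / sums
    with np.errstate(divide="ignore"):
        vals = -np.log10(rel.values)
    finite = vals[np.isfinite(vals)]
    sentinel = (finite.max() if finite.size else 0.0) + 1.0
    vals = np.where(np.isfinite(vals), vals, sentinel)
    return pd.DataFrame(vals, index=mat.index, columns=mat.columns)


def shannon_per_sample(asv: pd.DataFrame, taxonomy_col: str = "taxonomy") -> pd.Series:
    """Shannon diversity (bits) per sample column of an ASV table."""
    counts = asv.drop(columns=[taxonomy_col]) if taxonomy_col in asv else asv
    return counts.apply(lambda col: shannon(col.to_numpy(float)), axis=0)
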