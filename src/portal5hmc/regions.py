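"""Build and annotate the analysis region set from per-sample peaks.

Peaks are merged with 0-gap semantics (overlapping or abutting intervals
collapse), retained when supported by strictly more than ``min_samples``
samples and strictly narrower than ``max_width`` bp, and annotated against
gene models with the fixed feature priority
promoter > exon > intron > downstream > intergenic, where the promoter is
the +/- 2 kb window around the TSS (any overlap wins) and body/downstream
assignment uses the region midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CountMatrix, GeneModel, GenomicRegion

FEATURE_PRIORITY = ("promoter", "exon", "intron", "downstream", "intergenic")


@dataclass(frozen=True)
class MergedRegion:
    region: GenomicRegion
    support: int  # number of samples contributing >=1 peak

    @property
    def width(self) -> int:
        return self.region.width


@dataclass(frozen=True)
class AnnotatedRegion:
    region: GenomicRegion
    feature: str
    nearest_gene: str | None
    tss_distance: int | None  # signed: midpoint - TSS, strand-oriented


def merge_peaks(peaks_by_sample: Mapping[str, Sequence[GenomicRegion]]) -> list[MergedRegion]:
    """Merge per-sample peak lists into disjoint regions with support counts.

    The union of all intervals is partitioned into maximal
    overlapping-or-abutting runs (0-gap merge, bedtools default); support is
    the number of distinct samples contributing at least one peak to the run.
    """
    events: list[tuple[str, int, int, str]] = []
    for sample, peaks in peaks_by_sample.items():
        for p in peaks:
            events.append((p.chrom, p.start, p.end, sample))
    events.sort(key=lambda t: (t[0], t[1], t[2]))

    merged: list[MergedRegion] = []
    cur = None  # (chrom, start, end, sample set)
    for chrom, start, end, sample in events:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur = (chrom, cur[1], max(cur[2], end), cur[3] | {sample})
        else:
            if cur is not None:
                merged.append(_finish(cur, len(merged)))
            cur = (chrom, start, end, {sample})
    if cur is not None:
        merged.append(_finish(cur, len(merged)))
    return merged


def _finish(cur, idx: int) -> MergedRegion:
    chrom, start, end, samples = cur
    return MergedRegion(
        GenomicRegion(chrom, start, end, f"merged_{idx:06d}"), len(samples)
    )


def filter_regions(merged: Sequence[MergedRegion], min_samples: int = 10,
                   max_width: int = 1000,
                   blacklist: Sequence[GenomicRegion] = ()) -> list[MergedRegion]:
    """Retain regions that appeared in more than ``min_samples`` samples and
    are less than ``max_width`` bp wide (both strict), excluding any region
    overlapping the blacklist by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for b in blacklist:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end)
    out = []
    for m in merged:
        if m.support <= min_samples or m.width >= max_width:
            continue
        tree = trees.get(m.region.chrom)
        if tree is not None and tree.overlap(m.region.start, m.region.end):
            continue
        out.append(m)
    return out


def annotate_regions(regions: Sequence[GenomicRegion], genes: Sequence[GeneModel],
                     promoter_halfwidth: int = 2000,
                     downstream_extent: int = 3000) -> list[AnnotatedRegion]:
    """Assign one genomic feature per region.

    Priority: promoter (any overlap with [TSS-hw, TSS+hw)) > exon > intron >
    downstream (midpoint within ``downstream_extent`` bp past the TTS) >
    intergenic. Body labels use the region midpoint. The nearest gene
    minimizes |midpoint - TSS|, ties broken by gene name; the reported
    tss_distance is signed along the gene's strand (positive = downstream of
    the TSS).
    """
    if not genes:
        return [AnnotatedRegion(r, "intergenic", None, None) for r in regions]

    promoter_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    down_trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for g in genes:
        lo = max(0, g.tss - promoter_halfwidth)
        promoter_trees.setdefault(g.chrom, IntervalTree()).addi(lo, g.tss + promoter_halfwidth, g)
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        if g.strand == "+":
            down_trees.setdefault(g.chrom, IntervalTree()).addi(g.end, g.end + downstream_extent, g)
        elif g.start > 0:
            down_trees.setdefault(g.chrom, IntervalTree()).addi(
                max(0, g.start - downstream_extent), g.start, g)
        tss_by_chrom.setdefault(g.chrom, ([], []))[1].append(g)
    for chrom, (_, gl) in list(tss_by_chrom.items()):
        gl.sort(key=lambda g: (g.tss, g.name))
        tss_by_chrom[chrom] = (np.array([g.tss for g in gl]), gl)

    out = []
    for r in regions:
        mid = r.midpoint
        feature = "intergenic"
        if r.chrom in promoter_trees and promoter_trees[r.chrom].overlap(r.start, r.end):
            feature = "promoter"
        else:
            hits = gene_trees.get(r.chrom, IntervalTree())[mid]
            if hits:
                g = min((h.data for h in hits), key=lambda g: g.name)
                in_exon = any(s <= mid < e for s, e in g.exons)
                feature = "exon" if in_exon else "intron"
            elif r.chrom in down_trees and down_trees[r.chrom][mid]:
                feature = "downstream"

        nearest, dist = None, None
        if r.chrom in tss_by_chrom:
            tss_arr, gl = tss_by_chrom[r.chrom]
            i = int(np.searchsorted(tss_arr, mid))
            cands = [gl[j] for j in (i - 1, i, i + 1) if 0 <= j < len(gl)]
            nearest = min(cands, key=lambda g: (abs(mid - g.tss), g.name))
            raw = mid - nearest.tss
            dist = int(raw if nearest.strand == "+" else -raw)
            nearest = nearest.name
        out.append(AnnotatedRegion(r, feature, nearest, dist))
    return out


def feature_distribution(annotated: Sequence[AnnotatedRegion]) -> pd.DataFrame:
    """Counts and proportions per feature label (proportions sum to 1)."""
    if not annotated:
        raise ValueError("no annotated regions")
    counts = pd.Series([a.feature for a in annotated]).value_counts()
    counts = counts.reindex([f for f in FEATURE_PRIORITY if f in counts.index])
    return pd.DataFrame(
        {"count": counts, "proportion": counts / counts.sum()}
    ).rename_axis("feature")


def fpkm(counts: CountMatrix, regions: Sequence[GenomicRegion]) -> pd.DataFrame:
    """Fragments per kilobase of region per million mapped reads:
    FPKM_ij = count_ij / (width_i/1e3) / (library_size_j/1e6)."""
    widths = {}
    for r in regions:
        rid = r.name.split("|")[0]
        widths[rid] = r.width
    missing = [rid for rid in counts.region_ids if rid not in widths]
    if missing:
        raise ValueError(f"no width known for region(s) {missing[:3]}")
    w = np.array([widths[rid] for rid in counts.region_ids], dtype=float)
    if (w <= 0).any():
        raise ValueError("zero-width region")
    ls = counts.library_sizes.to_numpy(dtype=float)
    if (ls <= 0).any():
        raise ValueError("zero library size")
    mat = counts.counts.to_numpy(dtype=float) / (w[:, None] / 1e3) / (ls[None, :] / 1e6)
    return pd.DataFrame(mat, index=counts.counts.index, columns=counts.counts.columns)


def rpm(value, library_size):
    """Reads per million mapped reads."""
    library_size = np.asarray(library_size, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library size must be positive")
    return np.asarray(value, dtype=float) / (library_size / 1e6)
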