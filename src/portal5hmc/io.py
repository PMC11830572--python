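"""Readers and writers for the interval and table formats used throughout.

All coordinates are 0-based half-open internally (BED convention). Writers
emit LF line endings and deterministic ordering so that runs with the same
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUP_LABELS = ("PC", "MLM", "SLM")
COMPARTMENT_LABELS = ("PVB", "PB", "PT", "PN", "SPT", "SPN", "SMT", "SMN", "MPT", "MPN")


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open interval on a named chromosome; the unit of 5hmC
    quantification (an hMR)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative coordinate in region {self.name!r}")
        if self.start >= self.end:
            raise ValueError(
                f"region {self.name!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with ordered disjoint exon blocks.

    The TSS is ``start`` on the + strand and ``end - 1`` on the - strand;
    the TTS is the opposite extremity.
    """

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.name!r}: needs >=1 exon")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.name!r}: exon [{s},{e}) outside gene")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.name!r}: exons overlap or unordered")
            prev_end = e
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise ValueError(
                f"gene {self.name!r}: first exon must start at gene start and "
                "last exon end at gene end"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass
class CountMatrix:
    """Regions x samples non-negative integer read counts plus per-sample
    library sizes (total mapped reads; may exceed in-region totals)."""

    counts: pd.DataFrame  # regions x samples, integer
    library_sizes: pd.Series  # per sample, positive integer

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate region ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative count in count matrix")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes[self.library_sizes.isna()].index.tolist()
            raise ValueError(f"missing library sizes for samples {missing}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_regions(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)], self.library_sizes.copy())

    def subset_samples(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(ids)], self.library_sizes.loc[list(ids)])


@dataclass
class CoverageTrack:
    """Piecewise-constant genome coverage: per chromosome, sorted disjoint
    intervals with real values; gaps have value 0."""

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    # chrom -> (starts, ends, values), sorted, non-overlapping

    def __post_init__(self):
        self._cum = {}
        for chrom, (s, e, v) in self.intervals.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            if np.any(e <= s):
                raise ValueError(f"{chrom}: empty or inverted interval")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: overlapping or unsorted intervals")
            self.intervals[chrom] = (s, e, v)
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(v * (e - s))])

    def _integral_to(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, x) for each x (vectorized)."""
        if chrom not in self.intervals:
            return np.zeros_like(np.asarray(x, dtype=float))
        s, e, v = self.intervals[chrom]
        cum = self._cum[chrom]
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(s, x, side="right") - 1  # last interval starting <= x
        out = np.where(i >= 0, cum[np.maximum(i, 0)], 0.0)
        inside = (i >= 0) & (x < e[np.maximum(i, 0)])
        out = out + np.where(
            inside, v[np.maximum(i, 0)] * (x - s[np.maximum(i, 0)]), 0.0
        )
        full = (i >= 0) & ~inside
        out = np.where(full, cum[np.maximum(i, 0) + 1], out)
        return out

    def mean(self, chrom: str, start, end) -> np.ndarray:
        """Mean per-bp coverage over [start, end), vectorized over bins."""
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        width = end - start
        if np.any(width <= 0):
            raise ValueError("empty query interval")
        return (self._integral_to(chrom, end) - self._integral_to(chrom, start)) / width

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self.intervals:
            return 0.0
        s, e, v = self.intervals[chrom]
        i = np.searchsorted(s, pos, side="right") - 1
        if i >= 0 and pos < e[i]:
            return float(v[i])
        return 0.0


# ---------------------------------------------------------------------------
# BED3/BED6


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def _skippable(line: str) -> bool:
    ls = line.strip()
    return not ls or ls.startswith("#") or ls.startswith(("track", "browser"))


def read_bed(path) -> list[GenomicRegion]:
    """Read BED3/BED6; missing names auto-assigned ``chrom:start-end``.

    Returns regions sorted by (chrom, start, end).
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _skippable(line):
                continue
            f = _split_fields(line)
            if len(f) < 3:
                raise ParseError(path, lineno, f"expected >=3 tab-separated fields, got {len(f)}")
            chrom = f[0]
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinate {f[1]!r}/{f[2]!r}") from None
            if start < 0:
                raise ParseError(path, lineno, f"negative coordinate {start}")
            if start >= end:
                raise ParseError(path, lineno, f"start {start} >= end {end}")
            name = f[3] if len(f) > 3 and f[3] not in ("", ".") else f"{chrom}:{start}-{end}"
            score = 0.0
            if len(f) > 4 and f[4] not in ("", "."):
                try:
                    score = float(f[4])
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric score {f[4]!r}") from None
            strand = f[5] if len(f) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(path, lineno, f"invalid strand {strand!r}")
            regions.append(GenomicRegion(chrom, start, end, name, score, strand))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end, r.name))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path) -> None:
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.name))
    with open(path, "w", newline="\n") as fh:
        for r in regions:
            score = f"{r.score:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# BED12 gene models


def read_gene_models(path) -> list[GeneModel]:
    """Read BED12 gene models, expanding block starts/sizes into exons."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _skippable(line):
                continue
            f = _split_fields(line)
            if len(f) < 12:
                raise ParseError(path, lineno, f"expected 12 fields for BED12, got {len(f)}")
            chrom, name, strand = f[0], f[3], f[5]
            try:
                start, end = int(f[1]), int(f[2])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(path, lineno, "non-integer BED12 field") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(path, lineno, "blockCount disagrees with blockSizes/blockStarts")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            if exons[-1][1] != end:
                raise ParseError(
                    path, lineno, f"last block ends at {exons[-1][1]}, not gene end {end}"
                )
            try:
                genes.append(GeneModel(chrom, start, end, name, strand, exons))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.name))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.name))
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Count matrix + sample table (TSV)


def read_count_matrix(path, libsize_path=None) -> CountMatrix:
    """Read a regions x samples TSV (first column = region id).

    Library sizes come from a sidecar TSV with columns ``sample`` and
    ``library_size``; when absent they default to the column totals.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate region id {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts")
    if (arr < 0).any():
        raise ValueError(f"{path}: negative count")
    df = df.astype(np.int64)
    if libsize_path is not None:
        ls = pd.read_csv(libsize_path, sep="\t")
        if ls.columns.tolist()[:2] != ["sample", "library_size"]:
            raise ValueError(f"{libsize_path}: expected columns 'sample', 'library_size'")
        libsizes = ls.set_index("sample")["library_size"].astype(np.int64)
    else:
        libsizes = df.sum(axis=0).clip(lower=1).astype(np.int64)
    return CountMatrix(df, libsizes)


def write_count_matrix(cm: CountMatrix, path, libsize_path=None) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="region", lineterminator="\n")
    if libsize_path is not None:
        pd.DataFrame(
            {"sample": cm.library_sizes.index, "library_size": cm.library_sizes.values}
        ).to_csv(libsize_path, sep="\t", index=False, lineterminator="\n")


def validate_sample_table(df: pd.DataFrame, path="<sample table>") -> pd.DataFrame:
    if "sample" in df.columns:
        df = df.set_index("sample")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    if "group" not in df.columns:
        raise ValueError(f"{path}: missing 'group' column")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"{path}: unknown group label(s) {sorted(bad)}; expected {GROUP_LABELS}")
    if "compartment" in df.columns:
        bad = set(df["compartment"].dropna()) - set(COMPARTMENT_LABELS)
        if bad:
            raise ValueError(f"{path}: unknown compartment label(s) {sorted(bad)}")
    for col in ("os_months", "efs_months"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValueError(f"{path}: negative value in {col}")
    for col in ("os_event", "efs_event"):
        if col in df.columns:
            vals = set(df[col].dropna().unique()) - {0, 1, True, False}
            if vals:
                raise ValueError(f"{path}: non-boolean event flag(s) {sorted(vals)} in {col}")
    return df


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV (index: sample id)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: missing 'sample' column")
    return validate_sample_table(df, path)


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample", lineterminator="\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path) -> CoverageTrack:
    """Read a bedGraph into a coverage track; intervals must be sorted and
    non-overlapping within each chromosome; gaps imply value 0."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _skippable(line):
                continue
            f = line.split()
            if len(f) < 4:
                raise ParseError(path, lineno, f"expected 4 fields, got {len(f)}")
            chrom = f[0]
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric bedGraph field") from None
            if start < 0 or start >= end:
                raise ParseError(path, lineno, f"invalid interval [{start},{end})")
            if chrom in last and start < last[chrom]:
                raise ParseError(path, lineno, "overlapping or unsorted intervals")
            last[chrom] = end
            per_chrom.setdefault(chrom, []).append((start, end, value))
    intervals = {}
    for chrom, rows in per_chrom.items():
        a = np.array(rows, dtype=float)
        intervals[chrom] = (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64), a[:, 2])
    return CoverageTrack(intervals)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom in sorted(track.intervals):
            s, e, v = track.intervals[chrom]
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")
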