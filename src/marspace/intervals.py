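"""Genomic peak sets: reading, filtering, annotation and proximity statistics.

Peaks are BED-style 0-based half-open intervals. A :class:`PeakSet` keeps
peaks sorted by start within each chromosome, which the overlap, subtraction
and spacing routines rely on. Feature annotation assigns every peak exactly
one category (promoter > exon > intron > intergenic) by the location of its
midpoint relative to a set of gene models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import DataError, LoadError

__all__ = [
    "Peak",
    "PeakSet",
    "GeneModel",
    "FeatureAnnotation",
    "read_peaks",
    "read_gene_models",
    "write_bed",
    "subtract_input_peaks",
    "count_overlap_and_proximal",
    "peak_length_stats",
    "annotate_features",
    "genes_per_condition",
]

FEATURE_CATEGORIES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class Peak:
    """A genomic interval, 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DataError(f"peak start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise DataError(
                f"peak end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class PeakSet:
    """An ordered collection of peaks for one experimental condition.

    Within each chromosome peaks are sorted by (start, end); iteration yields
    chromosomes in lexicographic order. Duplicate coordinates are retained.
    """

    def __init__(
        self,
        peaks: Iterable[Peak] = (),
        label: str = "",
        genome_id: str | None = None,
    ) -> None:
        self.label = label
        self.genome_id = genome_id
        self._by_chrom: dict[str, list[Peak]] = {}
        for p in peaks:
            self._by_chrom.setdefault(p.chrom, []).append(p)
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda p: (p.start, p.end))
        # cached start/end arrays for searchsorted queries
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[Peak]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def peaks_on(self, chrom: str) -> list[Peak]:
        return self._by_chrom.get(chrom, [])

    def _chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._arrays:
            peaks = self._by_chrom.get(chrom, [])
            self._arrays[chrom] = (
                np.array([p.start for p in peaks], dtype=np.int64),
                np.array([p.end for p in peaks], dtype=np.int64),
            )
        return self._arrays[chrom]

    def lengths(self) -> np.ndarray:
        return np.array([p.length for p in self], dtype=np.int64)


@dataclass(frozen=True)
class GeneModel:
    """A transcript model in refFlat-style coordinates (0-based half-open)."""

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    gene_name: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise DataError(f"gene {self.gene_name}: tx_end <= tx_start")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise DataError(f"gene {self.gene_name}: exon outside transcript")
            if prev_end is not None and s < prev_end:
                raise DataError(f"gene {self.gene_name}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on +, tx_end - 1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def promoter_window(self, up: int, down: int) -> tuple[int, int]:
        """Half-open promoter interval, `up` nt upstream to `down` nt downstream
        of the TSS, oriented by strand."""
        if self.strand == "+":
            return (self.tx_start - up, self.tx_start + down)
        return (self.tx_end - down, self.tx_end + up)


@dataclass(frozen=True)
class FeatureAnnotation:
    peak: Peak
    category: str
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise DataError(f"unknown category {self.category!r}")
        if (self.gene_name is None) != (self.category == "intergenic"):
            raise DataError("gene_name present iff category != intergenic")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, format: str = "bed", label: str | None = None) -> PeakSet:
    """Read a BED3/BED5/BED6 or ENCODE narrowPeak file into a PeakSet.

    Empty files yield an empty PeakSet. Malformed records (non-integer
    coordinates, end <= start) raise :class:`LoadError` naming the line.
    narrowPeak summit offsets (column 10) are read but ignored.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            min_cols = 10 if format == "narrowPeak" else 3
            if len(fields) < min_cols:
                raise LoadError(f"{path}:{lineno}: expected >= {min_cols} columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise LoadError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise LoadError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                peaks.append(Peak(fields[0], start, end, name=name, score=score))
            except DataError as exc:
                raise LoadError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(peaks, label=label if label is not None else path.stem)


def write_bed(peaks: PeakSet | Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED5 (name '.', score 0 when absent)."""
    with open(path, "w") as fh:
        for p in peaks:
            name = p.name if p.name is not None else "."
            score = p.score if p.score is not None else 0
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score:g}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-style gene table.

    Tab-separated columns: geneName, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds (comma-separated, trailing comma tolerated).
    """
    genes: list[GeneModel] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise LoadError(f"{path}:{lineno}: expected 7 columns")
            try:
                tx_start, tx_end = int(fields[3]), int(fields[4])
                starts = [int(x) for x in fields[5].strip(",").split(",") if x]
                ends = [int(x) for x in fields[6].strip(",").split(",") if x]
            except ValueError as exc:
                raise LoadError(f"{path}:{lineno}: non-integer coordinates") from exc
            if len(starts) != len(ends):
                raise LoadError(f"{path}:{lineno}: exonStarts/exonEnds mismatch")
            try:
                genes.append(
                    GeneModel(
                        chrom=fields[1],
                        strand=fields[2],
                        tx_start=tx_start,
                        tx_end=tx_end,
                        exons=tuple(zip(starts, ends)),
                        gene_name=fields[0],
                    )
                )
            except DataError as exc:
                raise LoadError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                f"{g.gene_name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                f"\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# Overlap / proximity machinery
# ---------------------------------------------------------------------------

def _min_gap_to(peak: Peak, other: PeakSet) -> int | None:
    """Edge-to-edge gap from `peak` to its nearest peak in `other` on the same
    chromosome; 0 or negative means >= 1 bp of shared overlap is possible.

    Returns None when `other` has no peaks on that chromosome. Half-open
    arithmetic: abutting intervals ([100,200) vs [200,300)) have gap 0 and do
    NOT overlap.
    """
    starts, ends = other._chrom_arrays(peak.chrom)
    if starts.size == 0:
        return None
    # overlap exists iff some interval has start < peak.end and end > peak.start
    idx = np.searchsorted(starts, peak.end, side="left")
    if idx > 0 and np.max(ends[:idx]) > peak.start:
        return -1  # overlapping
    # nearest on the right: starts[idx] (first with start >= peak.end)
    gaps = []
    if idx < starts.size:
        gaps.append(int(starts[idx] - peak.end))
    if idx > 0:
        gaps.append(int(peak.start - np.max(ends[:idx])))
    return min(gaps)


def subtract_input_peaks(sample: PeakSet, control: PeakSet) -> PeakSet:
    """Remove every sample peak sharing >= 1 bp with any control peak.

    This is the input-sample filter applied to immunoprecipitation peak calls:
    a single shared base suffices for removal. Idempotent.
    """
    survivors = []
    for p in sample:
        gap = _min_gap_to(p, control)
        if gap is None or gap >= 0:
            survivors.append(p)
    return PeakSet(survivors, label=sample.label, genome_id=sample.genome_id)


def count_overlap_and_proximal(
    a: PeakSet, b: PeakSet, proximity: int = 200
) -> tuple[int, int]:
    """Count a-peaks overlapping (>= 1 bp) a b-peak, and those merely proximal.

    A peak is proximal when it does not overlap but its nearest b-peak lies at
    an edge-to-edge gap <= `proximity` nt. The two categories are disjoint.
    """
    if proximity < 0:
        raise ValueError(f"proximity must be >= 0, got {proximity}")
    n_overlap = n_proximal = 0
    for p in a:
        gap = _min_gap_to(p, b)
        if gap is None:
            continue
        if gap < 0:
            n_overlap += 1
        elif gap <= proximity:
            n_proximal += 1
    return n_overlap, n_proximal


def peak_length_stats(p: PeakSet) -> tuple[float, float, int]:
    """Mean peak length, its standard error (sample sd / sqrt(n)) and n."""
    n = len(p)
    if n == 0:
        raise DataError("peak_length_stats requires at least one peak")
    lengths = p.lengths().astype(float)
    mean = float(lengths.mean())
    sem = 0.0 if n == 1 else float(lengths.std(ddof=1) / np.sqrt(n))
    return mean, sem, n


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------

def _classify_midpoint(
    mid: int, genes: Sequence[GeneModel], promoter_up: int, promoter_down: int
) -> tuple[str, str | None]:
    """Category of a single position, precedence promoter > exon > intron.

    Ties between genes in the same category break on (tx_start, gene_name)
    for determinism.
    """
    best: tuple[int, int, str] | None = None  # (category rank, tx_start, gene)
    rank = {"promoter": 0, "exon": 1, "intron": 2}
    for g in genes:
        ps, pe = g.promoter_window(promoter_up, promoter_down)
        if ps <= mid < pe:
            cat = "promoter"
        elif g.tx_start <= mid < g.tx_end:
            cat = "exon" if any(s <= mid < e for s, e in g.exons) else "intron"
        else:
            continue
        key = (rank[cat], g.tx_start, g.gene_name)
        if best is None or key < best:
            best = key
    if best is None:
        return "intergenic", None
    return FEATURE_CATEGORIES[best[0]], best[2]


def annotate_features(
    p: PeakSet,
    genes: Iterable[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 200,
) -> tuple[list[FeatureAnnotation], dict[str, float]]:
    """Assign each peak one genomic-feature category by its midpoint.

    Returns the per-peak annotations and a fraction table (percent of peaks
    per category, summing to 100).
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    annotations = []
    counts = dict.fromkeys(FEATURE_CATEGORIES, 0)
    for peak in p:
        cat, gene = _classify_midpoint(
            peak.midpoint, genes_by_chrom.get(peak.chrom, ()), promoter_up, promoter_down
        )
        annotations.append(FeatureAnnotation(peak, cat, gene))
        counts[cat] += 1
    n = max(len(annotations), 1)
    fractions = {cat: 100.0 * c / n for cat, c in counts.items()}
    return annotations, fractions


def genes_per_condition(
    annotations_by_condition: Mapping[str, Iterable[FeatureAnnotation]],
) -> dict:
    """Per-condition peak-associated gene sets and their Venn-style overlaps.

    Genes are those named by non-intergenic annotations. Returns per-condition
    sets and counts, all pairwise intersection counts, and the intersection of
    every condition.
    """
    if not annotations_by_condition:
        raise ValueError("at least one condition required")
    gene_sets = {
        cond: {a.gene_name for a in anns if a.gene_name is not None}
        for cond, anns in annotations_by_condition.items()
    }
    pairwise = {
        f"{a}&{b}": len(gene_sets[a] & gene_sets[b])
        for a, b in combinations(sorted(gene_sets), 2)
    }
    common = set.intersection(*gene_sets.values())
    return {
        "genes": gene_sets,
        "counts": {c: len(s) for c, s in gene_sets.items()},
        "pairwise": pairwise,
        "intersection_all": len(common),
        "intersection_genes": sorted(common),
    }


def write_annotation_tsv(annotations: Iterable[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tcategory\tgene\n")
        for a in annotations:
            fh.write(
                f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t"
                f"{a.peak.name or '.'}\t{a.category}\t{a.gene_name or '.'}\n"
            )


def summary_json(p: PeakSet, fractions: dict[str, float] | None = None) -> str:
    mean, sem, n = peak_length_stats(p) if len(p) else (float("nan"), float("nan"), 0)
    out = {"label": p.label, "n_peaks": len(p), "mean_length": mean, "sem_length": sem}
    if fractions is not None:
        out["feature_fractions_pct"] = fractions
    return json.dumps(out, sort_keys=True)
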