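"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import re

import numpy as np

from marspace.intervals import Peak, PeakSet
from marspace.motifs import MotifPattern, reverse_complement


def overlaps(p: Peak, q: Peak) -> bool:
    return p.chrom == q.chrom and p.start < q.end and q.start < p.end


def gap(p: Peak, q: Peak) -> int | None:
    """Edge-to-edge gap; None for different chromosomes; <0 when overlapping."""
    if p.chrom != q.chrom:
        return None
    if overlaps(p, q):
        return -1
    return max(p.start - q.end, q.start - p.end)


def brute_subtract(sample: PeakSet, control: PeakSet) -> list[Peak]:
    return [p for p in sample if not any(overlaps(p, q) for q in control)]


def brute_overlap_proximal(a: PeakSet, b: PeakSet, proximity: int) -> tuple[int, int]:
    n_overlap = n_proximal = 0
    for p in a:
        gaps = [gap(p, q) for q in b if p.chrom == q.chrom]
        if not gaps:
            continue
        if any(g is not None and g < 0 for g in gaps):
            n_overlap += 1
        elif min(g for g in gaps if g is not None) <= proximity:
            n_proximal += 1
    return n_overlap, n_proximal


def brute_annotate(peak: Peak, genes, promoter_up: int, promoter_down: int) -> str:
    """Midpoint category with promoter > exon > intron precedence."""
    mid = (peak.start + peak.end) // 2
    cats = set()
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        ps, pe = g.promoter_window(promoter_up, promoter_down)
        if ps <= mid < pe:
            cats.add("promoter")
        if g.tx_start <= mid < g.tx_end:
            cats.add("exon" if any(s <= mid < e for s, e in g.exons) else "intron")
    for c in ("promoter", "exon", "intron"):
        if c in cats:
            return c
    return "intergenic"


def regex_scan(seq: str, pattern: MotifPattern, strands: str = "both"):
    """Backtracking-regex reference for the motif scanner (same non-overlap
    policy: re.finditer is leftmost, greedy, non-overlapping)."""
    seq = seq.upper()
    rx = re.compile(pattern.to_regex())
    hits = {(mo.start(), mo.end()): "+" for mo in rx.finditer(seq)}
    if strands == "both":
        n = len(seq)
        for mo in rx.finditer(reverse_complement(seq)):
            hits.setdefault((n - mo.end(), n - mo.start()), "-")
    return sorted((s, e, st) for (s, e), st in hits.items())


def brute_pixel_sets(points: np.ndarray, roi, pixel_size: float) -> set[tuple[int, int]]:
    xmin, ymin, xmax, ymax = roi
    nx = max(int(np.ceil((xmax - xmin) / pixel_size)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pixel_size)), 1)
    out = set()
    for x, y in points:
        ix = min(max(int((x - xmin) / pixel_size), 0), nx - 1)
        iy = min(max(int((y - ymin) / pixel_size), 0), ny - 1)
        out.add((iy, ix))
    return out


def random_peakset(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                   span: int = 10_000, max_len: int = 300, label: str = "rand") -> PeakSet:
    peaks = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        peaks.append(Peak(chrom, start, start + length))
    return PeakSet(peaks, label=label)
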