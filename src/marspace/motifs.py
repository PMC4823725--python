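"""Degenerate repeat-quantified motif patterns and sequence scanning.

Motifs such as the SATB1 binding site (A/T)3-6 C (A/T)3-n or the
G-quadruplex G3+ N1-20 G3+ N1-20 G3+ N1-20 G3+ are expressed in a small
grammar: a base class (IUPAC letter or bracketed set, e.g. ``[AT]``)
followed by an optional repeat quantifier ``{min,max}``, ``{min,}``
(unbounded) or ``{n}``; a bare class means ``{1,1}``. Scanning uses
leftmost, greedy, non-overlapping semantics — the same policy as a
backtracking regular-expression engine — on the forward strand and, for
``strands="both"``, on the reverse complement with hits reported in
forward coordinates.

The inverse-length weighting used for the motifs-per-peak statistic is
``w_i = 100 * m_i / L_i`` (hits per 100 nt of peak), which puts peak sets
with very different length distributions on a comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError, LoadError, MotifCompileError
from .intervals import PeakSet

__all__ = [
    "MotifPattern",
    "MotifHit",
    "WeightedMotifStat",
    "compile_pattern",
    "scan_sequence",
    "weighted_motifs_per_peak",
    "motif_presence_summary",
    "load_motif_file",
    "reverse_complement",
    "DEFAULT_MOTIF_SPECS",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_SEQ = frozenset("ACGTN")

# Default motif library for the motifs quoted in the main analyses: the SATB1
# site, the TC2-3AT element, the G-quadruplex, and an AT-island proxy for
# origin-of-replication/S/MAR AT-richness. This is a synthetic stand-in for a
# full scaffold/matrix-attachment-region rule library; replace via a motif
# file for production scans.
DEFAULT_MOTIF_SPECS: dict[str, str] = {
    "SATB1": "[AT]{3,6}C[AT]{3,}",
    "TC23AT": "TC{2,3}AT",
    "G4": "G{3,}N{1,20}G{3,}N{1,20}G{3,}N{1,20}G{3,}",
    "AT_island": "[AT]{10,}",
}


@dataclass(frozen=True)
class MotifElement:
    bases: frozenset[str]
    min_repeat: int
    max_repeat: int | None  # None = unbounded

    def __post_init__(self) -> None:
        if not self.bases:
            raise MotifCompileError("empty base class")
        if self.min_repeat < 1:
            raise MotifCompileError("min repeat must be >= 1")
        if self.max_repeat is not None and self.max_repeat < self.min_repeat:
            raise MotifCompileError("max repeat < min repeat")

    @property
    def match_chars(self) -> frozenset[str]:
        """Input characters this element accepts; an input N is ambiguous and
        only matches the fully degenerate class."""
        if self.bases == frozenset("ACGT"):
            return frozenset("ACGTN")
        return self.bases

    def class_spec(self) -> str:
        if self.bases == frozenset("ACGT"):
            return "N"
        if len(self.bases) == 1:
            return next(iter(self.bases))
        return "[" + "".join(sorted(self.bases)) + "]"

    def spec(self) -> str:
        cls = self.class_spec()
        lo, hi = self.min_repeat, self.max_repeat
        if hi is None:
            return f"{cls}{{{lo},}}"
        if lo == hi == 1:
            return cls
        if lo == hi:
            return f"{cls}{{{lo}}}"
        return f"{cls}{{{lo},{hi}}}"


@dataclass(frozen=True)
class MotifPattern:
    id: str
    elements: tuple[MotifElement, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise MotifCompileError("pattern needs at least one element")

    def spec(self) -> str:
        """Canonical grammar string; compile_pattern round-trips it."""
        return "".join(e.spec() for e in self.elements)

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    def to_regex(self) -> str:
        """Equivalent regular expression (used for cross-checks and export)."""
        parts = []
        for e in self.elements:
            chars = "".join(sorted(e.match_chars))
            cls = chars if len(chars) == 1 else f"[{chars}]"
            lo, hi = e.min_repeat, e.max_repeat
            if hi is None:
                parts.append(f"{cls}{{{lo},}}")
            elif lo == hi:
                parts.append(cls if lo == 1 else f"{cls}{{{lo}}}")
            else:
                parts.append(f"{cls}{{{lo},{hi}}}")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    sequence_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError("motif hit must have end > start")
        if self.strand not in ("+", "-"):
            raise DataError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class WeightedMotifStat:
    per_peak_values: tuple[float, ...]
    mean: float
    sem: float
    n_peaks: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "WeightedMotifStat":
        arr = np.asarray(values, dtype=float)
        n = arr.size
        if n == 0:
            raise DataError("no peaks to summarize")
        sem = 0.0 if n == 1 else float(arr.std(ddof=1) / np.sqrt(n))
        return cls(tuple(float(v) for v in arr), float(arr.mean()), sem, n)


# ---------------------------------------------------------------------------
# Grammar compilation
# ---------------------------------------------------------------------------

def compile_pattern(spec: str, pattern_id: str | None = None) -> MotifPattern:
    """Compile a grammar string into a MotifPattern.

    Raises :class:`MotifCompileError` with the character position on bad
    input (unknown letter, empty or malformed class, min > max).
    """
    elements: list[MotifElement] = []
    i, n = 0, len(spec)
    while i < n:
        pos = i
        ch = spec[i]
        if ch == "[":
            j = spec.find("]", i)
            if j < 0:
                raise MotifCompileError(f"position {pos}: unterminated '['")
            letters = spec[i + 1 : j]
            if not letters:
                raise MotifCompileError(f"position {pos}: empty base class")
            bases: set[str] = set()
            for c in letters:
                if c.upper() not in IUPAC:
                    raise MotifCompileError(f"position {pos}: unknown base {c!r}")
                bases.update(IUPAC[c.upper()])
            i = j + 1
        elif ch.upper() in IUPAC:
            bases = set(IUPAC[ch.upper()])
            i += 1
        else:
            raise MotifCompileError(f"position {pos}: unexpected character {ch!r}")
        lo, hi = 1, 1
        if i < n and spec[i] == "{":
            j = spec.find("}", i)
            if j < 0:
                raise MotifCompileError(f"position {i}: unterminated '{{'")
            body = spec[i + 1 : j]
            try:
                if "," in body:
                    lo_s, hi_s = body.split(",", 1)
                    lo = int(lo_s)
                    hi = int(hi_s) if hi_s.strip() else None
                else:
                    lo = hi = int(body)
            except ValueError as exc:
                raise MotifCompileError(f"position {i}: bad quantifier {{{body}}}") from exc
            i = j + 1
        try:
            elements.append(MotifElement(frozenset(bases), lo, hi))
        except MotifCompileError as exc:
            raise MotifCompileError(f"position {pos}: {exc}") from exc
    if not elements:
        raise MotifCompileError("empty pattern specification")
    return MotifPattern(pattern_id if pattern_id is not None else spec, tuple(elements))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _match_end(seq: str, pos: int, elements: tuple[MotifElement, ...], ei: int) -> int | None:
    """Greedy backtracking match of elements[ei:] at `pos`; returns match end."""
    if ei == len(elements):
        return pos
    elem = elements[ei]
    chars = elem.match_chars
    n = len(seq)
    limit = n - pos if elem.max_repeat is None else min(elem.max_repeat, n - pos)
    run = 0
    while run < limit and seq[pos + run] in chars:
        run += 1
    for r in range(run, elem.min_repeat - 1, -1):
        end = _match_end(seq, pos + r, elements, ei + 1)
        if end is not None:
            return end
    return None


def _scan_coords(seq: str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """Leftmost greedy non-overlapping matches on one strand, as (start, end)."""
    out: list[tuple[int, int]] = []
    n = len(seq)
    min_len = pattern.min_length
    pos = 0
    while pos + min_len <= n:
        end = _match_end(seq, pos, pattern.elements, 0)
        if end is not None:
            out.append((pos, end))
            pos = end
        else:
            pos += 1
    return out


def scan_sequence(
    seq: str,
    pattern: MotifPattern,
    strands: str = "both",
    sequence_id: str = "",
) -> list[MotifHit]:
    """Scan a sequence for a pattern; returns hits sorted by coordinate.

    Minus-strand hits are located on the reverse complement and reported in
    forward coordinates; hits with identical coordinates on both strands are
    reported once, as '+'. An empty sequence yields no hits; characters
    outside {A,C,G,T,N} raise :class:`DataError`.
    """
    if strands not in ("plus", "both"):
        raise ValueError(f"strands must be 'plus' or 'both', got {strands!r}")
    seq = seq.upper()
    if not set(seq) <= _VALID_SEQ:
        bad = sorted(set(seq) - _VALID_SEQ)
        raise DataError(f"invalid sequence characters: {bad}")
    hits: dict[tuple[int, int], str] = {}
    for s, e in _scan_coords(seq, pattern):
        hits[(s, e)] = "+"
    if strands == "both":
        n = len(seq)
        rc = reverse_complement(seq)
        for s, e in _scan_coords(rc, pattern):
            key = (n - e, n - s)
            hits.setdefault(key, "-")
    return [
        MotifHit(pattern.id, sequence_id, s, e, strand)
        for (s, e), strand in sorted(hits.items())
    ]


# ---------------------------------------------------------------------------
# Peak-level statistics
# ---------------------------------------------------------------------------

def _fetch_sequence(genome, peak) -> str:
    """Sequence under a peak from a dict of strings or a pyfaidx.Fasta."""
    try:
        record = genome[peak.chrom]
    except KeyError as exc:
        raise DataError(
            f"peak {peak.chrom}:{peak.start}-{peak.end}: chromosome not in genome"
        ) from exc
    if peak.end > len(record):
        raise DataError(
            f"peak {peak.chrom}:{peak.start}-{peak.end}: beyond chromosome end "
            f"({len(record)} nt)"
        )
    return str(record[peak.start : peak.end]).upper()


def weighted_motifs_per_peak(
    peaks: PeakSet,
    genome,
    patterns: Iterable[MotifPattern],
    strands: str = "both",
) -> WeightedMotifStat:
    """Inverse-length-weighted motif content per peak.

    For peak i with length L_i and m_i total hits across all patterns,
    w_i = 100 * m_i / L_i (motifs per 100 nt). Reports mean +/- SEM of w_i.
    """
    patterns = list(patterns)
    values = []
    for peak in peaks:
        seq = _fetch_sequence(genome, peak)
        m = sum(len(scan_sequence(seq, pat, strands=strands)) for pat in patterns)
        values.append(100.0 * m / peak.length)
    return WeightedMotifStat.from_values(values)


def motif_presence_summary(
    peaks: PeakSet,
    genome,
    pattern: MotifPattern,
    strands: str = "both",
) -> tuple[int, int]:
    """(number of peaks with >= 1 hit, total hits across peaks)."""
    n_with = n_total = 0
    for peak in peaks:
        seq = _fetch_sequence(genome, peak)
        k = len(scan_sequence(seq, pattern, strands=strands))
        n_with += k > 0
        n_total += k
    return n_with, n_total


def load_motif_file(path: str | Path) -> list[MotifPattern]:
    """Load a motif library: one grammar spec per line, optional leading
    ``id<TAB>`` column, ``#`` comments."""
    patterns = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "\t" in line:
                pid, spec = line.split("\t", 1)
            else:
                pid, spec = line, line
            try:
                patterns.append(compile_pattern(spec.strip(), pattern_id=pid.strip()))
            except MotifCompileError as exc:
                raise LoadError(f"{path}:{lineno}: {exc}") from exc
    return patterns


def default_motif_library() -> list[MotifPattern]:
    return [compile_pattern(spec, pattern_id=pid) for pid, spec in DEFAULT_MOTIF_SPECS.items()]


def write_hits_bed(hits: Iterable[MotifHit], path: str | Path, offset_by: Mapping[str, int] | None = None) -> None:
    """Write hits as BED6 (name = pattern id). `offset_by` maps sequence ids
    to genomic offsets when hits were found in peak-local coordinates."""
    with open(path, "w") as fh:
        for h in hits:
            off = 0 if offset_by is None else offset_by.get(h.sequence_id, 0)
            fh.write(
                f"{h.sequence_id}\t{h.start + off}\t{h.end + off}\t"
                f"{h.pattern_id}\t0\t{h.strand}\n"
            )
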