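"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator draws all randomness from one explicit seed, returns the
simulated object together with a :class:`SimulationTruth` sidecar recording
the parameters and planted truth, and emits the same standard formats the
readers consume. Defaults emulate the statistical structure of the study
system: ChIP-seq peaks a few hundred nt long spaced ~10^5 nt apart
(optionally on a jittered 125-kb period), genomic background at ~41% GC,
SMLM clusters of ~15 nm spread on a ~106-nm lattice, and qPCR Ct tables
obeying the ΔΔCt model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError
from .intervals import GeneModel, Peak, PeakSet
from .motifs import MotifPattern
from .qpcr import CtTable
from .smlm import LocalizationSet

__all__ = [
    "SimulationTruth",
    "simulate_peakset",
    "simulate_sequence_with_motifs",
    "simulate_localizations",
    "simulate_ct_table",
    "simulate_gene_models",
]


@dataclass
class SimulationTruth:
    seed: int
    parameters: dict
    truth: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"seed": self.seed, "parameters": self.parameters, "truth": self.truth},
            sort_keys=True,
            default=_jsonify,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _allocate(n: int, chrom_sizes: Mapping[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment of n items proportional to size."""
    chroms = sorted(chrom_sizes)
    total = sum(chrom_sizes[c] for c in chroms)
    exact = {c: n * chrom_sizes[c] / total for c in chroms}
    alloc = {c: int(exact[c]) for c in chroms}
    leftover = n - sum(alloc.values())
    for c in sorted(chroms, key=lambda c: exact[c] - alloc[c], reverse=True)[:leftover]:
        alloc[c] += 1
    return alloc


# ---------------------------------------------------------------------------
# Peak sets
# ---------------------------------------------------------------------------

def simulate_peakset(
    n_peaks: int,
    chrom_sizes: Mapping[str, int],
    length_mean: float = 170.0,
    length_sd: float = 40.0,
    spacing_mode: str = "poisson",
    period: float = 125_000.0,
    jitter_sd: float = 5_000.0,
    seed: int = 0,
    label: str = "simulated",
) -> tuple[PeakSet, SimulationTruth]:
    """Simulate a peak set with controlled lengths and inter-peak spacing.

    ``periodic`` mode places successive starts at ``period + N(0, jitter_sd)``
    (floored at one peak length); ``poisson`` mode draws exponential gaps
    sized so the peaks fit the chromosome. Lengths are Normal(length_mean,
    length_sd) truncated below at 20 nt. Peaks are apportioned across
    chromosomes proportional to size. Raises :class:`DataError` when the
    requested peaks cannot be packed.
    """
    if spacing_mode not in ("poisson", "periodic"):
        raise ValueError(f"unknown spacing_mode {spacing_mode!r}")
    if n_peaks < 1 or length_mean <= 0 or period <= 0:
        raise ValueError("n_peaks, length_mean and period must be positive")
    rng = np.random.default_rng(seed)
    alloc = _allocate(n_peaks, chrom_sizes)
    peaks: list[Peak] = []
    for chrom in sorted(alloc):
        n_c = alloc[chrom]
        if n_c == 0:
            continue
        size = chrom_sizes[chrom]
        lengths = np.maximum(
            np.rint(rng.normal(length_mean, length_sd, size=n_c)).astype(int), 20
        )
        max_len = int(lengths.max())
        if spacing_mode == "periodic":
            if (n_c - 1) * period + max_len > size:
                raise DataError(
                    f"{chrom}: {n_c} peaks at period {period:g} exceed size {size}"
                )
            gaps = period + rng.normal(0.0, jitter_sd, size=n_c - 1)
            starts = np.concatenate([[0.0], np.cumsum(np.maximum(gaps, max_len))])
            slack = size - max_len - starts[-1]
            if slack < 0:
                raise DataError(f"{chrom}: jittered periodic packing infeasible")
            starts += rng.uniform(0, slack) if slack > 0 else 0.0
        else:
            span = size - max_len
            if span <= n_c:
                raise DataError(f"{chrom}: {n_c} peaks do not fit in {size} nt")
            for _ in range(50):
                gaps = rng.exponential(scale=span / (n_c + 1), size=n_c)
                starts = np.cumsum(gaps)
                if starts[-1] <= span:
                    break
            else:
                raise DataError(f"{chrom}: poisson packing failed; lower n_peaks")
        for s, L in zip(starts.astype(int), lengths):
            peaks.append(Peak(chrom, int(s), int(s) + int(L)))
    truth = SimulationTruth(
        seed=seed,
        parameters={
            "n_peaks": n_peaks,
            "chrom_sizes": dict(chrom_sizes),
            "length_mean": length_mean,
            "length_sd": length_sd,
            "spacing_mode": spacing_mode,
            "period": period,
            "jitter_sd": jitter_sd,
        },
        truth={
            "allocation": alloc,
            "true_length_mean": length_mean,
            "true_period": period if spacing_mode == "periodic" else None,
        },
    )
    return PeakSet(peaks, label=label), truth


# ---------------------------------------------------------------------------
# Sequence with planted motifs
# ---------------------------------------------------------------------------

def _realize_pattern(pattern: MotifPattern, rng: np.random.Generator, unbounded_extra: int = 5) -> str:
    """One concrete string matching the pattern (unbounded repeats capped at
    min + unbounded_extra)."""
    parts = []
    for elem in pattern.elements:
        hi = elem.max_repeat if elem.max_repeat is not None else elem.min_repeat + unbounded_extra
        r = int(rng.integers(elem.min_repeat, hi + 1))
        bases = sorted(elem.bases)
        parts.append("".join(bases[int(i)] for i in rng.integers(0, len(bases), size=r)))
    return "".join(parts)


def simulate_sequence_with_motifs(
    length: int,
    gc_fraction: float = 0.41,
    plants: Sequence[tuple[MotifPattern, int]] = (),
    seed: int = 0,
) -> tuple[str, SimulationTruth]:
    """I.i.d. background sequence at the given GC content with planted,
    non-overlapping motif instances at recorded positions.

    The default GC fraction matches the human genome (~41%). Setting
    ``gc_fraction=1.0`` gives a G/C-only background in which A/T-based
    patterns can only match at planted sites. Raises :class:`DataError` when
    the requested instances cannot be placed without overlap.
    """
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([
        (1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2,
    ])
    seq = rng.choice(np.array(list("ACGT")), size=length, p=p)
    placed: list[tuple[int, int]] = []
    planted: list[dict] = []
    for pattern, count in plants:
        for _ in range(count):
            instance = _realize_pattern(pattern, rng)
            L = len(instance)
            if L > length:
                raise DataError(f"pattern {pattern.id} instance longer than sequence")
            for _attempt in range(2000):
                start = int(rng.integers(0, length - L + 1))
                end = start + L
                # keep >= 2 nt of background between instances: abutting
                # plants could merge under greedy scanning, and a single
                # separator base can complete a motif on the reverse strand
                # (e.g. a lone G reads as the C of an A/T-rich site)
                if all(end + 2 <= s or start >= e + 2 for s, e in placed):
                    placed.append((start, end))
                    seq[start:end] = list(instance)
                    planted.append(
                        {"pattern_id": pattern.id, "start": start, "end": end,
                         "instance": instance}
                    )
                    break
            else:
                raise DataError(
                    f"could not place {count} instances of {pattern.id}: sequence overcrowded"
                )
    truth = SimulationTruth(
        seed=seed,
        parameters={
            "length": length,
            "gc_fraction": gc_fraction,
            "plants": [(pat.id, cnt) for pat, cnt in plants],
        },
        truth={"planted": sorted(planted, key=lambda d: d["start"])},
    )
    return "".join(seq), truth


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            s = sequences[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SMLM localizations
# ---------------------------------------------------------------------------

def simulate_localizations(
    arrangement: str = "lattice",
    n_clusters: int = 20,
    spacing: float = 106.0,
    cluster_sigma: float = 15.0,
    molecules_per_cluster_mean: float = 30.0,
    centroid_jitter_sigma: float = 5.0,
    background_per_um2: float = 0.0,
    roi: tuple[float, float, float, float] = (0.0, 0.0, 3000.0, 3000.0),
    seed: int = 0,
    channel: str = "ch1",
    centroids: np.ndarray | None = None,
) -> tuple[LocalizationSet, SimulationTruth]:
    """Simulate a localization channel as molecular clusters plus background.

    ``lattice`` places cluster centroids in a row at `spacing` nm — the
    regularly patterned arrangement — each jittered by
    Normal(0, centroid_jitter_sigma) to emulate imperfect biological
    periodicity (spectral recovery of the lattice constant requires the
    jitter to stay below ~10% of the spacing); ``poisson`` scatters
    centroids uniformly. Molecules per cluster are Poisson-distributed (at
    least 1) around each centroid with isotropic Gaussian spread
    `cluster_sigma`; uniform background is added at `background_per_um2`. Passing `centroids` reuses
    an existing arrangement (e.g. to simulate a second channel sharing
    structure). True per-point cluster labels (-1 = background) are recorded.
    """
    if arrangement not in ("lattice", "poisson"):
        raise ValueError(f"unknown arrangement {arrangement!r}")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = roi
    if centroids is None:
        if arrangement == "lattice":
            if spacing <= 0:
                raise DataError("lattice spacing must be positive")
            extent = (n_clusters - 1) * spacing
            if extent > (xmax - xmin):
                raise DataError("lattice does not fit inside the ROI")
            x0 = xmin + 0.5 * ((xmax - xmin) - extent)
            yc = 0.5 * (ymin + ymax)
            centroids = np.column_stack([x0 + spacing * np.arange(n_clusters),
                                         np.full(n_clusters, yc)])
            # placement jitter: real cluster positions wobble about the lattice
            centroids = centroids + rng.normal(
                0.0, centroid_jitter_sigma, size=centroids.shape
            )
        else:
            m = min(3 * cluster_sigma, 0.25 * min(xmax - xmin, ymax - ymin))
            centroids = np.column_stack([
                rng.uniform(xmin + m, xmax - m, size=n_clusters),
                rng.uniform(ymin + m, ymax - m, size=n_clusters),
            ])
    else:
        centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
        n_clusters = centroids.shape[0]
    points, labels = [], []
    for k, c in enumerate(centroids):
        n_mol = max(int(rng.poisson(molecules_per_cluster_mean)), 1)
        pts = c + rng.normal(0.0, cluster_sigma, size=(n_mol, 2))
        points.append(pts)
        labels.extend([k] * n_mol)
    area_um2 = (xmax - xmin) * (ymax - ymin) / 1e6
    n_bg = int(rng.poisson(background_per_um2 * area_um2))
    if n_bg:
        bg = np.column_stack([
            rng.uniform(xmin, xmax, size=n_bg), rng.uniform(ymin, ymax, size=n_bg)
        ])
        points.append(bg)
        labels.extend([-1] * n_bg)
    pts = np.vstack(points)
    pts[:, 0] = np.clip(pts[:, 0], xmin, xmax)
    pts[:, 1] = np.clip(pts[:, 1], ymin, ymax)
    truth = SimulationTruth(
        seed=seed,
        parameters={
            "arrangement": arrangement,
            "n_clusters": n_clusters,
            "spacing": spacing,
            "cluster_sigma": cluster_sigma,
            "molecules_per_cluster_mean": molecules_per_cluster_mean,
            "centroid_jitter_sigma": centroid_jitter_sigma,
            "background_per_um2": background_per_um2,
            "roi": list(roi),
        },
        truth={
            "centroids": centroids,
            "labels": np.asarray(labels, dtype=int),
            "true_spacing": spacing if arrangement == "lattice" else None,
        },
    )
    return LocalizationSet(pts, channel=channel, roi=roi), truth


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    true_fold: float,
    ct_input_mean: float = 20.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    assay: str = "chip",
    treated: str = "abeta",
    control: str = "vehicle",
) -> tuple[CtTable, SimulationTruth]:
    """Ct table consistent with the ΔΔCt model at a known true fold change.

    ``chip`` assay: input at `ct_input_mean`, IgG 5 cycles later, ChIP at
    IgG − log2(true_fold), each plus Normal(0, noise_sd) replicate noise.
    ``rt`` assay: reference at `ct_input_mean` in both conditions, control
    target 2 cycles later, treated target shifted by −log2(true_fold).
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if assay not in ("chip", "rt"):
        raise ValueError(f"unknown assay {assay!r}")
    rng = np.random.default_rng(seed)
    shift = float(np.log2(true_fold))
    records = []

    def add(role: str, condition: str, mean: float) -> None:
        for rep in range(1, n_replicates + 1):
            ct = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            records.append((role, condition, rep, float(ct)))

    if assay == "chip":
        igg_mean = ct_input_mean + 5.0
        add("input", "chip_assay", ct_input_mean)
        add("igg", "chip_assay", igg_mean)
        add("chip", "chip_assay", igg_mean - shift)
    else:
        add("reference", control, ct_input_mean)
        add("reference", treated, ct_input_mean)
        add("target", control, ct_input_mean + 2.0)
        add("target", treated, ct_input_mean + 2.0 - shift)
    truth = SimulationTruth(
        seed=seed,
        parameters={
            "true_fold": true_fold,
            "ct_input_mean": ct_input_mean,
            "noise_sd": noise_sd,
            "n_replicates": n_replicates,
            "assay": assay,
        },
        truth={"true_fold": true_fold, "true_log2_fold": shift},
    )
    return CtTable.from_records(records), truth


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(
    n_genes: int,
    chrom_sizes: Mapping[str, int],
    exons_per_gene: int = 3,
    seed: int = 0,
) -> tuple[list[GeneModel], SimulationTruth]:
    """Non-overlapping gene models on equally sized slots per chromosome.

    Each gene occupies the middle ~half of its slot, with `exons_per_gene`
    exons alternating with introns inside the transcript and random strand,
    leaving generous intergenic space (and room for promoter windows).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if exons_per_gene < 1:
        raise ValueError("exons_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    alloc = _allocate(n_genes, chrom_sizes)
    genes: list[GeneModel] = []
    gi = 0
    for chrom in sorted(alloc):
        n_c = alloc[chrom]
        if n_c == 0:
            continue
        slot = chrom_sizes[chrom] // n_c
        if slot < 4 * (2 * exons_per_gene - 1):
            raise DataError(f"{chrom}: too many genes for chromosome size")
        for j in range(n_c):
            slot_start = j * slot
            tx_start = slot_start + slot // 4
            tx_end = tx_start + slot // 2
            n_seg = 2 * exons_per_gene - 1
            bounds = np.linspace(tx_start, tx_end, n_seg + 1).astype(int)
            exons = tuple(
                (int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(exons_per_gene)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            genes.append(
                GeneModel(
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(tx_start),
                    tx_end=int(tx_end),
                    exons=exons,
                    gene_name=f"gene{gi}",
                )
            )
    truth = SimulationTruth(
        seed=seed,
        parameters={
            "n_genes": n_genes,
            "chrom_sizes": dict(chrom_sizes),
            "exons_per_gene": exons_per_gene,
        },
        truth={
            "genes": [
                {
                    "gene_name": g.gene_name,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "tx_start": g.tx_start,
                    "tx_end": g.tx_end,
                    "exons": [list(e) for e in g.exons],
                }
                for g in genes
            ]
        },
    )
    return genes, truth
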