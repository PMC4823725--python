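"""Inter-peak spacing: distances, quantiles, and bounded kernel density modes.

Regularly spaced peaks along a chromosome — the signature expected of
scaffold/matrix-attachment regions — show up as a mode in the density of
successive inter-peak distances. The estimator is a Gaussian KDE restricted
to [0, upper_bound] (distances beyond the bound are dropped and the density
renormalized over the grid), with bandwidth ``smoothing`` times the
normal-reference (Silverman) bandwidth of the truncated sample. A mode is a
local maximum whose prominence exceeds ``prominence_frac`` of the density
maximum; when no mode qualifies the profile reports no regular spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import DataError
from .intervals import PeakSet

__all__ = ["SpacingProfile", "interpeak_distances", "spacing_quantile", "spacing_kde"]


@dataclass
class SpacingProfile:
    distances: list[tuple[str, int]]
    quantiles: dict[float, float]
    grid: np.ndarray  # positions, nt
    density: np.ndarray
    modes: list[tuple[float, float, float]]  # (position nt, density, prominence)
    bandwidth: float
    upper_bound: float

    @property
    def has_regular_spacing(self) -> bool:
        return len(self.modes) > 0

    def to_dict(self) -> dict:
        return {
            "n_distances": len(self.distances),
            "quantiles_nt": {str(q): v for q, v in self.quantiles.items()},
            "bandwidth_nt": self.bandwidth,
            "upper_bound_nt": self.upper_bound,
            "modes": [
                {"position_nt": p, "density": d, "prominence": pr}
                for p, d, pr in self.modes
            ],
            "has_regular_spacing": self.has_regular_spacing,
        }


def interpeak_distances(p: PeakSet, mode: str = "start") -> list[tuple[str, int]]:
    """Distances between successive peaks, per chromosome.

    `mode` selects the reference: "start" (start-to-start, default),
    "midpoint", or "gap" (end-to-next-start, clipped at 0 for overlaps).
    Chromosomes with fewer than two peaks contribute nothing; distances never
    cross a chromosome boundary.
    """
    if mode not in ("start", "midpoint", "gap"):
        raise ValueError(f"unknown spacing mode {mode!r}")
    out: list[tuple[str, int]] = []
    for chrom in p.chroms:
        peaks = p.peaks_on(chrom)
        for prev, cur in zip(peaks, peaks[1:]):
            if mode == "start":
                d = cur.start - prev.start
            elif mode == "midpoint":
                d = cur.midpoint - prev.midpoint
            else:
                d = max(cur.start - prev.end, 0)
            out.append((chrom, d))
    return out


def _as_array(distances: Iterable) -> np.ndarray:
    vals = [d[1] if isinstance(d, tuple) else d for d in distances]
    return np.asarray(vals, dtype=float)


def spacing_quantile(distances: Iterable, q: float) -> float:
    """Linear-interpolation (type-7) sample quantile of the distances."""
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    arr = _as_array(distances)
    if arr.size == 0:
        raise DataError("no distances to take a quantile of")
    return float(np.quantile(arr, q))  # numpy default is the type-7 estimator


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Normal-reference rule: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        raise DataError("distances are degenerate (zero spread); KDE undefined")
    return 0.9 * spread * x.size ** (-1 / 5)


def spacing_kde(
    distances: Iterable,
    upper_bound: float = 4_000_000,
    smoothing: float = 0.5,
    grid_points: int = 512,
    prominence_frac: float = 0.10,
    min_height_factor: float = 2.0,
) -> SpacingProfile:
    """Kernel density of inter-peak distances on [0, upper_bound] with modes.

    Distances above `upper_bound` are discarded before estimation; at least
    10 must remain. Bandwidth = smoothing x Silverman's normal-reference
    bandwidth of the truncated sample. The density is renormalized to unit
    trapezoid mass on the grid.

    A mode is an interior local maximum that (a) has prominence >=
    prominence_frac x max density and (b) stands at least min_height_factor
    times the density of *both* featureless reference profiles evaluated at
    the mode position: the uniform density 1/upper_bound and an exponential
    density with the sample's mean spacing (the Poisson-process null for
    randomly placed peaks). Requirement (b) rejects the sampling wiggle a
    flat profile inevitably shows as well as the spurious near-boundary
    maximum that truncating a decaying gap distribution at zero always
    creates — neither rises meaningfully above its own null curve, whereas a
    genuinely preferred spacing does. An empty mode list means no regular
    spacing was detected.
    """
    pairs = [d if isinstance(d, tuple) else ("", d) for d in distances]
    arr = _as_array(pairs)
    if np.any(arr < 0):
        raise DataError("negative inter-peak distance")
    keep = arr <= upper_bound
    x = arr[keep]
    if x.size < 10:
        raise DataError(
            f"only {x.size} distances <= {upper_bound:g} nt; need >= 10 "
            "(provide a larger peak set or raise the bound)"
        )
    bw = smoothing * _silverman_bandwidth(x)
    grid = np.linspace(0.0, float(upper_bound), grid_points)
    # Gaussian KDE evaluated directly; renormalized over the bounded grid.
    z = (grid[:, None] - x[None, :]) / bw
    density = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))
    mass = np.trapezoid(density, grid)
    density = density / mass
    peak_idx, props = find_peaks(density, prominence=prominence_frac * density.max())
    flat_ref = 1.0 / float(upper_bound)  # uniform spacing null
    scale = float(x.mean())  # Poisson-gap (exponential spacing) null
    exp_ref = np.exp(-grid / scale) / scale
    modes = sorted(
        (float(grid[i]), float(density[i]), float(pr))
        for i, pr in zip(peak_idx, props["prominences"])
        if density[i] >= min_height_factor * max(flat_ref, float(exp_ref[i]))
    )
    qs = {q: float(np.quantile(arr, q)) for q in (0.25, 0.5, 0.75)}
    return SpacingProfile(
        distances=[(c, int(d)) for c, d in pairs],
        quantiles=qs,
        grid=grid,
        density=density,
        modes=modes,
        bandwidth=float(bw),
        upper_bound=float(upper_bound),
    )
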