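"""Super-resolution localization analysis: co-localization, OPTICS, periodicity.

Single-molecule localization microscopy yields point clouds (x, y in nm) per
fluorescence channel. Four analyses are provided:

* dot co-localization — a localization is co-localized when its nearest
  neighbour in the other channel lies within 2/3 of the effective labelled
  protein size (60 nm with primary + secondary antibody, giving the 40 nm
  threshold);
* pixel co-localization — channels rasterized to an occupancy grid, optionally
  dilated, and compared pixel-wise;
* density-based clustering with a from-scratch OPTICS (Ordering Points To
  Identify the Clustering Structure) implementation: reachability ordering
  followed by a DBSCAN-style extraction at a reachability cut;
* spatial periodicity — pairwise inter-cluster centroid distances are
  histogrammed, mean-subtracted and Fourier transformed; regular spacing is
  declared when the dominant non-DC spectral component is a discrete interior
  peak rather than the broad low-frequency envelope of the distance
  distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .errors import DataError

__all__ = [
    "LocalizationSet",
    "ClusterResult",
    "PeriodicityResult",
    "ColocalizationResult",
    "read_localizations",
    "write_localizations",
    "dot_colocalization",
    "pixel_colocalization",
    "optics_cluster",
    "intercluster_distances",
    "detect_periodicity",
    "cluster_size_stats",
]

NOISE = -1


class LocalizationSet:
    """A channel's localizations (nm) inside a rectangular ROI."""

    def __init__(
        self,
        points: np.ndarray | Sequence[tuple[float, float]],
        channel: str = "",
        roi: tuple[float, float, float, float] | None = None,
    ) -> None:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise DataError("localization coordinates must be finite")
        if roi is None:
            if pts.size:
                roi = (
                    float(pts[:, 0].min()), float(pts[:, 1].min()),
                    float(pts[:, 0].max()), float(pts[:, 1].max()),
                )
            else:
                roi = (0.0, 0.0, 0.0, 0.0)
        xmin, ymin, xmax, ymax = roi
        if pts.size and (
            pts[:, 0].min() < xmin or pts[:, 0].max() > xmax
            or pts[:, 1].min() < ymin or pts[:, 1].max() > ymax
        ):
            raise DataError("localizations fall outside the stated ROI")
        self.points = pts
        self.channel = channel
        self.roi = (float(xmin), float(ymin), float(xmax), float(ymax))

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ClusterResult:
    ordering: np.ndarray          # point indices in OPTICS processing order
    reachability: np.ndarray      # per point (input order), inf where undefined
    core_distances: np.ndarray    # per point, inf where not a core point
    labels: np.ndarray            # per point cluster id, -1 = noise
    centroids: np.ndarray         # (k, 2)
    sizes: np.ndarray             # per cluster max pairwise member distance

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


@dataclass
class PeriodicityResult:
    bin_centers: np.ndarray
    counts: np.ndarray
    periods: np.ndarray            # nm, descending frequency order excluded; aligned with magnitudes
    magnitudes: np.ndarray         # normalized to max 1
    detected_periods: list[tuple[float, float]]  # (period nm, magnitude), increasing period
    has_regular_spacing: bool

    def to_dict(self) -> dict:
        return {
            "detected_periods_nm": [
                {"period_nm": p, "magnitude": m} for p, m in self.detected_periods
            ],
            "has_regular_spacing": self.has_regular_spacing,
        }


@dataclass
class ColocalizationResult:
    threshold_nm: float
    fraction_pct: float        # union denominator: both channels pooled
    fraction_a_pct: float
    fraction_b_pct: float

    def to_dict(self) -> dict:
        return {
            "threshold_nm": self.threshold_nm,
            "fraction_colocalized_pct": self.fraction_pct,
            "fraction_a_pct": self.fraction_a_pct,
            "fraction_b_pct": self.fraction_b_pct,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_localizations(path: str | Path, channel: str | None = None,
                       roi: tuple[float, float, float, float] | None = None) -> LocalizationSet:
    """Read a CSV with columns x_nm, y_nm[, channel]; optionally filter to one
    channel label."""
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    if channel is not None and "channel" in df.columns:
        df = df[df["channel"].astype(str) == str(channel)]
    pts = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
    return LocalizationSet(pts, channel=channel or "", roi=roi)


def write_localizations(locs: LocalizationSet, path: str | Path) -> None:
    df = pd.DataFrame(locs.points, columns=["x_nm", "y_nm"])
    df["channel"] = locs.channel
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Co-localization
# ---------------------------------------------------------------------------

def dot_colocalization(
    a: LocalizationSet,
    b: LocalizationSet,
    protein_size_a: float = 60.0,
    protein_size_b: float | None = None,
) -> ColocalizationResult:
    """Nearest-neighbour co-localization between two channels.

    The distance threshold is two thirds of the smallest effective protein
    size (60 nm by default, hence 40 nm). A dot is co-localized when its
    nearest neighbour in the other channel is within the threshold; the
    headline fraction pools both channels, per-channel fractions are
    reported alongside.
    """
    if len(a) == 0 or len(b) == 0:
        raise DataError("dot_colocalization requires non-empty channels")
    size_b = protein_size_a if protein_size_b is None else protein_size_b
    threshold = (2.0 / 3.0) * min(protein_size_a, size_b)
    tree_a, tree_b = cKDTree(a.points), cKDTree(b.points)
    d_a, _ = tree_b.query(a.points)
    d_b, _ = tree_a.query(b.points)
    n_a, n_b = int(np.sum(d_a <= threshold)), int(np.sum(d_b <= threshold))
    return ColocalizationResult(
        threshold_nm=threshold,
        fraction_pct=100.0 * (n_a + n_b) / (len(a) + len(b)),
        fraction_a_pct=100.0 * n_a / len(a),
        fraction_b_pct=100.0 * n_b / len(b),
    )


def _occupancy(locs: LocalizationSet, roi, pixel_size: float) -> np.ndarray:
    xmin, ymin, xmax, ymax = roi
    nx = max(int(np.ceil((xmax - xmin) / pixel_size)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pixel_size)), 1)
    ix = np.clip(((locs.points[:, 0] - xmin) / pixel_size).astype(int), 0, nx - 1)
    iy = np.clip(((locs.points[:, 1] - ymin) / pixel_size).astype(int), 0, ny - 1)
    grid = np.zeros((ny, nx), dtype=bool)
    grid[iy, ix] = True
    return grid


def pixel_colocalization(
    a: LocalizationSet,
    b: LocalizationSet,
    pixel_size: float = 20.0,
    dilation: float = 0.0,
) -> float:
    """Percent of occupied pixels shared by both channels.

    Channels are rasterized over the union ROI at `pixel_size` nm per pixel;
    each occupancy mask is binary-dilated by ceil(dilation / pixel_size)
    pixels (8-connected). The percentage is taken relative to pixels occupied
    in either channel.
    """
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    if dilation < 0:
        raise ValueError(f"dilation must be >= 0, got {dilation}")
    roi = (
        min(a.roi[0], b.roi[0]), min(a.roi[1], b.roi[1]),
        max(a.roi[2], b.roi[2]), max(a.roi[3], b.roi[3]),
    )
    ga, gb = _occupancy(a, roi, pixel_size), _occupancy(b, roi, pixel_size)
    n_iter = int(np.ceil(dilation / pixel_size))
    if n_iter:
        from scipy.ndimage import binary_dilation

        ga = binary_dilation(ga, structure=np.ones((3, 3), bool), iterations=n_iter)
        gb = binary_dilation(gb, structure=np.ones((3, 3), bool), iterations=n_iter)
    either = int(np.sum(ga | gb))
    if either == 0:
        return 0.0
    return 100.0 * int(np.sum(ga & gb)) / either


# ---------------------------------------------------------------------------
# OPTICS clustering (from scratch)
# ---------------------------------------------------------------------------

def optics_cluster(
    points: np.ndarray | LocalizationSet,
    min_pts: int = 5,
    eps: float = 100.0,
    reach_cut: float = 50.0,
) -> ClusterResult:
    """Order points by density reachability and extract clusters at a cut.

    Core distance of a point = distance to its min_pts-th closest point
    (counting itself) provided at least min_pts points lie within eps;
    otherwise the point is not core. Points are processed in order of current
    smallest reachability (ties and fresh starts resolved by ascending index,
    giving a deterministic ordering). Clusters are runs in the ordering with
    reachability <= reach_cut; a point exceeding the cut starts a new cluster
    when its own core distance is within the cut, and is noise otherwise.
    Clusters smaller than min_pts are demoted to noise.
    """
    if min_pts < 2:
        raise ValueError(f"min_pts must be >= 2, got {min_pts}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    pts = points.points if isinstance(points, LocalizationSet) else np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n == 0:
        return ClusterResult(
            ordering=np.empty(0, dtype=int),
            reachability=np.empty(0),
            core_distances=np.empty(0),
            labels=np.empty(0, dtype=int),
            centroids=np.empty((0, 2)),
            sizes=np.empty(0),
        )
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=eps)
    core_dist = np.full(n, np.inf)
    neighbor_dists: list[np.ndarray] = []
    for i, idx in enumerate(neighbors):
        idx_arr = np.asarray(idx, dtype=int)
        d = np.linalg.norm(pts[idx_arr] - pts[i], axis=1)
        order = np.argsort(d, kind="stable")
        idx_arr, d = idx_arr[order], d[order]
        neighbors[i] = idx_arr
        neighbor_dists.append(d)
        if idx_arr.size >= min_pts:
            core_dist[i] = d[min_pts - 1]  # includes the point itself at d=0

    reach = np.full(n, np.inf)
    processed = np.zeros(n, dtype=bool)
    ordering = np.empty(n, dtype=int)
    for step in range(n):
        # next point: smallest reachability among unprocessed, then index
        unproc = np.flatnonzero(~processed)
        best = unproc[int(np.argmin(reach[unproc]))]  # argmin ties -> lowest index
        processed[best] = True
        ordering[step] = best
        if np.isfinite(core_dist[best]):
            cd = core_dist[best]
            for q, dq in zip(neighbors[best], neighbor_dists[best]):
                if not processed[q]:
                    new_reach = max(cd, dq)
                    if new_reach < reach[q]:
                        reach[q] = new_reach

    # DBSCAN-style extraction along the ordering at reach_cut
    labels = np.full(n, NOISE, dtype=int)
    cluster_id = -1
    for idx in ordering:
        if reach[idx] > reach_cut:
            if core_dist[idx] <= reach_cut:
                cluster_id += 1
                labels[idx] = cluster_id
            # else: noise
        elif cluster_id >= 0:
            labels[idx] = cluster_id

    # enforce minimum cluster population
    final_labels = np.full(n, NOISE, dtype=int)
    centroids, sizes = [], []
    next_id = 0
    for cid in range(cluster_id + 1):
        members = np.flatnonzero(labels == cid)
        if members.size < min_pts:
            continue
        final_labels[members] = next_id
        member_pts = pts[members]
        centroids.append(member_pts.mean(axis=0))
        sizes.append(float(pdist(member_pts).max()) if members.size > 1 else 0.0)
        next_id += 1
    return ClusterResult(
        ordering=ordering,
        reachability=reach,
        core_distances=core_dist,
        labels=final_labels,
        centroids=np.array(centroids).reshape(-1, 2),
        sizes=np.asarray(sizes, dtype=float),
    )


def intercluster_distances(c: ClusterResult) -> np.ndarray:
    """All pairwise centroid distances, k(k-1)/2 values."""
    if c.n_clusters < 2:
        raise DataError("fewer than two clusters: no spacing measurable")
    return pdist(c.centroids)


def cluster_size_stats(c: ClusterResult) -> tuple[float, float]:
    """Mean and SEM of per-cluster maximum pairwise member distance."""
    if c.n_clusters == 0:
        raise DataError("no clusters to summarize")
    sizes = c.sizes
    sem = 0.0 if sizes.size == 1 else float(sizes.std(ddof=1) / np.sqrt(sizes.size))
    return float(sizes.mean()), sem


# ---------------------------------------------------------------------------
# Spectral periodicity
# ---------------------------------------------------------------------------

def detect_periodicity(
    distances: Sequence[float] | np.ndarray,
    bin_width: float = 10.0,
    magnitude_threshold: float = 0.2,
) -> PeriodicityResult:
    """Detect regular spacing in a set of pairwise distances.

    The distances are histogrammed at `bin_width`, the counts mean-subtracted
    and Fourier transformed; the magnitude spectrum is normalized to its
    maximum over non-zero frequencies. Qualifying peaks are interior local
    maxima of the spectrum with normalized magnitude >= magnitude_threshold
    whose period lies inside the resolvable range (2 x bin_width, histogram
    span). Up to the two largest are reported in increasing period — for a
    clustered point pattern the shorter one reflects the cluster-size scale
    and the longer the inter-cluster spacing.

    `has_regular_spacing` is true only when the spectrum's global non-DC
    maximum is itself one of the qualifying interior peaks: a periodic
    arrangement concentrates spectral power at its fundamental (and
    harmonics), whereas an irregular arrangement's spectrum is dominated by
    the broad low-frequency envelope of the distance distribution, with only
    minor interior bumps.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 3:
        raise DataError("need at least 3 distances to assess periodicity")
    if np.any(d < 0):
        raise DataError("distances must be non-negative")
    span = float(d.max())
    if span <= 0:
        raise DataError("all distances are zero; periodicity undefined")
    n_bins = max(int(np.ceil(span / bin_width)), 4)
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, n_bins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    signal = counts.astype(float) - counts.mean()
    spectrum = np.abs(np.fft.rfft(signal))
    freqs = np.fft.rfftfreq(n_bins, d=bin_width)  # cycles per nm
    mags = spectrum[1:]
    periods = 1.0 / freqs[1:]
    norm = mags.max()
    if norm > 0:
        mags = mags / norm
    peak_idx, _ = find_peaks(mags)
    hist_span = n_bins * bin_width
    in_range = {
        int(i) for i in peak_idx if 2 * bin_width < periods[i] < hist_span
    }
    qualifying = [
        (float(periods[i]), float(mags[i]))
        for i in sorted(in_range)
        if mags[i] >= magnitude_threshold
    ]
    qualifying.sort(key=lambda t: -t[1])
    detected = sorted(qualifying[:2])
    dominant_is_peak = int(np.argmax(mags)) in in_range
    return PeriodicityResult(
        bin_centers=centers,
        counts=counts,
        periods=periods,
        magnitudes=mags,
        detected_periods=detected,
        has_regular_spacing=bool(detected) and dominant_is_peak,
    )
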