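"""Detection of the collapse point of a duplicated map.

The nasotemporal axis is divided into equal bins and the SC termination
points of each bin's RGCs are split into two clusters along the AP axis
(exact 1D 2-means).  The clusters are distinct iff the separation of
their AP means exceeds 1.5 pooled standard deviations of the 2D
termination spread within clusters and the smaller cluster holds at
least 5% of the bin.  The collapse point is the nasal-most bin whose
projections form a single cluster, reported as the bin centre in % of
the NT axis.  The caller restricts the mapping to the central
mediolateral third of the retina so that the mediolateral extent of the
termination cloud does not drown the AP separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ephmap.analysis.mapping import PointMapping

N_BINS = 50
SD_FACTOR = 1.5
MIN_CLUSTER_FRACTION = 0.05
MIN_BIN_COUNT = 4


@dataclass
class CollapseResult:
    bin_centers: np.ndarray  # (n_bins,) NT positions in [0, 1]
    bin_counts: np.ndarray
    n_clusters: np.ndarray  # 2, 1, or -1 (undetermined: too few points)
    cluster_means_ap: list  # per bin, AP coordinates of cluster means
    cluster_sds: np.ndarray  # per bin, pooled 2D SD
    collapse_position: float | None  # % of NT axis, or None
    kind: str  # "collapse" | "no_split" | "no_merge"


def two_means_1d(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal 1D 2-means: the split point minimising within-cluster SS.

    Returns (labels, separation of cluster means).  Deterministic; scans
    every split of the sorted values.
    """
    order = np.argsort(values)
    v = values[order]
    n = v.size
    csum = np.cumsum(v)
    total = csum[-1]
    csum2 = np.cumsum(v * v)
    k = np.arange(1, n)  # left cluster sizes
    left_mean = csum[:-1] / k
    right_mean = (total - csum[:-1]) / (n - k)
    ss = (csum2[:-1] - csum[:-1] ** 2 / k) + (
        (csum2[-1] - csum2[:-1]) - (total - csum[:-1]) ** 2 / (n - k)
    )
    best = int(np.argmin(ss))
    labels = np.zeros(n, dtype=int)
    labels[order[best + 1 :]] = 1
    return labels, float(abs(right_mean[best] - left_mean[best]))


def _bin_clusters(points_sc: np.ndarray, sd_factor: float, min_frac: float):
    """Cluster one bin's 2D termination points along the AP axis."""
    n = points_sc.shape[0]
    labels, sep = two_means_1d(points_sc[:, 0])
    n0, n1 = np.sum(labels == 0), np.sum(labels == 1)
    ap_means = [float(np.mean(points_sc[labels == c, 0])) for c in (0, 1) if (labels == c).any()]
    ss = 0.0
    for c in (0, 1):
        cluster = points_sc[labels == c]
        if cluster.shape[0]:
            ss += float(np.sum((cluster - cluster.mean(axis=0)) ** 2))
    pooled_sd = np.sqrt(ss / max(n - 2, 1))
    distinct = (sep > sd_factor * pooled_sd) and (min(n0, n1) >= min_frac * n)
    if distinct:
        return 2, sorted(ap_means), pooled_sd
    return 1, [float(np.mean(points_sc[:, 0]))], pooled_sd


def collapse_point(
    mapping: PointMapping,
    n_bins: int = N_BINS,
    sd_factor: float = SD_FACTOR,
    min_cluster_fraction: float = MIN_CLUSTER_FRACTION,
    min_bin_count: int = MIN_BIN_COUNT,
    seed: int = 0,
) -> CollapseResult:
    """Locate where a duplicated map merges into one along the NT axis.

    Bins with fewer than ``min_bin_count`` RGCs are undetermined and are
    skipped when scanning for the nasal-most single-cluster bin.
    ``seed`` is accepted for interface stability; the 1D clustering is
    exact and needs no restarts.
    """
    if len(mapping) < 2 * n_bins:
        raise ValueError("too few mapped RGCs for binned collapse detection")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(mapping.retina[:, 0], edges) - 1, 0, n_bins - 1)

    n_clusters = np.full(n_bins, -1, dtype=int)
    counts = np.zeros(n_bins, dtype=int)
    means_ap: list = [[] for _ in range(n_bins)]
    sds = np.full(n_bins, np.nan)
    for b in range(n_bins):
        pts = mapping.sc[which == b]
        counts[b] = pts.shape[0]
        if counts[b] < min_bin_count:
            continue
        k, m_ap, sd = _bin_clusters(pts, sd_factor, min_cluster_fraction)
        n_clusters[b] = k
        means_ap[b] = m_ap
        sds[b] = sd

    determinate = n_clusters > 0
    if not determinate.any():
        raise ValueError("no bin held enough RGCs to cluster")
    single = determinate & (n_clusters == 1)
    double = determinate & (n_clusters == 2)
    if not double.any():
        kind, pos = "no_split", None
    elif not single.any():
        kind, pos = "no_merge", None
    else:
        # The merged region is by construction the temporal end of the
        # map: take the nasal-most bin of the contiguous single-cluster
        # run reaching the temporal-most determinate bin (robust to
        # sparse, spuriously single bins at the nasal pole).
        det_idx = np.nonzero(determinate)[0]
        if n_clusters[det_idx[-1]] == 2:
            kind, pos = "no_merge", None
        else:
            nasal_most = det_idx[-1]
            for b in det_idx[::-1]:
                if n_clusters[b] == 2:
                    break
                nasal_most = b
            kind, pos = "collapse", float(100.0 * centers[nasal_most])
    return CollapseResult(
        bin_centers=centers,
        bin_counts=counts,
        n_clusters=n_clusters,
        cluster_means_ap=means_ap,
        cluster_sds=sds,
        collapse_position=pos,
        kind=kind,
    )
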