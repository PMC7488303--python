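"""Difference-of-Gaussian reference-free particle picking and its scoring.

The tomogram is filtered with two 3-D Gaussians whose widths differ by a
fixed ratio (sigma2 = 1.1 sigma1); their difference is a band-pass map
whose local maxima are candidate particle centers.  Candidates are kept
above the threshold ``T = m + t (M - m) / 20`` computed from the extreme
peak values M and m at threshold level ``t`` (default 5).  Against a
ground-truth table of particle centers and radii, picks are matched
one-to-one greedily by distance; a particle with a matched pick inside its
radius counts as a true positive, and precision, recall and F-score follow
from the confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import DensityVolume

__all__ = [
    "PickResult",
    "PickScore",
    "dog_transform",
    "detect_peaks",
    "match_picks",
    "fscore",
    "pick_volume",
]


@dataclass
class PickResult:
    """Retained DoG peaks with the threshold bookkeeping that produced them."""

    peaks: np.ndarray  # (n, 3) voxel indices (i, j, k)
    intensities: np.ndarray  # (n,) DoG value at each peak
    sigma1: float
    sigma_ratio: float = 1.1
    t: float = 5.0
    threshold: float = 0.0

    def top_k(self, k: int) -> "PickResult":
        """The k highest-intensity peaks (the fixed-count protocol)."""
        order = np.argsort(self.intensities)[::-1][:k]
        return PickResult(
            peaks=self.peaks[order],
            intensities=self.intensities[order],
            sigma1=self.sigma1,
            sigma_ratio=self.sigma_ratio,
            t=self.t,
            threshold=self.threshold,
        )


@dataclass
class PickScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else 0.0

    @property
    def fscore(self) -> float:
        return fscore(self.precision, self.recall)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "fscore": self.fscore,
        }


def dog_transform(
    volume: DensityVolume, sigma1: float, ratio: float = 1.1
) -> DensityVolume:
    """Difference of Gaussians ``G(sigma1) * V - G(sigma1 * ratio) * V``.

    Sigmas are in voxels.  Standard separable 3-D Gaussian filtering; only
    relative DoG values matter for peak ranking.
    """
    if sigma1 <= 0:
        raise ValueError("sigma1 must be > 0")
    if ratio <= 1:
        raise ValueError("sigma ratio must exceed 1")
    g1 = ndimage.gaussian_filter(volume.grid, sigma1)
    g2 = ndimage.gaussian_filter(volume.grid, sigma1 * ratio)
    return DensityVolume(g1 - g2, voxel_size=volume.voxel_size,
                         origin=volume.origin.copy(),
                         resolution=volume.resolution)


def detect_peaks(dog_volume: DensityVolume, t: float = 5.0) -> PickResult:
    """Strict 26-neighborhood local maxima thresholded at
    ``T = m + t (M - m) / 20``.

    M and m are the largest and smallest local-peak values; peaks with
    value >= T are retained.  Plateaus (exact value ties) keep only the
    lexicographically smallest voxel of each plateau.  A constant volume
    has no peaks and yields an empty result.
    """
    v = dog_volume.grid
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbor_max = ndimage.maximum_filter(v, footprint=footprint,
                                          mode="constant", cval=-np.inf)
    strict = v > neighbor_max
    peaks_idx = np.argwhere(strict)
    # plateau case: voxel equals its neighborhood max but dominates the
    # plateau boundary; keep the lexicographically smallest voxel per plateau
    flat = (v == neighbor_max)
    if np.any(flat):
        conn = np.ones((3, 3, 3), dtype=bool)
        labels, nlab = ndimage.label(flat, structure=conn)
        for lab in range(1, nlab + 1):
            mask = labels == lab
            members = np.argwhere(mask)
            val = v[tuple(members[0])]
            grown = ndimage.binary_dilation(mask, structure=conn)
            boundary = grown & ~mask
            # a plateau filling the whole grid (constant volume) is no peak
            if np.any(boundary) and v[boundary].max() < val:
                members = members[np.lexsort(members.T[::-1])]
                peaks_idx = np.vstack([peaks_idx, members[0]])
    if len(peaks_idx) == 0:
        return PickResult(peaks=np.empty((0, 3), int),
                          intensities=np.empty(0), sigma1=np.nan, t=t)
    vals = v[tuple(peaks_idx.T)]
    M, m = float(vals.max()), float(vals.min())
    threshold = m + t * (M - m) / 20.0
    keep = vals >= threshold
    order = np.argsort(vals[keep])[::-1]
    return PickResult(
        peaks=peaks_idx[keep][order],
        intensities=vals[keep][order],
        sigma1=np.nan,
        t=t,
        threshold=threshold,
    )


def match_picks(
    peaks: np.ndarray,
    truth_centers: np.ndarray,
    truth_radii: np.ndarray,
    one_to_one: bool = True,
) -> PickScore:
    """Score picks against ground-truth particles.

    Default is one-to-one matching by pick-center distance over the
    within-radius candidate pairs, resolved as a minimum-distance
    maximum-cardinality assignment (it therefore agrees with a brute-force
    bipartite matching); a particle whose matched pick lies inside its
    radius is a true positive, unmatched picks are false positives,
    unmatched particles false negatives.  ``one_to_one=False`` switches to
    the permissive rule where any pick within the radius marks the
    particle detected (and any pick inside some particle's radius is not
    a false positive).
    """
    truth_centers = np.asarray(truth_centers, float).reshape(-1, 3)
    truth_radii = np.asarray(truth_radii, float).reshape(-1)
    if len(truth_centers) == 0:
        raise ValueError("ground truth is empty: nothing to evaluate")
    peaks = np.asarray(peaks, float).reshape(-1, 3)
    n_peaks, n_truth = len(peaks), len(truth_centers)
    if n_peaks == 0:
        return PickScore(tp=0, fp=0, fn=n_truth)

    dist = np.linalg.norm(
        peaks[:, None, :] - truth_centers[None, :, :], axis=2
    )
    within = dist <= truth_radii[None, :]

    if not one_to_one:
        tp = int(np.any(within, axis=0).sum())
        fp = int((~np.any(within, axis=1)).sum())
        return PickScore(tp=tp, fp=fp, fn=n_truth - tp)

    from scipy.optimize import linear_sum_assignment

    # forbidden (outside-radius) pairs get a cost dwarfing every distance,
    # so the assignment first maximizes matched pairs, then total distance
    big = dist[within].sum() + dist.max() + 1.0 if np.any(within) else 1.0
    cost = np.where(within, dist, big)
    rows, cols = linear_sum_assignment(cost)
    tp = int(np.sum(within[rows, cols]))
    return PickScore(tp=tp, fp=n_peaks - tp, fn=n_truth - tp)


def fscore(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; zero when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def pick_volume(
    volume: DensityVolume,
    sigma1: float,
    ratio: float = 1.1,
    t: float = 5.0,
    top_k: int | None = None,
) -> PickResult:
    """DoG transform + peak detection in one call.

    ``top_k`` switches to the fixed-count protocol that keeps the K
    strongest peaks after thresholding (K = truth count reproduces the
    equal-precision-recall evaluation setting).
    """
    result = detect_peaks(dog_transform(volume, sigma1, ratio), t=t)
    result.sigma1 = sigma1
    result.sigma_ratio = ratio
    if top_k is not None:
        result = result.top_k(top_k)
    return result
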