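"""Ommatidial disorder scoring.

A wild-type compound eye packs its ommatidia in a near-perfect hexagonal
lattice. Rough-eye phenotypes disturb that packing, and the degree of
disturbance is a quantitative severity readout. This module detects
ommatidial centers in a grayscale eye-surface image and summarises local
lattice disorder into a single phenotypic score S:

* each interior ommatidium contributes the coefficient of variation of the
  lengths of its (up to six) nearest-neighbour vectors, plus the mean
  absolute deviation of the sorted angular gaps between those vectors from
  the ideal 60 degrees (in units of 60 degrees);
* S is 100 times the mean contribution over interior ommatidia.

S is zero exactly on a perfect hexagonal lattice of any spacing or
orientation, is invariant under rigid motions and uniform scaling of the
center set, and grows with positional disorder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian


@dataclass
class EyeImage:
    """A rectangular grayscale intensity grid with optional metadata."""

    pixels: np.ndarray
    pixel_size: float | None = None
    provenance: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("EyeImage requires a 2-D intensity grid")
        if not np.isfinite(self.pixels).all():
            raise ValueError("EyeImage intensities must be finite")


@dataclass
class OmmatidialCenters:
    """Detected ommatidium centers, sub-pixel, as (x=column, y=row) pairs."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class LocalVectorSet:
    """Per-ommatidium neighbour geometry.

    For ommatidium ``i``: ``neighbors[i]`` are the indices of its
    k = min(6, N−1) nearest neighbours, ``lengths[i]`` the vector lengths,
    ``azimuths[i]`` the vector azimuths in degrees, ``gaps[i]`` the sorted
    circular angular gaps (which sum to 360 for k >= 2), and ``interior[i]``
    is False for points on the convex hull of the center set.
    """

    points: np.ndarray
    neighbors: list[np.ndarray]
    lengths: list[np.ndarray]
    azimuths: list[np.ndarray]
    gaps: list[np.ndarray]
    interior: np.ndarray

    @property
    def k(self) -> np.ndarray:
        return np.array([len(nbrs) for nbrs in self.neighbors])


@dataclass
class PhenotypicScore:
    score: float
    per_ommatidium: np.ndarray  # disorder d_i for scored (interior) ommatidia
    n_interior: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _refine_subpixel(weight_img: np.ndarray, peaks: np.ndarray,
                     radius: float, n_iter: int = 3) -> np.ndarray:
    """Iterated weighted centroid around each peak, window re-centered on the
    running estimate so truncation stays symmetric about the blob center."""
    r = max(1, int(round(radius)))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    disk = (dy**2 + dx**2) <= radius**2
    dy, dx = dy[disk], dx[disk]
    h, w = weight_img.shape
    refined = []
    for py, px in peaks:
        y, x = float(py), float(px)
        for _ in range(n_iter):
            ys, xs = y + dy, x + dx
            wts = map_coordinates(weight_img, [ys, xs], order=1, mode="constant")
            wts = np.clip(wts, 0.0, None)
            total = wts.sum()
            if total <= 0:
                break
            y, x = float((wts * ys).sum() / total), float((wts * xs).sum() / total)
        refined.append((min(max(x, 0.0), w - 1.0), min(max(y, 0.0), h - 1.0)))
    return np.asarray(refined, dtype=float).reshape(-1, 2)


def detect_ommatidia(image: EyeImage, expected_spacing: float,
                     threshold_quantile: float = 0.9) -> OmmatidialCenters:
    """Detect ommatidial centers as band-pass local maxima.

    The image is band-pass filtered with a difference of Gaussians at scales
    0.2 and 0.6 times the expected spacing (robust to illumination
    gradients), local maxima separated by at least 0.6 spacing and above the
    given intensity quantile of the filtered image are kept, and each is
    refined to sub-pixel precision by an iterated intensity-weighted
    centroid. A blank (constant) image yields an empty result.
    """
    if expected_spacing < 3:
        raise ValueError("expected_spacing must be at least 3 pixels")
    if not 0 <= threshold_quantile <= 1:
        raise ValueError("threshold_quantile must lie in [0, 1]")
    img = image.pixels
    if np.ptp(img) == 0:
        return OmmatidialCenters(np.empty((0, 2)))
    dog = gaussian(img, 0.2 * expected_spacing) - gaussian(img, 0.6 * expected_spacing)
    threshold = float(np.quantile(dog, threshold_quantile))
    peaks = peak_local_max(dog, min_distance=max(1, int(round(0.6 * expected_spacing))),
                           threshold_abs=threshold, exclude_border=False)
    if len(peaks) == 0:
        return OmmatidialCenters(np.empty((0, 2)))
    points = _refine_subpixel(dog, peaks, radius=0.45 * expected_spacing)
    return OmmatidialCenters(points)


# ---------------------------------------------------------------------------
# Local vectors and the score
# ---------------------------------------------------------------------------

def _interior_mask(pts: np.ndarray, nn_dist: np.ndarray,
                   collar: float = 0.75) -> np.ndarray:
    """Flag points on or near the convex hull boundary as non-interior.

    A staggered lattice edge leaves points strictly inside the hull whose
    neighbour rings are still truncated by the eye boundary, so in addition
    to the hull itself a collar of ``collar`` times the median
    nearest-neighbour distance is excluded. The rule is invariant under
    rigid motions and uniform scaling. Degenerate (e.g. collinear) sets
    have no interior.
    """
    n = len(pts)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return np.zeros(n, dtype=bool)
    # hull.equations rows (a, b, c) are outward unit normals: a*x + b*y + c <= 0
    # inside; min over facet planes lower-bounds the distance to the boundary.
    dist_to_hull = -(pts @ hull.equations[:, :2].T + hull.equations[:, 2]).max(axis=1)
    return dist_to_hull > collar * float(np.median(nn_dist))


def compute_local_vectors(centers: OmmatidialCenters) -> LocalVectorSet:
    """Neighbour vectors for each ommatidium.

    Each ommatidium gets its k = min(6, N−1) nearest neighbours by Euclidean
    distance, with ties broken by smaller azimuth and then by index. Points
    on the convex hull of the set are flagged non-interior (their neighbour
    geometry is truncated by the eye boundary, not by the phenotype).
    """
    pts = centers.points
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 centers to compute local vectors")
    neighbors, lengths, azimuths, gaps = [], [], [], []
    for i in range(n):
        delta = pts - pts[i]
        dist = np.hypot(delta[:, 0], delta[:, 1])
        azim = np.degrees(np.arctan2(delta[:, 1], delta[:, 0])) % 360.0
        order = sorted((j for j in range(n) if j != i),
                       key=lambda j: (dist[j], azim[j], j))
        chosen = np.array(order[: min(6, n - 1)], dtype=int)
        neighbors.append(chosen)
        lengths.append(dist[chosen])
        azimuths.append(azim[chosen])
        sorted_az = np.sort(azim[chosen])
        gap = np.diff(np.concatenate([sorted_az, [sorted_az[0] + 360.0]]))
        gaps.append(gap)
    interior = _interior_mask(pts, np.array([l[0] for l in lengths]))
    return LocalVectorSet(points=pts, neighbors=neighbors, lengths=lengths,
                          azimuths=azimuths, gaps=gaps, interior=interior)


def phenotypic_score(vectors: LocalVectorSet, length_weight: float = 1.0,
                     angle_weight: float = 1.0) -> PhenotypicScore:
    """Aggregate local disorder into the phenotypic score S.

    d_i = w_L * CV(lengths) + w_A * mean(|gap − 60°| / 60°), over interior
    ommatidia with at least two neighbours; S = 100 * mean(d_i). S = 0 iff
    every interior ommatidium sits in a locally perfect hexagonal
    neighbourhood.
    """
    ks = vectors.k
    mask = vectors.interior & (ks >= 2)
    if not mask.any():
        raise ValueError("no interior ommatidia with >= 2 neighbours to score")
    d = []
    for i in np.flatnonzero(mask):
        ls = vectors.lengths[i]
        cv = float(np.std(ls) / np.mean(ls))
        angle = float(np.mean(np.abs(vectors.gaps[i] - 60.0) / 60.0))
        d.append(length_weight * cv + angle_weight * angle)
    d = np.asarray(d)
    return PhenotypicScore(score=float(100.0 * d.mean()), per_ommatidium=d,
                           n_interior=int(mask.sum()),
                           params={"length_weight": length_weight,
                                   "angle_weight": angle_weight})


def score_image(image: EyeImage, expected_spacing: float,
                threshold_quantile: float = 0.9, length_weight: float = 1.0,
                angle_weight: float = 1.0) -> tuple[PhenotypicScore, OmmatidialCenters]:
    """Detect then score a single image."""
    centers = detect_ommatidia(image, expected_spacing, threshold_quantile)
    vectors = compute_local_vectors(centers)
    return phenotypic_score(vectors, length_weight, angle_weight), centers


# ---------------------------------------------------------------------------
# Batch scoring and rank concordance
# ---------------------------------------------------------------------------

def score_batch(images: Sequence[tuple[str, EyeImage]], expected_spacing: float,
                threshold_quantile: float = 0.9, length_weight: float = 1.0,
                angle_weight: float = 1.0) -> pd.DataFrame:
    """Score a labelled batch of images, recording failures instead of
    dropping them.

    Returns one row per image with columns (genotype, image_index, score,
    n_detected, n_interior, status, error).
    """
    if len(images) == 0:
        raise ValueError("score_batch requires a non-empty image list")
    rows = []
    for idx, (genotype, image) in enumerate(images):
        try:
            result, centers = score_image(image, expected_spacing,
                                          threshold_quantile, length_weight,
                                          angle_weight)
            rows.append((genotype, idx, result.score, centers.n,
                         result.n_interior, "ok", ""))
        except Exception as exc:  # per-image failures must not kill the batch
            rows.append((genotype, idx, np.nan, 0, 0, "error", str(exc)))
    return pd.DataFrame(rows, columns=["genotype", "image_index", "score",
                                       "n_detected", "n_interior", "status",
                                       "error"])


def percentile_rank(values: np.ndarray) -> np.ndarray:
    """Midrank percentile: 100 * (count strictly below + half the ties) / n."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    below = (values[:, None] > values[None, :]).sum(axis=1)
    ties = (values[:, None] == values[None, :]).sum(axis=1)  # includes self
    return 100.0 * (below + 0.5 * ties) / n


def percentile_ranks(scores_a: Mapping[str, float],
                     scores_b: Mapping[str, float]) -> tuple[pd.DataFrame, float]:
    """Percentile ranks of matched genotype score maps and their Pearson r.

    Used to check concordance of severity orderings between two scoring
    conditions (e.g. the same RNAi lines scored with and without an RNAi
    amplifier in the cross).
    """
    shared = sorted(set(scores_a) & set(scores_b))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genotypes for rank concordance")
    a = np.array([scores_a[g] for g in shared], dtype=float)
    b = np.array([scores_b[g] for g in shared], dtype=float)
    ranks_a, ranks_b = percentile_rank(a), percentile_rank(b)
    from scipy.stats import pearsonr

    r = float(pearsonr(ranks_a, ranks_b).statistic)
    table = pd.DataFrame({"genotype": shared, "score_a": a, "score_b": b,
                          "pct_rank_a": ranks_a, "pct_rank_b": ranks_b})
    return table, r
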