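"""Ridge (curvilinear feature) detection by a predictor-corrector scheme.

Bright filaments are intensity ridges: loci where the image relief is
locally maximal perpendicular to a preferred direction. On a ridge the
digital Laplacian of the (preprocessed) intensity u is strongly
negative, so

* predictor — *coarse segmentation*: threshold the ridge strength
  -Delta_u, with Delta_u the 4-neighbour digital Laplacian
  u(i±1,j) + u(i,j±1) - 4 u(i,j) (replicate-padded borders), at a
  quantile of its positive values;
* corrector — *fine segmentation*: for every 8-adjacent pair of coarse
  pixels, the straight candidate segment between them is validated by
  the mean concavity of the bilinearly interpolated relief perpendicular
  to it. At m points along the segment the profile u(-h), u(0), u(+h) is
  sampled at perpendicular offsets ±h; the segment is accepted when the
  mean second difference c = u(-h) - 2u(0) + u(+h) is <= -kappa.

Redundancy is avoided by successive reduction of the coarse pixel set:
candidates are processed from most to least concave; an accepted segment
represents every coarse pixel inside its perpendicular band, and a
candidate is skipped once both of its pixels are represented by the same
growing chain (a segment joining two distinct chains is never
redundant). Accepted endpoints are finally shifted perpendicular to the
segment onto the parabolic maximum of their 3-point profile, realising
subpixel "lines between pixels"; each pixel's subpixel position is fixed
by the first accepted segment that uses it, so chains stay connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import convolve, map_coordinates

from .image import ParameterError, RasterImage

_LAPLACIAN_4 = np.array([[0.0, 1.0, 0.0],
                         [1.0, -4.0, 1.0],
                         [0.0, 1.0, 0.0]])
_LAPLACIAN_8 = np.array([[1.0, 1.0, 1.0],
                         [1.0, -8.0, 1.0],
                         [1.0, 1.0, 1.0]])

#: 8-neighbourhood offsets enumerating each adjacent pair once.
_PAIR_OFFSETS = np.array([(0, 1), (1, -1), (1, 0), (1, 1)])


@dataclass
class DetectionConfig:
    """Parameters of the predictor-corrector detector.

    laplacian_quantile
        q in (0, 1): the ridge-strength threshold is the q-quantile of
        the *positive* -Delta_u values. Quantiles are invariant to
        intensity scaling, which is why no absolute threshold is used.
    concavity_threshold
        kappa > 0: a candidate segment is accepted when its mean
        perpendicular second difference is <= -kappa (intensities on the
        [0, 1] normalised scale).
    profile_offset_px
        h > 0: perpendicular sampling offset; should span the filament
        half-width (1-3 px) without touching neighbouring filaments.
    profile_samples
        m >= 3 sample points along each candidate segment.
    laplacian_neighbors
        4 (default, the standard digital Laplacian) or 8.
    """

    laplacian_quantile: float = 0.5
    concavity_threshold: float = 0.2
    profile_offset_px: float = 1.5
    profile_samples: int = 5
    laplacian_neighbors: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.laplacian_quantile < 1.0:
            raise ParameterError("laplacian_quantile must be in (0, 1)")
        if self.concavity_threshold <= 0:
            raise ParameterError("concavity_threshold must be > 0")
        if self.profile_offset_px <= 0:
            raise ParameterError("profile_offset_px must be > 0")
        if self.profile_samples < 3:
            raise ParameterError("profile_samples must be >= 3")
        if self.laplacian_neighbors not in (4, 8):
            raise ParameterError("laplacian_neighbors must be 4 or 8")


@dataclass
class RidgePixelSet:
    """Candidate ridge pixels (predictor output) with their strengths."""

    coords: np.ndarray  # (n, 2) int array of (row, col)
    strengths: np.ndarray  # (n,) ridge strength -Delta_u

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class LineSegment:
    """An accepted subpixel straight piece of a filament."""

    p: np.ndarray
    q: np.ndarray
    mean_concavity: float
    pixel_p: tuple[int, int] = field(default=(0, 0))
    pixel_q: tuple[int, int] = field(default=(0, 0))

    @property
    def length_px(self) -> float:
        return float(np.hypot(*(self.q - self.p)))


def ridge_strength(image: RasterImage, neighbors: int = 4) -> np.ndarray:
    """-Delta_u with a digital Laplacian, replicate-padded at borders."""
    kernel = _LAPLACIAN_4 if neighbors == 4 else _LAPLACIAN_8
    return -convolve(image.pixels, kernel, mode="nearest")


def coarse_segment(image: RasterImage, config: DetectionConfig | None = None) -> RidgePixelSet:
    """Predictor: pixels whose ridge strength exceeds the q-quantile of
    the positive strengths."""
    config = config or DetectionConfig()
    if image.pixels.size == 0:
        raise ParameterError("empty image")
    strength = ridge_strength(image, config.laplacian_neighbors)
    positive = strength[strength > 0]
    if positive.size == 0:
        return RidgePixelSet(np.empty((0, 2), dtype=int), np.empty(0))
    thr = float(np.quantile(positive, config.laplacian_quantile))
    # >= keeps a constant-strength crest intact when the quantile lands
    # exactly on its plateau (typical for clean synthetic ridges)
    rows, cols = np.nonzero(strength >= thr)
    coords = np.column_stack([rows, cols])
    return RidgePixelSet(coords, strength[rows, cols])


def _candidate_pairs(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """All 8-adjacent pairs within the coarse set, each pair once.

    Returns an (K, 2, 2) int array of endpoint pixel coordinates.
    """
    occupancy = np.zeros(shape, dtype=bool)
    occupancy[coords[:, 0], coords[:, 1]] = True
    pairs = []
    for dr, dc in _PAIR_OFFSETS:
        r2 = coords[:, 0] + dr
        c2 = coords[:, 1] + dc
        ok = (r2 >= 0) & (r2 < shape[0]) & (c2 >= 0) & (c2 < shape[1])
        ok[ok] = occupancy[r2[ok], c2[ok]]
        if np.any(ok):
            a = coords[ok]
            b = np.column_stack([r2[ok], c2[ok]])
            pairs.append(np.stack([a, b], axis=1))
    if not pairs:
        return np.empty((0, 2, 2), dtype=int)
    return np.concatenate(pairs, axis=0)


def _profiles(image: RasterImage, pairs: np.ndarray, h: float, m: int
              ) -> np.ndarray:
    """Sampled perpendicular profiles for all candidates.

    Returns a (K, m, 3) array: bilinear intensity at offsets (-h, 0, +h)
    for each of the m sample points of each candidate segment.
    """
    p = pairs[:, 0, :].astype(float)  # (K, 2)
    q = pairs[:, 1, :].astype(float)
    d = q - p
    norm = np.hypot(d[:, 0], d[:, 1])[:, None]
    tang = d / norm
    perp = np.column_stack([-tang[:, 1], tang[:, 0]])  # rotate 90 deg
    t = np.linspace(0.0, 1.0, m)  # includes the endpoints
    base = p[:, None, :] + t[None, :, None] * d[:, None, :]  # (K, m, 2)
    offs = np.array([-h, 0.0, h])
    coords = base[:, :, None, :] + offs[None, None, :, None] * perp[:, None, None, :]
    flat = coords.reshape(-1, 2).T  # (2, K*m*3)
    vals = map_coordinates(image.pixels, flat, order=1, mode="nearest")
    return vals.reshape(pairs.shape[0], m, 3)


def fine_segment(image: RasterImage, coarse: RidgePixelSet,
                 config: DetectionConfig | None = None) -> list[LineSegment]:
    """Corrector: validate 8-adjacent candidate segments by mean concavity.

    Candidates are processed from most negative mean concavity upward;
    a candidate whose two pixels are both already represented by
    accepted segments is skipped. An empty result is valid.
    """
    config = config or DetectionConfig()
    if len(coarse) == 0:
        return []
    pairs = _candidate_pairs(coarse.coords, image.shape)
    if len(pairs) == 0:
        return []
    h = config.profile_offset_px
    m = config.profile_samples
    prof = _profiles(image, pairs, h, m)  # (K, m, 3)
    second_diff = prof[:, :, 0] - 2.0 * prof[:, :, 1] + prof[:, :, 2]
    mean_c = second_diff.mean(axis=1)

    kappa = config.concavity_threshold
    keep = mean_c <= -kappa
    if not np.any(keep):
        return []
    pairs = pairs[keep]
    mean_c = mean_c[keep]
    prof = prof[keep]

    # deterministic processing order: concavity, then lexicographic pixels
    order = np.lexsort((pairs[:, 1, 1], pairs[:, 1, 0],
                        pairs[:, 0, 1], pairs[:, 0, 0], mean_c))
    # An accepted segment represents every coarse pixel inside its
    # perpendicular band (|perp dist| <= h, projection within the segment):
    # that is the "successive reduction of the coarse segmentation", and it
    # is what suppresses parallel duplicates across the ridge's width.
    # A candidate is redundant only when both pixels are represented by
    # the SAME growing chain; a segment joining two distinct chains is
    # always kept, otherwise every meeting point would leave a 1-px gap.
    from scipy.spatial import cKDTree
    coarse_pts = coarse.coords.astype(float)
    tree = cKDTree(coarse_pts)
    represented: set[tuple[int, int]] = set()
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    segments: list[LineSegment] = []
    refined: dict[tuple[int, int], np.ndarray] = {}
    for k in order:
        a = (int(pairs[k, 0, 0]), int(pairs[k, 0, 1]))
        b = (int(pairs[k, 1, 0]), int(pairs[k, 1, 1]))
        if a in represented and b in represented and find(a) == find(b):
            continue
        union(a, b)
        p_sub, q_sub = _refine_endpoints(pairs[k], prof[k], h)
        # a pixel's subpixel position is fixed by the first (most concave)
        # accepted segment that uses it, so consecutive segments share
        # their common endpoint exactly and chains stay connected
        p_sub = refined.setdefault(a, p_sub)
        q_sub = refined.setdefault(b, q_sub)
        segments.append(LineSegment(p_sub, q_sub, float(mean_c[k]),
                                    pixel_p=a, pixel_q=b))
        pa = pairs[k, 0].astype(float)
        pb = pairs[k, 1].astype(float)
        d = pb - pa
        seg_len = float(np.hypot(*d))
        mid = (pa + pb) / 2.0
        near = tree.query_ball_point(mid, seg_len / 2.0 + h)
        tang = d / seg_len
        for idx in near:
            rel = coarse_pts[idx] - pa
            t = float(rel @ tang)
            if -1e-9 <= t <= seg_len + 1e-9:
                perp = abs(rel[0] * tang[1] - rel[1] * tang[0])
                if perp <= h:
                    pix = (int(coarse_pts[idx][0]), int(coarse_pts[idx][1]))
                    represented.add(pix)
                    union(pix, a)
    return segments


def _refine_endpoints(pair: np.ndarray, prof: np.ndarray, h: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Shift each endpoint perpendicular to the segment onto the
    parabolic maximum of its 3-point profile, clamped to [-h, h]."""
    p = pair[0].astype(float)
    q = pair[1].astype(float)
    d = q - p
    tang = d / np.hypot(*d)
    perp = np.array([-tang[1], tang[0]])
    out = []
    for point, profile in ((p, prof[0]), (q, prof[-1])):
        um, u0, up = profile
        denom = up - 2.0 * u0 + um
        if denom < 0:  # concave: a genuine perpendicular maximum exists
            delta = -h * (up - um) / (2.0 * denom)
            delta = float(np.clip(delta, -h, h))
        else:
            delta = 0.0
        out.append(point + delta * perp)
    return out[0], out[1]


def segments_to_frame(segments: list[LineSegment]) -> pd.DataFrame:
    """Debug export: accepted segments as x1,y1,x2,y2,concavity rows
    (x = column, y = row, matching image-viewer conventions)."""
    return pd.DataFrame({
        "x1": [s.p[1] for s in segments],
        "y1": [s.p[0] for s in segments],
        "x2": [s.q[1] for s in segments],
        "y2": [s.q[0] for s in segments],
        "concavity": [s.mean_concavity for s in segments],
    })


def save_segments_csv(segments: list[LineSegment], path: str | Path) -> None:
    segments_to_frame(segments).to_csv(path, index=False)
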