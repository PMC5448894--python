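"""Axial orientation statistics of straight filament parts.

A filament part has an orientation but no direction, so angles are
*axial*: identified modulo 180 degrees and analysed on the doubled-angle
circle. Every statistic is weighted by part length — a long stress fiber
counts for more oriented material than a short fragment.

Given parts (theta_i, w_i) with axial angle theta_i and length w_i:

* length-weighted histogram over [0, 180) (the polar plot of which is
  mirrored at the origin);
* von Mises fit on the half circle: with phi_i = 2 theta_i,
  C = sum w cos phi / sum w, S = sum w sin phi / sum w,
  R = sqrt(C^2 + S^2), mu = atan2(S, C) / 2 in [0, 180),
  kappa = A1^{-1}(R) by the standard three-branch approximation. When
  the single-mode assumption is contradicted (e.g. two perpendicular
  families of equal length) the resultant cancels and the fit approaches
  the uniform density, kappa -> 0;
* orientation dispersion d = (1 - R) * 0.5 rad = (1 - R) * 28.6479 deg:
  0 deg means exactly one preferred orientation, 28.65 deg a uniform
  distribution of oriented length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ParameterError

#: Upper end of the dispersion scale: 0.5 radian in degrees.
DISPERSION_MAX_DEG = float(np.degrees(0.5))  # 28.6479...

#: Sentinel cap for the concentration of (near-)degenerate resultants.
KAPPA_CAP = 500.0


@dataclass
class OrientationStats:
    """Length-weighted axial statistics of straight filament parts."""

    histogram: np.ndarray
    bin_edges_deg: np.ndarray
    mu_deg: float
    kappa: float
    R: float
    dispersion_deg: float


def angle_histogram(angles_deg: np.ndarray, lengths: np.ndarray,
                    n_bins: int = 36) -> tuple[np.ndarray, np.ndarray]:
    """Length-weighted histogram of axial angles over [0, 180).

    Each straight part contributes its length to the bin containing its
    angle mod 180. With no parts the histogram is all-zero. Returns
    (weights, bin_edges_deg); the weights sum to the total part length.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    angles = np.asarray(angles_deg, dtype=float) % 180.0
    angles[angles >= 180.0] = 0.0  # tiny negatives round up to exactly 180
    lengths = np.asarray(lengths, dtype=float)
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    hist, _ = np.histogram(angles, bins=edges, weights=lengths)
    return hist, edges


def _a1_inv(r: float) -> float:
    """Inverse of A1(k) = I1(k)/I0(k), Best & Fisher style approximation."""
    if r < 0.53:
        return 2.0 * r + r ** 3 + 5.0 * r ** 5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    denom = r ** 3 - 4.0 * r ** 2 + 3.0 * r
    if denom <= 0:
        return KAPPA_CAP
    return min(1.0 / denom, KAPPA_CAP)


def fit_axial_von_mises(angles_deg, lengths) -> tuple[float, float, float]:
    """Length-weighted von Mises fit of axial angles (doubled-angle method).

    Returns (mu_deg in [0, 180), kappa >= 0, mean resultant length R in
    [0, 1]). kappa is capped at a large sentinel for R -> 1.
    Raises if the total length is zero (statistics undefined).
    """
    angles = np.asarray(angles_deg, dtype=float)
    w = np.asarray(lengths, dtype=float)
    total = float(w.sum())
    if total <= 0:
        raise ParameterError("orientation statistics undefined for zero total length")
    phi = np.radians(2.0 * angles)
    c = float(np.sum(w * np.cos(phi)) / total)
    s = float(np.sum(w * np.sin(phi)) / total)
    r = float(min(np.hypot(c, s), 1.0))
    # resultant of doubled angles ~ 0: no preferred axis, mu is arbitrary
    mu = float(np.degrees(np.arctan2(s, c)) / 2.0 % 180.0)
    if mu >= 180.0:  # tiny negative angles round up to exactly 180
        mu = 0.0
    kappa = _a1_inv(r)
    return mu, kappa, r


def orientation_dispersion(R: float) -> float:
    """Map the mean resultant length to the dispersion scale in degrees.

    Linear in R: dispersion = (1 - R) * 28.6479 deg, i.e. 0 for perfect
    alignment and 28.65 deg (2 d.p.) for a uniform axial distribution.
    """
    if not 0.0 <= R <= 1.0:
        raise ParameterError(f"R must be in [0, 1], got {R}")
    return (1.0 - R) * DISPERSION_MAX_DEG


def compute_orientation_stats(angles_deg, lengths, n_bins: int = 36) -> OrientationStats:
    """Histogram + von Mises fit + dispersion for a set of straight parts."""
    hist, edges = angle_histogram(angles_deg, lengths, n_bins)
    mu, kappa, r = fit_axial_von_mises(angles_deg, lengths)
    return OrientationStats(histogram=hist, bin_edges_deg=edges, mu_deg=mu,
                            kappa=kappa, R=r,
                            dispersion_deg=orientation_dispersion(r))


def trail_parts(graph, trails) -> tuple[np.ndarray, np.ndarray]:
    """Axial angle (deg) and length (um) of every straight part in `trails`.

    Parts are the node-to-node edges of each trail; lengths are converted
    with the trail's own pixel calibration (length_um / length_px).
    """
    from .geometry import axial_angle_deg
    angles: list[float] = []
    lengths: list[float] = []
    for t in trails:
        scale = t.length_um / t.length_px if t.length_px > 0 else 1.0
        for u, v in zip(t.nodes[:-1], t.nodes[1:]):
            pu, pv = graph.pos(u), graph.pos(v)
            angles.append(axial_angle_deg(pu, pv))
            lengths.append(float(np.hypot(*(pv - pu))) * scale)
    return np.asarray(angles), np.asarray(lengths)
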