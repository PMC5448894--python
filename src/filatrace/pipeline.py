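"""End-to-end quantification: preprocess -> ridge -> graph -> statistics.

One call turns a calibrated micrograph into the per-cell metric row used
throughout: filament number, total / average / maximum filament length
in micrometres, and the axial orientation statistics (mu, kappa, R,
orientation dispersion). Fixed configuration and input give a
byte-identical row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graph as fg
from . import orientation as ori
from . import preprocess as pp
from . import ridge
from .image import ParameterError, RasterImage

#: Column order of the per-cell metrics CSV.
METRIC_COLUMNS = [
    "filament_number", "total_length_um", "average_length_um",
    "max_length_um", "mu_deg", "kappa", "R", "dispersion_deg",
]


@dataclass
class RunConfig:
    """All tunable parameters of one quantification run."""

    pixel_size_um: float = 1.0
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    detection: ridge.DetectionConfig = field(default_factory=ridge.DetectionConfig)
    merge_tol_px: float = 0.75
    simplify_tol_px: float = fg.SIMPLIFY_TOL_PX
    spur_len_px: float = fg.SPUR_LEN_PX
    stitch_radius_px: float = 8.0
    debris_len_px: float = 6.0
    debris_dist_px: float = 3.0
    min_enclosed_deg: float = fg.MIN_ENCLOSED_DEG
    min_length_um: float = 0.0  # optional filter; 0 keeps single-edge trails
    n_bins: int = 36

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")

    def describe(self) -> dict:
        """Every parameter actually used, for the audit log."""
        return {
            "pixel_size_um": self.pixel_size_um,
            "denoise_weight": self.preprocess.denoise_weight,
            "tophat_radius_px": self.preprocess.tophat_radius_px,
            "laplacian_quantile": self.detection.laplacian_quantile,
            "concavity_threshold": self.detection.concavity_threshold,
            "profile_offset_px": self.detection.profile_offset_px,
            "profile_samples": self.detection.profile_samples,
            "laplacian_neighbors": self.detection.laplacian_neighbors,
            "merge_tol_px": self.merge_tol_px,
            "simplify_tol_px": self.simplify_tol_px,
            "spur_len_px": self.spur_len_px,
            "min_enclosed_deg": self.min_enclosed_deg,
            "min_length_um": self.min_length_um,
            "n_bins": self.n_bins,
        }


@dataclass
class QuantifyResult:
    """Everything produced for one image."""

    metrics: fg.FilamentMetrics
    stats: ori.OrientationStats | None
    graph: fg.FilamentGraph
    trails: list[fg.FilamentTrail]
    preprocessed: RasterImage

    def to_row(self) -> dict:
        row = self.metrics.to_dict()
        if self.stats is not None:
            row.update(mu_deg=self.stats.mu_deg, kappa=self.stats.kappa,
                       R=self.stats.R, dispersion_deg=self.stats.dispersion_deg)
        else:
            row.update(mu_deg=None, kappa=None, R=None, dispersion_deg=None)
        return {k: row[k] for k in METRIC_COLUMNS}


def quantify(image: RasterImage, config: RunConfig | None = None) -> QuantifyResult:
    """Run the full three-step quantification on one image.

    Zero detections are a valid outcome: the row then carries filament
    number 0 and missing length/orientation fields.
    """
    config = config or RunConfig()
    image = RasterImage(image.pixels, config.pixel_size_um, dict(image.meta))
    pre = pp.preprocess(image, config.preprocess)
    coarse = ridge.coarse_segment(pre, config.detection)
    segments = ridge.fine_segment(pre, coarse, config.detection)
    graph = fg.build_graph(segments, config.merge_tol_px,
                           config.simplify_tol_px, config.spur_len_px)
    trails = fg.decompose_with_cleanup(
        graph, config.min_enclosed_deg, config.pixel_size_um,
        debris_len_px=config.debris_len_px,
        debris_dist_px=config.debris_dist_px,
        stitch_radius_px=config.stitch_radius_px,
        spur_len_px=config.spur_len_px,
        simplify_tol_px=config.simplify_tol_px)
    if config.min_length_um > 0:
        trails = [t for t in trails if t.length_um >= config.min_length_um]
    metrics = fg.measure(trails)
    stats = None
    if trails:
        angles, lengths = ori.trail_parts(graph, trails)
        if lengths.sum() > 0:
            stats = ori.compute_orientation_stats(angles, lengths, config.n_bins)
    return QuantifyResult(metrics=metrics, stats=stats, graph=graph,
                          trails=trails, preprocessed=pre)


def rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(rows[0].keys()) if rows else METRIC_COLUMNS)


def aggregate(frame: pd.DataFrame, group_column: str) -> pd.DataFrame:
    """Mean +- sample SD (n-1 denominator) of each metric per group.

    SD for a single-row group is reported as missing. Raises on empty
    input.
    """
    if frame.empty:
        raise ParameterError("cannot aggregate an empty table")
    if group_column not in frame.columns:
        raise ParameterError(f"missing group column {group_column!r}")
    numeric = [c for c in frame.columns
               if c != group_column and pd.api.types.is_numeric_dtype(frame[c])]
    out_rows = []
    for key, sub in frame.groupby(group_column, sort=True):
        row: dict = {group_column: key, "n": len(sub)}
        for c in numeric:
            vals = sub[c].dropna().to_numpy(dtype=float)
            row[f"{c}_mean"] = float(np.mean(vals)) if len(vals) else None
            row[f"{c}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out_rows.append(row)
    return pd.DataFrame(out_rows)
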