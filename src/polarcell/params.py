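"""Tunable parameters of the polarity / division pipeline.

The defaults encode the published analysis settings: a 15-px polarity
identification zone measured inward from the cell boundary, a 10-px-radius
exclusion disk at the cell center, intensity quantization into five k-means
bins, removal of speckles smaller than 5 px, and the >1.5x / <1.2x sister
ratio thresholds for asymmetric / symmetric division calls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any


@dataclass(frozen=True)
class PolarityParams:
    """Parameter set shared by the polarity and paired-daughter analyses.

    Parameters
    ----------
    zone_width_px:
        Width of the polarity identification zone: within-mask pixels at
        Euclidean distance <= this from the cell boundary, in pixels.
    exclusion_radius_px:
        Radius of the closed exclusion disk around the mask centroid.
    n_bins:
        Number of 1D k-means intensity bins.
    min_cluster_px:
        Minimum surviving cluster size; components *strictly smaller* are
        discarded as speckles (a 5-px component survives under the default).
    asym_threshold:
        Sister ratio strictly above this is an asymmetric division.
    sym_threshold:
        Sister ratio strictly below this is a symmetric division; ratios in
        ``[sym_threshold, asym_threshold]`` are indeterminate.
    top_bins:
        How many of the brightest k-means bins feed cluster candidates
        (the dimmest bin is never a candidate). Two bins by default: shot
        noise spreads a bright polar cap across adjacent bins, and a
        single-bin rule would estimate the cap direction from only the
        upper-noise subset of cap pixels.
    coloc_angle_deg:
        Two polar channels whose polarization angle is <= this are counted
        as copolarized.
    min_area_px:
        Minimum connected-component area for a valid cell mask.
    median_filter_px:
        Side of the square median (despeckle) filter applied to each
        background-subtracted channel before intensity binning; 0
        disables. Suppresses isolated shot-noise maxima so the brightest
        k-means bin reflects spatial structure rather than the upper
        tail of pixel noise.
    cluster_scope:
        ``"mask"`` detects clusters over the whole cell mask (zone
        membership reported per cluster); ``"zone"`` restricts candidate
        pixels to the polarity identification zone.
    erode_px:
        Pixels of erosion applied to each daughter mask before intensity
        summation (0 disables; labeling already keeps daughters disjoint).
    """

    zone_width_px: float = 15.0
    exclusion_radius_px: float = 10.0
    n_bins: int = 5
    min_cluster_px: int = 5
    asym_threshold: float = 1.5
    sym_threshold: float = 1.2
    top_bins: int = 2
    coloc_angle_deg: float = 30.0
    min_area_px: int = 50
    median_filter_px: int = 3
    cluster_scope: str = "mask"
    erode_px: int = 0

    def __post_init__(self) -> None:
        if self.zone_width_px < 0:
            raise ValueError("zone_width_px must be >= 0")
        if self.exclusion_radius_px < 0:
            raise ValueError("exclusion_radius_px must be >= 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.min_cluster_px < 1:
            raise ValueError("min_cluster_px must be >= 1")
        if not self.asym_threshold > self.sym_threshold >= 1.0:
            raise ValueError("need asym_threshold > sym_threshold >= 1")
        if not 1 <= self.top_bins < self.n_bins:
            raise ValueError("top_bins must be in [1, n_bins)")
        if self.cluster_scope not in ("mask", "zone"):
            raise ValueError("cluster_scope must be 'mask' or 'zone'")

    def replace(self, **kwargs: Any) -> "PolarityParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
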