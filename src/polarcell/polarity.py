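"""Per-channel polarity calling.

A channel is *polar* when the bright signal sits in a boundary-proximal
patch: pixels in the brightest k-means intensity bin are grouped into
8-connected components, speckles smaller than ``min_cluster_px`` are
discarded, and the cell is called polar iff the convex hull of all
surviving cluster pixels stays clear of the exclusion disk at the cell
center. The cluster direction (centroid of the bright pixels relative to
the mask centroid) gives the polarization angle between channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage import measure

from .angles import angle_between_directions, angle_to_axis, direction_deg
from .errors import UndefinedAngle, UndefinedDirection
from .kmeans1d import IntensityBins, kmeans_1d
from .params import PolarityParams
from .preprocess import (
    CellGeometry,
    ImageStack,
    compute_geometry,
    exclusion_area,
    polarity_zone,
    segment_cell,
    subtract_background,
    z_project,
)


@dataclass
class Cluster:
    """One surviving bright-signal component of a channel."""

    pixels: np.ndarray  # (n, 2) array of (x, y) integer pixel coordinates
    size_px: int
    mean_intensity: float
    weighted_centroid_px: tuple[float, float]
    direction_deg: float  # absolute, [0, 360)
    angle_to_axis_deg: float  # vs. major axis, [0, 90]
    in_zone_fraction: float  # fraction of pixels inside the polarity zone


@dataclass
class PolarityCall:
    """Polar / nonpolar decision for one channel of one cell."""

    channel: str
    is_polar: bool
    clusters: list[Cluster]
    direction_deg: float | None  # None when no clusters survive
    angle_to_axis_deg: float | None
    hull_vertices: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class PolarizationAngle:
    """Angle between a channel's cluster direction and the reference's."""

    reference: str
    target: str
    angle_deg: float
    copolarized: bool


@dataclass
class CellScore:
    """Full polarity scoring of one cell: all channels plus angles."""

    calls: dict[str, PolarityCall]
    angles: dict[str, PolarizationAngle]  # target channel -> angle vs ref
    geometry: CellGeometry
    reference: str


# ---------------------------------------------------------------------------


def bin_channel(
    channel_img: np.ndarray, mask: np.ndarray, params: PolarityParams
) -> IntensityBins:
    """k-means intensity binning of the within-mask pixels of one channel."""
    return kmeans_1d(channel_img[mask], k=params.n_bins)


def extract_clusters(
    bins: IntensityBins,
    channel_img: np.ndarray,
    geom: CellGeometry,
    params: PolarityParams,
) -> list[Cluster]:
    """Bright-bin connected components with speckle exclusion.

    Candidate pixels are those assigned to the ``top_bins`` brightest bins
    (default: the single brightest). 8-connected components strictly
    smaller than ``min_cluster_px`` are removed as speckles. A degenerate
    binning (all intensities equal) yields no clusters.
    """
    mask = geom.mask
    if params.cluster_scope == "zone":
        scope = polarity_zone(geom, params)
    else:
        scope = mask
    if bins.n_bins < 2:
        return []
    # the dimmest bin is never a candidate, even when fewer effective
    # bins than top_bins remain after a degenerate binning; a candidate
    # bin must also reach half the brightest center, so that a dim cell
    # body sharing a bin boundary with a bright cap is never swept in
    # (scale-invariant contrast gate)
    cutoff = max(bins.n_bins - params.top_bins, 1)
    bright = np.flatnonzero(bins.centers >= 0.5 * bins.centers[-1])
    cutoff = max(cutoff, int(bright[0]) if len(bright) else cutoff)
    candidate_flat = bins.assignments >= cutoff
    candidate = np.zeros(mask.shape, dtype=bool)
    candidate[mask] = candidate_flat
    candidate &= scope

    labels = measure.label(candidate, connectivity=2)
    zone = polarity_zone(geom, params)
    cx, cy = geom.centroid_px
    clusters: list[Cluster] = []
    for region in measure.regionprops(labels, intensity_image=channel_img):
        if region.area < params.min_cluster_px:
            continue
        coords = region.coords  # (n, 2) as (row, col)
        intens = channel_img[coords[:, 0], coords[:, 1]]
        total = float(intens.sum())
        if total > 0:
            wy = float(np.average(coords[:, 0], weights=intens))
            wx = float(np.average(coords[:, 1], weights=intens))
        else:
            wy = float(coords[:, 0].mean())
            wx = float(coords[:, 1].mean())
        direction = direction_deg(wx - cx, wy - cy)
        clusters.append(
            Cluster(
                pixels=coords[:, ::-1].copy(),  # (x, y)
                size_px=int(region.area),
                mean_intensity=float(intens.mean()),
                weighted_centroid_px=(wx, wy),
                direction_deg=direction,
                angle_to_axis_deg=angle_to_axis(
                    direction, geom.major_axis_deg
                ),
                in_zone_fraction=float(
                    zone[coords[:, 0], coords[:, 1]].mean()
                ),
            )
        )
    return clusters


def cluster_hull(clusters: list[Cluster]):
    """Convex hull (shapely geometry) of all cluster pixel centers."""
    pts = np.vstack([c.pixels for c in clusters])
    return MultiPoint(pts).convex_hull


def hull_polarity_test(
    clusters: list[Cluster], exclusion_disk: np.ndarray
) -> bool:
    """Polar iff the joint convex hull avoids the exclusion area.

    The exclusion area is a pixel set; overlap means some disk pixel
    center lies in the closed hull. No surviving clusters -> nonpolar.
    """
    if not clusters:
        return False
    hull = cluster_hull(clusters)
    ys, xs = np.nonzero(exclusion_disk)
    if len(xs) == 0:
        return True
    disk_points = shapely.points(np.column_stack([xs, ys]))
    return not bool(np.any(shapely.intersects(hull, disk_points)))


def cluster_direction(
    clusters: list[Cluster], geom: CellGeometry, channel_img: np.ndarray
) -> tuple[float, float]:
    """Direction of the union of cluster pixels from the mask centroid.

    Returns ``(absolute_direction_deg, angle_to_axis_deg)`` where the
    direction points from the mask centroid to the intensity-weighted
    centroid of all surviving cluster pixels and the second value is the
    acute angle to the cell's major axis.
    """
    if not clusters:
        raise UndefinedDirection("no surviving clusters")
    pts = np.vstack([c.pixels for c in clusters])  # (n, 2) (x, y)
    weights = channel_img[pts[:, 1], pts[:, 0]]
    if weights.sum() <= 0:
        weights = np.ones(len(pts))
    wx = float(np.average(pts[:, 0], weights=weights))
    wy = float(np.average(pts[:, 1], weights=weights))
    cx, cy = geom.centroid_px
    absolute = direction_deg(wx - cx, wy - cy)
    return absolute, angle_to_axis(absolute, geom.major_axis_deg)


def polarization_angle(
    ref: PolarityCall, target: PolarityCall, coloc_angle_deg: float = 30.0
) -> PolarizationAngle:
    """Angle between two channels' cluster directions, folded to [0, 180]."""
    if not (ref.is_polar and target.is_polar):
        raise UndefinedAngle(
            f"polarization angle needs both channels polar "
            f"({ref.channel}: {ref.is_polar}, {target.channel}: "
            f"{target.is_polar})"
        )
    assert ref.direction_deg is not None and target.direction_deg is not None
    ang = angle_between_directions(ref.direction_deg, target.direction_deg)
    return PolarizationAngle(
        reference=ref.channel,
        target=target.channel,
        angle_deg=ang,
        copolarized=ang <= coloc_angle_deg,
    )


def call_channel(
    channel_name: str,
    channel_img: np.ndarray,
    geom: CellGeometry,
    exclusion_disk: np.ndarray,
    params: PolarityParams,
) -> PolarityCall:
    """Polarity decision for one background-subtracted channel image.

    The channel is despeckled with a small median filter (see
    ``median_filter_px``) before binning, so isolated shot-noise maxima
    do not masquerade as bright structure.
    """
    if params.median_filter_px > 1:
        channel_img = ndimage.median_filter(
            channel_img, size=params.median_filter_px
        )
    bins = bin_channel(channel_img, geom.mask, params)
    clusters = extract_clusters(bins, channel_img, geom, params)
    polar = hull_polarity_test(clusters, exclusion_disk)
    if clusters:
        absolute, to_axis = cluster_direction(clusters, geom, channel_img)
        hull = cluster_hull(clusters)
        verts = np.asarray(
            shapely.get_coordinates(hull), dtype=float
        )
    else:
        absolute = to_axis = None
        verts = None
    return PolarityCall(
        channel=channel_name,
        is_polar=polar,
        clusters=clusters,
        direction_deg=absolute,
        angle_to_axis_deg=to_axis,
        hull_vertices=verts,
    )


def score_cell(
    stack: ImageStack,
    params: PolarityParams | None = None,
    reference_channel: str = "tubulin",
) -> CellScore:
    """Run the full single-cell pipeline on one image stack.

    Projection -> composite mask -> background subtraction -> per-channel
    polarity call -> polarization angle of every channel against the
    reference. Channels with no surviving clusters are scored nonpolar.
    """
    params = params or PolarityParams()
    if reference_channel not in stack.channel_names:
        raise ValueError(f"reference channel {reference_channel!r} missing")
    proj = z_project(stack)
    cell = segment_cell(proj, min_area=params.min_area_px)
    proj = subtract_background(proj, cell)
    geom = compute_geometry(cell)
    disk = exclusion_area(geom, params)

    calls = {
        name: call_channel(name, proj.channel(name), geom, disk, params)
        for name in stack.channel_names
    }
    ref_call = calls[reference_channel]
    angles: dict[str, PolarizationAngle] = {}
    for name, call in calls.items():
        if name == reference_channel:
            continue
        if ref_call.is_polar and call.is_polar:
            angles[name] = polarization_angle(
                ref_call, call, params.coloc_angle_deg
            )
    return CellScore(
        calls=calls, angles=angles, geometry=geom, reference=reference_channel
    )
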