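"""Paired-daughter assay: sister ratios and division-class calls.

After one division, the two daughter cells of a doublet image are
segmented, each marker's pixel intensities are summed per daughter, and
the sister ratio (larger sum over smaller sum) classifies the division:
ratio > 1.5 is asymmetric, ratio < 1.2 symmetric, and the band between is
left indeterminate. Two markers co-segregate when both are asymmetric
into the same daughter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import AmbiguousPair, NoCellFound, NotAPair, UndefinedRatio
from .params import PolarityParams
from .preprocess import (
    ImageStack,
    Projection,
    foreground_mask,
    z_project,
)
from .synth import cosegregation_class


@dataclass
class DaughterPair:
    """Two disjoint daughter masks with per-channel intensity sums.

    Daughter "A" is the larger-area component. Sums are computed after
    per-channel background subtraction against the region outside both
    masks.
    """

    mask_a: np.ndarray
    mask_b: np.ndarray
    sums_a: dict[str, float]
    sums_b: dict[str, float]
    channel_names: tuple[str, ...]


@dataclass
class SisterRatio:
    """Label-free sister ratio of one marker: max sum / min sum."""

    channel: str
    ratio: float
    high_daughter: str  # "A" or "B"


@dataclass
class DivisionCall:
    """Asymmetric / symmetric / indeterminate call for one marker."""

    channel: str
    division_class: str
    ratio: float
    high_daughter: str


@dataclass
class CoSegregation:
    """Joint segregation class of a marker pair in one doublet."""

    channels: tuple[str, str]
    coseg_class: str


# ---------------------------------------------------------------------------


def segment_pair(
    proj: Projection,
    min_area: int = 50,
    erode_px: int = 0,
) -> DaughterPair:
    """Segment a doublet into exactly two daughters and sum intensities.

    Foreground from :func:`polarcell.preprocess.foreground_mask` on the
    across-channel max composite; exactly two 8-connected components of
    at least ``min_area`` px must be present
    (fewer raises :class:`NotAPair`, a qualifying third raises
    :class:`AmbiguousPair`). Optionally erodes each daughter by
    ``erode_px`` before summation.
    """
    composite = proj.composite_max()
    vals = composite.ravel()
    if vals.size == 0 or np.all(vals == vals[0]):
        raise NoCellFound("composite image is constant")
    labels = measure.label(foreground_mask(composite), connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    qualifying = np.flatnonzero(sizes >= min_area)
    if len(qualifying) < 2:
        raise NotAPair(
            f"found {len(qualifying)} component(s) >= {min_area} px"
        )
    if len(qualifying) > 2:
        raise AmbiguousPair(
            f"found {len(qualifying)} components >= {min_area} px"
        )
    first, second = sorted(qualifying, key=lambda lbl: -sizes[lbl])
    mask_a = ndimage.binary_fill_holes(labels == first)
    mask_b = ndimage.binary_fill_holes(labels == second)

    outside = ~(mask_a | mask_b)
    sum_mask_a, sum_mask_b = mask_a, mask_b
    if erode_px > 0:
        structure = ndimage.generate_binary_structure(2, 1)
        sum_mask_a = ndimage.binary_erosion(
            mask_a, structure, iterations=erode_px
        )
        sum_mask_b = ndimage.binary_erosion(
            mask_b, structure, iterations=erode_px
        )
    sums_a: dict[str, float] = {}
    sums_b: dict[str, float] = {}
    for ci, name in enumerate(proj.channel_names):
        img = proj.pixels[ci]
        bg = float(np.median(img[outside]))
        corrected = np.clip(img - bg, 0.0, None)
        sums_a[name] = float(corrected[sum_mask_a].sum())
        sums_b[name] = float(corrected[sum_mask_b].sum())
    return DaughterPair(
        mask_a=mask_a,
        mask_b=mask_b,
        sums_a=sums_a,
        sums_b=sums_b,
        channel_names=proj.channel_names,
    )


def sister_ratio(pair: DaughterPair, channel: str) -> SisterRatio:
    """Sister ratio = max(sum_A, sum_B) / min(sum_A, sum_B)."""
    sa = pair.sums_a[channel]
    sb = pair.sums_b[channel]
    lo = min(sa, sb)
    if lo <= 0:
        raise UndefinedRatio(
            f"channel {channel!r}: daughter with zero total signal"
        )
    return SisterRatio(
        channel=channel,
        ratio=max(sa, sb) / lo,
        high_daughter="A" if sa >= sb else "B",
    )


def classify_division(
    r: SisterRatio, params: PolarityParams | None = None
) -> DivisionCall:
    """Apply the strict >1.5x / <1.2x thresholds to a sister ratio."""
    params = params or PolarityParams()
    if r.ratio > params.asym_threshold:
        cls = "asymmetric"
    elif r.ratio < params.sym_threshold:
        cls = "symmetric"
    else:
        cls = "indeterminate"
    return DivisionCall(
        channel=r.channel,
        division_class=cls,
        ratio=r.ratio,
        high_daughter=r.high_daughter,
    )


def cosegregation(call1: DivisionCall, call2: DivisionCall) -> CoSegregation:
    """Joint class of two markers scored on the same doublet."""
    return CoSegregation(
        channels=(call1.channel, call2.channel),
        coseg_class=cosegregation_class(
            call1.division_class,
            call2.division_class,
            call1.high_daughter,
            call2.high_daughter,
        ),
    )


def score_pair(
    stack: ImageStack, params: PolarityParams | None = None
) -> tuple[DaughterPair, dict[str, DivisionCall], dict[tuple[str, str],
           CoSegregation]]:
    """Full doublet scoring: segmentation, per-marker calls, co-segregation.

    Channels whose ratio is undefined (one daughter at zero signal) are
    omitted from the call dict; callers flag them from the pair sums.
    """
    params = params or PolarityParams()
    proj = z_project(stack)
    pair = segment_pair(
        proj, min_area=params.min_area_px, erode_px=params.erode_px
    )
    calls: dict[str, DivisionCall] = {}
    for name in stack.channel_names:
        try:
            calls[name] = classify_division(sister_ratio(pair, name), params)
        except UndefinedRatio:
            continue
    coseg: dict[tuple[str, str], CoSegregation] = {}
    names = [n for n in stack.channel_names if n in calls]
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            coseg[(n1, n2)] = cosegregation(calls[n1], calls[n2])
    return pair, calls, coseg
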