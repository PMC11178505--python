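"""Synthetic fluorescence cells and daughter doublets with ground truth.

The generator produces the statistical structure the scoring pipeline
assumes rather than photorealistic microscopy: roughly elliptical cell
bodies; per-channel signal that is either spatially uniform across the
cell or concentrated in a boundary-proximal cap of controllable direction
and angular width; optional small bright speckles; Poisson shot noise on
signal plus a uniform background. Daughter doublets carry a programmable
per-marker total-intensity ratio. Every image comes with its ground truth
(polarity, cap direction, sister ratio and division class), so pipeline
recovery can be measured exactly.

Signal is conserved by construction: in the noiseless limit the
within-mask sum of a channel equals ``total_signal`` up to float rounding,
with speckle photons taken out of the uniform budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyCohort, InvalidSpec
from .preprocess import ImageStack, boundary_distance_map

#: ratio strictly above this is an asymmetric division (ground truth rule)
ASYM_RATIO = 1.5
#: ratio strictly below this is a symmetric division (ground truth rule)
SYM_RATIO = 1.2


def classify_ratio(ratio: float) -> str:
    """Ground-truth division class of a sister ratio (>1.5x / <1.2x rule)."""
    if ratio > ASYM_RATIO:
        return "asymmetric"
    if ratio < SYM_RATIO:
        return "symmetric"
    return "indeterminate"


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class ChannelSpec:
    """Signal model for one fluorescence channel of one synthetic cell.

    ``polar_fraction`` of ``total_signal`` goes into a boundary cap
    centered on ``cap_direction_deg`` with angular half-width
    ``cap_halfwidth_deg``; the rest is uniform over the mask. Each of the
    ``n_speckles`` speckles is a compact ``speckle_size_px``-pixel blob
    carrying ``speckle_signal`` units taken out of the uniform budget.
    """

    name: str
    total_signal: float = 3e5
    polar_fraction: float = 0.0
    cap_direction_deg: float = 0.0
    cap_halfwidth_deg: float = 35.0
    n_speckles: int = 0
    speckle_size_px: int = 4
    speckle_signal: float = 2e3

    def __post_init__(self) -> None:
        if not 0.0 <= self.polar_fraction <= 1.0:
            raise InvalidSpec("polar_fraction must be in [0, 1]")
        if not 0.0 <= self.cap_direction_deg < 360.0:
            raise InvalidSpec("cap_direction_deg must be in [0, 360)")
        if self.speckle_size_px < 1:
            raise InvalidSpec("speckle_size_px must be >= 1")
        if self.total_signal < 0 or self.speckle_signal < 0:
            raise InvalidSpec("signal amounts must be >= 0")
        if self.n_speckles < 0:
            raise InvalidSpec("n_speckles must be >= 0")


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Geometry, channels and noise model of one synthetic cell."""

    semiaxes_px: tuple[float, float] = (40.0, 32.0)
    orientation_deg: float = 0.0
    center_px: tuple[float, float] = (64.0, 64.0)
    channels: tuple[ChannelSpec, ...] = ()
    background_level: float = 8.0
    noise_model: str = "poisson"  # none | poisson | poisson+gaussian
    gaussian_sd: float = 0.0
    canvas_shape: tuple[int, int] = (128, 128)  # (y, x)
    n_z: int = 1
    cap_depth_px: float = 12.0
    polar_threshold: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        a, b = self.semiaxes_px
        if not a >= b > 0:
            raise InvalidSpec("need semiaxes a >= b > 0")
        if self.noise_model not in ("none", "poisson", "poisson+gaussian"):
            raise InvalidSpec(f"unknown noise model {self.noise_model!r}")
        if self.n_z < 1:
            raise InvalidSpec("n_z must be >= 1")
        if not self.channels:
            raise InvalidSpec("at least one channel required")
        # canvas must fully contain the ellipse (axis-aligned extents of
        # the rotated ellipse)
        th = np.radians(self.orientation_deg)
        ext_x = np.hypot(a * np.cos(th), b * np.sin(th))
        ext_y = np.hypot(a * np.sin(th), b * np.cos(th))
        cx, cy = self.center_px
        h, w = self.canvas_shape
        if (
            cx - ext_x < 0
            or cx + ext_x > w - 1
            or cy - ext_y < 0
            or cy + ext_y > h - 1
        ):
            raise InvalidSpec("ellipse extends outside the canvas")


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Two daughter cells on one canvas with a per-channel sister ratio.

    ``marker_ratio`` maps channel name to the intended ratio of totals
    high/low (>= 1); ``high_daughter`` says which cell ("A" or "B")
    carries the larger total for each channel. Totals are derived from
    ``cell_a``'s channel specs: the low daughter gets ``total_signal``,
    the high daughter ``ratio * total_signal``.
    """

    cell_a: SyntheticCellSpec
    cell_b: SyntheticCellSpec
    marker_ratio: dict[str, float] = field(default_factory=dict)
    high_daughter: dict[str, str] = field(default_factory=dict)
    bridge: bool = False
    bridge_level: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        names_a = tuple(c.name for c in self.cell_a.channels)
        names_b = tuple(c.name for c in self.cell_b.channels)
        if names_a != names_b:
            raise InvalidSpec("daughters must share channel names")
        if self.cell_a.canvas_shape != self.cell_b.canvas_shape:
            raise InvalidSpec("daughters must share the canvas")
        for name, r in self.marker_ratio.items():
            if r < 1.0:
                raise InvalidSpec(f"marker_ratio[{name!r}] must be >= 1")
        for name, hd in self.high_daughter.items():
            if hd not in ("A", "B"):
                raise InvalidSpec("high_daughter entries must be 'A' or 'B'")

    def ratio_for(self, name: str) -> float:
        return self.marker_ratio.get(name, 1.0)

    def high_for(self, name: str) -> str:
        return self.high_daughter.get(name, "A")


@dataclass
class GroundTruth:
    """Programmed truth stored alongside each synthetic image."""

    is_polar: dict[str, bool] = field(default_factory=dict)
    true_direction_deg: dict[str, float | None] = field(default_factory=dict)
    sister_ratio: dict[str, float] = field(default_factory=dict)
    division_class: dict[str, str] = field(default_factory=dict)
    high_daughter: dict[str, str] = field(default_factory=dict)
    cosegregation: dict[tuple[str, str], str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rasterization


def ellipse_mask(spec: SyntheticCellSpec) -> np.ndarray:
    """Rasterize the cell body: pixel centers inside the rotated ellipse."""
    h, w = spec.canvas_shape
    a, b = spec.semiaxes_px
    cx, cy = spec.center_px
    th = np.radians(spec.orientation_deg)
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _cap_mask(
    mask: np.ndarray, spec: SyntheticCellSpec, chan: ChannelSpec
) -> np.ndarray:
    """Boundary-proximal angular cap: within ``cap_depth_px`` of the
    boundary and within ``cap_halfwidth_deg`` of the cap direction."""
    bdist = boundary_distance_map(mask)
    cx, cy = spec.center_px
    h, w = spec.canvas_shape
    yy, xx = np.mgrid[0:h, 0:w]
    ang = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    dang = np.abs((ang - chan.cap_direction_deg + 180.0) % 360.0 - 180.0)
    with np.errstate(invalid="ignore"):
        near_boundary = bdist <= spec.cap_depth_px
    cap = mask & near_boundary & (dang <= chan.cap_halfwidth_deg)
    if not cap.any():
        raise InvalidSpec("cap region rasterized to zero pixels")
    return cap


def _place_speckles(
    mask: np.ndarray, chan: ChannelSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-pixel speckle intensity field (total = n_speckles*speckle_signal)."""
    field_img = np.zeros(mask.shape, dtype=float)
    if chan.n_speckles == 0:
        return field_img
    ys, xs = np.nonzero(mask)
    per_px = chan.speckle_signal / chan.speckle_size_px
    for _ in range(chan.n_speckles):
        i = rng.integers(len(ys))
        sy, sx = ys[i], xs[i]
        # compact blob: nearest within-mask pixels to the seed
        d2 = (ys - sy) ** 2 + (xs - sx) ** 2
        order = np.argsort(d2, kind="stable")[: chan.speckle_size_px]
        field_img[ys[order], xs[order]] += per_px
    return field_img


def _render_channel(
    mask: np.ndarray,
    spec: SyntheticCellSpec,
    chan: ChannelSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noiseless expected image of one channel (no background)."""
    img = np.zeros(mask.shape, dtype=float)
    n_mask = int(mask.sum())
    speckle_total = chan.n_speckles * chan.speckle_signal
    uniform_budget = chan.total_signal * (1.0 - chan.polar_fraction)
    uniform_budget -= speckle_total
    if uniform_budget < 0:
        raise InvalidSpec(
            "speckle budget exceeds the non-polar share of total_signal"
        )
    img[mask] += uniform_budget / n_mask
    if chan.polar_fraction > 0:
        cap = _cap_mask(mask, spec, chan)
        img[cap] += chan.total_signal * chan.polar_fraction / cap.sum()
    img += _place_speckles(mask, chan, rng)
    return img


def _apply_noise(
    expected: np.ndarray, spec: SyntheticCellSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.noise_model == "none":
        return expected
    noisy = rng.poisson(expected).astype(float)
    if spec.noise_model == "poisson+gaussian":
        noisy = noisy + rng.normal(0.0, spec.gaussian_sd, expected.shape)
    return np.clip(noisy, 0.0, None)


def _stack_slices(
    expected_2d: list[np.ndarray], spec: SyntheticCellSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Build the (C, Z, Y, X) array: the signal lives in the middle z
    slice, the other slices carry background only."""
    c = len(expected_2d)
    h, w = spec.canvas_shape
    out = np.empty((c, spec.n_z, h, w), dtype=float)
    mid = spec.n_z // 2
    for ci, img in enumerate(expected_2d):
        for z in range(spec.n_z):
            expected = (img if z == mid else 0.0) + spec.background_level
            out[ci, z] = _apply_noise(np.asarray(expected, dtype=float)
                                      * np.ones((h, w)), spec, rng)
    return out


# ---------------------------------------------------------------------------
# public generators


def make_cell(
    spec: SyntheticCellSpec, rng: np.random.Generator | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic cell and its ground truth.

    Deterministic given ``spec.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mask = ellipse_mask(spec)
    expected = [_render_channel(mask, spec, ch, rng) for ch in spec.channels]
    pixels = _stack_slices(expected, spec, rng)
    stack = ImageStack(
        pixels=pixels, channel_names=tuple(c.name for c in spec.channels)
    )
    truth = GroundTruth()
    for ch in spec.channels:
        polar = ch.polar_fraction > spec.polar_threshold
        truth.is_polar[ch.name] = polar
        truth.true_direction_deg[ch.name] = (
            ch.cap_direction_deg if ch.polar_fraction > 0 else None
        )
    return stack, truth


def make_pair(
    spec: SyntheticPairSpec, rng: np.random.Generator | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render a daughter doublet with programmed per-channel sister ratios.

    The two cells are rasterized on the shared canvas; their masks must be
    disjoint. In the noiseless limit the ratio of within-mask sums equals
    ``marker_ratio`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mask_a = ellipse_mask(spec.cell_a)
    mask_b = ellipse_mask(spec.cell_b)
    if (mask_a & mask_b).any():
        raise InvalidSpec("daughter masks overlap")

    names = tuple(c.name for c in spec.cell_a.channels)
    expected: list[np.ndarray] = []
    truth = GroundTruth()
    for ci, name in enumerate(names):
        chan_a = spec.cell_a.channels[ci]
        chan_b = spec.cell_b.channels[ci]
        ratio = spec.ratio_for(name)
        high = spec.high_for(name)
        low_total = chan_a.total_signal
        total_a = low_total * (ratio if high == "A" else 1.0)
        total_b = low_total * (ratio if high == "B" else 1.0)
        img_a = _render_channel(
            mask_a, spec.cell_a, replace(chan_a, total_signal=total_a), rng
        )
        img_b = _render_channel(
            mask_b, spec.cell_b, replace(chan_b, total_signal=total_b), rng
        )
        img = img_a + img_b
        if spec.bridge and ci == 0:
            img = img + _bridge_image(spec, mask_a, mask_b)
        expected.append(img)
        truth.sister_ratio[name] = ratio
        truth.division_class[name] = classify_ratio(ratio)
        truth.high_daughter[name] = high
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            truth.cosegregation[(n1, n2)] = cosegregation_class(
                truth.division_class[n1],
                truth.division_class[n2],
                truth.high_daughter[n1],
                truth.high_daughter[n2],
            )
    pixels = _stack_slices(expected, spec.cell_a, rng)
    return ImageStack(pixels=pixels, channel_names=names), truth


def _bridge_image(
    spec: SyntheticPairSpec, mask_a: np.ndarray, mask_b: np.ndarray
) -> np.ndarray:
    """Thin dim line between the cell centers (reference channel only)."""
    from skimage.draw import line

    img = np.zeros(mask_a.shape, dtype=float)
    ax, ay = spec.cell_a.center_px
    bx, by = spec.cell_b.center_px
    rr, cc = line(int(round(ay)), int(round(ax)), int(round(by)),
                  int(round(bx)))
    img[rr, cc] = spec.bridge_level
    img[mask_a | mask_b] = 0.0
    return img


def cosegregation_class(
    class1: str, class2: str, high1: str, high2: str
) -> str:
    """Joint segregation class of two markers of one doublet."""
    if class1 == "indeterminate" or class2 == "indeterminate":
        return "indeterminate"
    if class1 == "asymmetric" and class2 == "asymmetric":
        return (
            "both_asymmetric_concordant"
            if high1 == high2
            else "both_asymmetric_discordant"
        )
    if class1 == "asymmetric":
        return "only_first_asymmetric"
    if class2 == "asymmetric":
        return "only_second_asymmetric"
    return "both_symmetric"


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    n_cells: int,
    polar_fraction_of_cohort: float = 0.6,
    seed: int = 0,
    channel_names: tuple[str, ...] = ("tubulin", "marker"),
    condition: str = "CTRL",
    n_replicates: int = 3,
    noise_model: str = "poisson",
    polar_fraction_range: tuple[float, float] = (0.6, 0.9),
    angle_offset_deg: float | None = None,
) -> tuple[list[tuple[ImageStack, GroundTruth]], pd.DataFrame]:
    """Generate a labeled cohort of single cells.

    A ``polar_fraction_of_cohort`` share of cells get boundary caps (with
    per-channel polar fractions drawn from ``polar_fraction_range``); the
    rest are spatially uniform. When ``angle_offset_deg`` is given, every
    non-reference channel's cap is rotated by exactly that offset from the
    reference cap, which makes the programmed polarization angle known.
    Returns the rendered cells and a truth table with condition/replicate
    labels (cells assigned to replicates round-robin).
    """
    if n_cells < 1:
        raise EmptyCohort("n_cells must be >= 1")
    if not 0.0 <= polar_fraction_of_cohort <= 1.0:
        raise InvalidSpec("cohort polar fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_polar = int(round(n_cells * polar_fraction_of_cohort))
    polar_flags = np.zeros(n_cells, dtype=bool)
    polar_flags[:n_polar] = True
    rng.shuffle(polar_flags)

    cells: list[tuple[ImageStack, GroundTruth]] = []
    rows = []
    for i in range(n_cells):
        a = rng.uniform(34.0, 44.0)
        b = rng.uniform(28.0, 34.0)
        orient = rng.uniform(0.0, 180.0)
        cap_dir = rng.uniform(0.0, 360.0)
        chans = []
        for j, name in enumerate(channel_names):
            if polar_flags[i]:
                pf = rng.uniform(*polar_fraction_range)
                if angle_offset_deg is not None and j > 0:
                    cdir = (cap_dir + angle_offset_deg) % 360.0
                elif j > 0:
                    cdir = rng.uniform(0.0, 360.0)
                else:
                    cdir = cap_dir
            else:
                pf = 0.0
                cdir = 0.0
            chans.append(
                ChannelSpec(name=name, polar_fraction=pf,
                            cap_direction_deg=cdir)
            )
        cell_seed = int(rng.integers(2**31))
        spec = SyntheticCellSpec(
            semiaxes_px=(a, b),
            orientation_deg=orient,
            channels=tuple(chans),
            noise_model=noise_model,
            seed=cell_seed,
        )
        stack, truth = make_cell(spec)
        cells.append((stack, truth))
        for ch in spec.channels:
            rows.append(
                {
                    "cell_id": f"cell_{i:04d}",
                    "condition": condition,
                    "replicate": f"rep{i % n_replicates + 1}",
                    "channel": ch.name,
                    "is_polar": truth.is_polar[ch.name],
                    "true_direction_deg": truth.true_direction_deg[ch.name],
                    "polar_fraction": ch.polar_fraction,
                    "seed": cell_seed,
                }
            )
    return cells, pd.DataFrame(rows)


def make_pair_cohort(
    n_pairs: int,
    ratio: float | dict[str, float] = 2.0,
    seed: int = 0,
    channel_names: tuple[str, ...] = ("numb", "cdc42"),
    condition: str = "CTRL",
    n_replicates: int = 3,
    noise_model: str = "poisson",
    concordant: bool = True,
    total_signal: float = 5e4,
) -> tuple[list[tuple[ImageStack, GroundTruth]], pd.DataFrame]:
    """Generate a labeled cohort of daughter doublets.

    Every pair is programmed with the same per-channel sister ratio(s);
    the identity of the high daughter is randomized per pair (shared
    across channels when ``concordant``).
    """
    if n_pairs < 1:
        raise EmptyCohort("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    ratios = (
        {n: float(ratio) for n in channel_names}
        if np.isscalar(ratio)
        else dict(ratio)
    )
    pairs: list[tuple[ImageStack, GroundTruth]] = []
    rows = []
    for i in range(n_pairs):
        pair_seed = int(rng.integers(2**31))
        high = "A" if rng.random() < 0.5 else "B"
        high_map = {}
        for name in channel_names:
            if concordant:
                high_map[name] = high
            else:
                high_map[name] = "A" if rng.random() < 0.5 else "B"
        sem = (rng.uniform(24.0, 28.0), rng.uniform(20.0, 24.0))
        sem2 = (rng.uniform(24.0, 28.0), rng.uniform(20.0, 24.0))
        chans = tuple(
            ChannelSpec(name=n, total_signal=total_signal)
            for n in channel_names
        )
        cell_a = SyntheticCellSpec(
            semiaxes_px=(max(sem), min(sem)),
            orientation_deg=rng.uniform(0, 180),
            center_px=(54.0, 64.0),
            channels=chans,
            noise_model=noise_model,
            canvas_shape=(128, 192),
        )
        cell_b = SyntheticCellSpec(
            semiaxes_px=(max(sem2), min(sem2)),
            orientation_deg=rng.uniform(0, 180),
            center_px=(138.0, 64.0),
            channels=chans,
            noise_model=noise_model,
            canvas_shape=(128, 192),
        )
        spec = SyntheticPairSpec(
            cell_a=cell_a,
            cell_b=cell_b,
            marker_ratio=ratios,
            high_daughter=high_map,
            seed=pair_seed,
        )
        stack, truth = make_pair(spec)
        pairs.append((stack, truth))
        for name in channel_names:
            rows.append(
                {
                    "pair_id": f"pair_{i:04d}",
                    "condition": condition,
                    "replicate": f"rep{i % n_replicates + 1}",
                    "channel": name,
                    "true_ratio": truth.sister_ratio[name],
                    "true_class": truth.division_class[name],
                    "high_daughter": truth.high_daughter[name],
                    "seed": pair_seed,
                }
            )
    return pairs, pd.DataFrame(rows)
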