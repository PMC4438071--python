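"""Spatio-temporal LBP descriptors on video volumes.

A video volume is a 3-D float array indexed ``[y, x, t]`` (height, width,
length).  Three families of descriptors are provided:

``lbp_top``
    LBP on Three Orthogonal Planes: every voxel is LBP-coded three times,
    once in its XY plane (the frame), once in its XT plane (the slice at
    fixed y, axes x and t) and once in its YT plane (fixed x, axes y and t).
    Per spatial block the three 2**P-bin histograms are concatenated in XY,
    XT, YT order.

``lbp_sip``
    Six Intersection Points: only the six unique neighbors on the three
    intersection lines of the orthogonal planes are used — the four
    axis-aligned spatial neighbors (x +- R_x, y +- R_y) and the two temporal
    neighbors (t +- R_t).  Grouped "XY+2": a 16-bin spatial histogram plus a
    4-bin temporal histogram per block, 20 bins in total, versus 48 for TOP.

``lbp_mop``
    Mean Orthogonal Planes: each stack of parallel planes is first averaged
    into a single mean image (average frame, average XT slice, average YT
    slice) and plain 2-D LBP histograms of the three mean images are
    concatenated.  Same dimensionality as TOP but the coding cost drops from
    O(w*h*l) to O(w*h + w*l + h*l).

Codable voxels are those whose full neighborhood fits in the volume:
``y in [ceil(R_y), h-1-ceil(R_y)]``, ``x in [ceil(R_x), w-1-ceil(R_x)]``,
``t in [ceil(R_t), l-1-ceil(R_t)]``; all three planes of TOP are coded on
exactly this common set so every codable voxel contributes one code per
plane.  Block partitioning applies to the spatial (y, x) interior only; all
frames of a block feed that block's segments.

Every descriptor tallies the number of neighbor-vs-center intensity
comparisons it performs into ``result.meta["comparisons"]``.  With
``full_volume=True`` border exclusion is disabled (edge replication) so the
tally covers the idealized full volume: 12*w*h*l for TOP, 6*w*h*l for SIP
and 4*(w*h + w*l + h*l) for MOP, matching ``comparison_count``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .lbp import (
    BlockGrid,
    DegenerateBlockError,
    FeatureHistogram,
    NeighborSpec,
    Segment,
    block_of,
    lbp_code_map,
    lbp_histogram,
    normalize_segments,
)

__all__ = [
    "TOPParams",
    "SIPParams",
    "MOPParams",
    "MeanPlanes",
    "TemporalExtentError",
    "lbp_top",
    "lbp_sip",
    "mean_planes",
    "lbp_mop",
    "comparison_count",
]


class TemporalExtentError(ValueError):
    """Video too short for the requested temporal radius."""


@dataclass(frozen=True)
class TOPParams:
    """LBP-TOP configuration: neighbor counts per plane, radii per axis."""

    P_xy: int = 4
    P_xt: int = 4
    P_yt: int = 4
    R_x: float = 1.0
    R_y: float = 1.0
    R_t: float = 3.0
    grid: BlockGrid = field(default_factory=BlockGrid)


@dataclass(frozen=True)
class SIPParams:
    """LBP-SIP configuration (spatial radii and temporal radius)."""

    R_x: float = 1.0
    R_y: float = 1.0
    R_t: float = 3.0
    grid: BlockGrid = field(default_factory=BlockGrid)


@dataclass(frozen=True)
class MOPParams:
    """LBP-MOP configuration: one 2-D LBP spec, one grid per mean plane."""

    spec: NeighborSpec = field(default_factory=lambda: NeighborSpec(4, 1.0))
    grid_xy: BlockGrid = field(default_factory=BlockGrid)
    grid_xt: BlockGrid = field(default_factory=BlockGrid)
    grid_yt: BlockGrid = field(default_factory=BlockGrid)


@dataclass
class MeanPlanes:
    """The three averaged plane images of a video volume.

    ``xy_mean``: (h, w), average over t.  ``xt_mean``: (w, l), rows = x,
    cols = t, average over y.  ``yt_mean``: (h, l), rows = y, cols = t,
    average over x.
    """

    xy_mean: np.ndarray
    xt_mean: np.ndarray
    yt_mean: np.ndarray


def _check_volume(video: np.ndarray) -> np.ndarray:
    video = np.asarray(video, dtype=float)
    if video.ndim != 3:
        raise ValueError(f"expected a (h, w, l) volume, got shape {video.shape}")
    if not np.all(np.isfinite(video)):
        raise ValueError("volume contains non-finite intensities")
    return video


def _margins(R_x: float, R_y: float, R_t: float) -> tuple[int, int, int]:
    return (
        int(np.ceil(R_y - 1e-12)),
        int(np.ceil(R_x - 1e-12)),
        int(np.ceil(R_t - 1e-12)),
    )


def _prepare(
    video: np.ndarray, R_x: float, R_y: float, R_t: float, full_volume: bool
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Validate extents; edge-pad when border exclusion is disabled."""
    video = _check_volume(video)
    my, mx, mt = _margins(R_x, R_y, R_t)
    if full_volume:
        video = np.pad(video, ((my, my), (mx, mx), (mt, mt)), mode="edge")
    h, w, l = video.shape
    if l < 2 * mt + 1:
        raise TemporalExtentError(
            f"video length {l} shorter than 2*ceil(R_t)+1 = {2 * mt + 1}"
        )
    if h < 2 * my + 1 or w < 2 * mx + 1:
        raise ValueError(
            f"spatial extent {h}x{w} leaves no interior for margins {(my, mx)}"
        )
    return video, (my, mx, mt)


def _spatial_block_ids(
    hi: int, wi: int, grid: BlockGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Block ordinals of interior rows (y) and cols (x)."""
    if hi < grid.rows or wi < grid.cols:
        raise DegenerateBlockError(
            f"spatial interior {hi}x{wi} cannot fill a {grid.rows}x{grid.cols} grid"
        )
    by = block_of(np.arange(hi), hi, grid.rows)
    bx = block_of(np.arange(wi), wi, grid.cols)
    return by, bx


def lbp_top(
    video: np.ndarray, params: TOPParams = TOPParams(), *, full_volume: bool = False
) -> FeatureHistogram:
    """LBP-TOP feature histogram of a video volume.

    Returns the block-major concatenation: for each spatial block (row-major)
    the XY, XT and YT plane histograms, each ``2**P`` bins and L1-normalized.
    Total length ``(2**P) * 3 * m`` for ``m`` blocks — 48*m at P=4.
    """
    video, (my, mx, mt) = _prepare(video, params.R_x, params.R_y, params.R_t, full_volume)
    h, w, l = video.shape
    hi, wi, ti = h - 2 * my, w - 2 * mx, l - 2 * mt
    grid = params.grid
    by, bx = _spatial_block_ids(hi, wi, grid)
    bid_xy = by[:, None] * grid.cols + bx[None, :]

    spec_xy = NeighborSpec(params.P_xy, (params.R_y, params.R_x))
    spec_xt = NeighborSpec(params.P_xt, (params.R_x, params.R_t))
    spec_yt = NeighborSpec(params.P_yt, (params.R_y, params.R_t))
    nb = {"XY": 1 << params.P_xy, "XT": 1 << params.P_xt, "YT": 1 << params.P_yt}
    counts = {p: np.zeros((grid.n_blocks, nb[p]), dtype=float) for p in ("XY", "XT", "YT")}
    n_cmp = 0

    # XY: one frame per interior t
    for t in range(mt, l - mt):
        codes, c = lbp_code_map(video[:, :, t], spec_xy)
        n_cmp += c
        flat = bid_xy * nb["XY"] + codes
        counts["XY"] += np.bincount(
            flat.ravel(), minlength=grid.n_blocks * nb["XY"]
        ).reshape(grid.n_blocks, nb["XY"])

    # XT: one (x, t) slice per interior y; slice rows = x, cols = t
    for iy in range(hi):
        codes, c = lbp_code_map(video[my + iy, :, :], spec_xt)
        n_cmp += c
        bid = (by[iy] * grid.cols + bx)[:, None] * nb["XT"] + codes
        counts["XT"] += np.bincount(
            bid.ravel(), minlength=grid.n_blocks * nb["XT"]
        ).reshape(grid.n_blocks, nb["XT"])

    # YT: one (y, t) slice per interior x; slice rows = y, cols = t
    for ix in range(wi):
        codes, c = lbp_code_map(video[:, mx + ix, :], spec_yt)
        n_cmp += c
        bid = (by * grid.cols + bx[ix])[:, None] * nb["YT"] + codes
        counts["YT"] += np.bincount(
            bid.ravel(), minlength=grid.n_blocks * nb["YT"]
        ).reshape(grid.n_blocks, nb["YT"])

    values: list[np.ndarray] = []
    segments: list[Segment] = []
    off = 0
    for b in range(grid.n_blocks):
        br, bc = divmod(b, grid.cols)
        for plane in ("XY", "XT", "YT"):
            seg = normalize_segments(counts[plane][b])
            values.append(seg)
            segments.append(Segment(f"{plane}.b{br}_{bc}", off, nb[plane]))
            off += nb[plane]
    return FeatureHistogram(np.concatenate(values), segments, {"comparisons": n_cmp})


def lbp_sip(
    video: np.ndarray, params: SIPParams = SIPParams(), *, full_volume: bool = False
) -> FeatureHistogram:
    """LBP-SIP feature histogram of a video volume (XY+2 grouping).

    Per spatial block: a 16-bin histogram of the 4-bit code over the four
    XY-plane intersection neighbors (east, north, west, south -> bits 0..3)
    concatenated with a 4-bin histogram of the 2-bit temporal code (past
    frame t-R_t -> bit 0, future frame t+R_t -> bit 1); 20 bins per block.
    """
    if abs(params.R_t - round(params.R_t)) > 1e-9:
        raise ValueError(f"temporal radius must be integral, got {params.R_t}")
    video, (my, mx, mt) = _prepare(video, params.R_x, params.R_y, params.R_t, full_volume)
    h, w, l = video.shape
    hi, wi, ti = h - 2 * my, w - 2 * mx, l - 2 * mt
    grid = params.grid
    by, bx = _spatial_block_ids(hi, wi, grid)
    bid_xy = by[:, None] * grid.cols + bx[None, :]

    spec_xy = NeighborSpec(4, (params.R_y, params.R_x))
    sp_counts = np.zeros((grid.n_blocks, 16), dtype=float)
    n_cmp = 0
    for t in range(mt, l - mt):
        codes, c = lbp_code_map(video[:, :, t], spec_xy)
        n_cmp += c
        flat = bid_xy * 16 + codes
        sp_counts += np.bincount(flat.ravel(), minlength=grid.n_blocks * 16).reshape(
            grid.n_blocks, 16
        )

    rt = int(round(params.R_t))
    center = video[my : h - my, mx : w - mx, mt : l - mt]
    past = video[my : h - my, mx : w - mx, mt - rt : l - mt - rt]
    future = video[my : h - my, mx : w - mx, mt + rt : l - mt + rt]
    tcodes = (past >= center).astype(np.int64) | ((future >= center).astype(np.int64) << 1)
    n_cmp += 2 * center.size
    flat = bid_xy[:, :, None] * 4 + tcodes
    t_counts = np.bincount(flat.ravel(), minlength=grid.n_blocks * 4).reshape(
        grid.n_blocks, 4
    ).astype(float)

    values: list[np.ndarray] = []
    segments: list[Segment] = []
    off = 0
    for b in range(grid.n_blocks):
        br, bc = divmod(b, grid.cols)
        values.append(normalize_segments(sp_counts[b]))
        segments.append(Segment(f"XY.b{br}_{bc}", off, 16))
        off += 16
        values.append(normalize_segments(t_counts[b]))
        segments.append(Segment(f"T.b{br}_{bc}", off, 4))
        off += 4
    return FeatureHistogram(np.concatenate(values), segments, {"comparisons": n_cmp})


def mean_planes(video: np.ndarray) -> MeanPlanes:
    """Average each stack of parallel planes of a volume into one image."""
    video = _check_volume(video)
    return MeanPlanes(
        xy_mean=video.mean(axis=2),  # (h, w)
        xt_mean=video.mean(axis=0),  # (w, l): rows = x, cols = t
        yt_mean=video.mean(axis=1),  # (h, l): rows = y, cols = t
    )


def lbp_mop(
    video: np.ndarray,
    params: MOPParams = MOPParams(),
    *,
    plane_filter: Callable[[np.ndarray], np.ndarray] | None = None,
    full_volume: bool = False,
) -> FeatureHistogram:
    """LBP-MOP feature histogram: 2-D LBP on the three mean plane images.

    ``plane_filter`` (e.g. a Wiener denoiser) is applied to each mean plane
    before coding — averaging raw frames first and filtering the three mean
    images only, rather than filtering every frame.
    """
    planes = mean_planes(video)
    parts: list[FeatureHistogram] = []
    for name, img, grid in (
        ("XY", planes.xy_mean, params.grid_xy),
        ("XT", planes.xt_mean, params.grid_xt),
        ("YT", planes.yt_mean, params.grid_yt),
    ):
        if plane_filter is not None:
            img = plane_filter(img)
        try:
            parts.append(
                lbp_histogram(
                    img,
                    params.spec,
                    grid,
                    label_fmt=name + ".b{r}_{c}",
                    full_coverage=full_volume,
                )
            )
        except DegenerateBlockError as e:
            raise DegenerateBlockError(f"{name} mean plane: {e}") from e
    return FeatureHistogram.concatenate(parts)


_COUNT_FORMULAS = {
    "top": lambda w, h, l: 12 * w * h * l,
    "sip": lambda w, h, l: 6 * w * h * l,
    "mop": lambda w, h, l: 4 * (w * h + w * l + h * l),
}


def comparison_count(method: str, w: int, h: int, l: int) -> int:
    """Closed-form neighbor-vs-center comparison count over a full w*h*l volume.

    TOP codes every voxel on three planes with 4 neighbors each (12 per
    voxel); SIP uses 4 spatial + 2 temporal neighbors (6 per voxel); MOP
    codes only the three mean images (4 neighbors per mean-plane pixel).
    """
    if min(w, h, l) < 1:
        raise ValueError(f"dimensions must be positive, got {(w, h, l)}")
    key = method.lower().replace("lbp-", "").replace("lbp_", "")
    if key not in _COUNT_FORMULAS:
        raise ValueError(f"unknown method {method!r}; expected one of top, sip, mop")
    return int(_COUNT_FORMULAS[key](w, h, l))
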