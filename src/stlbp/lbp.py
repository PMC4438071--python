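"""Pixel-level local binary pattern coding on 2-D images.

The LBP operator codes each pixel by thresholding the intensities of its
``P`` circular neighbors at radius ``R`` against the center intensity: bit
``p`` of the code is 1 iff the sampled neighbor intensity is greater than or
equal to the center intensity, and bit ``p`` carries weight ``2**p``.
Histograms of the resulting integer codes, accumulated per rectangular block
of the image and L1-normalized, are the texture descriptor.

Coordinate and ordering conventions (fixed throughout the package):

* images are indexed ``[row, col]`` with ``row = y`` increasing downward and
  ``col = x`` increasing rightward; pixel positions are 0-based;
* neighbor ``p`` (``p = 0..P-1``) lies at angle ``2*pi*p/P`` counter-clockwise
  from the positive x-axis in conventional mathematical orientation, i.e. at
  offset ``(drow, dcol) = (-R*sin(theta), R*cos(theta))``.  For ``P = 4,
  R = 1`` the neighbors are exactly the east, north, west, south pixels, in
  that bit order (east = bit 0, least significant);
* non-integer sampling positions are resolved by bilinear interpolation;
* pixels whose full neighborhood does not fit inside the image are excluded
  from all histograms (no padding is fabricated), unless border exclusion is
  explicitly disabled via edge replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "NeighborSpec",
    "BlockGrid",
    "Segment",
    "FeatureHistogram",
    "DegenerateBlockError",
    "sample_intensity",
    "lbp_code",
    "lbp_code_map",
    "lbp_histogram",
    "block_index_edges",
]

_EPS = 1e-12


class DegenerateBlockError(ValueError):
    """A histogram block received zero codable pixels."""


@dataclass(frozen=True)
class NeighborSpec:
    """Circular LBP neighborhood: ``P`` neighbors at radius ``R``.

    ``radius`` may be a single positive float or a ``(row_radius,
    col_radius)`` pair; the pair form yields elliptical sampling, which is
    how per-axis radii on space-time planes are realized.
    """

    P: int
    R: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError(f"neighbor count P must be >= 1, got {self.P}")
        rr, rc = self.radii
        if rr <= 0 or rc <= 0:
            raise ValueError(f"radius must be positive, got {self.R}")

    @property
    def radii(self) -> tuple[float, float]:
        """(row_radius, col_radius)."""
        if isinstance(self.R, tuple):
            return float(self.R[0]), float(self.R[1])
        return float(self.R), float(self.R)

    def offsets(self) -> np.ndarray:
        """(P, 2) array of (drow, dcol) neighbor offsets, bit order p=0..P-1."""
        rr, rc = self.radii
        theta = 2.0 * np.pi * np.arange(self.P) / self.P
        drow = -rr * np.sin(theta)
        dcol = rc * np.cos(theta)
        # snap numerically-integral offsets so the common axis-aligned
        # configurations use exact pixel values
        drow[np.abs(drow - np.round(drow)) < _EPS] = np.round(
            drow[np.abs(drow - np.round(drow)) < _EPS]
        )
        dcol[np.abs(dcol - np.round(dcol)) < _EPS] = np.round(
            dcol[np.abs(dcol - np.round(dcol)) < _EPS]
        )
        return np.stack([drow, dcol], axis=1)

    @property
    def margins(self) -> tuple[int, int]:
        """Interior margins (rows, cols) needed for a full neighborhood."""
        rr, rc = self.radii
        return int(np.ceil(rr - _EPS)), int(np.ceil(rc - _EPS))


@dataclass(frozen=True)
class BlockGrid:
    """An ``rows x cols`` partition of the coded image interior."""

    rows: int = 1
    cols: int = 1

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"block grid must be positive, got {self}")

    @property
    def n_blocks(self) -> int:
        return self.rows * self.cols


class Segment(NamedTuple):
    """Layout entry of one histogram segment inside a concatenated vector."""

    label: str
    offset: int
    length: int


@dataclass
class FeatureHistogram:
    """Concatenated per-segment histogram vector with layout metadata.

    Each segment is one block's (or one plane-block's) histogram; after
    normalization every segment that received at least one coded pixel sums
    to one.  ``meta`` carries run information such as the number of
    neighbor-vs-center comparisons performed while coding.
    """

    values: np.ndarray
    segments: list[Segment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        total = sum(s.length for s in self.segments)
        if total != self.values.size:
            raise ValueError(
                f"segment lengths sum to {total} but vector has {self.values.size} entries"
            )
        off = 0
        for s in self.segments:
            if s.offset != off:
                raise ValueError(f"segment {s.label} at offset {s.offset}, expected {off}")
            off += s.length

    def __len__(self) -> int:
        return int(self.values.size)

    def segment(self, label: str) -> np.ndarray:
        for s in self.segments:
            if s.label == label:
                return self.values[s.offset : s.offset + s.length]
        raise KeyError(label)

    def segment_labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def column_names(self) -> list[str]:
        """One name per entry, ``<segment label>.<bin index>``."""
        names: list[str] = []
        for s in self.segments:
            names.extend(f"{s.label}.{b}" for b in range(s.length))
        return names

    @classmethod
    def concatenate(cls, parts: Sequence["FeatureHistogram"]) -> "FeatureHistogram":
        values = np.concatenate([p.values for p in parts])
        segments: list[Segment] = []
        off = 0
        meta: dict = {}
        for p in parts:
            for s in p.segments:
                segments.append(Segment(s.label, off, s.length))
                off += s.length
            for k, v in p.meta.items():
                meta[k] = meta.get(k, 0) + v if isinstance(v, (int, float)) else v
        return cls(values, segments, meta)


def sample_intensity(img: np.ndarray, x: float, y: float) -> float:
    """Bilinear intensity at real-valued position (x, y) = (col, row).

    Exact pixel value at integer coordinates; raises ``ValueError`` outside
    ``[0, width-1] x [0, height-1]``.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise ValueError(f"position (x={x}, y={y}) outside image of shape {h}x{w}")
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    top = (1 - fx) * img[y0, x0] + fx * img[y0, x1]
    bot = (1 - fx) * img[y1, x0] + fx * img[y1, x1]
    return float((1 - fy) * top + fy * bot)


def lbp_code(img: np.ndarray, center: tuple[int, int], spec: NeighborSpec) -> int:
    """LBP code of a single pixel; ``center`` is (row, col).

    Bit ``p`` is 1 iff the sampled neighbor intensity >= the center
    intensity.  Raises if the full neighborhood does not fit in the image.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    r, c = center
    mr, mc = spec.margins
    if not (mr <= r <= h - 1 - mr and mc <= c <= w - 1 - mc):
        raise ValueError(
            f"neighborhood of margins {spec.margins} at center {center} "
            f"exceeds image bounds {h}x{w}"
        )
    code = 0
    ic = img[r, c]
    for p, (drow, dcol) in enumerate(spec.offsets()):
        ip = sample_intensity(img, c + dcol, r + drow)
        if ip >= ic:
            code |= 1 << p
    return code


def _sampled_plane(img: np.ndarray, drow: float, dcol: float, mr: int, mc: int) -> np.ndarray:
    """Neighbor intensities for every interior pixel, vectorized.

    Integer offsets become pure slicing; fractional offsets go through
    bilinear interpolation (``map_coordinates`` order 1).
    """
    h, w = img.shape
    rows = np.arange(mr, h - mr)
    cols = np.arange(mc, w - mc)
    if drow == int(drow) and dcol == int(dcol):
        dr, dc = int(drow), int(dcol)
        return img[mr + dr : h - mr + dr, mc + dc : w - mc + dc]
    rr, cc = np.meshgrid(rows + drow, cols + dcol, indexing="ij")
    return ndimage.map_coordinates(img, [rr, cc], order=1, mode="nearest")


def lbp_code_map(
    img: np.ndarray,
    spec: NeighborSpec,
    *,
    full_coverage: bool = False,
) -> tuple[np.ndarray, int]:
    """Integer LBP codes for every codable pixel of ``img``.

    Returns ``(codes, n_comparisons)`` where ``codes`` has shape
    ``(h - 2*mr, w - 2*mc)`` for interior margins ``(mr, mc)`` — or the full
    ``(h, w)`` when ``full_coverage`` is set, in which case the image is
    edge-replicated so that every pixel is coded (used by the complexity
    instrumentation, where border exclusion is disabled).  ``n_comparisons``
    tallies one unit per neighbor-vs-center intensity comparison performed.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite intensities")
    mr, mc = spec.margins
    if full_coverage:
        img = np.pad(img, ((mr, mr), (mc, mc)), mode="edge")
    h, w = img.shape
    if h - 2 * mr < 1 or w - 2 * mc < 1:
        raise ValueError(
            f"image of shape {img.shape} has no interior for margins {(mr, mc)}"
        )
    center = img[mr : h - mr, mc : w - mc]
    codes = np.zeros(center.shape, dtype=np.int64)
    n_cmp = 0
    for p, (drow, dcol) in enumerate(spec.offsets()):
        neighbor = _sampled_plane(img, drow, dcol, mr, mc)
        codes |= (neighbor >= center).astype(np.int64) << p
        n_cmp += center.size
    return codes, n_cmp


def block_index_edges(extent: int, n: int) -> np.ndarray:
    """Boundaries splitting ``extent`` positions into ``n`` contiguous blocks.

    Edge ``i`` sits at ``floor(i * extent / n)``; returns ``n + 1`` edges.
    """
    if extent < n:
        raise DegenerateBlockError(
            f"cannot split extent {extent} into {n} non-empty blocks"
        )
    return (np.arange(n + 1) * extent) // n


def block_of(index: np.ndarray, extent: int, n: int) -> np.ndarray:
    """Block ordinal of each 0-based position along one axis.

    Inverse of ``block_index_edges``: position ``i`` belongs to the block
    ``r`` with ``floor(r*extent/n) <= i < floor((r+1)*extent/n)``, so
    trailing blocks absorb any remainder.
    """
    return ((np.asarray(index) + 1) * n - 1) // extent


def _accumulate_blocks(
    codes: np.ndarray, n_bins: int, grid: BlockGrid, label_fmt: str
) -> tuple[np.ndarray, list[str], list[tuple[int, int]]]:
    """Per-block bincounts of a 2-D code map; blocks in row-major order."""
    hi, wi = codes.shape
    redges = block_index_edges(hi, grid.rows)
    cedges = block_index_edges(wi, grid.cols)
    counts = np.zeros((grid.rows, grid.cols, n_bins), dtype=float)
    labels, coords = [], []
    for br in range(grid.rows):
        for bc in range(grid.cols):
            block = codes[redges[br] : redges[br + 1], cedges[bc] : cedges[bc + 1]]
            if block.size == 0:
                raise DegenerateBlockError(
                    f"block (row={br}, col={bc}) of grid {grid.rows}x{grid.cols} "
                    "contains zero codable pixels"
                )
            counts[br, bc] = np.bincount(block.ravel(), minlength=n_bins)
            labels.append(label_fmt.format(r=br, c=bc))
            coords.append((br, bc))
    return counts.reshape(grid.n_blocks, n_bins), labels, coords


def normalize_segments(counts: np.ndarray) -> np.ndarray:
    """L1-normalize each row; all-zero rows are left untouched."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=-1, keepdims=True)
    return np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), counts)


def lbp_histogram(
    img: np.ndarray,
    spec: NeighborSpec,
    grid: BlockGrid = BlockGrid(1, 1),
    *,
    normalize: bool = True,
    label_fmt: str = "b{r}_{c}",
    full_coverage: bool = False,
) -> FeatureHistogram:
    """Block-wise LBP histogram of a 2-D image.

    One ``2**P``-bin segment per block, bins indexed by decimal code,
    concatenated in row-major block order; each segment L1-normalized when
    ``normalize`` is set.  Border pixels lacking a full neighborhood are
    excluded from all counts.
    """
    codes, n_cmp = lbp_code_map(img, spec, full_coverage=full_coverage)
    n_bins = 1 << spec.P
    counts, labels, _ = _accumulate_blocks(codes, n_bins, grid, label_fmt)
    if normalize:
        counts = normalize_segments(counts)
    segments = [
        Segment(lab, i * n_bins, n_bins) for i, lab in enumerate(labels)
    ]
    return FeatureHistogram(counts.ravel(), segments, {"comparisons": n_cmp})
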