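"""Naive reference implementations used as independent oracles.

Everything here is written as plain nested Python loops with direct
neighbor-vs-center comparisons, deliberately sharing no code with the
vectorized implementations under test.  The documented conventions are
restated inline: neighbor bit order east, north, west, south within a plane
(first in-plane axis = columns of the slice), threshold ``neighbor >=
center``, border pixels excluded, block edge ``i`` of ``n`` at
``floor(i * extent / n)``.
"""

from __future__ import annotations

import numpy as np


def _block(idx: int, extent: int, n: int) -> int:
    # edge r sits at floor(r * extent / n); idx is in the last block whose
    # edge does not exceed it
    edges = [(r * extent) // n for r in range(n + 1)]
    return max(r for r in range(n) if edges[r] <= idx)


def naive_lbp_blocks(img, P4_offsets, rows, cols, n_bins):
    """Per-block histogram counts of a 2-D image under given (dr, dc) offsets."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    mr = max(abs(dr) for dr, _ in P4_offsets)
    mc = max(abs(dc) for _, dc in P4_offsets)
    hi, wi = h - 2 * mr, w - 2 * mc
    counts = np.zeros((rows * cols, n_bins))
    for r in range(mr, h - mr):
        for c in range(mc, w - mc):
            code = 0
            for p, (dr, dc) in enumerate(P4_offsets):
                if img[r + dr, c + dc] >= img[r, c]:
                    code |= 1 << p
            b = _block(r - mr, hi, rows) * cols + _block(c - mc, wi, cols)
            counts[b, code] += 1
    return counts


def _normalize(counts):
    counts = np.asarray(counts, dtype=float)
    out = counts.copy()
    for i, row in enumerate(counts):
        s = row.sum()
        if s > 0:
            out[i] = row / s
    return out


# east, north, west, south in (drow, dcol) slice coordinates, unit radius
ENWS = [(0, 1), (-1, 0), (0, -1), (1, 0)]


def _enws(r_row: int, r_col: int):
    return [(0, r_col), (-r_row, 0), (0, -r_col), (r_row, 0)]


def naive_lbp_histogram(img, rows=1, cols=1, r=1):
    """Normalized block LBP histogram, P=4 axis-aligned neighbors."""
    return _normalize(naive_lbp_blocks(img, _enws(r, r), rows, cols, 16)).ravel()


def naive_top(video, R_x=1, R_y=1, R_t=3, rows=1, cols=1):
    """Block-major (XY, XT, YT per block) normalized LBP-TOP vector, P=4."""
    v = np.asarray(video, dtype=float)
    h, w, l = v.shape
    hi, wi = h - 2 * R_y, w - 2 * R_x
    counts = {p: np.zeros((rows * cols, 16)) for p in ("XY", "XT", "YT")}
    for y in range(R_y, h - R_y):
        for x in range(R_x, w - R_x):
            b = _block(y - R_y, hi, rows) * cols + _block(x - R_x, wi, cols)
            for t in range(R_t, l - R_t):
                c = v[y, x, t]
                # XY slice: rows=y cols=x -> E=(x+Rx), N=(y-Ry), W, S
                code = 0
                for p, (dy, dx) in enumerate(
                    [(0, R_x), (-R_y, 0), (0, -R_x), (R_y, 0)]
                ):
                    if v[y + dy, x + dx, t] >= c:
                        code |= 1 << p
                counts["XY"][b, code] += 1
                # XT slice: rows=x cols=t -> E=(t+Rt), N=(x-Rx), W, S
                code = 0
                for p, (dx, dt) in enumerate(
                    [(0, R_t), (-R_x, 0), (0, -R_t), (R_x, 0)]
                ):
                    if v[y, x + dx, t + dt] >= c:
                        code |= 1 << p
                counts["XT"][b, code] += 1
                # YT slice: rows=y cols=t -> E=(t+Rt), N=(y-Ry), W, S
                code = 0
                for p, (dy, dt) in enumerate(
                    [(0, R_t), (-R_y, 0), (0, -R_t), (R_y, 0)]
                ):
                    if v[y + dy, x, t + dt] >= c:
                        code |= 1 << p
                counts["YT"][b, code] += 1
    parts = []
    for b in range(rows * cols):
        for plane in ("XY", "XT", "YT"):
            parts.append(_normalize(counts[plane][b : b + 1]).ravel())
    return np.concatenate(parts)


def naive_sip(video, R_x=1, R_y=1, R_t=3, rows=1, cols=1):
    """Block-major (spatial 16 + temporal 4 per block) LBP-SIP vector."""
    v = np.asarray(video, dtype=float)
    h, w, l = v.shape
    hi, wi = h - 2 * R_y, w - 2 * R_x
    sp = np.zeros((rows * cols, 16))
    tp = np.zeros((rows * cols, 4))
    for y in range(R_y, h - R_y):
        for x in range(R_x, w - R_x):
            b = _block(y - R_y, hi, rows) * cols + _block(x - R_x, wi, cols)
            for t in range(R_t, l - R_t):
                c = v[y, x, t]
                code = 0
                for p, (dy, dx) in enumerate(
                    [(0, R_x), (-R_y, 0), (0, -R_x), (R_y, 0)]
                ):
                    if v[y + dy, x + dx, t] >= c:
                        code |= 1 << p
                sp[b, code] += 1
                tcode = (1 if v[y, x, t - R_t] >= c else 0) | (
                    (1 if v[y, x, t + R_t] >= c else 0) << 1
                )
                tp[b, tcode] += 1
    parts = []
    for b in range(rows * cols):
        parts.append(_normalize(sp[b : b + 1]).ravel())
        parts.append(_normalize(tp[b : b + 1]).ravel())
    return np.concatenate(parts)


def naive_mop(video, grids=((1, 1), (1, 1), (1, 1))):
    """Plane-major (XY, XT, YT) normalized LBP-MOP vector, P=4, R=1."""
    v = np.asarray(video, dtype=float)
    h, w, l = v.shape
    xy = np.zeros((h, w))
    xt = np.zeros((w, l))
    yt = np.zeros((h, l))
    for y in range(h):
        for x in range(w):
            for t in range(l):
                xy[y, x] += v[y, x, t]
                xt[x, t] += v[y, x, t]
                yt[y, t] += v[y, x, t]
    xy /= l
    xt /= h
    yt /= w
    parts = []
    for img, (r, c) in zip((xy, xt, yt), grids):
        parts.append(_normalize(naive_lbp_blocks(img, ENWS, r, c, 16)).ravel())
    return np.concatenate(parts)
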