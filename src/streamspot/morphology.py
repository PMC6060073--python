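"""Grayscale 1D morphology with line and pair structuring elements.

Small bright targets in a 2D image can be separated from their surroundings
using only one-dimensional structuring elements (SEs): a flat *line* of
``L`` pixels sliding within a row, and a *pair* of two adjacent pixels along
either the row (``in_row``) or the column (``cross_row``) axis.  Keeping the
SEs one-dimensional is what makes the whole detection chain runnable during
row-wise pixel readout with only a handful of FIFO buffers of state.

Erosion and dilation are the sliding-window minimum and maximum of the gray
values over the SE domain.  At row boundaries the window is intersected with
the row: positions outside the image contribute nothing (no padding values
are invented).  The width selectivity that drives the whole method follows
directly from these definitions: a flat plateau of width ``K`` on a dark
ground survives a line erosion iff ``L <= K``, so an opening (erosion then
dilation) with ``K < L < K_l`` produces a background estimate that contains
every structure wider than ``L`` and none narrower.

Axis convention used throughout the package: ``x`` is the row index and
``y`` is the column index; arrays are indexed ``[row, col]`` and 0-based.

Intensities are promoted to signed working dtypes internally so that
subtractions never wrap; clamping to bit depth happens only on image export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LINE = "line"
PAIR = "pair"
IN_ROW = "in_row"
CROSS_ROW = "cross_row"


@dataclass(frozen=True)
class StructElem:
    """A flat 1D structuring element.

    ``line`` SEs have a length ``L >= 1`` and slide within a row; their
    anchor is the centre, with even ``L`` anchored at index ``L // 2``.
    ``pair`` SEs span exactly two adjacent pixels along ``axis`` and are
    anchored at the first pixel, so an in-row pair erosion consumes pixels
    ``j`` and ``j + 1`` and a cross-row pair erosion consumes rows ``i``
    and ``i + 1`` — the convention that lets the hardware model keep just
    one whole-row buffer for the vertical pair.
    """

    kind: str
    length: int = 2
    axis: str = IN_ROW

    def __post_init__(self) -> None:
        if self.kind not in (LINE, PAIR):
            raise ValueError(f"unknown SE kind: {self.kind!r}")
        if self.kind == LINE:
            if self.length < 1:
                raise ValueError("line SE length must be >= 1")
        else:
            if self.length != 2:
                raise ValueError("pair SE spans exactly 2 pixels")
            if self.axis not in (IN_ROW, CROSS_ROW):
                raise ValueError(f"unknown pair axis: {self.axis!r}")

    @property
    def origin(self) -> int:
        """Index of the anchor within the SE domain."""
        return self.length // 2 if self.kind == LINE else 0


def line(length: int) -> StructElem:
    return StructElem(LINE, length)


def pair(axis: str = IN_ROW) -> StructElem:
    return StructElem(PAIR, 2, axis)


@dataclass(frozen=True)
class FeatureScale:
    """Characteristic widths (pixels) of the image constituents.

    ``K`` is the target scale, ``K_s`` the sub-target (single-pixel noise)
    scale and ``K_l`` the background / large-interference scale.  A line SE
    length chosen with ``K < L < K_l`` turns an opening into a background
    estimator that excludes the targets.
    """

    K: int
    K_s: int
    K_l: int

    def __post_init__(self) -> None:
        if not (self.K_s < self.K < self.K_l):
            raise ValueError("feature scales must satisfy K_s < K < K_l")


def _check_row(row: np.ndarray) -> np.ndarray:
    a = np.asarray(row)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("row must be a non-empty 1D array")
    return a


def _sentinels(dtype: np.dtype, mode: str):
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return info.max if mode == "min" else info.min
    return np.inf if mode == "min" else -np.inf


def sliding_extreme(arr: np.ndarray, length: int, origin: int, mode: str) -> np.ndarray:
    """Row-wise sliding min/max over windows clipped to the array.

    ``out[:, j]`` reduces ``arr[:, j - origin : j - origin + length]``
    intersected with the valid column range.  Implemented with the two-pass
    block prefix/suffix scheme (van Herk / Gil–Werman), O(1) comparisons per
    pixel independent of ``length``; out-of-range positions are padded with
    the identity of the reduction, which is equivalent to clipping because
    every window contains its own anchor pixel.
    """
    a = np.asarray(arr)
    squeeze = a.ndim == 1
    if squeeze:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError("expected a 1D row or 2D (rows, cols) array")
    n, W = a.shape
    if W == 0:
        raise ValueError("rows must be non-empty")
    if length == 1:
        out = a.copy()
        return out[0] if squeeze else out
    if not 0 <= origin < length:
        raise ValueError("SE origin must lie inside the SE domain")
    reduce_fn = np.minimum if mode == "min" else np.maximum
    sentinel = _sentinels(a.dtype, mode)
    left, right = origin, length - 1 - origin
    total = left + W + right
    blocks = -(-total // length)
    buf = np.full((n, blocks * length), sentinel, dtype=a.dtype)
    buf[:, left:left + W] = a
    b = buf.reshape(n, blocks, length)
    prefix = reduce_fn.accumulate(b, axis=2).reshape(n, -1)
    suffix = reduce_fn.accumulate(b[:, :, ::-1], axis=2)[:, :, ::-1].reshape(n, -1)
    # window for output j starts at padded index j and ends at j + length - 1
    out = reduce_fn(suffix[:, :W], prefix[:, length - 1:length - 1 + W])
    return out[0] if squeeze else out


def erode_line(row: np.ndarray, se: StructElem) -> np.ndarray:
    """Grayscale erosion of one row (or a stack of rows) by a line SE."""
    if se.kind != LINE:
        raise ValueError("erode_line requires a line SE")
    a = np.asarray(row)
    if a.ndim == 1:
        a = _check_row(a)
    return sliding_extreme(a, se.length, se.origin, "min")


def dilate_line(row: np.ndarray, se: StructElem) -> np.ndarray:
    """Grayscale dilation of one row (or a stack of rows) by a line SE.

    Uses the same (unreflected) window as :func:`erode_line`, so the duality
    ``dilate(f) == -erode(-f)`` holds exactly for every SE.
    """
    if se.kind != LINE:
        raise ValueError("dilate_line requires a line SE")
    a = np.asarray(row)
    if a.ndim == 1:
        a = _check_row(a)
    return sliding_extreme(a, se.length, se.origin, "max")


def open_line(row: np.ndarray, se: StructElem) -> np.ndarray:
    """Opening (erosion, then dilation by the reflected SE) along rows.

    The dilation stage anchors at the reflected origin ``L - 1 - origin`` so
    that the composite is a true opening — anti-extensive and idempotent —
    for even SE lengths as well; for the usual odd, centred SE the
    reflection is the identity.
    """
    if se.kind != LINE:
        raise ValueError("open_line requires a line SE")
    eroded = erode_line(row, se)
    return sliding_extreme(eroded, se.length, se.length - 1 - se.origin, "max")


def erode_pair(mask: np.ndarray, axis: str = IN_ROW) -> np.ndarray:
    """Binary erosion by a 2-pixel pair SE anchored at its first pixel.

    A pixel survives only when its partner one step to the right
    (``in_row``) or one row below (``cross_row``) is also set.  Beyond the
    last column/row the partner does not exist and the pixel is cleared, so
    isolated single pixels are removed everywhere, including at image
    borders; genuine target pixels clipped this way are restored by the
    conditional recovery dilations.
    """
    m = np.asarray(mask, dtype=bool)
    out = np.zeros_like(m)
    if axis == IN_ROW:
        out[..., :-1] = m[..., :-1] & m[..., 1:]
    elif axis == CROSS_ROW:
        if m.ndim < 2:
            raise ValueError("cross_row pair erosion needs a 2D (rows, cols) mask")
        out[:-1] = m[:-1] & m[1:]
    else:
        raise ValueError(f"unknown pair axis: {axis!r}")
    return out


def dilate_pair(mask: np.ndarray, axis: str = IN_ROW) -> np.ndarray:
    """Binary dilation by a 2-pixel pair SE (dual of :func:`erode_pair`)."""
    m = np.asarray(mask, dtype=bool)
    out = m.copy()
    if axis == IN_ROW:
        out[..., 1:] |= m[..., :-1]
    elif axis == CROSS_ROW:
        if m.ndim < 2:
            raise ValueError("cross_row pair dilation needs a 2D (rows, cols) mask")
        out[1:] |= m[:-1]
    else:
        raise ValueError(f"unknown pair axis: {axis!r}")
    return out
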