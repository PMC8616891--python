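"""Conversion between suture point sets and single-channel likelihood maps.

Ground-truth points are encoded as a heatmap by centring a radial profile on
each point — an amplitude-normalised Gaussian ``exp(-d^2 / (2 sigma1^2))`` or
the sharper ``1 - tanh(d^2 / alpha)`` — and combining overlapping profiles by
the pixel-wise maximum, which keeps values interpretable as likelihoods in
[0, 1] and keeps the 0.5 decoding threshold meaningful for nearby points.
Predicted heatmaps are decoded back to points by thresholding, grouping the
surviving pixels into connected components, and taking the intensity-weighted
centre of mass of each component for sub-pixel localisation.

Coordinates are 0-based ``(row, col)`` with pixel centres at integer
positions; labelme's ``(x, y)`` convention is converted at the I/O boundary
(``row = y``, ``col = x``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PointSet",
    "DistributionSpec",
    "encode_heatmap",
    "encode_binary_mask",
    "decode_points",
    "save_heatmap_png",
    "load_heatmap_png",
]


@dataclass(frozen=True)
class PointSet:
    """An ordered set of sub-pixel suture point locations in an image frame.

    Attributes
    ----------
    points : ndarray of shape (n, 2)
        Sub-pixel ``(row, col)`` coordinates; may be empty (images contain a
        variable number of sutures).
    height, width : int
        Frame dimensions in pixels; every point must lie inside the frame.
    """

    points: np.ndarray = field()
    height: int = 288
    width: int = 512

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if len(pts):
            rows, cols = pts[:, 0], pts[:, 1]
            if (rows < 0).any() or (rows >= self.height).any() \
                    or (cols < 0).any() or (cols >= self.width).any():
                raise ValueError(
                    "point outside image frame "
                    f"({self.height}x{self.width}): {pts[_oob_index(pts, self.height, self.width)]}")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


def _oob_index(pts: np.ndarray, h: int, w: int) -> int:
    bad = (pts[:, 0] < 0) | (pts[:, 0] >= h) | (pts[:, 1] < 0) | (pts[:, 1] >= w)
    return int(np.argmax(bad))


@dataclass(frozen=True)
class DistributionSpec:
    """Choice of the encoding profile and its spread.

    ``kind`` is one of ``gaussian`` (spread ``sigma1`` in pixels), ``tanh``
    (spread ``alpha`` in pixels squared; the conventional pairing with a
    Gaussian of spread sigma is ``alpha = 3.5 * sigma``) or ``binary``.
    """

    kind: str = "gaussian"
    sigma1: float = 2.0
    alpha: float = 7.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "tanh", "binary"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma1 <= 0:
            raise ValueError("sigma1 must be positive")
        if self.kind == "tanh" and self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def profile(self, d2: np.ndarray) -> np.ndarray:
        """Profile value as a function of squared distance to the centre."""
        if self.kind == "gaussian":
            return np.exp(-d2 / (2.0 * self.sigma1 ** 2))
        if self.kind == "tanh":
            return 1.0 - np.tanh(d2 / self.alpha)
        raise ValueError(f"distribution kind {self.kind!r} has no radial profile")


def encode_heatmap(points: PointSet, spec: DistributionSpec) -> np.ndarray:
    """Encode a point set as an H x W likelihood map in [0, 1].

    Each pixel takes the maximum over all points of the radial profile of its
    distance to that point, so the value at every exact point location is 1
    and overlapping profiles never push values above 1.  An empty point set
    encodes to the all-zero map.
    """
    if spec.kind not in ("gaussian", "tanh"):
        raise ValueError(
            f"encode_heatmap requires a gaussian or tanh spec, got {spec.kind!r}")
    h, w = points.height, points.width
    out = np.zeros((h, w))
    if not len(points):
        return out
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for r, c in points.points:
        d2 = (rows - r) ** 2 + (cols - c) ** 2
        np.maximum(out, spec.profile(d2), out=out)
    return out


def encode_binary_mask(points: PointSet) -> np.ndarray:
    """Encode a point set as a {0, 1} mask, one pixel per rounded location."""
    out = np.zeros((points.height, points.width))
    if len(points):
        rr = np.clip(np.rint(points.points[:, 0]).astype(int), 0, points.height - 1)
        cc = np.clip(np.rint(points.points[:, 1]).astype(int), 0, points.width - 1)
        out[rr, cc] = 1.0
    return out


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def decode_points(heatmap: np.ndarray, threshold: float = 0.5,
                  connectivity: int = 8) -> PointSet:
    """Decode a likelihood map back to sub-pixel points.

    Pixels strictly above ``threshold`` are grouped into connected components
    (8-connectivity by default) and each component is reduced to its
    intensity-weighted centre of mass.  Points are returned in row-major
    order of the component labels; an all-below-threshold map decodes to an
    empty :class:`PointSet`.
    """
    heatmap = np.asarray(heatmap, dtype=np.float64)
    if heatmap.ndim != 2:
        raise ValueError(f"expected a 2-D heatmap, got shape {heatmap.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = heatmap > threshold
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return PointSet(np.empty((0, 2)), *heatmap.shape)
    centres = ndimage.center_of_mass(heatmap, labels, index=range(1, n + 1))
    pts = np.clip(np.asarray(centres, dtype=np.float64),
                  [0.0, 0.0], [heatmap.shape[0] - 1e-9, heatmap.shape[1] - 1e-9])
    return PointSet(pts, *heatmap.shape)


def save_heatmap_png(heatmap: np.ndarray, path) -> None:
    """Write a [0, 1] heatmap as a single-channel 16-bit PNG (scaled by 65535)."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(heatmap), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 65535.0).astype(np.uint16))


def load_heatmap_png(path) -> np.ndarray:
    """Read a heatmap written by :func:`save_heatmap_png` back to [0, 1]."""
    import imageio.v3 as iio

    return iio.imread(path).astype(np.float64) / 65535.0
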