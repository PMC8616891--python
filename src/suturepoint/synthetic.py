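"""Synthetic endoscopy-like scenes with known suture-point ground truth.

Real annuloplasty endoscopy frames show reddish tissue under a circular
endoscope field of view, specular highlights from the light source, and
pale suture threads whose entry/exit points into the tissue are the
detection targets.  The generator reproduces the properties the detector is
sensitive to rather than photorealism: a low-frequency reddish background,
an elliptical field-of-view vignette, bright specular blobs as distractors,
and each annotated point rendered as the end of a short curved thread with
a small dark puncture mark at the entry point.  Point placement is
controlled: a configurable fraction of points is laid out in close pairs
(partner within 15 px), the regime where overlapping heatmap encodings
confound detection, while all remaining points keep at least 15 px of
clearance from everything else.

Also here: labelme-dialect JSON annotation I/O and the photometric +
geometric augmentation suite (flips, +/-60 deg rotation, +/-10 %
translation, shear, brightness/contrast/saturation/hue jitter, each applied
with probability 0.5) with coordinate-consistent point transforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from skimage import color as skcolor
from skimage import transform as sktransform

from .codec import PointSet

__all__ = [
    "SceneSpec",
    "AugmentConfig",
    "generate_scene",
    "generate_dataset",
    "read_labelme",
    "write_labelme",
    "augment_sample",
    "affine_matrix",
    "apply_affine",
]

CLOSE_THRESHOLD = 15.0  # px; a point with a neighbour below this is "close"
_CLEARANCE = 16.0  # px separation enforced between unrelated points


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene (all randomness from ``seed``).

    ``n_points`` is an inclusive (low, high) range; ``close_pair_fraction``
    of the drawn points are placed 4-14 px from a partner, the rest at
    least 15 px from every other point.
    """

    height: int = 288
    width: int = 512
    n_points: tuple[int, int] = (5, 25)
    min_separation: float = 4.0
    close_pair_fraction: float = 0.2
    vignette: bool = True
    specular_count: tuple[int, int] = (2, 6)
    texture_scale: float = 48.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.n_points
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid n_points range {self.n_points}")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1 px")
        if not 0.0 <= self.close_pair_fraction <= 1.0:
            raise ValueError("close_pair_fraction must lie in [0, 1]")


class SceneGenerationError(RuntimeError):
    """Raised when points cannot be packed into the scene."""


# ---------------------------------------------------------------------------
# point layout
# ---------------------------------------------------------------------------

def _fov_radius(r: np.ndarray, c: np.ndarray, h: int, w: int) -> np.ndarray:
    """Normalised elliptical field-of-view radius (1.0 at the frame edge)."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return np.sqrt(((r - cy) / (0.5 * h)) ** 2 + ((c - cx) / (0.5 * w)) ** 2)


def _sample_point(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    for _ in range(1000):
        p = rng.uniform([2.0, 2.0], [h - 3.0, w - 3.0])
        if _fov_radius(p[0], p[1], h, w) <= 0.82:
            return p
    raise SceneGenerationError("could not sample a point inside the field of view")


def _layout_points(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Place points honouring the close-pair composition.

    Returns the (n, 2) array and the number of close points actually
    placed.  Close points come in clusters of two (one cluster of three
    when the requested count is odd and >= 3; a request of exactly one
    close point is rounded up to two, since a lone point cannot be close).
    """
    h, w = spec.height, spec.width
    n = int(rng.integers(spec.n_points[0], spec.n_points[1] + 1))
    if n == 0:
        return np.empty((0, 2)), 0
    n_close = int(round(spec.close_pair_fraction * n))
    if n_close == 1:
        n_close = 2 if n >= 2 else 0
    n_close = min(n_close, n)
    cluster_sizes = []
    remaining = n_close
    while remaining > 0:
        size = 3 if remaining == 3 else 2
        cluster_sizes.append(size)
        remaining -= size
    n_single = n - n_close
    lo = max(spec.min_separation, 4.0)
    hi = CLOSE_THRESHOLD - 1.0

    accepted: list[np.ndarray] = []
    for size in cluster_sizes + [1] * n_single:
        placed = None
        for _ in range(400):
            anchor = _sample_point(rng, h, w)
            cluster = [anchor]
            ok = True
            for _ in range(size - 1):
                for _ in range(50):
                    dist = rng.uniform(lo, hi)
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    cand = anchor + dist * np.array([math.sin(theta), math.cos(theta)])
                    inside = (2.0 <= cand[0] <= h - 3.0 and 2.0 <= cand[1] <= w - 3.0
                              and _fov_radius(cand[0], cand[1], h, w) <= 0.82)
                    far_enough = all(np.linalg.norm(cand - q) >= spec.min_separation
                                     for q in cluster)
                    if inside and far_enough:
                        cluster.append(cand)
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            if all(np.linalg.norm(p - q) >= _CLEARANCE
                   for p in cluster for q in accepted):
                placed = cluster
                break
        if placed is None:
            raise SceneGenerationError(
                f"could not pack {n} points into a {h}x{w} scene")
        accepted.extend(placed)
    return np.array(accepted).reshape(-1, 2), n_close


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _low_frequency_field(rng: np.random.Generator, h: int, w: int,
                         scale: float) -> np.ndarray:
    gh = max(2, int(round(h / scale)) + 1)
    gw = max(2, int(round(w / scale)) + 1)
    coarse = rng.normal(0.0, 1.0, size=(gh, gw))
    return sktransform.resize(coarse, (h, w), order=3, mode="reflect",
                              anti_aliasing=False)


def _splat_gaussian(canvas: np.ndarray, r: float, c: float, sigma: float,
                    amplitude: float) -> None:
    h, w = canvas.shape
    rad = int(math.ceil(3.0 * sigma))
    r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    patch = amplitude * np.exp(-(rr ** 2 + cc ** 2) / (2.0 * sigma ** 2))
    np.maximum(canvas[r0:r1, c0:c1], patch, out=canvas[r0:r1, c0:c1])


def _render_thread(mask: np.ndarray, endpoint: np.ndarray,
                   rng: np.random.Generator) -> None:
    """Draw a short curved thread whose end is exactly at ``endpoint``."""
    length = rng.uniform(16.0, 34.0)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    u = np.array([math.sin(theta), math.cos(theta)])
    perp = np.array([-u[1], u[0]])
    bend = rng.uniform(-0.25, 0.25) * length
    p0 = endpoint
    p2 = endpoint + length * u
    p1 = endpoint + 0.5 * length * u + bend * perp
    t = np.linspace(0.0, 1.0, max(8, int(3 * length)))[:, None]
    curve = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
    for r, c in curve:
        _splat_gaussian(mask, r, c, 0.9, 1.0)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, PointSet]:
    """Render one synthetic endoscopy scene.

    Returns an 8-bit RGB image of shape (H, W, 3) and the exact render-time
    ground truth as a :class:`PointSet`.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    pts, _ = _layout_points(spec, rng)

    rows = np.arange(h)[:, None].astype(np.float64)
    cols = np.arange(w)[None, :].astype(np.float64)
    base = np.array([0.58, 0.23, 0.22])  # tissue red
    img = np.empty((h, w, 3))
    lum = _low_frequency_field(rng, h, w, spec.texture_scale)
    tint = _low_frequency_field(rng, h, w, spec.texture_scale * 2.0)
    for ch in range(3):
        img[..., ch] = base[ch] * (1.0 + 0.22 * lum) + 0.05 * tint

    # specular highlight distractors
    n_spec = int(rng.integers(spec.specular_count[0], spec.specular_count[1] + 1))
    spec_mask = np.zeros((h, w))
    for _ in range(n_spec):
        p = _sample_point(rng, h, w)
        _splat_gaussian(spec_mask, p[0], p[1], rng.uniform(1.5, 5.0),
                        rng.uniform(0.6, 1.0))
    img += spec_mask[..., None] * np.array([1.0, 0.97, 0.92])

    # suture threads with puncture marks at the annotated endpoints
    thread_mask = np.zeros((h, w))
    puncture = np.zeros((h, w))
    for p in pts:
        _render_thread(thread_mask, p, rng)
        _splat_gaussian(puncture, p[0], p[1], 1.3, 1.0)
    thread_mask = np.clip(thread_mask, 0.0, 1.0)
    thread_colour = np.array([0.78, 0.88, 0.74])  # pale green braided suture
    img = img * (1.0 - 0.85 * thread_mask[..., None]) \
        + 0.85 * thread_mask[..., None] * thread_colour
    img *= 1.0 - 0.55 * puncture[..., None]

    if spec.vignette:
        fov = _fov_radius(rows, cols, h, w)
        img *= np.clip(1.15 - 1.3 * np.maximum(fov - 0.62, 0.0) ** 1.5, 0.0, 1.0)[..., None]

    img = np.clip(img, 0.0, 1.0)
    return (np.round(img * 255.0).astype(np.uint8),
            PointSet(pts, height=h, width=w))


# ---------------------------------------------------------------------------
# dataset generation and labelme I/O
# ---------------------------------------------------------------------------

def generate_dataset(spec: SceneSpec, n_images: int, out_dir,
                     n_groups: int = 4) -> dict:
    """Write ``n_images`` scenes as PNG + labelme JSON plus a manifest.

    Per-image seeds are derived from ``spec.seed``; images are assigned to
    ``n_groups`` contiguous groups (stand-ins for surgery/session ids used
    by group-wise cross-validation).  Returns the manifest dict, which is
    also written to ``manifest.json``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_images)
    entries = []
    for i in range(n_images):
        scene_spec = replace(spec, seed=int(seeds[i] % (2 ** 31)))
        image, points = generate_scene(scene_spec)
        image_name = f"image_{i:04d}.png"
        ann_name = f"image_{i:04d}.json"
        iio.imwrite(out_dir / image_name, image)
        write_labelme(points, image_name, out_dir / ann_name)
        from .matching import close_gt_mask

        entries.append({
            "image": image_name,
            "annotation": ann_name,
            "n_points": len(points),
            "n_close": int(close_gt_mask(points, CLOSE_THRESHOLD).sum()),
            "group": f"group{(i * n_groups) // n_images}",
            "seed": scene_spec.seed,
        })
    manifest = {"spec": _spec_as_dict(spec), "seed": spec.seed,
                "n_images": n_images, "entries": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _spec_as_dict(spec: SceneSpec) -> dict:
    d = asdict(spec)
    d["n_points"] = list(spec.n_points)
    d["specular_count"] = list(spec.specular_count)
    return d


def read_labelme(path) -> PointSet:
    """Parse a labelme JSON annotation into a :class:`PointSet`.

    Each shape must have ``shape_type == "point"`` with a single ``[x, y]``
    coordinate; labelme's ``(x, y)`` maps to ``(col, row)``.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed labelme JSON in {path}: {err}") from err
    h, w = int(doc["imageHeight"]), int(doc["imageWidth"])
    pts = []
    for i, shape in enumerate(doc.get("shapes", [])):
        if shape.get("shape_type") != "point":
            raise ValueError(
                f"{path}: shape {i} (label {shape.get('label')!r}) has "
                f"shape_type {shape.get('shape_type')!r}, expected 'point'")
        (x, y), = shape["points"]
        pts.append((float(y), float(x)))
    return PointSet(np.array(pts, dtype=np.float64).reshape(-1, 2), h, w)


def write_labelme(points: PointSet, image_path, out_path) -> None:
    """Write a :class:`PointSet` as a labelme JSON point annotation."""
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": [
            {"label": "suture", "shape_type": "point", "group_id": None,
             "points": [[float(c), float(r)]], "flags": {}}
            for r, c in points.points
        ],
        "imagePath": str(image_path),
        "imageData": None,
        "imageHeight": int(points.height),
        "imageWidth": int(points.width),
    }
    Path(out_path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation suite; every transform fires independently with ``p_apply``.

    Geometric: horizontal/vertical flip, rotation uniform in
    +/-``rotation_limit`` degrees, translation uniform in
    +/-``translate_limit`` of the frame size, shear in +/-``shear_limit``.
    Photometric: additive brightness +/-``brightness_limit``, multiplicative
    contrast factor drawn from ``contrast_range`` (about mid-grey),
    saturation scale from ``saturation_range``, hue shift
    +/-``hue_limit`` (fraction of the hue circle), additive intensity shift
    +/-``shift_limit`` of the dynamic range.
    """

    p_apply: float = 0.5
    rotation_limit: float = 60.0
    translate_limit: float = 0.10
    shear_limit: float = 0.1
    shift_limit: float = 0.01
    brightness_limit: float = 0.2
    contrast_range: tuple[float, float] = (0.3, 0.5)
    saturation_range: tuple[float, float] = (0.5, 2.0)
    hue_limit: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must lie in [0, 1]")


def affine_matrix(height: int, width: int, *, hflip: bool = False,
                  vflip: bool = False, rotation_deg: float = 0.0,
                  translate: tuple[float, float] = (0.0, 0.0),
                  shear: float = 0.0) -> np.ndarray:
    """Homogeneous 3x3 matrix in (x, y) pixel coordinates.

    Rotation and shear act about the image centre ``((W-1)/2, (H-1)/2)``;
    ``translate`` is (dx, dy) in pixels.  The matrix maps input (x, y, 1)
    to output coordinates.
    """
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0

    def about_centre(m):
        pre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=np.float64)
        post = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=np.float64)
        return post @ m @ pre

    mat = np.eye(3)
    if hflip:
        mat = np.array([[-1, 0, width - 1.0], [0, 1, 0], [0, 0, 1]]) @ mat
    if vflip:
        mat = np.array([[1, 0, 0], [0, -1, height - 1.0], [0, 0, 1]]) @ mat
    if rotation_deg:
        a = math.radians(rotation_deg)
        rot = np.array([[math.cos(a), -math.sin(a), 0],
                        [math.sin(a), math.cos(a), 0], [0, 0, 1]])
        mat = about_centre(rot) @ mat
    if shear:
        sh = np.array([[1, shear, 0], [0, 1, 0], [0, 0, 1]], dtype=np.float64)
        mat = about_centre(sh) @ mat
    if translate != (0.0, 0.0):
        mat = np.array([[1, 0, translate[0]], [0, 1, translate[1]],
                        [0, 0, 1]], dtype=np.float64) @ mat
    return mat


def apply_affine(image: np.ndarray, points: PointSet,
                 matrix: np.ndarray) -> tuple[np.ndarray, PointSet]:
    """Warp image and points with the same homogeneous (x, y) matrix.

    The image is resampled bilinearly (zero fill outside); points that land
    outside the frame are dropped.  The image is returned as float64 in
    [0, 1] regardless of the input dtype.
    """
    img = _as_float(image)
    tform = sktransform.ProjectiveTransform(matrix=np.linalg.inv(matrix))
    warped = sktransform.warp(img, tform, order=1, mode="constant", cval=0.0,
                              preserve_range=True)
    if len(points):
        xy = points.points[:, ::-1]  # (row, col) -> (x, y)
        ones = np.ones((len(points), 1))
        new_xy = (matrix @ np.hstack([xy, ones]).T).T[:, :2]
        new_rc = new_xy[:, ::-1]
        keep = ((new_rc[:, 0] >= 0) & (new_rc[:, 0] < points.height)
                & (new_rc[:, 1] >= 0) & (new_rc[:, 1] < points.width))
        new_pts = new_rc[keep]
    else:
        new_pts = points.points
    return warped, PointSet(new_pts, points.height, points.width)


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def augment_sample(image: np.ndarray, points: PointSet,
                   config: AugmentConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, PointSet]:
    """Apply the augmentation suite to one (image, points) sample.

    Deterministic given ``config.seed`` (or an explicit ``rng``).  Returns
    a float64 RGB image in [0, 1] and the coordinate-consistent point set;
    with ``p_apply = 0`` the sample passes through unchanged (up to the
    float conversion).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p = config.p_apply
    h, w = points.height, points.width

    fire = rng.uniform(size=9) < p  # one decision per transform, fixed order
    draws = {
        "rotation": rng.uniform(-config.rotation_limit, config.rotation_limit),
        "translate": rng.uniform(-config.translate_limit, config.translate_limit,
                                 size=2),
        "shear": rng.uniform(-config.shear_limit, config.shear_limit),
        "brightness": rng.uniform(-config.brightness_limit, config.brightness_limit),
        "contrast": rng.uniform(*config.contrast_range),
        "saturation": rng.uniform(*config.saturation_range),
        "hue": rng.uniform(-config.hue_limit, config.hue_limit),
        "shift": rng.uniform(-config.shift_limit, config.shift_limit),
    }

    matrix = affine_matrix(
        h, w,
        hflip=bool(fire[0]),
        vflip=bool(fire[1]),
        rotation_deg=draws["rotation"] if fire[2] else 0.0,
        translate=(tuple(draws["translate"] * np.array([w, h]))
                   if fire[3] else (0.0, 0.0)),
        shear=draws["shear"] if fire[4] else 0.0,
    )
    img = _as_float(image)
    if fire[:5].any():
        img, points = apply_affine(img, points, matrix)

    if fire[5]:
        img = img + draws["brightness"]
    if fire[6]:
        img = 0.5 + draws["contrast"] * (img - 0.5)
    if fire[7] or fire[8]:
        hsv = skcolor.rgb2hsv(np.clip(img, 0.0, 1.0))
        if fire[7]:
            hsv[..., 1] = np.clip(hsv[..., 1] * draws["saturation"], 0.0, 1.0)
        if fire[8]:
            hsv[..., 0] = np.mod(hsv[..., 0] + draws["hue"], 1.0)
        img = skcolor.hsv2rgb(hsv)
    shift_fire = rng.uniform() < p
    if shift_fire:
        img = img + draws["shift"]
    return np.clip(img, 0.0, 1.0), points
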