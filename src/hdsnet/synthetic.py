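"""Synthetic dermoscopy-style image/mask pairs.

Emulates the features that make real skin-lesion segmentation hard — irregular
lesion shapes (star-convex contours with radial noise), blurred lesion/skin
boundaries, size variation, and hair-like curvilinear clutter — while keeping
the exact ground-truth mask available by construction. Output follows the
ISIC challenge layout (``ISIC_<id>.jpg`` + ``ISIC_<id>_segmentation.png``) so
the same data-loading path serves real and synthetic data.

Not modeled: dermoscopic gel bubbles, rulers/markers, vignetting, real ISIC
intensity statistics. Segmentation quality reached on these images therefore
demonstrates that the pipeline learns, not that it would match benchmark
scores on real dermoscopy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

__all__ = ["LesionParams", "GenerationError", "generate_sample", "generate_dataset"]


class GenerationError(RuntimeError):
    """Raised when a sample cannot satisfy its parameters after bounded retries."""


@dataclass
class LesionParams:
    """Knobs of the generator.

    Defaults give a mid-size, clearly pigmented but irregular lesion on a
    lightly textured skin background with a few occluding hairs — the typical
    regime of dermoscopic archives.
    """

    image_size: tuple = (128, 128)
    n_control_points: tuple = (8, 16)       # contour control points (min, max)
    radial_noise: float = 0.35              # relative radius jitter amplitude
    boundary_blur_sigma: float = 1.5        # px; 0 = hard boundary
    lesion_color: tuple = (0.38, 0.24, 0.18)  # RGB mean, dark brown
    skin_color: tuple = (0.80, 0.62, 0.55)    # RGB mean, light skin
    color_jitter: float = 0.05              # per-sample color shift (uniform half-width)
    texture_noise: float = 0.02             # per-pixel background texture std
    hair_count: tuple = (0, 8)              # hairs per image (min, max inclusive)
    hair_thickness: tuple = (1, 2)          # px
    area_fraction: tuple = (0.05, 0.40)     # lesion area / image area
    max_retries: int = 20

    def __post_init__(self):
        lo, hi = self.area_fraction
        if not (0.0 < lo < hi < 0.9):
            raise ValueError(f"area_fraction range must satisfy 0 < lo < hi < 0.9, got {self.area_fraction}")
        if self.boundary_blur_sigma < 0:
            raise ValueError("boundary_blur_sigma must be >= 0")
        if self.n_control_points[0] < 4 or self.n_control_points[1] < self.n_control_points[0]:
            raise ValueError("n_control_points must be a non-degenerate range >= 4")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LesionParams":
        d = dict(d)
        for key in ("image_size", "n_control_points", "hair_thickness", "hair_count", "area_fraction",
                    "lesion_color", "skin_color"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _star_convex_mask(params: LesionParams, rng: np.random.Generator, target_af: float) -> np.ndarray:
    """Binary mask of a star-convex blob with the requested area fraction."""
    h, w = params.image_size
    n_pts = int(rng.integers(params.n_control_points[0], params.n_control_points[1] + 1))
    cy = h * (0.5 + 0.1 * rng.uniform(-1, 1))
    cx = w * (0.5 + 0.1 * rng.uniform(-1, 1))
    # radius profile: periodic cubic interpolation of noisy control radii
    base = np.sqrt(target_af * h * w / np.pi)
    ctrl_theta = np.linspace(0.0, 2 * np.pi, n_pts + 1)
    ctrl_r = 1.0 + params.radial_noise * rng.uniform(-1, 1, n_pts)
    ctrl_r = np.append(ctrl_r, ctrl_r[0])
    spline = CubicSpline(ctrl_theta, ctrl_r, bc_type="periodic")
    theta = np.linspace(0.0, 2 * np.pi, 360, endpoint=False)
    r_rel = np.clip(spline(theta), 0.2, None)

    for _ in range(params.max_retries):
        r = base * r_rel
        rr = cy + r * np.sin(theta)
        cc = cx + r * np.cos(theta)
        if rr.min() < 1 or cc.min() < 1 or rr.max() > h - 2 or cc.max() > w - 2:
            base *= 0.9  # shrink until the contour fits inside the frame
            continue
        mask = np.zeros((h, w), dtype=np.uint8)
        pr, pc = draw_polygon(rr, cc, shape=(h, w))
        mask[pr, pc] = 1
        af = mask.mean()
        lo, hi = params.area_fraction
        if lo <= af <= hi:
            return mask
        if af <= 0:
            raise GenerationError("degenerate (empty) lesion polygon")
        # rescale radii toward the target area and retry
        base *= np.sqrt(np.clip(target_af / af, 0.5, 2.0))
    raise GenerationError(
        f"could not realize an area fraction in {params.area_fraction} after {params.max_retries} retries"
    )


def _draw_hairs(img: np.ndarray, params: LesionParams, rng: np.random.Generator):
    """Dark quadratic-Bezier strokes over the composited image (in place)."""
    h, w = img.shape[:2]
    n = int(rng.integers(params.hair_count[0], params.hair_count[1] + 1))
    for _ in range(n):
        pts = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2))
        t = np.linspace(0.0, 1.0, 4 * (h + w))[:, None]
        bez = (1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1] + t**2 * pts[2]
        thick = int(rng.integers(params.hair_thickness[0], params.hair_thickness[1] + 1))
        shade = rng.uniform(0.05, 0.25)
        color = np.array([shade, shade * 0.9, shade * 0.8])
        ys, xs = bez[:, 0], bez[:, 1]
        for dy in range(thick):
            for dx in range(thick):
                yy = np.clip(np.round(ys) + dy, 0, h - 1).astype(int)
                xx = np.clip(np.round(xs) + dx, 0, w - 1).astype(int)
                img[yy, xx] = color


def generate_sample(params: LesionParams, rng: np.random.Generator, return_layers: bool = False):
    """One (image, mask) pair; image float RGB in [0,1], mask uint8 {0,1}.

    The mask is the exact, un-blurred lesion support; boundary blur only
    softens the *image* compositing alpha.
    """
    h, w = params.image_size
    lo, hi = params.area_fraction
    target_af = rng.uniform(lo, hi)
    mask = _star_convex_mask(params, rng, target_af)

    jit = params.color_jitter
    skin = np.clip(np.array(params.skin_color) + rng.uniform(-jit, jit, 3), 0, 1)
    lesion = np.clip(np.array(params.lesion_color) + rng.uniform(-jit, jit, 3), 0, 1)

    # background: flat skin tone + low-frequency illumination + pixel texture
    yy, xx = np.mgrid[0:h, 0:w]
    gdir = rng.uniform(-1, 1, 2)
    gradient = 0.04 * (gdir[0] * (yy / h - 0.5) + gdir[1] * (xx / w - 0.5))
    texture = rng.normal(0.0, params.texture_noise, (h, w))
    base = np.clip(skin[None, None, :] + (gradient + texture)[:, :, None], 0, 1)

    # lesion layer: darker center, slight texture of its own
    dist = np.sqrt((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / max(h, w)
    lesion_layer = np.clip(
        lesion[None, None, :] * (1.0 - 0.25 * (1 - dist))[:, :, None]
        + rng.normal(0.0, params.texture_noise, (h, w))[:, :, None],
        0, 1,
    )

    alpha = mask.astype(np.float64)
    if params.boundary_blur_sigma > 0:
        alpha = gaussian_filter(alpha, params.boundary_blur_sigma)
    img = alpha[:, :, None] * lesion_layer + (1.0 - alpha[:, :, None]) * base
    _draw_hairs(img, params, rng)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    if return_layers:
        return img, mask, {"base": base, "lesion_layer": lesion_layer, "alpha": alpha}
    return img, mask


def generate_dataset(n: int, params: LesionParams, out_dir, seed: int = 0) -> dict:
    """Write ``n`` pairs in ISIC layout plus a JSON manifest with per-sample seeds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    sample_seeds = master.integers(0, 2**31 - 1, size=n)
    records = []
    for k, s in enumerate(sample_seeds):
        img, mask = generate_sample(params, np.random.default_rng(int(s)))
        sid = f"{k:07d}"
        img_path = out_dir / f"ISIC_{sid}.jpg"
        mask_path = out_dir / f"ISIC_{sid}_segmentation.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(img_path, quality=95)
        Image.fromarray((mask * 255).astype(np.uint8)).save(mask_path)
        records.append({"id": sid, "image": img_path.name, "mask": mask_path.name, "seed": int(s)})
    manifest = {"n": n, "seed": int(seed), "params": params.to_dict(), "records": records}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
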