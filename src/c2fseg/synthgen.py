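"""Seeded synthetic datasets with ground-truth fine labels and inflated MGRLs.

Two families are generated:

* **Circle scenes** — noisy discs on a noisy background ("pallet").  The
  ground truth is the exact rasterized disc; the rough label (MGRL) is the
  same disc with its radius inflated, emulating a hand-drawn convex outline
  of "somewhat wider diameter".  Discs are rendered with a green-biased
  foreground so the channel-difference machinery applies to them unchanged.

* **Field-like scenes** — lobed leaf-shaped blobs (unions of rotated
  ellipses, optionally with circular holes) over a low-frequency red-brown
  soil texture.  Foreground pixels have G-channel dominance, background has
  R >= G on average, mirroring the colour statistics of vegetation imagery.
  MGRLs are per-class convex hulls dilated by a configurable margin.

Everything is deterministic given the spec's seed: identical specs produce
byte-identical pixel arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image, disk

__all__ = [
    "CircleSpec",
    "FieldSpec",
    "SyntheticSample",
    "gen_circles",
    "gen_field",
    "gen_pair_separable",
    "inflate_to_mgrl",
    "write_dataset",
]


@dataclass(frozen=True)
class CircleSpec:
    """Configuration of the circle dataset.

    Foreground/background colours are chosen so the foreground's normalized
    G - R margin clearly exceeds the background's, keeping threshold labels
    derivable from the same images.  Noise std defaults to 10/255 of the
    intensity range, applied per channel and clipped to [0, 255].
    """

    n_images: int = 500
    image_size: int = 512
    circles_per_image: tuple[int, int] = (2, 5)
    radius_range: tuple[int, int] = (40, 90)
    mgrl_inflation: float = 1.3
    noise_std: float = 25.5
    fg_color: tuple[int, int, int] = (80, 160, 90)
    bg_color: tuple[int, int, int] = (150, 130, 110)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.mgrl_inflation <= 1.0:
            raise ValueError("mgrl_inflation must exceed 1.0 so MGRL strictly contains the disc")
        lo, hi = self.radius_range
        if lo < 1 or hi < lo:
            raise ValueError("radius_range must satisfy 1 <= lo <= hi")
        if 2 * int(hi * self.mgrl_inflation) + 2 >= self.image_size:
            raise ValueError(
                "radius_range exceeds image bounds: the inflated MGRL disc "
                f"(radius ~{int(hi * self.mgrl_inflation)}) must fit in a "
                f"{self.image_size}px image"
            )
        fg_margin = self.fg_color[1] - self.fg_color[0]
        bg_margin = self.bg_color[1] - self.bg_color[0]
        if fg_margin <= bg_margin:
            raise ValueError("fg_color must have a larger G-R margin than bg_color")


@dataclass(frozen=True)
class FieldSpec:
    """Configuration of the field-like leaf/soil dataset."""

    n_images: int = 100
    image_size: int = 512
    blobs_per_image: tuple[int, int] = (1, 3)
    hole_probability: float = 0.5
    mgrl_dilation: int = 6
    noise_std: float = 18.0
    soil_smoothness: float = 12.0  # gaussian sigma of the low-frequency soil texture
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not 0.0 <= self.hole_probability <= 1.0:
            raise ValueError("hole_probability must be in [0, 1]")
        if self.mgrl_dilation < 0:
            raise ValueError("mgrl_dilation must be >= 0")


@dataclass
class SyntheticSample:
    """One generated scene: RGB image, exact fine label, rough label."""

    image: np.ndarray  # H x W x 3 uint8
    fine_label: np.ndarray  # H x W uint8, 0 = background
    mgrl: np.ndarray  # H x W uint8, contains the fine label per class
    meta: dict = field(default_factory=dict)

    def check_containment(self) -> bool:
        """Every fine-label pixel of class k lies inside the class-k MGRL."""
        fg = self.fine_label > 0
        return bool(np.all(self.mgrl[fg] == self.fine_label[fg]))


def _disc_mask(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _noisy_paint(shape_hw: tuple[int, int], color, noise_std: float,
                 rng: np.random.Generator) -> np.ndarray:
    base = np.empty((*shape_hw, 3), dtype=np.float64)
    base[...] = color
    base += rng.normal(0.0, noise_std, size=base.shape)
    return base


def gen_circles(spec: CircleSpec) -> list[SyntheticSample]:
    """Generate the circle dataset: noisy discs on a noisy pallet."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    samples: list[SyntheticSample] = []
    for i in range(spec.n_images):
        fine = np.zeros((size, size), dtype=np.uint8)
        mgrl = np.zeros((size, size), dtype=np.uint8)
        n = int(rng.integers(spec.circles_per_image[0], spec.circles_per_image[1] + 1))
        img = _noisy_paint((size, size), spec.bg_color, spec.noise_std, rng)
        fg = _noisy_paint((size, size), spec.fg_color, spec.noise_std, rng)
        for _ in range(n):
            r = float(rng.uniform(*spec.radius_range))
            r_mgrl = r * spec.mgrl_inflation
            margin = int(np.ceil(r_mgrl)) + 1
            cy = float(rng.uniform(margin, size - margin))
            cx = float(rng.uniform(margin, size - margin))
            gt = _disc_mask(size, cy, cx, r)
            fine[gt] = 1
            mgrl[_disc_mask(size, cy, cx, r_mgrl)] = 1
        img[fine > 0] = fg[fine > 0]
        img = np.clip(img, 0, 255).astype(np.uint8)
        samples.append(SyntheticSample(img, fine, mgrl, {"index": i, "n_circles": n}))
    return samples


def _leaf_blob(size: int, rng: np.random.Generator) -> np.ndarray:
    """A lobed leaf-like region: union of 2-4 rotated ellipses round a centre."""
    mask = np.zeros((size, size), dtype=bool)
    margin = size // 5
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    yy, xx = np.mgrid[:size, :size]
    for _ in range(int(rng.integers(2, 5))):
        a = rng.uniform(size / 12, size / 5)  # semi-axes
        b = a * rng.uniform(0.4, 0.8)
        theta = rng.uniform(0, np.pi)
        oy = cy + rng.uniform(-a / 2, a / 2)
        ox = cx + rng.uniform(-a / 2, a / 2)
        ry = (yy - oy) * np.cos(theta) + (xx - ox) * np.sin(theta)
        rx = -(yy - oy) * np.sin(theta) + (xx - ox) * np.cos(theta)
        mask |= (ry / a) ** 2 + (rx / b) ** 2 <= 1.0
    return mask


def gen_field(spec: FieldSpec) -> list[SyntheticSample]:
    """Generate field-like scenes: green leaves over red-brown soil."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    samples: list[SyntheticSample] = []
    for i in range(spec.n_images):
        # soil: low-frequency red-brown texture, R >= G on average
        lowfreq = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, (size, size)), spec.soil_smoothness
        )
        lowfreq /= max(np.abs(lowfreq).max(), 1e-9)
        soil = np.empty((size, size, 3), dtype=np.float64)
        soil[..., 0] = 150 + 40 * lowfreq
        soil[..., 1] = 120 + 30 * lowfreq
        soil[..., 2] = 95 + 25 * lowfreq

        fine = np.zeros((size, size), dtype=np.uint8)
        n_blobs = int(rng.integers(spec.blobs_per_image[0], spec.blobs_per_image[1] + 1))
        for _ in range(n_blobs):
            blob = _leaf_blob(size, rng)
            if rng.uniform() < spec.hole_probability:
                ys, xs = np.nonzero(blob)
                if len(ys) > 0:
                    j = int(rng.integers(len(ys)))
                    hole = _disc_mask(size, ys[j], xs[j], rng.uniform(size / 40, size / 16))
                    blob &= ~hole
            fine[blob] = 1

        leaf = np.empty((size, size, 3), dtype=np.float64)
        leaf[..., 0] = 75
        leaf[..., 1] = 150
        leaf[..., 2] = 85
        img = np.where(fine[..., None] > 0, leaf, soil)
        img += rng.normal(0.0, spec.noise_std, img.shape)
        img = np.clip(img, 0, 255).astype(np.uint8)

        mgrl = inflate_to_mgrl(fine, spec.mgrl_dilation)
        fgm = fine > 0
        bgm = ~fgm
        gp = img[..., 1].astype(float)
        rp = img[..., 0].astype(float)
        meta = {"index": i, "n_blobs": n_blobs}
        if fgm.any() and bgm.any():
            gmax, rmax = max(gp.max(), 1.0), max(rp.max(), 1.0)
            d = gp / gmax - rp / rmax
            meta["gr_margin"] = float(d[fgm].mean() - d[bgm].mean())
        samples.append(SyntheticSample(img, fine, mgrl, meta))
    return samples


def inflate_to_mgrl(fine_label: np.ndarray, dilation: int) -> np.ndarray:
    """Rough label from a fine label: per-class convex hull, then dilation.

    Emulates a hand-drawn convex envelope of each class region.  Where hulls
    of different classes overlap, later classes overwrite earlier ones and
    the fine labels are re-stamped on top, so per-class containment of the
    fine label is preserved exactly.
    """
    if dilation < 0:
        raise ValueError("dilation must be >= 0")
    fine_label = np.asarray(fine_label)
    out = np.zeros_like(fine_label, dtype=np.uint8)
    selem = disk(dilation) if dilation > 0 else None
    for k in sorted(int(v) for v in np.unique(fine_label) if v != 0):
        region = fine_label == k
        hull = convex_hull_image(region)
        if selem is not None:
            hull = ndimage.binary_dilation(hull, structure=selem)
        out[hull] = k
    fg = fine_label > 0
    out[fg] = fine_label[fg]
    return out


def gen_pair_separable(
    n_images: int,
    image_size: int = 64,
    n_classes: int = 2,
    seed: int = 0,
) -> list[tuple[SyntheticSample, dict[int, tuple[str, str]]]]:
    """Diagnostic scenes where a *known* ordered channel pair separates each class.

    Each class occupies a disc whose colour raises exactly one normalized
    channel difference above the background's; the expected winning pair per
    class is returned alongside the sample.  Used to exercise the GCDT
    selection loop against an independent exhaustive search.
    """
    # colour recipes: (fg colour, background-safe pair) — each foreground
    # colour makes `pair` strongly positive while the grey background keeps
    # all differences near zero
    recipes = {
        ("G", "R"): (40, 200, 90),
        ("B", "G"): (90, 40, 200),
        ("R", "B"): (200, 90, 40),
    }
    pair_cycle = list(recipes.items())
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_images):
        img = np.empty((image_size, image_size, 3), dtype=np.float64)
        img[...] = (120, 120, 120)
        fine = np.zeros((image_size, image_size), dtype=np.uint8)
        expected: dict[int, tuple[str, str]] = {}
        r = image_size // 6
        for k in range(1, n_classes + 1):
            pair, color = pair_cycle[(k - 1) % len(pair_cycle)]
            placed = False
            for _attempt in range(50):
                cy = rng.uniform(r + 2, image_size - r - 2)
                cx = rng.uniform(r + 2, image_size - r - 2)
                m = _disc_mask(image_size, cy, cx, r)
                if not (fine[m] > 0).any():
                    placed = True
                    break
            if not placed:
                continue
            img[m] = color
            fine[m] = k
            expected[k] = pair
        img += rng.normal(0.0, 6.0, img.shape)
        img = np.clip(img, 0, 255).astype(np.uint8)
        mgrl = inflate_to_mgrl(fine, dilation=4)
        out.append((SyntheticSample(img, fine, mgrl, {}), expected))
    return out


def write_dataset(samples: list[SyntheticSample], root: str | Path,
                  spec=None) -> Path:
    """Write a dataset directory: images/, fine/, mgrl/ and manifest.json."""
    from .io import write_image, write_mask  # local import to avoid a cycle

    root = Path(root)
    for sub in ("images", "fine", "mgrl"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(samples))))
    for i, s in enumerate(samples):
        stem = f"{i:0{width}d}"
        write_image(root / "images" / f"{stem}.png", s.image)
        write_mask(root / "fine" / f"{stem}.png", s.fine_label)
        write_mask(root / "mgrl" / f"{stem}.png", s.mgrl)
    manifest = {"n_samples": len(samples)}
    if spec is not None:
        manifest["spec"] = {k: list(v) if isinstance(v, tuple) else v
                            for k, v in asdict(spec).items()}
        manifest["spec_type"] = type(spec).__name__
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root
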