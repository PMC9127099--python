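"""Dataset I/O: image/mask reading and writing, pairing, resizing, config.

Directory layout (as written by the synthetic generators, and expected from
user-supplied data):

    root/
      images/<stem>.png     RGB images (PNG/JPEG/TIFF)
      mgrl/<stem>.png       rough labels, single-channel indexed PNG
      fine/<stem>.png       optional fine labels (ground truth / validation)

Masks are single-channel indexed PNGs whose pixel value *is* the class index
(0 = background): class recovery is unambiguous and the round-trip is
lossless.  Coordinates are 0-based (row, col), origin top-left.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "DatasetIndex",
    "DatasetEntry",
    "load_dataset",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "resize_image",
    "resize_mask",
    "resize_sample",
    "save_checkpoint",
    "load_checkpoint",
    "log_stage",
]

IMAGE_EXTS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass(frozen=True)
class DatasetEntry:
    stem: str
    image: Path
    mgrl: Path
    fine: Path | None = None


@dataclass
class DatasetIndex:
    root: Path
    entries: list[DatasetEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_dataset(root: str | Path) -> DatasetIndex:
    """Index a dataset directory, pairing images to masks by filename stem.

    Entries come back in lexicographic stem order.  An image without an MGRL
    is a hard error naming the stem; an orphan mask only warns.
    """
    root = Path(root)
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    images = sorted(
        (p for p in img_dir.iterdir() if p.suffix.lower() in IMAGE_EXTS),
        key=lambda p: p.stem,
    )
    if not images:
        raise FileNotFoundError(f"no images found under {img_dir}")
    stems = {p.stem for p in images}
    for orphan in sorted((root / "mgrl").glob("*.png")):
        if orphan.stem not in stems:
            warnings.warn(f"orphan mask without image skipped: {orphan.name}", stacklevel=2)
    entries, missing = [], []
    for p in images:
        mgrl = root / "mgrl" / f"{p.stem}.png"
        if not mgrl.exists():
            missing.append(p.stem)
            continue
        fine = root / "fine" / f"{p.stem}.png"
        entries.append(DatasetEntry(p.stem, p, mgrl, fine if fine.exists() else None))
    if missing:
        raise FileNotFoundError(
            f"images without MGRL masks: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    return DatasetIndex(root, entries)


def read_image(path: str | Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise OSError(f"failed to read image {path}: {exc}") from exc


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"failed to read mask {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"mask {path} is not single-channel (shape {arr.shape})")
    return arr.astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.max(initial=0) > 255:
        raise ValueError("masks with more than 255 classes are not supported")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)


def resize_image(image: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize to target x target, aspect ratio not preserved."""
    if target < 32:
        raise ValueError("resize target must be >= 32")
    if image.shape[:2] == (target, target):
        return image
    out = _sk_resize(
        image, (target, target), order=1, preserve_range=True, anti_aliasing=True
    )
    return np.clip(out, 0, 255).astype(np.uint8)


def resize_mask(mask: np.ndarray, target: int) -> np.ndarray:
    """Nearest-neighbour resize: class indices preserved, none invented."""
    if target < 32:
        raise ValueError("resize target must be >= 32")
    if mask.shape == (target, target):
        return mask
    out = _sk_resize(
        mask, (target, target), order=0, preserve_range=True, anti_aliasing=False
    )
    return out.astype(mask.dtype)


def resize_sample(sample, target: int):
    """Resize a SyntheticSample-like object (image + masks) in place-free form."""
    from .synthgen import SyntheticSample

    return SyntheticSample(
        image=resize_image(sample.image, target),
        fine_label=resize_mask(sample.fine_label, target),
        mgrl=resize_mask(sample.mgrl, target),
        meta=dict(getattr(sample, "meta", {})),
    )


def save_checkpoint(model, path: str | Path) -> None:
    """Persist model weights + config as an .npz archive (native format)."""
    from .segmodel import NetConfig  # noqa: F401 - documented format owner

    state = model.state_dict()
    cfg = model.cfg
    arrays = {f"p{i}": a for i, a in enumerate(state["params"])}
    for i, (m, v) in enumerate(state["bn"]):
        arrays[f"bnm{i}"] = m
        arrays[f"bnv{i}"] = v
    meta = {
        "depth": cfg.depth,
        "base_channels": cfg.base_channels,
        "n_classes": cfg.n_classes,
        "gamma": cfg.fusion.gamma,
        "use_fusion": cfg.use_fusion,
        "n_params": len(state["params"]),
        "n_bn": len(state["bn"]),
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path):
    from .segmodel import FusionConfig, NetConfig, build_model

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg = NetConfig(
            depth=meta["depth"],
            base_channels=meta["base_channels"],
            n_classes=meta["n_classes"],
            fusion=FusionConfig(meta["gamma"]),
            use_fusion=meta["use_fusion"],
        )
        model = build_model(cfg)
        state = {
            "params": [z[f"p{i}"] for i in range(meta["n_params"])],
            "bn": [(z[f"bnm{i}"], z[f"bnv{i}"]) for i in range(meta["n_bn"])],
        }
    model.load_state_dict(state)
    return model


def config_hash(obj) -> str:
    """Stable short digest of a config-like mapping, for log lines."""
    blob = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_stage(stage: str, **fields) -> None:
    """One structured log line per pipeline stage (JSON to stderr)."""
    print(json.dumps({"stage": stage, **fields}, default=str), file=sys.stderr)
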