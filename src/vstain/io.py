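"""Shared I/O: TIFF images and stacks, scene bundles, manifests, run configs.

Images round-trip losslessly for 8/16-bit integer and float TIFF, single and
multi-page.  Pixel size is carried in a JSON ``ImageDescription`` tag.  Scenes
are written as one multi-page TIFF (page 0 bright-field, then the fluorescence
channels, final page the 16-bit label mask) plus a JSON sidecar manifest
holding the spec, channel order, pixel size and ground-truth records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .imgen import ScenePair, SceneSpec

__all__ = ["read_image", "write_image", "write_scene", "read_scene",
           "PairManifest", "RunConfig"]

_SUPPORTED = (np.uint8, np.uint16, np.float32, np.float64)


def write_image(path, image, pixel_size_um: float = None) -> None:
    """Write a 2-D image or a (pages, H, W) stack to TIFF, losslessly."""
    arr = np.asarray(image)
    if arr.dtype.type not in _SUPPORTED:
        raise ValueError(f"unsupported dtype {arr.dtype}; use uint8/uint16/float32/float64")
    meta = {"pixel_size_um": pixel_size_um} if pixel_size_um else None
    tifffile.imwrite(str(path), arr, photometric="minisblack",
                     description=json.dumps(meta) if meta else None)


def read_image(path, with_pixel_size: bool = False):
    """Read a TIFF written by :func:`write_image`; bit-identical round-trip."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image not found: {p}")
    with tifffile.TiffFile(str(p)) as tf:
        arr = tf.asarray()
        if not with_pixel_size:
            return arr
        px = None
        desc = tf.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                px = json.loads(desc.value).get("pixel_size_um")
            except (json.JSONDecodeError, AttributeError):
                px = None
        return arr, px


def write_scene(pair: ScenePair, path) -> None:
    """Scene bundle: multi-page float32 TIFF + JSON sidecar; exact round-trip."""
    path = Path(path)
    names = sorted(pair.channels)
    pages = [pair.brightfield.astype(np.float32)]
    pages += [pair.channels[n].astype(np.float32) for n in names]
    tifffile.imwrite(str(path), np.stack(pages), photometric="minisblack")
    tifffile.imwrite(str(path.with_suffix(".labels.tif")),
                     pair.labels.astype(np.uint16), photometric="minisblack")
    sidecar = {
        "spec": dataclasses.asdict(pair.spec),
        "channel_order": names,
        "pixel_size_um": pair.spec.pixel_size_um,
        "truth": list(pair.truth),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_scene(path) -> ScenePair:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(str(path))
    labels = tifffile.imread(str(path.with_suffix(".labels.tif"))).astype(np.int32)
    names = sidecar["channel_order"]
    spec = SceneSpec(**sidecar["spec"])
    channels = {n: pages[i + 1] for i, n in enumerate(names)}
    truth = tuple({k: tuple(v) if isinstance(v, list) else v for k, v in t.items()}
                  for t in sidecar["truth"])
    return ScenePair(spec=spec, brightfield=pages[0], channels=channels,
                     labels=labels, truth=truth)


@dataclass(frozen=True)
class PairManifest:
    """Paths of paired bright-field / target images for training."""

    pairs: tuple  # of (brightfield_path, target_path, channel_name)
    pixel_size_um: float = 1.0
    note: str = ""

    @classmethod
    def load(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(pairs=tuple(tuple(p) for p in d["pairs"]),
                   pixel_size_um=d.get("pixel_size_um", 1.0),
                   note=d.get("note", ""))

    def save(self, path):
        Path(path).write_text(json.dumps(
            {"pairs": [list(p) for p in self.pairs],
             "pixel_size_um": self.pixel_size_um, "note": self.note}, indent=2))

    def load_images(self):
        out = []
        for bf_path, tgt_path, name in self.pairs:
            bf = read_image(bf_path)
            tgt = read_image(tgt_path)
            if bf.shape != tgt.shape:
                raise ValueError(f"shape mismatch in pair {bf_path} / {tgt_path}")
            out.append((bf, tgt, name))
        return out


@dataclass
class RunConfig:
    """One experiment run: id, per-module settings, global seed, output dir."""

    experiment: str
    seed: int = 0
    out_dir: str = "runs"
    options: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path):
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls(**d)

    def save(self, path):
        d = dataclasses.asdict(self)
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            Path(path).write_text(json.dumps(d, indent=2))

    def child_seed(self, stage: str) -> int:
        """Per-stage child seed from the global seed by a fixed derivation."""
        h = np.uint64(self.seed)
        for ch in stage:
            h = np.uint64((int(h) * 1000003 + ord(ch)) % (2 ** 31 - 1))
        return int(h)
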