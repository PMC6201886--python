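"""On-disk formats: PNG tiles + CSV manifests, TIFF slides + truth masks.

Tiles are stored as 8-bit RGB PNGs next to a manifest CSV (tile_path,
source_id, offset_um, label, sigma_px, ...); slides as plain TIFF with the
tissue truth as a 0/255 PNG and the per-tile blur truth as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .blurlab import SyntheticSlide
from .tileset import scale_intensities


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(pixels) * 255.0), 0, 255).astype(np.uint8)


def write_tiles(pixels: np.ndarray, manifest: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write tiles as PNGs plus a manifest CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    (out_dir / "tiles").mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tile in enumerate(pixels):
        rel = f"tiles/tile{i:06d}.png"
        iio.imwrite(out_dir / rel, _to_uint8(tile))
        paths.append(rel)
    man = manifest.copy()
    man.insert(0, "tile_path", paths)
    csv_path = out_dir / "manifest.csv"
    man.to_csv(csv_path, index=False)
    return csv_path


def read_tiles(manifest_csv: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Load a tile collection written by :func:`write_tiles`; pixel values
    come back linearly scaled to [0, 1]."""
    manifest_csv = Path(manifest_csv)
    man = pd.read_csv(manifest_csv)
    root = manifest_csv.parent
    pixels = np.stack(
        [scale_intensities(iio.imread(root / p)) for p in man["tile_path"]]
    )
    return pixels, man


def write_slide(slide: SyntheticSlide, out_dir: str | Path, name: str = "slide") -> dict[str, Path]:
    """Write a synthetic slide: tiled TIFF, tissue-truth PNG, blur-truth
    TSV and a small metadata JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{name}.tiff"
    tifffile.imwrite(tiff_path, _to_uint8(slide.pixels), tile=(256, 256))
    tissue_path = out_dir / f"{name}_tissue_truth.png"
    iio.imwrite(tissue_path, (slide.tissue_truth.astype(np.uint8) * 255))
    truth_path = out_dir / f"{name}_blur_truth.tsv"
    pd.DataFrame(slide.blur_truth).to_csv(truth_path, sep="\t", index=False, header=False)
    meta_path = out_dir / f"{name}_meta.json"
    meta_path.write_text(json.dumps({"pixel_size_um": slide.pixel_size_um}))
    return {"tiff": tiff_path, "tissue_truth": tissue_path,
            "blur_truth": truth_path, "meta": meta_path}
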