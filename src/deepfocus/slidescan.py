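"""Whole-slide focus mapping.

Pipeline: a low-magnification (~1x) thumbnail of the slide is split into
tissue and glass by Otsu thresholding; the full-resolution image is then
partitioned into non-overlapping 64x64 tiles, every tile whose footprint
is sufficiently covered by tissue is classified by a trained tile-focus
model, and the result is a per-tile focus mask that can be rendered as a
green (in-focus) / red (blurred) overlay or exported as PNG/TSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

from .blurlab import LABEL_BLURRED, LABEL_IN_FOCUS, TILE_SIZE
from .tileset import apply_stats

STATE_BACKGROUND = "background"
STATE_IN_FOCUS = LABEL_IN_FOCUS
STATE_BLURRED = LABEL_BLURRED

_LUMA = np.array([0.299, 0.587, 0.114])


# ---------------------------------------------------------------------------
# slide container


@dataclass
class SlidePyramid:
    """A minimal slide reader: level-0 pixels plus downsampled thumbnails.

    Backed by an in-memory array (synthetic slides, plain TIFF/PNG).  The
    ~1x thumbnail is taken at 1/magnification of level 0 when the scan
    magnification is known, else at a fixed 1/32 downsample.
    """

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    pixel_size_um: float | None = None
    magnification: float | None = 40.0

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[-1] != 3:
            raise ValueError("slide pixels must be (H, W, 3)")
        if np.issubdtype(p.dtype, np.integer):
            p = p.astype(np.float32) / 255.0
        self.pixels = p

    @classmethod
    def from_tiff(cls, path: str | Path, magnification: float | None = 40.0) -> "SlidePyramid":
        try:
            arr = tifffile.imread(str(path))
        except Exception as exc:  # pragma: no cover - I/O failure path
            raise IOError(f"cannot read slide {path}: {exc}") from exc
        return cls(pixels=arr, magnification=magnification)

    @property
    def dimensions(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def thumbnail_factor(self) -> int:
        if self.magnification:
            return max(1, int(round(self.magnification)))
        return 32

    def thumbnail(self) -> np.ndarray:
        """Block-averaged ~1x thumbnail (crops a partial edge block)."""
        f = self.thumbnail_factor
        h, w = self.dimensions
        hc, wc = (h // f) * f, (w // f) * f
        cropped = self.pixels[:hc, :wc]
        return cropped.reshape(hc // f, f, wc // f, f, 3).mean(axis=(1, 3))

    def read_region(self, row0: int, col0: int, height: int, width: int) -> np.ndarray:
        return self.pixels[row0:row0 + height, col0:col0 + width]


# ---------------------------------------------------------------------------
# Otsu tissue detection


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold on an intensity histogram.

    Returns the cut point t maximizing the between-class variance of the
    split {levels <= t} vs {levels > t}; ties resolve to the smallest t.
    A histogram with a single occupied bin returns that bin.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("expected a 1-D histogram with at least two bins")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    occupied = np.flatnonzero(hist)
    if len(occupied) == 1:
        return int(occupied[0])
    levels = np.arange(hist.size)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    total, grand = w0[-1], m0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(w0 > 0, m0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (grand - m0) / np.maximum(w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(between))


def tissue_mask(slide: SlidePyramid) -> np.ndarray:
    """Boolean tissue map at thumbnail (~1x) resolution.

    Stained tissue absorbs light, so the darker Otsu class is tissue and
    the bright class is glass.  A constant (all-glass) thumbnail yields an
    empty mask rather than failing.
    """
    thumb = slide.thumbnail()
    gray = np.clip(np.round((thumb @ _LUMA) * 255), 0, 255).astype(np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256)
    if len(np.flatnonzero(hist)) == 1:
        return np.zeros(gray.shape, dtype=bool)
    t = otsu_threshold(hist)
    return gray <= t


# ---------------------------------------------------------------------------
# tiling


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping level-0 tiling: 0-based, row-major, half-open pixel
    intervals [r*size, (r+1)*size); partial edge tiles are dropped."""

    n_rows: int
    n_cols: int
    tile_size: int = TILE_SIZE

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols


def build_tile_grid(height: int, width: int, tile_size: int = TILE_SIZE) -> TileGrid:
    if height < tile_size or width < tile_size:
        raise ValueError(f"slide smaller than one {tile_size}px tile")
    return TileGrid(n_rows=height // tile_size, n_cols=width // tile_size, tile_size=tile_size)


# ---------------------------------------------------------------------------
# focus mask


@dataclass
class FocusMask:
    """Per-tile classification grid over a slide.

    Every cell is exactly one of background / in_focus / blurred;
    ``p_in_focus`` is NaN on background cells.
    """

    states: np.ndarray  # (n_rows, n_cols) of state strings
    p_in_focus: np.ndarray  # (n_rows, n_cols) float, NaN where background
    tile_size: int = TILE_SIZE
    provenance: dict = field(default_factory=dict)

    @property
    def grid(self) -> TileGrid:
        return TileGrid(*self.states.shape, tile_size=self.tile_size)

    @property
    def n_classified(self) -> int:
        return int((self.states != STATE_BACKGROUND).sum())

    @property
    def blurred_fraction(self) -> float:
        n = self.n_classified
        return float((self.states == STATE_BLURRED).sum() / n) if n else 0.0


def tile_tissue_fractions(slide: SlidePyramid, grid: TileGrid,
                          mask: np.ndarray | None = None) -> np.ndarray:
    """Approximate tissue coverage of each tile footprint, from the 1x
    tissue mask (area-resampled to the tile grid)."""
    if mask is None:
        mask = tissue_mask(slide)
    frac = resize(
        mask.astype(float), (grid.n_rows, grid.n_cols),
        order=1, anti_aliasing=True, mode="reflect",
    )
    return np.clip(frac, 0.0, 1.0)


def classify_slide(
    slide: SlidePyramid,
    model,
    tissue_rule_fraction: float = 0.5,
    batch_size: int = 256,
    slide_id: str = "",
) -> FocusMask:
    """Classify every tissue tile of a slide into in-focus / blurred.

    A tile is classified iff at least ``tissue_rule_fraction`` of its
    footprint maps to tissue in the 1x Otsu mask; all other tiles are
    background.  Tiles are streamed row-by-row in bounded batches.
    """
    if getattr(model, "preprocess_stats", None) is None:
        raise ValueError("model carries no PreprocessStats; train or load a full checkpoint")
    h, w = slide.dimensions
    grid = build_tile_grid(h, w)
    frac = tile_tissue_fractions(slide, grid)
    states = np.full((grid.n_rows, grid.n_cols), STATE_BACKGROUND, dtype=object)
    probs = np.full((grid.n_rows, grid.n_cols), np.nan)

    ts = grid.tile_size
    pending_tiles, pending_rc = [], []

    def _flush():
        if not pending_tiles:
            return
        batch = apply_stats(np.stack(pending_tiles), model.preprocess_stats)
        p = model.predict_proba(batch, batch_size=batch_size)
        for (r, c), pi in zip(pending_rc, p):
            probs[r, c] = pi
            states[r, c] = STATE_IN_FOCUS if pi > 0.5 else STATE_BLURRED
        pending_tiles.clear()
        pending_rc.clear()

    for r in range(grid.n_rows):
        strip = slide.read_region(r * ts, 0, ts, grid.n_cols * ts)
        for c in range(grid.n_cols):
            if frac[r, c] >= tissue_rule_fraction:
                pending_tiles.append(np.asarray(strip[:, c * ts:(c + 1) * ts], dtype=np.float32))
                pending_rc.append((r, c))
                if len(pending_tiles) >= batch_size:
                    _flush()
    _flush()
    return FocusMask(
        states=states.astype(str),
        p_in_focus=probs,
        tile_size=ts,
        provenance={"slide_id": slide_id, "threshold": 0.5,
                    "tissue_rule_fraction": tissue_rule_fraction},
    )


# ---------------------------------------------------------------------------
# rendering and export

_TINTS = {STATE_IN_FOCUS: np.array([0.0, 0.85, 0.0]),
          STATE_BLURRED: np.array([0.9, 0.0, 0.0])}


def render_overlay(thumbnail: np.ndarray, mask: FocusMask, alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend the focus mask over a slide thumbnail: green tiles are
    in focus, red tiles blurred, background untinted."""
    thumb = np.asarray(thumbnail, dtype=float)
    if thumb.ndim != 3 or thumb.shape[-1] != 3:
        raise ValueError("thumbnail must be (h, w, 3)")
    h, w = thumb.shape[:2]
    out = thumb.copy()
    n_rows, n_cols = mask.states.shape
    # map each thumbnail pixel to its tile cell
    rr = np.minimum((np.arange(h) * n_rows) // max(h, 1), n_rows - 1)
    cc = np.minimum((np.arange(w) * n_cols) // max(w, 1), n_cols - 1)
    cell = mask.states[np.ix_(rr, cc)]
    for state, tint in _TINTS.items():
        sel = cell == state
        out[sel] = (1 - alpha) * out[sel] + alpha * tint
    return np.clip(out, 0.0, 1.0)


def export_mask(mask: FocusMask, out_dir: str | Path) -> dict[str, Path]:
    """Write the focus mask as PNG (states upscaled to tile size), TSV
    (row, col, state, p_in_focus) and a summary JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # PNG: black background, green in-focus, red blurred, at tile_size scale
    color = np.zeros((*mask.states.shape, 3), dtype=np.uint8)
    color[mask.states == STATE_IN_FOCUS] = (0, 217, 0)
    color[mask.states == STATE_BLURRED] = (230, 0, 0)
    png_path = out_dir / "focus_mask.png"
    iio.imwrite(png_path, np.kron(color, np.ones((mask.tile_size, mask.tile_size, 1), dtype=np.uint8)))

    rows, cols = np.indices(mask.states.shape)
    tsv_path = out_dir / "focus_mask.tsv"
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "state": mask.states.ravel(),
            "p_in_focus": mask.p_in_focus.ravel(),
        }
    ).to_csv(tsv_path, sep="\t", index=False)

    summary_path = out_dir / "summary.json"
    summary = {
        "n_rows": int(mask.states.shape[0]),
        "n_cols": int(mask.states.shape[1]),
        "tile_size": mask.tile_size,
        "n_tissue_tiles": mask.n_classified,
        "n_blurred": int((mask.states == STATE_BLURRED).sum()),
        "blurred_fraction": mask.blurred_fraction,
        "provenance": mask.provenance,
    }
    summary_path.write_text(json.dumps(summary, indent=2))
    return {"png": png_path, "tsv": tsv_path, "summary": summary_path}


def load_mask(tsv_path: str | Path, tile_size: int = TILE_SIZE) -> FocusMask:
    """Rebuild a FocusMask from its exported TSV."""
    df = pd.read_csv(tsv_path, sep="\t")
    n_rows, n_cols = int(df["row"].max()) + 1, int(df["col"].max()) + 1
    states = np.full((n_rows, n_cols), STATE_BACKGROUND, dtype=object)
    probs = np.full((n_rows, n_cols), np.nan)
    states[df["row"], df["col"]] = df["state"]
    probs[df["row"], df["col"]] = df["p_in_focus"]
    return FocusMask(states=states.astype(str), p_in_focus=probs, tile_size=tile_size)
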