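"""Synthetic focal-offset acquisition protocol.

Emulates the data-curation strategy used to train slide-focus classifiers:
a region of interest is (virtually) scanned at a grid of focal-plane
offsets Omega (micrometres); defocus blur grows with |Omega|, and tiles are
labelled in-focus when Omega lies within [-0.5, 0.5] um.  The renderer
produces stained-tissue-like 64x64 RGB tiles (H&E or IHC colour schemes)
and whole synthetic slides containing tissue and blank-glass background,
with ground truth for both tissue location and per-tile blur state.

Everything here is a pure function of its seed: the same seed yields a
bit-identical tile, dataset or slide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

TILE_SIZE = 64
#: Focal-plane offsets (um) of the nine-plane acquisition protocol.
OFFSET_GRID: tuple[float, ...] = (-2.5, -2.0, -1.5, -0.5, 0.0, 0.5, 1.5, 2.0, 2.5)
#: Offsets labelled in-focus: the closed interval [-0.5, 0.5] um.
IN_FOCUS_RANGE: tuple[float, float] = (-0.5, 0.5)
PIXEL_SIZE_UM = 0.2461  # 40x scan

LABEL_IN_FOCUS = "in_focus"
LABEL_BLURRED = "blurred"

DEFAULT_SIGMA0 = 0.4  # px, residual blur of a perfectly focused scan
DEFAULT_SLOPE = 1.0  # px per um of focal offset
DEFAULT_NOISE_SD = 0.01
DEFAULT_NUCLEUS_DENSITY = 7.0


@dataclass(frozen=True)
class StainProfile:
    """Colour scheme of a stain: nuclei, cytoplasm, glass, and the fraction
    of nuclei carrying brown DAB chromogen (zero for plain H&E)."""

    name: str
    nucleus_color: tuple[float, float, float]
    cytoplasm_color: tuple[float, float, float]
    background_color: tuple[float, float, float] = (0.96, 0.95, 0.96)
    chromogen_fraction: float = 0.0

    def __post_init__(self) -> None:
        for c in (*self.nucleus_color, *self.cytoplasm_color, *self.background_color):
            if not 0.0 <= c <= 1.0:
                raise ValueError("colour components must lie in [0, 1]")
        if not 0.0 <= self.chromogen_fraction <= 1.0:
            raise ValueError("chromogen_fraction must lie in [0, 1]")


CHROMOGEN_COLOR = (0.48, 0.31, 0.14)  # DAB brown

STAINS: dict[str, StainProfile] = {
    "HE": StainProfile("HE", (0.38, 0.24, 0.54), (0.89, 0.70, 0.80)),
    "Ki67": StainProfile("Ki67", (0.32, 0.36, 0.62), (0.91, 0.87, 0.85), chromogen_fraction=0.40),
    "CD21": StainProfile("CD21", (0.33, 0.37, 0.61), (0.90, 0.86, 0.84), chromogen_fraction=0.30),
    "CD10": StainProfile("CD10", (0.31, 0.35, 0.60), (0.92, 0.88, 0.86), chromogen_fraction=0.35),
}


@dataclass(frozen=True)
class SyntheticTileSpec:
    """Everything needed to render one sharp tile deterministically."""

    seed: int
    stain: StainProfile = STAINS["HE"]
    offset: float = 0.0
    nucleus_density: float = DEFAULT_NUCLEUS_DENSITY
    noise_sd: float = DEFAULT_NOISE_SD
    depth_variation: bool = False

    def __post_init__(self) -> None:
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LabeledTile:
    """A 64x64 RGB tile with its focal offset, label and provenance."""

    pixels: np.ndarray  # (64, 64, 3) float in [0, 1]
    offset: float
    label: str
    sigma_px: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.shape != (TILE_SIZE, TILE_SIZE, 3):
            raise ValueError(f"tile must be {TILE_SIZE}x{TILE_SIZE}x3, got {self.pixels.shape}")
        if self.sigma_px < 0:
            raise ValueError("sigma_px must be >= 0")
        if self.label != label_from_offset(self.offset):
            raise ValueError("label inconsistent with offset under the in-focus rule")


@dataclass
class SyntheticSlide:
    """A synthetic whole slide: pixels, per-pixel tissue truth and the
    per-64px-tile blur truth grid."""

    pixels: np.ndarray  # (H, W, 3) float32
    tissue_truth: np.ndarray  # (H, W) bool
    blur_truth: np.ndarray  # (H//64, W//64) of {in_focus, blurred}
    offset_field: np.ndarray  # (H//64, W//64) float, Omega per tile
    pixel_size_um: float = PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        h, w = self.pixels.shape[:2]
        expected = (h // TILE_SIZE, w // TILE_SIZE)
        if self.blur_truth.shape != expected:
            raise ValueError(f"blur_truth grid must be {expected}")
        if self.tissue_truth.shape != (h, w):
            raise ValueError("tissue_truth must align with pixels")


# ---------------------------------------------------------------------------
# offset -> blur and offset -> label rules


def offset_to_sigma(
    omega: float, sigma0: float = DEFAULT_SIGMA0, slope: float = DEFAULT_SLOPE
):
    """Gaussian PSF width (px) at focal offset ``omega`` (um).

    Linear in |Omega|: ``sigma0 + slope * |omega|`` — symmetric in the sign
    of the offset and strictly increasing in its magnitude.
    """
    if sigma0 < 0:
        raise ValueError("sigma0 must be >= 0")
    if slope <= 0:
        raise ValueError("slope must be > 0")
    return sigma0 + slope * np.abs(omega)


def label_from_offset(omega: float) -> str:
    """In-focus iff the offset lies in the closed interval [-0.5, 0.5] um."""
    lo, hi = IN_FOCUS_RANGE
    return LABEL_IN_FOCUS if lo <= omega <= hi else LABEL_BLURRED


# ---------------------------------------------------------------------------
# tile rendering


def _low_freq_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smooth zero-mean unit-ish field used for cytoplasm/tissue texture."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def _draw_nucleus(img, mask, cy, cx, a, b, theta, color) -> None:
    """Composite one anti-aliased ellipse onto ``img`` in place."""
    r = int(np.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - r), min(img.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(img.shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    q = np.sqrt(u * u + v * v)
    cov = np.clip((1.0 - q) / 0.18 + 0.5, 0.0, 1.0)  # ~1 px soft edge
    shade = 1.0 - 0.25 * q * q  # darker rim -> chromatin-ish gradient
    patch = img[y0:y1, x0:x1]
    patch[:] = (1 - cov[..., None]) * patch + cov[..., None] * (
        np.asarray(color) * shade[..., None]
    )
    mask[y0:y1, x0:x1] |= cov > 0.5


def render_sharp_tile(spec: SyntheticTileSpec, return_mask: bool = False):
    """Render a sharp (pre-defocus) 64x64 stained-tissue tile.

    Deterministic in ``spec.seed``.  The random draws that fix geometry are
    independent of the stain, so two specs differing only in stain give
    tiles with identical geometry and different colour statistics.

    Returns the tile, and with ``return_mask=True`` also the boolean
    nucleus mask (used by :func:`apply_defocus` for depth variation).
    """
    rng = np.random.default_rng(int(spec.seed))
    n = TILE_SIZE
    stain = spec.stain

    # Cytoplasm density field and fine texture (stain-independent draws).
    coarse = _low_freq_field(rng, (n, n), 6.0)
    fine = _low_freq_field(rng, (n, n), 1.2)
    w = np.clip(0.65 + 0.35 * coarse, 0.0, 1.0)[..., None]  # tissue coverage
    bg = np.asarray(stain.background_color)
    cy = np.asarray(stain.cytoplasm_color)
    img = (1 - w) * bg + w * cy
    img += 0.035 * fine[..., None]

    mask = np.zeros((n, n), dtype=bool)
    if spec.nucleus_density > 0:
        count = max(1, int(rng.poisson(spec.nucleus_density)))
        for _ in range(count):
            ccy, ccx = rng.uniform(2, n - 2, size=2)
            a = rng.uniform(3.0, 8.0)
            b = a * rng.uniform(0.55, 1.0)
            theta = rng.uniform(0, np.pi)
            jitter = rng.uniform(-0.05, 0.05, size=3)
            u_chrom = rng.uniform()  # always drawn: keeps streams aligned across stains
            color = (
                CHROMOGEN_COLOR
                if u_chrom < stain.chromogen_fraction
                else stain.nucleus_color
            )
            _draw_nucleus(img, mask, ccy, ccx, a, b, theta, np.asarray(color) + jitter)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return (img, mask) if return_mask else img


def apply_defocus(
    pixels: np.ndarray,
    sigma_px: float,
    depth_variation: bool = False,
    sharp_fraction: float = 0.15,
    sharp_regions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Convolve with an isotropic Gaussian PSF of width ``sigma_px``.

    Reflect boundary, kernel truncated at 4 sigma; a normalized kernel, so
    total intensity is preserved up to boundary effects.  With
    ``depth_variation`` and a nucleus mask in ``sharp_regions``, a
    ``sharp_fraction`` of the connected nucleus regions is composited back
    unblurred — emulating nuclei that sit at a different depth and stay
    sharp on one side of the focal sweep.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    pixels = np.asarray(pixels, dtype=np.float32)
    if sigma_px == 0:
        return pixels.copy()
    out = ndimage.gaussian_filter(
        pixels, sigma=(sigma_px, sigma_px, 0), mode="reflect", truncate=4.0
    )
    if depth_variation and sharp_regions is not None and sharp_fraction > 0:
        labels, n_regions = ndimage.label(sharp_regions)
        if n_regions > 0:
            rng = rng or np.random.default_rng(0)
            n_keep = max(1, int(round(sharp_fraction * n_regions)))
            keep = rng.choice(np.arange(1, n_regions + 1), size=n_keep, replace=False)
            sel = np.isin(labels, keep).astype(np.float32)
            sel = ndimage.gaussian_filter(sel, 1.0, mode="reflect")[..., None]
            out = sel * pixels + (1 - sel) * out
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def add_sensor_noise(
    pixels: np.ndarray, sd: float = DEFAULT_NOISE_SD, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Additive Gaussian sensor noise, clipped back to [0, 1]."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return np.asarray(pixels, dtype=np.float32).copy()
    rng = rng or np.random.default_rng(0)
    noisy = pixels + rng.normal(0.0, sd, size=pixels.shape)
    return np.clip(noisy, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# dataset generation


def _mix_seeds(*parts: np.ndarray | int) -> np.ndarray:
    """Deterministic 31-bit stream seeds from integer coordinates
    (splitmix64-style avalanche, vectorized)."""
    acc = np.uint64(0x9E3779B97F4A7C15)
    z = np.zeros_like(np.broadcast_arrays(*[np.asarray(p, dtype=np.uint64) for p in parts])[0])
    with np.errstate(over="ignore"):
        for p in parts:
            z = (z ^ np.asarray(p, dtype=np.uint64)) * np.uint64(0xBF58476D1CE4E5B9) + acc
        z ^= z >> np.uint64(31)
        z *= np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(29)
    return (z % np.uint64(2**31)).astype(np.int64)


def generate_manifest(
    n_slides: int,
    offsets=OFFSET_GRID,
    tiles_per_roi: int = 2500,
    stains: tuple[str, ...] = ("HE", "Ki67", "CD21", "CD10"),
    seed: int = 0,
    sigma0: float = DEFAULT_SIGMA0,
    slope: float = DEFAULT_SLOPE,
) -> pd.DataFrame:
    """Plan a full acquisition without rendering pixels.

    One row per (slide, ROI position, offset): ``n_slides * len(offsets) *
    tiles_per_roi`` rows.  The per-position ``tile_seed`` is shared across
    offsets, so the offset versions of a position depict the same content
    at different blur; ``noise_seed`` differs per offset.
    """
    offsets = list(offsets)
    if not offsets:
        raise ValueError("offsets list must not be empty")
    if n_slides < 1 or tiles_per_roi < 1:
        raise ValueError("n_slides and tiles_per_roi must be >= 1")

    slide = np.repeat(np.arange(n_slides), len(offsets) * tiles_per_roi)
    roi = np.tile(np.repeat(np.arange(tiles_per_roi), len(offsets)), n_slides)
    omega = np.tile(np.asarray(offsets, dtype=float), n_slides * tiles_per_roi)
    tile_seed = _mix_seeds(seed, slide * 1_000_003, roi)
    noise_seed = _mix_seeds(seed + 1, slide * 1_000_003, roi * 17 + np.round(omega * 10).astype(int) + 64)
    sigma = offset_to_sigma(omega, sigma0, slope)
    labels = np.where(
        (omega >= IN_FOCUS_RANGE[0]) & (omega <= IN_FOCUS_RANGE[1]),
        LABEL_IN_FOCUS,
        LABEL_BLURRED,
    )
    slide_names = np.array([f"slide{s:02d}" for s in range(n_slides)])
    return pd.DataFrame(
        {
            "tile_id": np.arange(slide.size),
            "source_id": slide_names[slide],
            "stain": np.asarray(stains, dtype=object)[slide % len(stains)],
            "roi_index": roi,
            "offset_um": omega,
            "label": labels,
            "sigma_px": sigma,
            "tile_seed": tile_seed,
            "noise_seed": noise_seed,
        }
    )


def render_manifest_tiles(
    manifest: pd.DataFrame,
    nucleus_density: float = DEFAULT_NUCLEUS_DENSITY,
    noise_sd: float = DEFAULT_NOISE_SD,
    depth_variation: bool = False,
    sharp_fraction: float = 0.15,
) -> np.ndarray:
    """Render pixels for every manifest row -> (n, 64, 64, 3) float32.

    Sharp tiles are cached per tile_seed so the offset-paired rows share
    geometry; with ``depth_variation`` a fraction of nuclei is composited
    back sharp at negative offsets only.
    """
    out = np.empty((len(manifest), TILE_SIZE, TILE_SIZE, 3), dtype=np.float32)
    cache: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
    for k, row in enumerate(manifest.itertuples(index=False)):
        key = (int(row.tile_seed), str(row.stain))
        if key not in cache:
            spec = SyntheticTileSpec(
                seed=int(row.tile_seed),
                stain=STAINS[str(row.stain)],
                nucleus_density=nucleus_density,
            )
            cache[key] = render_sharp_tile(spec, return_mask=True)
        sharp, mask = cache[key]
        dv = depth_variation and row.offset_um < 0
        blurred = apply_defocus(
            sharp,
            float(row.sigma_px),
            depth_variation=dv,
            sharp_fraction=sharp_fraction,
            sharp_regions=mask,
            rng=np.random.default_rng(int(row.noise_seed) + 1),
        )
        out[k] = add_sensor_noise(
            blurred, noise_sd, rng=np.random.default_rng(int(row.noise_seed))
        )
    return out


def generate_dataset(
    n_slides: int,
    offsets=OFFSET_GRID,
    tiles_per_roi: int = 2500,
    stains: tuple[str, ...] = ("HE", "Ki67", "CD21", "CD10"),
    seed: int = 0,
    nucleus_density: float = DEFAULT_NUCLEUS_DENSITY,
    noise_sd: float = DEFAULT_NOISE_SD,
    depth_variation: bool = False,
    sigma0: float = DEFAULT_SIGMA0,
    slope: float = DEFAULT_SLOPE,
):
    """Generate a labelled tile collection: (pixels, manifest).

    ``pixels`` is (n, 64, 64, 3) float32 in [0, 1]; the manifest records
    source_id, offset_um, label and sigma_px per tile.  Fully deterministic
    in ``seed``.
    """
    manifest = generate_manifest(
        n_slides, offsets, tiles_per_roi, stains, seed, sigma0, slope
    )
    pixels = render_manifest_tiles(
        manifest, nucleus_density, noise_sd, depth_variation
    )
    return pixels, manifest


# ---------------------------------------------------------------------------
# whole synthetic slides


def constant_blur_field(grid_shape: tuple[int, int], omega: float = 0.0) -> np.ndarray:
    """Uniform focal-offset field over the tile grid."""
    return np.full(grid_shape, float(omega))


def quadrant_blur_field(
    grid_shape: tuple[int, int], omega_blur: float = 2.0, quadrant: int = 3
) -> np.ndarray:
    """Offset field that blurs one quadrant (0=TL, 1=TR, 2=BL, 3=BR)."""
    field = np.zeros(grid_shape)
    h2, w2 = grid_shape[0] // 2, grid_shape[1] // 2
    sl = {
        0: (slice(None, h2), slice(None, w2)),
        1: (slice(None, h2), slice(w2, None)),
        2: (slice(h2, None), slice(None, w2)),
        3: (slice(h2, None), slice(w2, None)),
    }[quadrant]
    field[sl] = omega_blur
    return field


def generate_slide(
    width: int,
    height: int,
    tissue_fraction: float = 0.5,
    blur_field: np.ndarray | None = None,
    seed: int = 0,
    stain: str = "HE",
    nucleus_density: float = DEFAULT_NUCLEUS_DENSITY,
    noise_sd: float = DEFAULT_NOISE_SD,
    sigma0: float = DEFAULT_SIGMA0,
    slope: float = DEFAULT_SLOPE,
) -> SyntheticSlide:
    """Render a synthetic slide with tissue, glass background, and a
    spatially coherent defocus field.

    ``blur_field`` gives the focal offset Omega (um) per 64-px tile; if
    None the slide is sharp everywhere.  The ground-truth ``blur_truth``
    applies the in-focus labelling rule to that field.
    """
    if width < 256 or height < 256:
        raise ValueError("slide must be at least 256x256 px")
    if not 0.0 < tissue_fraction < 1.0:
        raise ValueError("tissue_fraction must lie in (0, 1)")
    grid_shape = (height // TILE_SIZE, width // TILE_SIZE)
    if blur_field is None:
        blur_field = constant_blur_field(grid_shape)
    blur_field = np.asarray(blur_field, dtype=float)
    if blur_field.shape != grid_shape:
        raise ValueError(f"blur_field must have tile-grid shape {grid_shape}")

    rng = np.random.default_rng(int(seed))
    profile = STAINS[stain]

    # Tissue support: smooth field thresholded at the requested quantile.
    support = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), sigma=min(height, width) / 8, mode="reflect"
    )
    thresh = np.quantile(support, 1.0 - tissue_fraction)
    tissue = support > thresh

    # Glass background with faint texture; tissue gets cytoplasm colouring.
    img = np.empty((height, width, 3), dtype=np.float32)
    glass = np.asarray(profile.background_color, dtype=np.float32)
    img[:] = glass + 0.012 * rng.standard_normal((height, width, 1)).astype(np.float32)
    coarse = _low_freq_field(rng, (height, width), 12.0)
    fine = _low_freq_field(rng, (height, width), 1.2)
    w = np.clip(0.65 + 0.35 * coarse, 0, 1)[..., None]
    tissue_img = (1 - w) * glass + w * np.asarray(profile.cytoplasm_color)
    tissue_img += 0.035 * fine[..., None]
    soft = ndimage.gaussian_filter(tissue.astype(np.float32), 3.0)[..., None]
    img = (1 - soft) * img + soft * tissue_img.astype(np.float32)

    # Nuclei scattered over the tissue only.
    n_nuclei = int(nucleus_density * tissue.sum() / TILE_SIZE**2)
    mask = np.zeros((height, width), dtype=bool)
    tissue_rows, tissue_cols = np.nonzero(tissue)
    if len(tissue_rows) and n_nuclei > 0:
        pick = rng.integers(0, len(tissue_rows), size=n_nuclei)
        for cyx, cxx in zip(tissue_rows[pick], tissue_cols[pick]):
            a = rng.uniform(3.0, 8.0)
            b = a * rng.uniform(0.55, 1.0)
            theta = rng.uniform(0, np.pi)
            jitter = rng.uniform(-0.05, 0.05, size=3)
            u_chrom = rng.uniform()
            color = (
                CHROMOGEN_COLOR
                if u_chrom < profile.chromogen_fraction
                else profile.nucleus_color
            )
            _draw_nucleus(img, mask, cyx, cxx, a, b, theta, np.asarray(color) + jitter)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    # Patchwise defocus: blur once per distinct sigma, blend with smooth
    # per-pixel weights upsampled from the tile-level field.
    sigma_field = offset_to_sigma(np.abs(blur_field), sigma0, slope)
    sigma_field = np.where(blur_field == 0.0, sigma0, sigma_field)
    out = np.zeros_like(img)
    weight_total = np.zeros((height, width, 1), dtype=np.float32)
    for s in np.unique(sigma_field):
        sel = (sigma_field == s).astype(np.float32)
        sel_px = np.kron(sel, np.ones((TILE_SIZE, TILE_SIZE), dtype=np.float32))
        full = np.ones((height, width), dtype=np.float32)
        full[: sel_px.shape[0], : sel_px.shape[1]] = sel_px
        full[sel_px.shape[0]:, :] = full[sel_px.shape[0] - 1: sel_px.shape[0], :]
        full[:, sel_px.shape[1]:] = full[:, sel_px.shape[1] - 1: sel_px.shape[1]]
        wgt = ndimage.gaussian_filter(full, 8.0, mode="reflect")[..., None]
        out += wgt * apply_defocus(img, float(s))
        weight_total += wgt
    img = out / np.maximum(weight_total, 1e-8)
    img = add_sensor_noise(img, noise_sd, rng=rng)

    blur_truth = np.where(
        (blur_field >= IN_FOCUS_RANGE[0]) & (blur_field <= IN_FOCUS_RANGE[1]),
        LABEL_IN_FOCUS,
        LABEL_BLURRED,
    )
    return SyntheticSlide(
        pixels=img,
        tissue_truth=tissue,
        blur_truth=blur_truth,
        offset_field=blur_field,
    )
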