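"""Synthetic calibration-card scene renderer with ground-truth metadata.

Every downstream stage (detection, sampling, calibration, QC, inversion) is
exercised on scenes rendered here: a flat calibration card photographed
fronto-parallel at a nominal 25 cm, with a central hole exposing simulated
newborn skin.  The card carries 24 color patches, 8 gray patches, a 6-tone
gray strip, 4 corner fiducial markers (card versions v2/v3), and a stripe
barcode encoding the card id.

Nuisances mimic the failure modes a quality-control stage must catch:
illuminant tint, a linear shadow gradient, rectangular occluders, a soft
dark lens blob, sensor noise, distance error, and damaged (recolored)
patches.  All randomness flows from the scene seed; identical specs render
identical rasters.

Geometry: card frame in mm, origin at the card top-left, x across the
width, y down.  Pixel frame is (row, col), 0-based, origin image top-left.
The mm-to-pixel map is a similarity transform with pinhole scaling
``scale = FOCAL_PX / distance_mm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .forward_model import (
    BilicamError,
    CameraModel,
    ChromophoreState,
    Illuminant,
    SpectralCurve,
    DEFAULT_GRID,
    default_camera,
    diffuse_reflectance,
    flat_illuminant,
    render_rgb,
)

# pinhole focal constant, px: marker pitch in px = FOCAL_PX * pitch_mm / distance_mm
FOCAL_PX = 1250.0
#: canvas size (rows, cols); card rendered centered
CANVAS_SHAPE = (520, 640)
#: flat-spectrum flash boost blended into the ambient SPD
FLASH_WEIGHT = 0.7
#: lab measurement noise added to the simulated reference TSB, umol/L
TSB_NOISE_SD = 5.0

BARCODE_BITS = 12


# ---------------------------------------------------------------------------
# sRGB transfer (applied only at the raster boundary; all math is linear)
# ---------------------------------------------------------------------------

def srgb_encode(linear: np.ndarray) -> np.ndarray:
    linear = np.clip(linear, 0.0, 1.0)
    return np.where(linear <= 0.0031308, 12.92 * linear,
                    1.055 * np.power(linear, 1 / 2.4) - 0.055)


def srgb_decode(encoded: np.ndarray) -> np.ndarray:
    encoded = np.clip(encoded, 0.0, 1.0)
    return np.where(encoded <= 0.04045, encoded / 12.92,
                    np.power((encoded + 0.055) / 1.055, 2.4))


# ---------------------------------------------------------------------------
# Card layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    id: str
    role: str  # color | gray | graystrip
    reflectance: SpectralCurve
    cx_mm: float
    cy_mm: float
    w_mm: float
    h_mm: float


@dataclass(frozen=True)
class BarcodeSpec:
    y_mm: float
    x0_mm: float  # center of first cell
    cell_w_mm: float
    cell_h_mm: float
    n_cells: int  # dark sentinel + BARCODE_BITS data + light sentinel


@dataclass(frozen=True)
class CardLayout:
    version: str
    width_mm: float
    height_mm: float
    patches: tuple[Patch, ...]
    markers_mm: tuple[tuple[float, float], ...]
    marker_size_mm: float
    barcode: BarcodeSpec | None
    hole_center_mm: tuple[float, float]
    hole_diameter_mm: float
    base_reflectance: SpectralCurve

    def __post_init__(self) -> None:
        if self.version not in ("v1", "v2", "v3"):
            raise BilicamError(f"unknown card version {self.version!r}")
        counts = {r: sum(1 for p in self.patches if p.role == r)
                  for r in ("color", "gray", "graystrip")}
        if self.version == "v1" and (counts["color"] != 24 or counts["gray"] != 8
                                     or counts["graystrip"] != 6):
            raise BilicamError("v1 card requires 24 color + 8 gray patches and a 6-tone strip")
        if self.version in ("v2", "v3") and len(self.markers_mm) != 4:
            raise BilicamError("v2/v3 cards require exactly 4 position markers")
        hx, hy = self.hole_center_mm
        r = self.hole_diameter_mm / 2.0
        for p in self.patches:
            # closest point of the patch rectangle to the hole center
            dx = max(abs(hx - p.cx_mm) - p.w_mm / 2.0, 0.0)
            dy = max(abs(hy - p.cy_mm) - p.h_mm / 2.0, 0.0)
            if dx * dx + dy * dy < r * r:
                raise BilicamError(f"hole intersects patch {p.id}")
            if not (0 <= p.cx_mm - p.w_mm / 2 and p.cx_mm + p.w_mm / 2 <= self.width_mm
                    and 0 <= p.cy_mm - p.h_mm / 2 and p.cy_mm + p.h_mm / 2 <= self.height_mm):
                raise BilicamError(f"patch {p.id} outside card bounds")

    @property
    def gray_patches(self) -> tuple[Patch, ...]:
        return tuple(p for p in self.patches if p.role in ("gray", "graystrip"))

    def patch_by_id(self, pid: str) -> Patch:
        for p in self.patches:
            if p.id == pid:
                return p
        raise BilicamError(f"no patch {pid!r} in layout")


def _palette_spectra(n: int, seed: int) -> list[SpectralCurve]:
    """Fixed seeded palette of smooth reflectance spectra spanning the gamut."""
    rng = np.random.default_rng(seed)
    lam = DEFAULT_GRID
    t = (lam - 400.0) / 300.0
    out = []
    for _ in range(n):
        a1, a2 = rng.uniform(0.15, 0.38), rng.uniform(0.0, 0.22)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        base = rng.uniform(0.35, 0.6)
        vals = base + a1 * np.sin(2 * np.pi * t * rng.uniform(0.5, 1.2) + p1) \
                    + a2 * np.sin(4 * np.pi * t * rng.uniform(0.8, 1.2) + p2)
        out.append(SpectralCurve(lam, np.clip(vals, 0.15, 0.92)))
    return out


#: chromophore states painted on the skin-tone patches (side columns): the
#: card carries colors from the same spectral family as the measured skin,
#: which anchors the calibration fit for skin colors (metameric residual
#: roughly halves compared with an all-abstract palette)
SKIN_PATCH_STATES = (
    (50.0, 0.03, 0.015), (150.0, 0.03, 0.03), (250.0, 0.04, 0.02),
    (350.0, 0.05, 0.04), (80.0, 0.09, 0.02), (180.0, 0.11, 0.035),
    (280.0, 0.12, 0.015), (120.0, 0.07, 0.045),
)


def default_layout(version: str = "v3", palette_seed: int = 20240117) -> CardLayout:
    """The package's standard 100 x 76 mm card.

    All versions share the patch complement (16 abstract + 8 skin-tone color
    patches, 8 grays, 6-tone strip, central hole); v2/v3 add the 4 corner
    markers and the barcode band.
    """
    colors = _palette_spectra(16, palette_seed)
    patches: list[Patch] = []
    k = 0
    # top and bottom rows: 8 abstract color patches each
    for cy in (16.0, 60.0):
        for i in range(8):
            patches.append(Patch(f"C{k + 1:02d}", "color", colors[k],
                                 16.0 + 10.0 * i, cy, 8.0, 8.0))
            k += 1
    # outer side columns: 8 skin-tone patches (closest colors to the hole)
    si = 0
    for cx in (16.0, 84.0):
        for cy in (24.0, 33.0, 42.0, 51.0):
            b, m, f = SKIN_PATCH_STATES[si]
            refl = diffuse_reflectance(ChromophoreState(b, m, f, 0.7))
            patches.append(Patch(f"C{k + 1:02d}", "color", refl, cx, cy, 8.0, 8.0))
            k += 1
            si += 1
    # inner side columns: 8 gray patches
    gray_levels = np.linspace(0.2, 0.85, 8)
    g = 0
    for cx in (26.0, 74.0):
        for cy in (24.0, 33.0, 42.0, 51.0):
            patches.append(Patch(f"G{g + 1:02d}", "gray",
                                 SpectralCurve.constant(float(gray_levels[g])),
                                 cx, cy, 8.0, 8.0))
            g += 1
    # 6-tone gray strip below the hole
    strip_levels = np.linspace(0.18, 0.88, 6)
    for i in range(6):
        patches.append(Patch(f"S{i + 1}", "graystrip",
                             SpectralCurve.constant(float(strip_levels[i])),
                             35.0 + 6.0 * i, 50.0, 6.0, 6.0))
    markers = ((7.0, 7.0), (93.0, 7.0), (93.0, 69.0), (7.0, 69.0)) \
        if version in ("v2", "v3") else ()
    barcode = BarcodeSpec(y_mm=69.0, x0_mm=22.0, cell_w_mm=4.0, cell_h_mm=5.0,
                          n_cells=BARCODE_BITS + 2) if version in ("v2", "v3") else None
    return CardLayout(
        version=version, width_mm=100.0, height_mm=76.0,
        patches=tuple(patches), markers_mm=markers, marker_size_mm=6.0,
        barcode=barcode, hole_center_mm=(50.0, 36.0), hole_diameter_mm=14.0,
        base_reflectance=SpectralCurve.constant(0.9),
    )


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShadowSpec:
    direction_deg: float = 0.0  # gradient direction in the image plane
    depth: float = 0.3          # relative darkening across the card extent

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth < 1.0:
            raise BilicamError("shadow depth must be in [0, 1)")


@dataclass(frozen=True)
class OcclusionSpec:
    """Rectangular occluder, card-mm frame, painted with a constant linear RGB."""
    x_mm: float
    y_mm: float
    w_mm: float
    h_mm: float
    color: tuple[float, float, float] = (0.22, 0.26, 0.45)


@dataclass(frozen=True)
class LensBlobSpec:
    """Soft Gaussian darkening, fractional image coordinates (col, row).

    Default sits over the lower-left gray column, compact enough that the
    gain field's planar component stays small (it must read as localized
    darkening, not as a shadow gradient)."""
    cx_frac: float = 0.3125
    cy_frac: float = 0.625
    radius_frac: float = 0.047  # Gaussian sigma as a fraction of image width
    depth: float = 0.5


@dataclass(frozen=True)
class SceneSpec:
    layout: CardLayout
    skin: ChromophoreState
    illuminant: Illuminant
    camera: CameraModel
    distance_cm: float = 25.0
    rotation_deg: float = 0.0
    noise_sd: float = 0.005
    shadow: ShadowSpec | None = None
    occlusion: OcclusionSpec | None = None
    lens_blob: LensBlobSpec | None = None
    damaged_patches: tuple[tuple[str, tuple], ...] = ()
    flash: bool = False
    card_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise BilicamError("distance_cm must be > 0")
        if self.noise_sd < 0:
            raise BilicamError("noise_sd must be >= 0")
        if not 0 <= self.card_id < 2 ** BARCODE_BITS:
            raise BilicamError(f"card_id must fit in {BARCODE_BITS} bits")


@dataclass
class SceneImage:
    raster: np.ndarray  # uint8, (H, W, 3), sRGB-encoded
    truth: SceneSpec
    scale_px_per_mm: float
    marker_px: np.ndarray | None  # (4, 2) float (row, col), None for v1

    def __post_init__(self) -> None:
        if self.scale_px_per_mm <= 0:
            raise BilicamError("scale must be positive")
        if self.marker_px is not None:
            h, w = self.raster.shape[:2]
            if (self.marker_px < 0).any() or (self.marker_px[:, 0] >= h).any() \
                    or (self.marker_px[:, 1] >= w).any():
                raise BilicamError("truth marker coordinates outside the raster")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _scene_illuminant(spec: SceneSpec) -> Illuminant:
    if not spec.flash:
        return spec.illuminant
    spd = spec.illuminant.spd
    boost = FLASH_WEIGHT * float(spd.values.mean())
    blended = SpectralCurve(spd.wavelengths_nm, spd.values + boost)
    return Illuminant(spec.illuminant.name + "+flash", blended).normalized(spec.camera)


def _mm_to_px(spec: SceneSpec, xy_mm: np.ndarray) -> np.ndarray:
    """Card-mm (x, y) -> pixel (row, col) under the scene's similarity transform."""
    scale = FOCAL_PX / (spec.distance_cm * 10.0)
    th = np.deg2rad(spec.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    cx0, cy0 = spec.layout.width_mm / 2.0, spec.layout.height_mm / 2.0
    x = np.asarray(xy_mm, dtype=float)[..., 0] - cx0
    y = np.asarray(xy_mm, dtype=float)[..., 1] - cy0
    col = CANVAS_SHAPE[1] / 2.0 + scale * (c * x - s * y)
    row = CANVAS_SHAPE[0] / 2.0 + scale * (s * x + c * y)
    return np.stack([row, col], axis=-1)


def render_scene(spec: SceneSpec) -> SceneImage:
    """Render the card scene to an sRGB raster with ground truth attached.

    Painting happens in linear RGB; corruptions apply in the order
    shadow -> occlusion -> lens blob -> noise; sRGB encoding and 8-bit
    quantization come last.
    """
    layout = spec.layout
    H, W = CANVAS_SHAPE
    scale = FOCAL_PX / (spec.distance_cm * 10.0)
    illum = _scene_illuminant(spec)
    cam = spec.camera

    def rgb_of(refl: SpectralCurve) -> np.ndarray:
        return render_rgb(refl, illum, cam)

    base_rgb = rgb_of(layout.base_reflectance)
    background = rgb_of(SpectralCurve.constant(0.32))
    black = rgb_of(SpectralCurve.constant(0.02))
    white = rgb_of(SpectralCurve.constant(0.95))
    bar_dark = rgb_of(SpectralCurve.constant(0.05))
    skin_rgb = render_rgb(diffuse_reflectance(spec.skin), illum, cam)

    damaged = dict(spec.damaged_patches)

    # inverse map: pixel grid -> card mm
    rows, cols = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                             indexing="ij")
    th = np.deg2rad(spec.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    u = (cols - W / 2.0) / scale
    v = (rows - H / 2.0) / scale
    X = c * u + s * v + layout.width_mm / 2.0
    Y = -s * u + c * v + layout.height_mm / 2.0

    img = np.empty((H, W, 3))
    img[:] = background
    card_mask = (X >= 0) & (X < layout.width_mm) & (Y >= 0) & (Y < layout.height_mm)
    img[card_mask] = base_rgb

    def _bbox(cx, cy, w, h):
        corners = np.array([[cx - w / 2, cy - h / 2], [cx + w / 2, cy - h / 2],
                            [cx + w / 2, cy + h / 2], [cx - w / 2, cy + h / 2]])
        px = _mm_to_px(spec, corners)
        r0 = max(int(np.floor(px[:, 0].min())) - 1, 0)
        r1 = min(int(np.ceil(px[:, 0].max())) + 2, H)
        c0 = max(int(np.floor(px[:, 1].min())) - 1, 0)
        c1 = min(int(np.ceil(px[:, 1].max())) + 2, W)
        return slice(r0, r1), slice(c0, c1)

    def fill_rect(cx, cy, w, h, color):
        rs, cs = _bbox(cx, cy, w, h)
        m = (np.abs(X[rs, cs] - cx) < w / 2.0) & (np.abs(Y[rs, cs] - cy) < h / 2.0)
        img[rs, cs][m] = color

    for p in layout.patches:
        color = rgb_of(p.reflectance)
        if p.id in damaged:
            kind, arg = damaged[p.id]
            if kind == "recolor":
                color = np.asarray(arg, dtype=float)
            elif kind == "scale":
                color = np.clip(color * float(arg), 0.0, 1.0)
            else:
                raise BilicamError(f"unknown patch perturbation {kind!r}")
        fill_rect(p.cx_mm, p.cy_mm, p.w_mm, p.h_mm, color)

    hx, hy = layout.hole_center_mm
    hole_mask = (X - hx) ** 2 + (Y - hy) ** 2 < (layout.hole_diameter_mm / 2.0) ** 2
    img[hole_mask] = skin_rgb

    # fiducials: white surround, black square, white center dot
    for mx, my in layout.markers_mm:
        msz = layout.marker_size_mm
        fill_rect(mx, my, msz + 4.0, msz + 4.0, white)
        fill_rect(mx, my, msz, msz, black)
        dot = (X - mx) ** 2 + (Y - my) ** 2 < 1.2 ** 2
        img[dot] = white

    if layout.barcode is not None:
        bc = layout.barcode
        bits = [1] + [(spec.card_id >> (BARCODE_BITS - 1 - i)) & 1
                      for i in range(BARCODE_BITS)] + [0]
        for i, bit in enumerate(bits):
            cx = bc.x0_mm + i * bc.cell_w_mm
            fill_rect(cx, bc.y_mm, bc.cell_w_mm, bc.cell_h_mm,
                      bar_dark if bit else base_rgb)

    # --- corruptions ---------------------------------------------------
    if spec.shadow is not None:
        d = np.deg2rad(spec.shadow.direction_deg)
        dcol, drow = np.cos(d), np.sin(d)
        proj = dcol * cols + drow * rows
        corners_mm = np.array([[0, 0], [layout.width_mm, 0],
                               [layout.width_mm, layout.height_mm],
                               [0, layout.height_mm]], dtype=float)
        cpx = _mm_to_px(spec, corners_mm)
        cproj = dcol * cpx[:, 1] + drow * cpx[:, 0]
        lo, hi = cproj.min(), cproj.max()
        t = np.clip((proj - lo) / max(hi - lo, 1e-9), 0.0, 1.0)
        img *= (1.0 - spec.shadow.depth * t)[..., None]

    if spec.occlusion is not None:
        oc = spec.occlusion
        m = (np.abs(X - oc.x_mm) < oc.w_mm / 2.0) & (np.abs(Y - oc.y_mm) < oc.h_mm / 2.0)
        img[m] = np.asarray(oc.color, dtype=float)

    if spec.lens_blob is not None:
        lb = spec.lens_blob
        sig = lb.radius_frac * W
        r2 = (cols - lb.cx_frac * W) ** 2 + (rows - lb.cy_frac * H) ** 2
        img *= (1.0 - lb.depth * np.exp(-r2 / (2.0 * sig ** 2)))[..., None]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    raster = np.round(srgb_encode(np.clip(img, 0.0, 1.0)) * 255.0).astype(np.uint8)

    marker_px = None
    if layout.markers_mm:
        marker_px = _mm_to_px(spec, np.asarray(layout.markers_mm, dtype=float))
    return SceneImage(raster=raster, truth=spec, scale_px_per_mm=scale,
                      marker_px=marker_px)


# ---------------------------------------------------------------------------
# Image sets and cohorts
# ---------------------------------------------------------------------------

def make_image_set(base: SceneSpec, n_flash: int = 3, n_noflash: int = 3,
                   per_image: list[dict] | None = None) -> list[SceneImage]:
    """Render an image set: ``n_flash`` flash frames first, then ``n_noflash``.

    ``per_image`` optionally carries one dict of SceneSpec field overrides per
    frame (corruption switches for QC fixtures).  Per-frame noise seeds are
    drawn deterministically from the base seed.
    """
    if n_flash < 0 or n_noflash < 0:
        raise BilicamError("image counts must be >= 0")
    n = n_flash + n_noflash
    if n == 0:
        raise BilicamError("an image set needs at least one image")
    if per_image is not None and len(per_image) != n:
        raise BilicamError("per_image overrides must match the number of images")
    seeds = np.random.SeedSequence(base.seed).generate_state(n) % (2 ** 31)
    images = []
    for i in range(n):
        overrides = dict(per_image[i]) if per_image is not None else {}
        spec = replace(base, flash=(i < n_flash), seed=int(seeds[i]), **overrides)
        images.append(render_scene(spec))
    return images


def corruption_catalog() -> dict[str, tuple[dict, str]]:
    """Default-severity corruptions and the QC check each is designed to trip.

    Keys are corruption names; values are (SceneSpec field overrides,
    designated check name).  Severities are the renderer defaults the QC
    thresholds are documented against; each corruption leaves the other
    checks untouched on an otherwise clean scene.
    """
    return {
        "shadow": ({"shadow": ShadowSpec(direction_deg=0.0, depth=0.3)},
                   "shadow_ok"),
        "patch_occlusion": ({"occlusion": OcclusionSpec(46.0, 14.0, 8.0, 4.0)},
                            "patches_present"),
        "hole_occlusion": ({"occlusion": OcclusionSpec(50.0, 36.0, 16.0, 16.0,
                                                       (0.15, 0.5, 0.2))},
                           "skin_plausible"),
        "marker_occlusion": ({"occlusion": OcclusionSpec(7.0, 7.0, 11.0, 11.0,
                                                         (0.8, 0.8, 0.78))},
                             "card_present"),
        "barcode_occlusion": ({"occlusion": OcclusionSpec(48.0, 69.0, 60.0, 6.0,
                                                          (0.8, 0.8, 0.78))},
                              "barcode_present"),
        "distance_error": ({"distance_cm": 40.0}, "distance_ok"),
        "damaged_patch": ({"damaged_patches": (("C10", ("recolor", (0.6, 0.3, 0.5))),)},
                          "card_undamaged"),
        "lens_blob": ({"lens_blob": LensBlobSpec()}, "lens_clear"),
    }


DEFAULT_BILIRUBIN_DISTRIBUTION = {
    "kind": "truncnorm", "mean": 178.2, "sd": 76.5, "low": 13.0, "high": 367.0,
}
#: cohort skin-type ranges (interior of the lookup grid)
MELANIN_RANGE = (0.02, 0.13)
BLOOD_RANGE = (0.008, 0.045)


def _sample_bilirubin(dist: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist.get("kind")
    if kind == "truncnorm":
        a = (dist["low"] - dist["mean"]) / dist["sd"]
        b = (dist["high"] - dist["mean"]) / dist["sd"]
        return stats.truncnorm.rvs(a, b, loc=dist["mean"], scale=dist["sd"],
                                   size=n, random_state=rng)
    if kind == "uniform":
        return rng.uniform(dist["low"], dist["high"], size=n)
    if kind == "degenerate":
        return np.full(n, float(dist["value"]))
    raise BilicamError(f"unsupported bilirubin distribution {kind!r}")


def make_cohort(n_subjects: int,
                bilirubin_distribution: dict | None = None,
                seed: int = 0,
                layout: CardLayout | None = None,
                illuminant: Illuminant | None = None,
                camera: CameraModel | None = None,
                n_flash: int = 3, n_noflash: int = 3,
                noise_sd: float = 0.005,
                tsb_noise_sd: float = TSB_NOISE_SD,
                render: bool = True,
                outdir: str | Path | None = None,
                ) -> tuple[pd.DataFrame, list[list[SceneImage]]]:
    """Simulate a validation-study cohort: image sets plus a truth manifest.

    Each subject gets a sampled chromophore state, a rendered image set, and
    a reference TSB equal to the skin bilirubin plus lab measurement noise
    (sd ``tsb_noise_sd``).  Returns (manifest, image sets); with ``outdir``
    the PNGs, per-image truth JSON sidecars and manifest CSV are written.
    ``render=False`` skips rendering (sampler-only studies); the manifest is
    identical either way.
    """
    if n_subjects < 1:
        raise BilicamError("n_subjects must be >= 1")
    dist = DEFAULT_BILIRUBIN_DISTRIBUTION if bilirubin_distribution is None \
        else bilirubin_distribution
    layout = default_layout() if layout is None else layout
    illuminant = flat_illuminant() if illuminant is None else illuminant
    camera = default_camera() if camera is None else camera
    rng = np.random.default_rng(seed)
    bili = _sample_bilirubin(dist, n_subjects, rng)
    melanin = rng.uniform(*MELANIN_RANGE, size=n_subjects)
    blood = rng.uniform(*BLOOD_RANGE, size=n_subjects)
    tsb = np.maximum(bili + rng.normal(0.0, tsb_noise_sd, size=n_subjects), 0.0)
    subject_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2 ** 31)

    rows, sets = [], []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    for i in range(n_subjects):
        sid = f"S{i + 1:04d}"
        skin = ChromophoreState(float(bili[i]), float(melanin[i]), float(blood[i]), 0.7)
        base = SceneSpec(layout=layout, skin=skin, illuminant=illuminant,
                         camera=camera, noise_sd=noise_sd, card_id=i + 1,
                         seed=int(subject_seeds[i]))
        if render:
            images = make_image_set(base, n_flash=n_flash, n_noflash=n_noflash)
        else:
            flash_flags = [True] * n_flash + [False] * n_noflash
            images = [SceneImage(raster=np.zeros((1, 1, 3), dtype=np.uint8),
                                 truth=replace(base, flash=f), scale_px_per_mm=1.0,
                                 marker_px=None)
                      for f in flash_flags]
        sets.append(images)
        paths = []
        if outdir is not None:
            import imageio.v3 as iio
            for j, im in enumerate(images):
                p = outdir / f"{sid}_{j}.png"
                iio.imwrite(p, im.raster)
                with open(p.with_suffix(".json"), "w") as fh:
                    json.dump({"subject_id": sid, "flash": bool(im.truth.flash),
                               "seed": im.truth.seed,
                               "bilirubin_umol_per_L": skin.bilirubin_umol_per_L,
                               "melanin_fraction": skin.melanin_fraction,
                               "blood_fraction": skin.blood_fraction},
                              fh, indent=2, sort_keys=True)
                    fh.write("\n")
                paths.append(str(p))
        rows.append({
            "subject_id": sid,
            "image_paths": ";".join(paths),
            "true_tsb_umol_L": float(tsb[i]),
            "bilirubin_umol_per_L": float(bili[i]),
            "melanin_fraction": float(melanin[i]),
            "blood_fraction": float(blood[i]),
            "flash_flags": ";".join("1" if im.truth.flash else "0" for im in images),
        })
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        write_manifest(manifest, outdir / "manifest.csv")
    return manifest, sets


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
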