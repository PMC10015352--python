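"""Locate the card in an image, sample patch colors, read the card id.

The four corner fiducials are black squares with a white center dot; they
are found by thresholding dark pixels and keeping connected components whose
topology (one hole), squareness and fill match a fiducial.  A projective
transform fitted to the four marker correspondences maps card-millimeter
geometry into the image, after which each patch is sampled with a
luminance-trimmed mean in linear RGB.

Conventions: pixel = (row, col), 0-based, origin top-left; card frame in mm.
Marker canonical order is by angle around the marker centroid, starting from
the marker nearest the image top-left corner, proceeding clockwise on screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.draw import polygon as draw_polygon
from skimage.transform import ProjectiveTransform

from .forward_model import BilicamError
from .synthetic_scenes import CardLayout, srgb_decode

#: luminance threshold separating fiducial/barcode ink from card colors
DARK_THRESHOLD = 0.10
#: fiducial candidate component area bounds, px
MARKER_AREA_RANGE = (140, 2600)
#: central luminance band kept by the trimmed mean
TRIM_KEEP = 0.6
#: a patch whose full-region channel SD exceeds this is flagged missing
MISSING_SD = 0.06
#: minimum sentinel contrast for a legible barcode band
BARCODE_MIN_CONTRAST = 0.15

LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


class CardNotDetectedError(BilicamError):
    """Fewer than four usable fiducials found (maps to a QC failure)."""


@dataclass
class PatchSample:
    patch_id: str
    pixel_count: int
    mean_rgb: np.ndarray | None     # trimmed-mean linear RGB, None when missing
    channel_sd: np.ndarray | None   # full-region per-channel SD
    trim_fraction: float
    missing: bool


@dataclass
class CardObservation:
    marker_px: np.ndarray            # (4, 2) float (row, col), canonical order
    transform: ProjectiveTransform   # card mm (x, y) -> pixel (col, row)
    patch_samples: dict[str, PatchSample]
    skin_sample: PatchSample
    barcode_id: int | None
    distance_cm: float


def _linear_image(image: np.ndarray) -> np.ndarray:
    """uint8/uint16 sRGB raster (or float already in [0,1]) -> linear float."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise BilicamError("expected an (H, W, 3) RGB raster")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(float) / 65535.0
    else:
        img = img.astype(float)
    return srgb_decode(img)


def detect_markers(image: np.ndarray) -> np.ndarray:
    """Subpixel centers of the 4 fiducials, canonically ordered (row, col).

    Raises :class:`CardNotDetectedError` unless exactly four candidates with
    fiducial shape (square-ish dark component containing one hole) are found.
    """
    lin = _linear_image(image)
    luma = lin @ LUMA_WEIGHTS
    dark = luma < DARK_THRESHOLD
    labels = measure.label(dark, connectivity=2)
    centers = []
    h, w = dark.shape
    for region in measure.regionprops(labels):
        if not MARKER_AREA_RANGE[0] <= region.area_filled <= MARKER_AREA_RANGE[1]:
            continue
        if region.euler_number != 0:  # need exactly one hole (the white dot)
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue
        aspect = (r1 - r0) / max(c1 - c0, 1)
        if not 0.7 <= aspect <= 1.43:
            continue
        if region.area_filled / ((r1 - r0) * (c1 - c0)) < 0.6:
            continue
        # hole is centered in the square, so the ring centroid is unbiased
        centers.append(region.centroid)
    if len(centers) != 4:
        raise CardNotDetectedError(
            f"card not detected: found {len(centers)} fiducial candidates, need 4")
    return _canonical_order(np.asarray(centers, dtype=float))


def _canonical_order(markers: np.ndarray) -> np.ndarray:
    """Order 4 (row, col) points clockwise on screen, starting nearest the
    image top-left corner."""
    centroid = markers.mean(axis=0)
    ang = np.arctan2(markers[:, 0] - centroid[0], markers[:, 1] - centroid[1])
    order = np.argsort(ang)  # increasing angle = clockwise in (row, col)
    start = np.argmin(markers[order].sum(axis=1))
    return markers[np.roll(order, -start)]


def locate_patches(markers: np.ndarray, layout: CardLayout,
                   margin: float = 0.2) -> tuple[ProjectiveTransform, dict]:
    """Projective card-mm -> pixel transform and per-patch pixel regions.

    Patch regions are the layout rectangles shrunk by ``margin`` per side.
    The skin hole is included under id ``"HOLE"`` (radius shrunk 25%).
    """
    markers = _canonical_order(np.asarray(markers, dtype=float))
    if len(layout.markers_mm) != 4:
        raise BilicamError("layout has no markers; cannot locate patches")
    src = np.asarray(layout.markers_mm, dtype=float)          # (x, y) mm
    dst = markers[:, ::-1]                                    # (col, row) px
    # reject degenerate (collinear) marker sets
    def _cross(u, v):
        return u[0] * v[1] - u[1] * v[0]
    area = 0.5 * abs(_cross(dst[1] - dst[0], dst[2] - dst[0])) \
        + 0.5 * abs(_cross(dst[2] - dst[0], dst[3] - dst[0]))
    if area < 100.0:
        raise BilicamError("degenerate marker configuration (collinear)")
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, dst)
        if not tf:
            raise BilicamError("homography estimation failed")
    else:  # scikit-image < 0.26
        tf = ProjectiveTransform()
        if not tf.estimate(src, dst):
            raise BilicamError("homography estimation failed")
    regions = {}
    for p in layout.patches:
        hw, hh = p.w_mm / 2.0 * (1 - margin), p.h_mm / 2.0 * (1 - margin)
        corners = np.array([[p.cx_mm - hw, p.cy_mm - hh], [p.cx_mm + hw, p.cy_mm - hh],
                            [p.cx_mm + hw, p.cy_mm + hh], [p.cx_mm - hw, p.cy_mm + hh]])
        px = tf(corners)  # (col, row)
        regions[p.id] = (px[:, 1], px[:, 0])
    hx, hy = layout.hole_center_mm
    r = layout.hole_diameter_mm / 2.0 * 0.75
    th = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
    circ = np.stack([hx + r * np.cos(th), hy + r * np.sin(th)], axis=1)
    px = tf(circ)
    regions["HOLE"] = (px[:, 1], px[:, 0])
    return tf, regions


def _sample_region(lin: np.ndarray, poly_rows: np.ndarray, poly_cols: np.ndarray,
                   patch_id: str) -> PatchSample:
    h, w = lin.shape[:2]
    rr, cc = draw_polygon(poly_rows, poly_cols, shape=(h, w))
    inside = (poly_rows >= 0).all() and (poly_rows < h).all() \
        and (poly_cols >= 0).all() and (poly_cols < w).all()
    if rr.size < 9 or not inside:
        return PatchSample(patch_id, int(rr.size), None, None, 0.0, True)
    pix = lin[rr, cc]
    luma = pix @ LUMA_WEIGHTS
    lo, hi = np.quantile(luma, [(1 - TRIM_KEEP) / 2, 1 - (1 - TRIM_KEEP) / 2])
    keep = (luma >= lo) & (luma <= hi)
    mean = pix[keep].mean(axis=0)
    sd = pix.std(axis=0, ddof=1)
    missing = bool(sd.max() > MISSING_SD)
    return PatchSample(patch_id, int(pix.shape[0]), mean, sd,
                       1.0 - keep.mean(), missing)


def sample_patches(image: np.ndarray, regions: dict) -> dict[str, PatchSample]:
    """Trimmed-mean linear RGB per region (sRGB decoded first).

    Regions falling outside the raster yield a missing-flagged sample rather
    than an error; regions with excessive internal spread (occluders, edges)
    are flagged missing via the SD rule.
    """
    lin = _linear_image(image)
    return {pid: _sample_region(lin, rows, cols, pid)
            for pid, (rows, cols) in regions.items()}


def read_barcode(image: np.ndarray, transform: ProjectiveTransform,
                 layout: CardLayout) -> int | None:
    """Decode the 12-bit card id from the stripe band; None when illegible."""
    if layout.barcode is None:
        return None
    bc = layout.barcode
    lin = _linear_image(image)
    h, w = lin.shape[:2]
    values = []
    for i in range(bc.n_cells):
        cx = bc.x0_mm + i * bc.cell_w_mm
        # sample the central 40% of each cell
        hw, hh = bc.cell_w_mm * 0.2, bc.cell_h_mm * 0.2
        corners = np.array([[cx - hw, bc.y_mm - hh], [cx + hw, bc.y_mm - hh],
                            [cx + hw, bc.y_mm + hh], [cx - hw, bc.y_mm + hh]])
        px = transform(corners)
        rr, cc = draw_polygon(px[:, 1], px[:, 0], shape=(h, w))
        if rr.size < 4:
            return None
        values.append(float((lin[rr, cc] @ LUMA_WEIGHTS).mean()))
    dark_ref, light_ref = values[0], values[-1]
    if light_ref - dark_ref < BARCODE_MIN_CONTRAST:
        return None
    mid = 0.5 * (dark_ref + light_ref)
    bits = [1 if v < mid else 0 for v in values[1:-1]]
    return int("".join(map(str, bits)), 2)


def estimate_distance(markers: np.ndarray, layout: CardLayout,
                      focal_px: float) -> float:
    """Camera-to-card distance (cm) from marker pixel pitch, pinhole relation."""
    markers = _canonical_order(np.asarray(markers, dtype=float))
    mm = np.asarray(layout.markers_mm, dtype=float)
    px_pitch = np.array([np.linalg.norm(markers[i] - markers[(i + 1) % 4])
                         for i in range(4)])
    mm_pitch = np.array([np.linalg.norm(mm[i] - mm[(i + 1) % 4]) for i in range(4)])
    if np.any(px_pitch <= 0):
        raise BilicamError("zero marker pitch")
    return float(np.mean(focal_px * mm_pitch / px_pitch) / 10.0)


def observe_card(image: np.ndarray, layout: CardLayout,
                 focal_px: float = 1250.0) -> CardObservation:
    """Full card read-out: detect, locate, sample, decode, range.

    Raises :class:`CardNotDetectedError` when the fiducials cannot be found;
    all other degradations surface as flags in the observation.
    """
    markers = detect_markers(image)
    tf, regions = locate_patches(markers, layout)
    samples = sample_patches(image, regions)
    skin = samples.pop("HOLE")
    return CardObservation(
        marker_px=markers,
        transform=tf,
        patch_samples=samples,
        skin_sample=skin,
        barcode_id=read_barcode(image, tf, layout),
        distance_cm=estimate_distance(markers, layout, focal_px),
    )
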