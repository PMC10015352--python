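"""Color correction against the card's known patch spectra.

Observed patch colors (any illuminant, any camera) are mapped into the
reference space of the lookup database — the flat canonical illuminant seen
through the canonical camera — by a least-squares transform fitted on the
card patches.  The default is a linear 3x3 matrix with no offset, which is
invariant to exposure scale; a degree-2 root-polynomial variant (6 terms,
still scale-invariant) is available for stress tests.

Leave-one-out residuals over the patches provide the card-damage check: a
recolored patch predicts poorly from the others.  Damage residuals are
measured on intensity-normalized colors, so spatially varying but
channel-uniform gain (shadow gradients, vignetting) does not masquerade as
damage under the offset-free linear transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward_model import (
    BilicamError,
    CameraModel,
    Illuminant,
    default_camera,
    flat_illuminant,
    render_rgb,
)
from .synthetic_scenes import CardLayout
from .card_processing import PatchSample


class CalibrationError(BilicamError):
    """Too few usable patches to fit a correction (maps to a QC failure)."""


MIN_PATCHES_LINEAR = 4
MIN_PATCHES_LOO = 5


@dataclass
class ColorCorrection:
    kind: str                      # linear_3x3 | root_polynomial
    matrix: np.ndarray             # (3, 3) or (3, 6)
    residual_rgb: pd.Series        # per-patch scalar ||T(obs) - ref||
    residual_channels: pd.DataFrame  # per-patch signed delta-RGB
    n_patches_used: int


def reference_colors(layout: CardLayout,
                     illuminant: Illuminant | None = None,
                     camera: CameraModel | None = None) -> dict[str, np.ndarray]:
    """Linear RGB of every patch's reference spectrum in the database space."""
    illuminant = flat_illuminant() if illuminant is None else illuminant
    camera = default_camera() if camera is None else camera
    return {p.id: render_rgb(p.reflectance, illuminant, camera)
            for p in layout.patches}


def _features(rgb: np.ndarray, kind: str) -> np.ndarray:
    rgb = np.atleast_2d(rgb)
    if kind == "linear_3x3":
        return rgb
    if kind == "root_polynomial":
        r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
        return np.column_stack([r, g, b, np.sqrt(r * g), np.sqrt(r * b), np.sqrt(g * b)])
    raise BilicamError(f"unknown correction kind {kind!r}")


def _usable(observed: dict[str, PatchSample]) -> list[str]:
    return [pid for pid, s in observed.items() if not s.missing and s.mean_rgb is not None]


def fit_color_correction(observed: dict[str, PatchSample], layout: CardLayout,
                         kind: str = "linear_3x3",
                         reference: dict[str, np.ndarray] | None = None
                         ) -> ColorCorrection:
    """Least-squares fit of T minimizing sum ||T(observed) - reference||^2.

    Missing patches are excluded; fewer than four usable patches raises
    :class:`CalibrationError` ("calibration impossible").
    """
    reference = reference_colors(layout) if reference is None else reference
    ids = [pid for pid in _usable(observed) if pid in reference]
    if len(ids) < MIN_PATCHES_LINEAR:
        raise CalibrationError(
            f"calibration impossible: {len(ids)} usable patches, need >= {MIN_PATCHES_LINEAR}")
    O = np.vstack([observed[pid].mean_rgb for pid in ids])
    R = np.vstack([reference[pid] for pid in ids])
    F = _features(O, kind)
    coeffs, *_ = np.linalg.lstsq(F, R, rcond=None)
    M = coeffs.T  # (3, n_features)
    pred = F @ M.T
    delta = pred - R
    residual = pd.Series(np.linalg.norm(delta, axis=1), index=ids, name="residual")
    channels = pd.DataFrame(delta, index=ids, columns=["dr", "dg", "db"])
    return ColorCorrection(kind=kind, matrix=M, residual_rgb=residual,
                           residual_channels=channels, n_patches_used=len(ids))


def apply_correction(correction: ColorCorrection, rgb: np.ndarray,
                     clip: bool = True) -> np.ndarray:
    """Apply a fitted correction to linear RGB; output clipped to [0, 1]."""
    out = (_features(np.asarray(rgb, dtype=float), correction.kind)
           @ correction.matrix.T)
    out = out[0] if np.asarray(rgb).ndim == 1 else out
    return np.clip(out, 0.0, 1.0) if clip else out


def _chromaticity(rgb: np.ndarray) -> np.ndarray:
    s = np.sum(rgb, axis=-1, keepdims=True)
    return rgb / np.maximum(s, 1e-9)


def cross_validate_colors(observed: dict[str, PatchSample], layout: CardLayout,
                          kind: str = "linear_3x3",
                          reference: dict[str, np.ndarray] | None = None,
                          outlier_chroma: float = 0.03) -> pd.DataFrame:
    """Leave-one-out patch prediction residuals (the damage signal).

    For each usable patch the correction is refitted on the others and the
    held-out patch predicted.  ``residual_rgb`` is the raw linear-RGB error;
    ``residual_chroma`` is the error after intensity normalization, which is
    the quantity the card-damage QC check thresholds.

    Two passes: patches whose first-pass chromaticity residual exceeds
    ``outlier_chroma`` (damage candidates) are excluded from every other
    patch's fit on the second pass, so one damaged patch does not bleed into
    its neighbours' residuals.
    """
    reference = reference_colors(layout) if reference is None else reference
    ids = [pid for pid in _usable(observed) if pid in reference]
    if len(ids) < MIN_PATCHES_LOO:
        raise CalibrationError(
            f"cross-validation needs >= {MIN_PATCHES_LOO} usable patches, got {len(ids)}")

    def loo_pass(fit_ids: list[str]) -> pd.DataFrame:
        rows = []
        for held in ids:
            rest = {pid: observed[pid] for pid in fit_ids if pid != held}
            corr = fit_color_correction(rest, layout, kind=kind, reference=reference)
            pred = apply_correction(corr, observed[held].mean_rgb, clip=False)
            ref = reference[held]
            rows.append({
                "patch_id": held,
                "residual_rgb": float(np.linalg.norm(pred - ref)),
                "residual_chroma": float(np.linalg.norm(
                    _chromaticity(pred) - _chromaticity(ref))),
            })
        return pd.DataFrame(rows).set_index("patch_id")

    first = loo_pass(ids)
    suspects = set(first.index[first["residual_chroma"] > outlier_chroma])
    if not suspects or len(ids) - len(suspects) < MIN_PATCHES_LOO - 1:
        return first
    return loo_pass([pid for pid in ids if pid not in suspects])
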