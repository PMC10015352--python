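"""Image- and set-level quality checks and the inclusion decision.

Eight checks run per image, geometric before colorimetric:

====================  =====================================================
card_present          four fiducials detected
patches_present       no card patch flagged missing (occlusion, specks)
barcode_present       stripe band decoded
distance_ok           estimated capture distance within tolerance of 25 cm
shadow_ok             planar (smooth-gradient) component of the gray-patch
                      luminance-gain field has low range
lens_clear            no strong localized darkening: gain-field residuals
                      from the fitted plane stay above a floor
skin_plausible        calibrated hole color inside the (dilated) convex hull
                      of lookup-database skin colors — rejects non-skin
                      objects in the hole
card_undamaged        max leave-one-out chromaticity residual small
====================  =====================================================

The gray-patch gain field (observed/reference luminance per gray patch)
separates the two illumination checks: a shadow is a smooth gradient, well
captured by a plane over card coordinates; a partly covered lens darkens a
localized region, leaving a strongly negative residual from that plane.

When ``card_present`` fails the remaining checks are reported as
not-evaluated.  The image passes when every evaluated check passes; the
first failing check names the exclusion code, so codes partition excluded
images.  A set is included when at least ``m`` of its ``n`` images pass
(3-of-4 for the four-frame protocol, 4-of-6 for the 3-flash/3-no-flash
protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .forward_model import BilicamError, LookupDatabase
from .synthetic_scenes import CardLayout
from .card_processing import CardObservation, LUMA_WEIGHTS
from .calibration import (
    CalibrationError,
    ColorCorrection,
    apply_correction,
    cross_validate_colors,
    fit_color_correction,
    reference_colors,
)

CHECK_ORDER = ("card_present", "patches_present", "barcode_present", "distance_ok",
               "shadow_ok", "lens_clear", "skin_plausible", "card_undamaged")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the image checks (defaults tuned to the renderer's
    default corruption severities; no clinical values exist for them)."""

    nominal_distance_cm: float = 25.0
    distance_tol_cm: float = 5.0
    #: planar-fit range / mean of the gain field above this fails shadow_ok
    shadow_max_rel_range: float = 0.15
    #: plane residual below -this (relative to mean gain) fails lens_clear
    lens_max_neg_residual: float = 0.15
    #: max leave-one-out chromaticity residual above this fails card_undamaged
    damage_max_loo_chroma: float = 0.03
    #: dilation margin of the skin color hull, linear RGB units
    skin_hull_margin: float = 0.02


@dataclass
class CheckRecord:
    name: str
    status: str          # pass | fail | not_evaluated
    measured: float | None
    threshold: float | None


@dataclass
class QCReport:
    checks: list[CheckRecord]
    image_pass: bool
    failure_codes: list[str]

    def __post_init__(self) -> None:
        names = [c.name for c in self.checks]
        if sorted(names) != sorted(CHECK_ORDER):
            raise BilicamError("QCReport must contain every check exactly once")

    def check(self, name: str) -> CheckRecord:
        return next(c for c in self.checks if c.name == name)


@dataclass
class SetDecision:
    n_images: int
    n_passing: int
    m_required: int
    n_expected: int
    include: bool


class SkinHull:
    """Convex hull of the lookup database's skin colors, dilated by a margin.

    A point is inside when every hull facet inequality holds up to the
    margin; signed distance <= 0 means inside the dilated hull.
    """

    def __init__(self, db: LookupDatabase) -> None:
        self.hull = ConvexHull(db.rgb)

    def signed_distance(self, rgb: np.ndarray) -> float:
        eq = self.hull.equations  # A x + b <= 0 inside
        return float((eq[:, :3] @ np.asarray(rgb, dtype=float) + eq[:, 3]).max())

    def contains(self, rgb: np.ndarray, margin: float = 0.0) -> bool:
        return self.signed_distance(rgb) <= margin


def gray_gain_field(observation: CardObservation, layout: CardLayout
                    ) -> pd.DataFrame:
    """Observed/reference luminance ratio per gray-role patch, with position.

    Illuminant tint and exposure enter as a common factor, so relative
    statistics of this field isolate spatial illumination structure
    (shadow gradients, lens blobs).
    """
    ref = reference_colors(layout)
    rows = []
    for p in layout.gray_patches:
        s = observation.patch_samples.get(p.id)
        if s is None or s.mean_rgb is None:
            continue
        ref_lum = float(ref[p.id] @ LUMA_WEIGHTS)
        rows.append({"patch_id": p.id, "x_mm": p.cx_mm, "y_mm": p.cy_mm,
                     "gain": float(s.mean_rgb @ LUMA_WEIGHTS) / max(ref_lum, 1e-9)})
    return pd.DataFrame(rows)


def illumination_field_stats(gains: pd.DataFrame
                             ) -> tuple[float, float, np.ndarray]:
    """(planar range / mean, most negative plane residual / mean, plane coef).

    Fits gain ~ a + b x + c y over the gray-patch positions.  The fitted
    plane's range captures smooth shadow gradients; the most negative
    residual captures localized darkening (lens blobs).  The returned
    coefficients allow flat-fielding other samples by the same plane."""
    g = gains["gain"].to_numpy()
    n = len(g)
    A = np.column_stack([np.ones(n), gains["x_mm"], gains["y_mm"]])
    # least-median-of-squares plane via elemental subsets: a localized blob
    # must not tilt the plane (ordinary or trimmed LS has bad local minima)
    from itertools import combinations
    triples = np.array(list(combinations(range(n), 3)))
    M = A[triples]                                    # (t, 3, 3)
    nonsingular = np.abs(np.linalg.det(M)) > 1e-6
    M, b = M[nonsingular], g[triples[nonsingular]]
    coefs = np.linalg.solve(M, b[..., None])[..., 0]  # (t, 3)
    resid = np.abs(g[None, :] - coefs @ A.T)          # (t, n)
    med = np.median(resid, axis=1)
    best = int(np.argmin(med))
    scale = max(1.4826 * float(med[best]), 1e-3)
    inliers = resid[best] <= 2.5 * scale
    coef, *_ = np.linalg.lstsq(A[inliers], g[inliers], rcond=None)
    fitted = A @ coef
    mean = max(float(g.mean()), 1e-9)
    planar_range = float(fitted.max() - fitted.min()) / mean
    worst_residual = float((g - fitted).min()) / mean
    return planar_range, worst_residual, coef


def run_image_qc(observation: CardObservation | None,
                 layout: CardLayout,
                 db: LookupDatabase | SkinHull,
                 config: QCConfig | None = None,
                 correction: ColorCorrection | None = None) -> QCReport:
    """Evaluate all image checks; failures are verdicts, never exceptions.

    ``observation`` is None when card detection failed (card_present fails
    and the colorimetric checks are not evaluated).  A prefitted
    ``correction`` may be passed to avoid refitting.
    """
    config = QCConfig() if config is None else config
    hull = db if isinstance(db, SkinHull) else SkinHull(db)
    records: list[CheckRecord] = []

    def add(name: str, ok: bool | None, measured=None, threshold=None):
        status = "not_evaluated" if ok is None else ("pass" if ok else "fail")
        records.append(CheckRecord(name, status, measured, threshold))

    add("card_present", observation is not None)
    if observation is None:
        for name in CHECK_ORDER[1:]:
            add(name, None)
        return _finalize(records)

    n_missing = sum(1 for s in observation.patch_samples.values() if s.missing)
    add("patches_present", n_missing == 0, float(n_missing), 0.0)
    add("barcode_present", observation.barcode_id is not None)
    dist_err = abs(observation.distance_cm - config.nominal_distance_cm)
    add("distance_ok", dist_err <= config.distance_tol_cm, dist_err,
        config.distance_tol_cm)

    gains = gray_gain_field(observation, layout)
    plane_coef = None
    if len(gains) >= 4:
        planar_range, worst_residual, plane_coef = illumination_field_stats(gains)
        add("shadow_ok", planar_range <= config.shadow_max_rel_range,
            planar_range, config.shadow_max_rel_range)
        add("lens_clear", worst_residual >= -config.lens_max_neg_residual,
            worst_residual, -config.lens_max_neg_residual)
    else:
        add("shadow_ok", None)
        add("lens_clear", None)

    try:
        if correction is None:
            correction = fit_color_correction(observation.patch_samples, layout)
        skin_ok: bool | None
        if observation.skin_sample.mean_rgb is None:
            skin_ok, sdist = False, None
        else:
            skin_cal = apply_correction(correction, observation.skin_sample.mean_rgb)
            sdist = hull.signed_distance(skin_cal)
            skin_ok = sdist <= config.skin_hull_margin
        add("skin_plausible", skin_ok, sdist, config.skin_hull_margin)
        # flat-field by the illumination plane so a smooth (sub- or
        # super-threshold) gradient cannot masquerade as card damage
        loo_samples = observation.patch_samples
        if plane_coef is not None:
            loo_samples = _flat_fielded(loo_samples, layout, plane_coef)
        loo = cross_validate_colors(loo_samples, layout)
        worst = float(loo["residual_chroma"].max())
        add("card_undamaged", worst <= config.damage_max_loo_chroma, worst,
            config.damage_max_loo_chroma)
    except CalibrationError:
        add("skin_plausible", None)
        add("card_undamaged", None)

    return _finalize(records)


def _flat_fielded(samples: dict, layout: CardLayout, coef: np.ndarray) -> dict:
    from dataclasses import replace as _replace
    out = {}
    positions = {p.id: (p.cx_mm, p.cy_mm) for p in layout.patches}
    for pid, s in samples.items():
        if s.mean_rgb is None or pid not in positions:
            out[pid] = s
            continue
        x, y = positions[pid]
        gain = max(float(coef[0] + coef[1] * x + coef[2] * y), 0.1)
        out[pid] = _replace(s, mean_rgb=s.mean_rgb / gain)
    return out


def _finalize(records: list[CheckRecord]) -> QCReport:
    failed = [c.name for c in records if c.status == "fail"]
    evaluated = [c for c in records if c.status != "not_evaluated"]
    image_pass = bool(evaluated) and not failed \
        and all(c.status == "pass" for c in evaluated) \
        and records[0].status == "pass"
    return QCReport(checks=records, image_pass=image_pass, failure_codes=failed)


DEFAULT_SET_RULES = {4: (3, 4), 6: (4, 6)}


def decide_set(reports: list[QCReport], rule: tuple[int, int] | None = None
               ) -> SetDecision:
    """Include the set iff at least ``m`` of the supplied images pass QC.

    Default rules: 3-of-4 (four-frame protocol) and 4-of-6 (six-frame
    protocol); other sizes default to majority.
    """
    if not reports:
        raise BilicamError("decide_set needs at least one report")
    n = len(reports)
    if rule is None:
        rule = DEFAULT_SET_RULES.get(n, (n // 2 + 1, n))
    m_required, n_expected = rule
    if m_required > n:
        raise BilicamError(
            f"misconfigured set rule: requires {m_required} passes of {n} images")
    n_passing = sum(r.image_pass for r in reports)
    return SetDecision(n_images=n, n_passing=n_passing, m_required=m_required,
                       n_expected=n_expected, include=n_passing >= m_required)


def qc_summary(manifest: pd.DataFrame, percent_decimals: int = 1) -> pd.DataFrame:
    """Recruitment-style accounting table from per-set decisions.

    ``manifest`` needs columns ``subject_id`` and ``exclusion_code`` (empty
    or NaN for included sets).  Codes must partition the excluded sets: one
    code per excluded set, by construction the first failing check.
    """
    if manifest["subject_id"].duplicated().any():
        raise BilicamError("duplicate subject ids: exclusion codes would double-count")
    total = len(manifest)
    codes = manifest["exclusion_code"].fillna("").astype(str)
    excluded = codes != ""
    rows = [{"category": "recruited", "n": total, "percent": 100.0}]
    for code, n in codes[excluded].value_counts().sort_index().items():
        rows.append({"category": f"excluded:{code}", "n": int(n),
                     "percent": round(100.0 * n / total, percent_decimals)})
    remaining = total - int(excluded.sum())
    rows.append({"category": "remaining", "n": remaining,
                 "percent": round(100.0 * remaining / total, percent_decimals)})
    return pd.DataFrame(rows)
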