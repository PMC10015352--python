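"""Calibrated skin color -> bilirubin estimate, per image and per set.

The estimator is a k-nearest-neighbor lookup in linear-RGB space over the
simulated bilirubin-color database: the estimate is the inverse-distance
weighted mean of the bilirubin values of the k closest entries.  Local
averaging over neighbors marginalizes small mismatches in melanin and blood
between the subject and the grid.  A set-level measurement is the median of
the estimates from QC-passing images; a set failing the inclusion rule
carries no estimate, only its failure codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .forward_model import BilicamError, LookupDatabase
from .synthetic_scenes import CardLayout, SceneImage
from .card_processing import CardNotDetectedError, observe_card
from .calibration import CalibrationError, apply_correction, fit_color_correction
from .quality_control import (
    QCConfig,
    QCReport,
    SetDecision,
    SkinHull,
    decide_set,
    run_image_qc,
)
from .biostat import umol_to_mgdl

K_NEIGHBORS = 5
EPS_DISTANCE = 1e-9
#: queries farther than this from every database color are flagged extrapolated
EXTRAPOLATION_DISTANCE = 0.02


class LookupIndex:
    """KD-tree over the database colors (build once, query per image)."""

    def __init__(self, db: LookupDatabase) -> None:
        if len(db.entries) == 0:
            raise BilicamError("empty lookup database")
        self.db = db
        self.tree = cKDTree(db.rgb)
        self.bilirubin = db.bilirubin

    def query(self, rgb: np.ndarray, k: int = K_NEIGHBORS,
              weights: str = "inverse_distance") -> tuple[float, bool]:
        """Estimate (umol/L) and an extrapolation flag for one RGB triple."""
        rgb = np.asarray(rgb, dtype=float)
        if rgb.shape != (3,) or rgb.min() < 0 or rgb.max() > 1:
            raise BilicamError("query rgb must be a triple in [0, 1]^3")
        k = min(k, len(self.bilirubin))
        dist, idx = self.tree.query(rgb, k=k)
        dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
        if weights == "uniform":
            est = float(self.bilirubin[idx].mean())
        elif weights == "inverse_distance":
            if dist[0] < EPS_DISTANCE:  # exact database entry
                return float(self.bilirubin[idx[0]]), False
            w = 1.0 / (dist + EPS_DISTANCE)
            est = float(np.sum(w * self.bilirubin[idx]) / np.sum(w))
        else:
            raise BilicamError(f"unknown weighting {weights!r}")
        return est, bool(dist[0] > EXTRAPOLATION_DISTANCE)


def estimate_from_color(rgb: np.ndarray, db: LookupDatabase | LookupIndex,
                        k: int = K_NEIGHBORS,
                        weights: str = "inverse_distance") -> float:
    """Bilirubin (umol/L) for one calibrated linear-RGB triple."""
    index = db if isinstance(db, LookupIndex) else LookupIndex(db)
    return index.query(rgb, k=k, weights=weights)[0]


@dataclass
class MeasurementResult:
    per_image: pd.DataFrame      # estimate_umol_L, qc_pass, exclusion_code, extrapolated
    set_decision: SetDecision
    set_estimate_umol_L: float | None
    set_estimate_mg_dL: float | None
    estimate_iqr_umol_L: float | None
    db_version: str

    @property
    def rejected(self) -> bool:
        return not self.set_decision.include


def measure_set(images: list[SceneImage] | list[np.ndarray],
                layout: CardLayout,
                db: LookupDatabase,
                qc_config: QCConfig | None = None,
                rule: tuple[int, int] | None = None,
                k: int = K_NEIGHBORS) -> MeasurementResult:
    """Run the full per-image pipeline and aggregate to a set measurement.

    Pipeline per image: detect markers -> locate/sample patches -> fit color
    correction -> QC -> kNN estimate.  The set estimate is the median over
    QC-passing images; a set rejected by the inclusion rule reports no
    estimate (that is a verdict, not an error).
    """
    if len(images) == 0:
        raise BilicamError("measure_set needs at least one image")
    qc_config = QCConfig() if qc_config is None else qc_config
    index = LookupIndex(db)
    hull = SkinHull(db)
    rows, reports = [], []
    for i, image in enumerate(images):
        raster = image.raster if isinstance(image, SceneImage) else image
        estimate, extrapolated, code = None, False, ""
        try:
            obs = observe_card(raster, layout)
        except CardNotDetectedError:
            obs = None
        correction = None
        if obs is not None:
            try:
                correction = fit_color_correction(obs.patch_samples, layout)
            except CalibrationError:
                correction = None
        report = run_image_qc(obs, layout, hull, qc_config, correction=correction)
        reports.append(report)
        if obs is not None and correction is not None \
                and obs.skin_sample.mean_rgb is not None:
            skin_cal = apply_correction(correction, obs.skin_sample.mean_rgb)
            estimate, extrapolated = index.query(skin_cal, k=k)
        if not report.image_pass:
            code = report.failure_codes[0] if report.failure_codes else "not_evaluated"
        rows.append({"image": i, "estimate_umol_L": estimate,
                     "qc_pass": report.image_pass, "exclusion_code": code,
                     "extrapolated": extrapolated})
    per_image = pd.DataFrame(rows)
    decision = decide_set(reports, rule=rule)
    set_est = set_mgdl = iqr = None
    if decision.include:
        passing = per_image.loc[per_image["qc_pass"], "estimate_umol_L"].dropna()
        if len(passing) == 0:
            decision.include = False
        else:
            set_est = float(passing.median())
            set_mgdl = umol_to_mgdl(set_est)
            q1, q3 = np.percentile(passing, [25, 75])
            iqr = float(q3 - q1)
    return MeasurementResult(
        per_image=per_image, set_decision=decision,
        set_estimate_umol_L=set_est, set_estimate_mg_dL=set_mgdl,
        estimate_iqr_umol_L=iqr,
        db_version=str(db.provenance.get("version", "")),
    )
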