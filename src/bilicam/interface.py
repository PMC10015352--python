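"""Command-line interface, run configuration, logging and file plumbing.

Subcommands mirror the pipeline stages::

    bilicam build-db   render the lookup database to CSV (+ JSON sidecar)
    bilicam render     render one scene (or a small sweep) to PNG
    bilicam cohort     simulate a synthetic validation cohort
    bilicam inspect    card detection + patch samples for one image -> JSON
    bilicam qc         QC accounting table for a cohort directory
    bilicam measure    per-set bilirubin measurement -> JSON
    bilicam validate   truth-vs-estimate statistics report -> JSON

Exit codes: 0 success, 1 domain error (bad input data), 2 usage error.
A QC rejection is a result, not an error.  All randomness flows from
``--seed``.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from .forward_model import (
    BilicamError,
    GridSpec,
    LookupDatabase,
    build_lookup,
    standard_cameras,
    standard_illuminants,
)
from . import synthetic_scenes as scenes
from .card_processing import CardNotDetectedError, observe_card
from .quality_control import QCConfig, qc_summary
from .inversion import measure_set
from .biostat import validate_cohort

log = logging.getLogger("bilicam")

SCHEMA_VERSION = "1"

MANIFEST_COLUMNS = ["subject_id", "image_paths", "true_tsb_umol_L",
                    "bilirubin_umol_per_L", "melanin_fraction",
                    "blood_fraction", "flash_flags"]


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    layout_version: str = "v3"
    nominal_distance_cm: float = 25.0
    distance_tol_cm: float = 5.0
    shadow_max_rel_range: float = 0.15
    lens_max_neg_residual: float = 0.15
    damage_max_loo_chroma: float = 0.03
    skin_hull_margin: float = 0.02
    set_rule_m: int | None = None
    set_rule_n: int | None = None
    database: str | None = None
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "INFO"

    def qc_config(self) -> QCConfig:
        return QCConfig(
            nominal_distance_cm=self.nominal_distance_cm,
            distance_tol_cm=self.distance_tol_cm,
            shadow_max_rel_range=self.shadow_max_rel_range,
            lens_max_neg_residual=self.lens_max_neg_residual,
            damage_max_loo_chroma=self.damage_max_loo_chroma,
            skin_hull_margin=self.skin_hull_margin,
        )

    def set_rule(self) -> tuple[int, int] | None:
        if self.set_rule_m is None or self.set_rule_n is None:
            return None
        return (self.set_rule_m, self.set_rule_n)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a JSON/TOML config file and apply CLI overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith(".toml"):
            import tomllib
            data = tomllib.loads(text)
        else:
            data = json.loads(text)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise BilicamError(f"invalid configuration: {exc}") from exc


# ---------------------------------------------------------------------------
# Manifest / results IO
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (UTF-8, BOM tolerated); validates columns."""
    df = pd.read_csv(path, encoding="utf-8-sig",
                     converters={"image_paths": str, "flash_flags": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise BilicamError(f"manifest {path} is missing columns: {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise BilicamError(f"manifest is missing columns: {missing}")
    scenes.write_manifest(df, path)


def write_results(results: dict, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **results}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_results(path: str | Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    if "schema_version" not in data:
        raise BilicamError(f"{path} is not a bilicam results file (no schema_version)")
    return data


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _setup_logging(level: str, no_timestamps: bool = False) -> None:
    fmt = "%(levelname)s %(name)s %(message)s" if no_timestamps \
        else "%(asctime)s %(levelname)s %(name)s %(message)s"
    logging.basicConfig(stream=sys.stderr, level=level.upper(), format=fmt, force=True)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="JSON or TOML run configuration.")
@click.option("--seed", type=int, default=None, help="Master random seed.")
@click.option("--log-level", default=None, help="Logging level (default INFO).")
@click.option("--no-timestamps", is_flag=True, help="Omit timestamps from logs.")
@click.pass_context
def main(ctx, config_path, seed, log_level, no_timestamps):
    """Smartphone-style bilirubin estimation pipeline on synthetic scenes."""
    cfg = load_config(config_path, seed=seed, verbosity=log_level)
    _setup_logging(cfg.verbosity, no_timestamps)
    ctx.obj = cfg


def _run(fn):
    """Wrap a subcommand body: domain errors exit 1, usage handled by click."""
    try:
        fn()
        return 0
    except BilicamError as exc:
        log.error("%s", exc)
        sys.exit(1)


@main.command("build-db")
@click.option("--camera", default="canonical", type=click.Choice(["canonical", "alternate"]))
@click.option("--illuminant", default="flat", type=click.Choice(["flat", "warm", "cool"]))
@click.option("--grid", "grid_json", default=None,
              help='JSON grid spec, e.g. {"bilirubin_umol_per_L": [0, 100, 200]}.')
@click.option("-o", "--output", required=True, type=click.Path())
@click.pass_obj
def build_db_cmd(cfg, camera, illuminant, grid_json, output):
    """Render the bilirubin-color lookup database to CSV + JSON sidecar."""
    def body():
        grid = GridSpec(**json.loads(grid_json)) if grid_json else GridSpec()
        db = build_lookup(grid, illuminant=standard_illuminants()[illuminant],
                          camera=standard_cameras()[camera])
        out = Path(output)
        db.to_csv(out, out.with_suffix(".json"))
        log.info("wrote %d entries to %s", len(db.entries), out)
    _run(body)


@main.command("render")
@click.option("--bilirubin", type=float, default=150.0)
@click.option("--melanin", type=float, default=0.05)
@click.option("--blood", type=float, default=0.02)
@click.option("--illuminant", default="flat", type=click.Choice(["flat", "warm", "cool"]))
@click.option("--camera", default="canonical", type=click.Choice(["canonical", "alternate"]))
@click.option("-o", "--output", required=True, type=click.Path())
@click.pass_obj
def render_cmd(cfg, bilirubin, melanin, blood, illuminant, camera, output):
    """Render a single card scene to PNG."""
    def body():
        import imageio.v3 as iio
        from .forward_model import ChromophoreState
        layout = scenes.default_layout(cfg.layout_version)
        spec = scenes.SceneSpec(
            layout=layout,
            skin=ChromophoreState(bilirubin, melanin, blood, 0.7),
            illuminant=standard_illuminants()[illuminant],
            camera=standard_cameras()[camera],
            seed=cfg.seed)
        iio.imwrite(output, scenes.render_scene(spec).raster)
        log.info("wrote %s", output)
    _run(body)


@main.command("cohort")
@click.option("--n", "n_subjects", type=int, required=True)
@click.option("-o", "--outdir", required=True, type=click.Path())
@click.pass_obj
def cohort_cmd(cfg, n_subjects, outdir):
    """Simulate a cohort: image sets, truth sidecars and manifest CSV."""
    def body():
        layout = scenes.default_layout(cfg.layout_version)
        manifest, _ = scenes.make_cohort(n_subjects, seed=cfg.seed, layout=layout,
                                         outdir=outdir)
        log.info("wrote %d subjects to %s", len(manifest), outdir)
    _run(body)


@main.command("inspect")
@click.argument("image", type=click.Path(exists=True))
@click.option("--layout", "layout_version", default=None)
@click.option("-o", "--output", required=True, type=click.Path())
@click.pass_obj
def inspect_cmd(cfg, image, layout_version, output):
    """Detect the card in IMAGE and emit the observation as JSON."""
    def body():
        import imageio.v3 as iio
        layout = scenes.default_layout(layout_version or cfg.layout_version)
        raster = iio.imread(image)
        try:
            obs = observe_card(raster, layout)
        except CardNotDetectedError as exc:
            write_results({"card_detected": False, "error": str(exc)}, output)
            log.warning("%s", exc)
            return
        write_results({
            "card_detected": True,
            "marker_px": obs.marker_px,
            "distance_cm": obs.distance_cm,
            "barcode_id": obs.barcode_id,
            "patches": {pid: {"mean_rgb": s.mean_rgb, "sd": s.channel_sd,
                              "missing": s.missing}
                        for pid, s in obs.patch_samples.items()},
            "skin": {"mean_rgb": obs.skin_sample.mean_rgb,
                     "missing": obs.skin_sample.missing},
        }, output)
        log.info("wrote %s", output)
    _run(body)


def _load_set_images(set_dir: Path, subject_id: str | None = None) -> dict[str, list]:
    import imageio.v3 as iio
    manifest = read_manifest(set_dir / "manifest.csv")
    if subject_id is not None:
        manifest = manifest[manifest["subject_id"] == subject_id]
    out = {}
    for _, row in manifest.iterrows():
        paths = [p for p in str(row["image_paths"]).split(";") if p]
        out[row["subject_id"]] = [iio.imread(p) for p in paths]
    return out


@main.command("measure")
@click.argument("set_dir", type=click.Path(exists=True, file_okay=False))
@click.option("--db", "db_path", required=True, type=click.Path(exists=True))
@click.option("--subject", default=None, help="Measure a single subject id.")
@click.option("-o", "--output", required=True, type=click.Path())
@click.pass_obj
def measure_cmd(cfg, set_dir, db_path, subject, output):
    """Measure bilirubin for every image set in SET_DIR."""
    def body():
        layout = scenes.default_layout(cfg.layout_version)
        db = LookupDatabase.from_csv(db_path)
        results = []
        for sid, images in _load_set_images(Path(set_dir), subject).items():
            res = measure_set(images, layout, db, qc_config=cfg.qc_config(),
                              rule=cfg.set_rule())
            log.info("subject %s: estimate=%s included=%s", sid,
                     res.set_estimate_umol_L, res.set_decision.include)
            results.append({
                "subject_id": sid,
                "estimate_umol_L": res.set_estimate_umol_L,
                "estimate_mg_dL": res.set_estimate_mg_dL,
                "iqr_umol_L": res.estimate_iqr_umol_L,
                "included": res.set_decision.include,
                "n_passing": res.set_decision.n_passing,
                "per_image": res.per_image,
            })
        write_results({"results": results}, output)
    _run(body)


@main.command("qc")
@click.argument("set_dir", type=click.Path(exists=True, file_okay=False))
@click.option("--db", "db_path", required=True, type=click.Path(exists=True))
@click.option("-o", "--output", default=None, type=click.Path())
@click.pass_obj
def qc_cmd(cfg, set_dir, db_path, output):
    """Print the QC accounting table for a cohort directory as CSV."""
    def body():
        from .quality_control import SkinHull, decide_set, run_image_qc
        from .calibration import CalibrationError, fit_color_correction
        layout = scenes.default_layout(cfg.layout_version)
        db = LookupDatabase.from_csv(db_path)
        hull = SkinHull(db)
        rows = []
        for sid, images in _load_set_images(Path(set_dir)).items():
            reports = []
            for raster in images:
                try:
                    obs = observe_card(raster, layout)
                except CardNotDetectedError:
                    obs = None
                reports.append(run_image_qc(obs, layout, hull, cfg.qc_config()))
            decision = decide_set(reports, rule=cfg.set_rule())
            code = ""
            if not decision.include:
                codes = [r.failure_codes[0] for r in reports if r.failure_codes]
                code = codes[0] if codes else "unknown"
            rows.append({"subject_id": sid, "exclusion_code": code})
        table = qc_summary(pd.DataFrame(rows))
        csv = table.to_csv(index=False)
        if output:
            Path(output).write_text(csv)
        else:
            click.echo(csv, nl=False)
    _run(body)


@main.command("validate")
@click.option("--manifest", "manifest_path", required=True, type=click.Path(exists=True))
@click.option("--results", "results_path", required=True, type=click.Path(exists=True))
@click.option("-o", "--output", required=True, type=click.Path())
@click.pass_obj
def validate_cmd(cfg, manifest_path, results_path, output):
    """Compare measured estimates against manifest truth (scatter/BA/ROC)."""
    def body():
        manifest = read_manifest(manifest_path)
        payload = read_results(results_path)
        results = pd.DataFrame([{"subject_id": r["subject_id"],
                                 "estimate_umol_L": r["estimate_umol_L"]}
                                for r in payload["results"]])
        report = validate_cohort(manifest, results)
        out = {
            "n_pairs": report["n_pairs"],
            "pearson_r": report["agreement"].pearson_r,
            "p_value": report["agreement"].p_value,
            "bias_umol_L": report["agreement"].bias,
            "loa_lower_umol_L": report["agreement"].loa_lower,
            "loa_upper_umol_L": report["agreement"].loa_upper,
            "median_abs_error_umol_L": report["median_abs_error_umol_L"],
            "join_failures": report["join_failures"],
        }
        if report["screening"] is not None:
            s = report["screening"]
            out.update({"auc": s.auc, "youden_cutoff_umol_L": s.youden_cutoff,
                        "sensitivity": s.sensitivity, "specificity": s.specificity,
                        "disease_threshold_umol_L": s.disease_threshold})
        write_results(out, output)
        log.info("wrote %s", output)
    _run(body)


if __name__ == "__main__":
    main()
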