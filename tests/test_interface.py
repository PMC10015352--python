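"""CLI and plumbing tests: exit codes, config validation, manifest IO, and
end-to-end determinism of the cohort -> measure -> validate chain."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from bilicam import interface
from bilicam.forward_model import BilicamError


TINY_GRID = ('{"bilirubin_umol_per_L": [0, 50, 100, 150, 200, 250, 300],'
             ' "melanin_fraction": [0.03, 0.06, 0.09, 0.12],'
             ' "blood_fraction": [0.01, 0.025, 0.04]}')


@pytest.fixture(scope="module")
def runner():
    return CliRunner()


@pytest.fixture(scope="module")
def workspace(tmp_path_factory, runner):
    """A rendered 2-subject cohort plus a small database, built via the CLI."""
    root = tmp_path_factory.mktemp("cli")
    r = runner.invoke(interface.main, ["--seed", "7", "build-db", "--grid",
                                       TINY_GRID, "-o", str(root / "db.csv")])
    assert r.exit_code == 0, r.output
    r = runner.invoke(interface.main, ["--seed", "7", "cohort", "--n", "2",
                                       "-o", str(root / "cohort")])
    assert r.exit_code == 0, r.output
    return root


class TestExitCodes:
    def test_unknown_subcommand_is_usage_error(self, runner):
        assert runner.invoke(interface.main, ["bogus"]).exit_code == 2

    def test_missing_required_option_is_usage_error(self, runner):
        assert runner.invoke(interface.main, ["measure"]).exit_code == 2

    def test_domain_error_exits_one(self, runner, tmp_path):
        bad = tmp_path / "empty"
        bad.mkdir()
        (bad / "manifest.csv").write_text("subject_id\nS1\n")
        r = runner.invoke(interface.main,
                          ["measure", str(bad), "--db", str(bad / "manifest.csv"),
                           "-o", str(tmp_path / "o.json")])
        assert r.exit_code == 1


class TestRunConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(BilicamError, match="invalid configuration"):
            interface.load_config(None, typo_key=1)

    def test_json_config_file_loaded(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"distance_tol_cm": 7.5, "seed": 3}))
        cfg = interface.load_config(path)
        assert cfg.qc_config().distance_tol_cm == 7.5
        assert cfg.seed == 3

    def test_set_rule_requires_both_fields(self):
        assert interface.load_config(None, set_rule_m=3).set_rule() is None
        assert interface.load_config(None, set_rule_m=3, set_rule_n=4).set_rule() == (3, 4)


class TestManifestIO:
    def test_round_trip_stable(self, tmp_path):
        from bilicam import synthetic_scenes as sc
        manifest, _ = sc.make_cohort(4, seed=5, render=False)
        path = tmp_path / "m.csv"
        interface.write_manifest(manifest, path)
        back = interface.read_manifest(path)
        pd.testing.assert_frame_equal(back, manifest)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,image_paths\nS1,a.png\n")
        with pytest.raises(BilicamError, match="true_tsb_umol_L"):
            interface.read_manifest(path)

    def test_utf8_bom_tolerated(self, tmp_path):
        from bilicam import synthetic_scenes as sc
        manifest, _ = sc.make_cohort(2, seed=5, render=False)
        path = tmp_path / "bom.csv"
        with open(path, "w", encoding="utf-8-sig", newline="") as fh:
            manifest.to_csv(fh, index=False)
        back = interface.read_manifest(path)
        assert list(back["subject_id"]) == list(manifest["subject_id"])

    def test_results_schema_guard(self, tmp_path):
        path = tmp_path / "r.json"
        path.write_text("{}")
        with pytest.raises(BilicamError, match="schema_version"):
            interface.read_results(path)


class TestPipelineCommands:
    def test_measure_writes_estimates(self, runner, workspace, tmp_path):
        out = tmp_path / "meas.json"
        r = runner.invoke(interface.main,
                          ["measure", str(workspace / "cohort"),
                           "--db", str(workspace / "db.csv"), "-o", str(out)])
        assert r.exit_code == 0, r.output
        payload = interface.read_results(out)
        assert len(payload["results"]) == 2
        assert all(row["included"] for row in payload["results"])

    def test_qc_accounting_printed(self, runner, workspace):
        r = runner.invoke(interface.main,
                          ["qc", str(workspace / "cohort"),
                           "--db", str(workspace / "db.csv")])
        assert r.exit_code == 0, r.output
        assert "remaining,2,100.0" in r.output

    def test_validate_reports_statistics(self, runner, workspace, tmp_path):
        meas = tmp_path / "meas.json"
        report = tmp_path / "report.json"
        runner.invoke(interface.main, ["measure", str(workspace / "cohort"),
                                       "--db", str(workspace / "db.csv"),
                                       "-o", str(meas)])
        r = runner.invoke(interface.main,
                          ["validate", "--manifest",
                           str(workspace / "cohort" / "manifest.csv"),
                           "--results", str(meas), "-o", str(report)])
        assert r.exit_code == 0, r.output
        payload = interface.read_results(report)
        assert payload["n_pairs"] == 2
        assert "bias_umol_L" in payload

    def test_chain_is_deterministic(self, runner, workspace, tmp_path):
        outputs = []
        for tag in ("a", "b"):
            d = tmp_path / tag
            runner.invoke(interface.main, ["--seed", "11", "cohort", "--n", "2",
                                           "-o", str(d)])
            meas = tmp_path / f"meas_{tag}.json"
            runner.invoke(interface.main, ["measure", str(d), "--db",
                                           str(workspace / "db.csv"), "-o", str(meas)])
            rep = tmp_path / f"rep_{tag}.json"
            runner.invoke(interface.main, ["validate", "--manifest",
                                           str(d / "manifest.csv"),
                                           "--results", str(meas), "-o", str(rep)])
            outputs.append(rep.read_bytes())
        assert outputs[0] == outputs[1]

    def test_rejected_set_is_result_not_error(self, runner, workspace, tmp_path,
                                              layout):
        # hand-build a one-subject set whose images all fail QC (deep shadow)
        import imageio.v3 as iio
        from bilicam import synthetic_scenes as sc
        from conftest import make_spec
        d = tmp_path / "badset"
        d.mkdir()
        spec = make_spec(layout, shadow=sc.ShadowSpec(0.0, 0.45))
        paths = []
        for i, im in enumerate(sc.make_image_set(spec, 0, 4)):
            p = d / f"S0001_{i}.png"
            iio.imwrite(p, im.raster)
            paths.append(str(p))
        manifest = pd.DataFrame([{
            "subject_id": "S0001", "image_paths": ";".join(paths),
            "true_tsb_umol_L": 150.0, "bilirubin_umol_per_L": 150.0,
            "melanin_fraction": 0.05, "blood_fraction": 0.02,
            "flash_flags": "0;0;0;0"}])
        interface.write_manifest(manifest, d / "manifest.csv")
        out = tmp_path / "rej.json"
        r = runner.invoke(interface.main,
                          ["measure", str(d), "--db", str(workspace / "db.csv"),
                           "-o", str(out)])
        assert r.exit_code == 0, r.output
        payload = interface.read_results(out)
        assert payload["results"][0]["included"] is False
        assert payload["results"][0]["estimate_umol_L"] is None
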