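"""File formats, configuration round-trips, the umbrella pipeline and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from corescale import (RunConfig, SyntheticConfig, generate, read_observed,
                       read_trait_matrix, run_strategy, write_observed,
                       write_trait_matrix)
from corescale.cli import main as cli_main
from conftest import random_matrix


def test_trait_matrix_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    m = random_matrix(rng, 7, 3)
    path = tmp_path / "m.tsv"
    write_trait_matrix(m, path)
    back = read_trait_matrix(path)
    assert back.accession_ids == m.accession_ids
    assert back.trait_names == m.trait_names
    np.testing.assert_allclose(back.values, m.values, rtol=1e-9)


def test_parse_errors_cite_the_line(tmp_path):
    path = tmp_path / "bad.tsv"
    lines = ["accession\tt1\tt2"] + [f"a{i}\t1.0\t2.0" for i in range(6)]
    lines[5] = "a4\t1.0"  # ragged row on file line 6
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="line 6"):
        read_trait_matrix(path)
    lines[5] = "a4\t1.0\tx"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="line 6.*non-numeric"):
        read_trait_matrix(path)
    lines[5] = "a0\t1.0\t2.0"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_trait_matrix(path)


def test_trial_scale_file_shape(tmp_path):
    _, truth = generate(SyntheticConfig(seed=1))
    path = tmp_path / "truth.tsv"
    write_trait_matrix(truth, path)
    with path.open() as fh:
        header = fh.readline().split("\t")
    assert len(header) == 21  # id column + 20 traits
    back = read_trait_matrix(path)
    assert back.n_accessions == 168 and back.n_traits == 20


def test_observed_round_trip(tmp_path):
    observed, _ = generate(SyntheticConfig(
        n_accessions=6, n_traits=2, n_rows=2, n_columns=4, seed=2))
    path = tmp_path / "obs.tsv"
    write_observed(observed, path)
    back = read_observed(path)
    assert len(back.records) == len(observed.records)
    np.testing.assert_allclose(back.records["value"],
                               observed.records["value"], rtol=1e-9)


def test_run_config_round_trips_losslessly(tmp_path):
    cfg = RunConfig(percentages=(10.0, 12.5, 15.0), trait_counts=(1, 2, 3),
                    replications=4, cr_threshold=80.0, seed=13,
                    metric="euclid")
    path = tmp_path / "run.cfg"
    cfg.to_file(path)
    assert RunConfig.from_file(path) == cfg
    with pytest.raises(ValueError, match="unknown config key"):
        RunConfig.from_mapping({"bogus": 1})


def _tiny_config(seed=3):
    return RunConfig(percentages=(15.0, 20.0, 25.0, 30.0),
                     trait_counts=(1, 2, 4, 8), replications=2,
                     validation_percentages=(15.0,), validation_seeds=2,
                     seed=seed)


def test_pipeline_emits_curve_and_manifest(tmp_path):
    manifest = run_strategy(_tiny_config(), tmp_path / "run")
    stages = [s["stage"] for s in manifest["stages"]]
    assert stages == ["simulate", "surface", "select", "invert", "validate"]
    curve = (tmp_path / "run" / "optimal_curve.tsv").read_text().splitlines()
    assert len(curve) == 1 + 4  # header + one row per trait count
    saved = json.loads((tmp_path / "run" / "manifest.json").read_text())
    assert saved["config_digest"] == _tiny_config().digest()


def test_pipeline_rerun_is_byte_identical(tmp_path):
    run_strategy(_tiny_config(), tmp_path / "r1")
    run_strategy(_tiny_config(), tmp_path / "r2")
    for name in ("surface.tsv", "fits.tsv", "optimal_curve.tsv",
                 "validation.tsv", "pca_projection.tsv", "manifest.json"):
        assert (tmp_path / "r1" / name).read_bytes() == \
            (tmp_path / "r2" / name).read_bytes()


def test_cli_optimal_reproduces_published_endpoints(tmp_path):
    runner = CliRunner()
    out = tmp_path / "curve.tsv"
    result = runner.invoke(cli_main, ["optimal", "--family", "6",
                                      "--cr", "80", "--traits", "1:20",
                                      "--out", str(out)])
    assert result.exit_code == 0, result.output
    rows = [ln.split("\t") for ln in out.read_text().splitlines()[1:]]
    curve = {int(r[0]): float(r[1]) for r in rows}
    assert curve[1] == 25.01 and curve[20] == 6.07


def test_cli_sample_and_evaluate(tmp_path):
    rng = np.random.default_rng(5)
    m = random_matrix(rng, 20, 3)
    matrix_path = tmp_path / "m.tsv"
    write_trait_matrix(m, matrix_path)
    runner = CliRunner()
    ids_out = tmp_path / "ids.txt"
    res = runner.invoke(cli_main, ["sample", str(matrix_path),
                                   "-p", "50", "-s", "1",
                                   "--ids-out", str(ids_out)])
    assert res.exit_code == 0, res.output
    assert len(ids_out.read_text().split()) == 10
    res = runner.invoke(cli_main, ["evaluate", str(matrix_path),
                                   str(ids_out),
                                   "--out", str(tmp_path / "ev.tsv")])
    assert res.exit_code == 0, res.output
    assert "CR" in res.output
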